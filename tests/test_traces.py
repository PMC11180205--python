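"""FRET observables, segmentation, dwell extraction, fates, efficiencies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sen1kin import (
    Condition,
    KineticScheme,
    TrajectoryConfig,
    SegmentThresholds,
    classify_codissociation,
    classify_pol2_fate,
    compute_fret,
    correct_fret,
    extract_dwells,
    gamma_factor,
    lag_zero_extrapolation,
    pife_ratio,
    render_trajectory,
    segment_trace,
    simulate_pathway,
    termination_efficiency,
)
from sen1kin.core import StateSegment


class TestComputeFret:
    def test_arithmetic(self):
        assert compute_fret(40.0, 60.0) == pytest.approx(0.6)

    def test_zero_acceptor(self):
        assert compute_fret(25.0, 0.0) == 0.0

    def test_all_zero_frame_invalid(self):
        out = compute_fret(np.array([0.0, 50.0]), np.array([0.0, 50.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)

    def test_noiseless_stall_trace_constant(self, scheme, noiseless_config):
        cond = Condition()
        ev = simulate_pathway(scheme, cond, seed=3)
        traj = render_trajectory(ev, noiseless_config, cond, seed=3)
        g = traj.green_frames()
        t = traj.times[g]
        sel = (t >= ev.stall_start) & (t < ev.sen1_bind)
        fret = compute_fret(traj.i_dd[g][sel], traj.i_da[g][sel])
        np.testing.assert_allclose(fret, 0.2, atol=1e-12)


class TestCorrectFret:
    @pytest.mark.parametrize(
        "observed,expected", [(0.8, 0.6861), (0.6, 0.4505)]
    )
    def test_pife_corrected_levels(self, observed, expected):
        assert correct_fret(observed, 1.83) == pytest.approx(expected, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correct_fret(1.2, 1.83)

    @settings(deadline=None, derandomize=True)
    @given(
        f=st.floats(0.0, 1.0),
        r=st.floats(0.2, 5.0),
    )
    def test_identity_bounds_monotone(self, f, r):
        assert correct_fret(f, 1.0) == pytest.approx(f, rel=1e-12, abs=1e-15)
        out = correct_fret(f, r)
        assert 0.0 <= out <= 1.0
        assert correct_fret(0.0, r) == 0.0
        assert correct_fret(1.0, r) == 1.0
        if f < 0.999:
            assert correct_fret(min(f + 1e-3, 1.0), r) >= out


class TestGammaFactor:
    def test_unit_and_double(self):
        assert gamma_factor(100, 20, 40, 120) == pytest.approx(1.0)
        assert gamma_factor(150, 30, 40, 100) == pytest.approx(2.0)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            gamma_factor(100, 20, 40, 40)


class TestPifeRatio:
    def test_constant_windows(self):
        trace = np.r_[np.full(50, 200.0), np.full(50, 100.0)]
        assert pife_ratio(trace, (0, 50), (50, 100)) == pytest.approx(2.0)
        assert pife_ratio(trace, (0, 50), (0, 50)) == pytest.approx(1.0)

    def test_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            pife_ratio(np.r_[np.ones(5), np.zeros(5)], (0, 5), (5, 10))

    def test_recovers_rendering_factor_under_noise(self, scheme):
        cond = Condition()
        config = TrajectoryConfig(duration=40.0, noise_sd=2.0, pife_factor=1.83)
        rng = np.random.default_rng(21)
        ratios = []
        for _ in range(40):
            ev = simulate_pathway(scheme, cond, seed=rng)
            if ev.stall_start - ev.elong_start < 1.0 or ev.sen1_bind - ev.stall_start < 1.0:
                continue
            traj = render_trajectory(ev, config, cond, seed=rng)
            r = traj.red_frames()
            t = traj.times[r]
            a = np.flatnonzero((t >= ev.elong_start) & (t < ev.stall_start))
            b = np.flatnonzero(
                (t >= ev.stall_start) & (t < min(ev.sen1_bind, config.duration))
            )
            ratios.append(pife_ratio(traj.i_aa[r], (a[0], a[-1] + 1), (b[0], b[-1] + 1)))
        assert len(ratios) > 10
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 1.83) < 3 * max(se, 1e-3)


def _truth_boundaries(traj, n_super):
    """Expected (state, first frame) pairs from embedded truth.

    Only boundaries whose true state run is at least the 2-superframe
    minimum dwell are returned — shorter runs are below the segmentation's
    resolution by design.  Assumes no bleaching within the record.
    """
    cp = traj.truth["changepoints"]
    fate = traj.truth["fate"]
    seq = []
    for state, key in (
        ("elongation", "elong_start"),
        ("stall", "stall_start"),
        ("intermediate", "sen1_bind"),
    ):
        if key not in cp:
            break
        seq.append((state, cp[key]))
    else:
        if "termination" in cp:
            seq.append(
                ("dark" if fate == "simultaneous" else "post_termination",
                 cp["termination"])
            )
    out = []
    for i, (state, start) in enumerate(seq):
        if i + 1 < len(seq):
            end = seq[i + 1][1]
        elif state == "post_termination":
            t_pol2 = traj.truth["events"].get("pol2_depart")
            if t_pol2 is None:
                end = n_super
            else:
                # acceptor is read on the red frame, half a superframe after
                # the green sample the changepoint convention refers to
                period = traj.channel_period
                end = int(np.ceil((t_pol2 - period / 2) / period))
        else:
            end = n_super
        if start < n_super and min(end, n_super) - start >= 2:
            out.append((state, start))
    return out


class TestSegmentation:
    def test_noiseless_changepoints_exact(self, noiseless_config):
        scheme = KineticScheme(t0=1e9)  # no bleaching: pure segmentation check
        cond = Condition()
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(20):
            ev = simulate_pathway(scheme, cond, seed=rng)
            traj = render_trajectory(ev, noiseless_config, cond, seed=rng)
            segs = segment_trace(traj)
            starts = {}
            for s in segs:
                starts.setdefault(s.state, s.start_frame)
            n_super = len(traj.green_frames())
            for state, frame in _truth_boundaries(traj, n_super):
                assert starts.get(state) == frame, (state, starts, frame)
                checked += 1
        assert checked > 20

    def test_constant_trace_single_segment(self):
        config = TrajectoryConfig(duration=10.0, noise_sd=0.0)
        n = int(10.0 / 0.02)
        times = np.arange(n) * 0.02
        laser = np.array(["green", "red"] * (n // 2))
        i_dd, i_da = np.full(n, 80.0), np.full(n, 20.0)
        i_aa = np.full(n, 100.0)
        from sen1kin import Trajectory

        traj = Trajectory(times, laser, i_dd, i_da, i_aa, Condition())
        segs = segment_trace(traj)
        assert len(segs) == 1
        assert segs[0].state == "stall"
        assert (segs[0].start_frame, segs[0].end_frame) == (0, n // 2 - 1)

    def test_noisy_changepoints_within_one_frame(self):
        # 5% of the donor intensity scale; intermediate made long-lived so
        # every state is resolvable
        scheme = KineticScheme(k1=2.0, k2=2.0, t0=1e9)
        cond = Condition()
        config = TrajectoryConfig(duration=60.0, noise_sd=5.0)
        rng = np.random.default_rng(17)
        errors = []
        for _ in range(120):
            ev = simulate_pathway(scheme, cond, seed=rng)
            traj = render_trajectory(ev, config, cond, seed=rng)
            segs = segment_trace(traj)
            starts = {}
            for s in segs:
                starts.setdefault(s.state, s.start_frame)
            n_super = len(traj.green_frames())
            for state, frame in _truth_boundaries(traj, n_super):
                if state in starts:
                    errors.append(abs(starts[state] - frame))
                else:
                    errors.append(np.inf)
        errors = np.array(errors)
        assert len(errors) > 200
        assert np.median(errors) <= 1
        assert np.mean(errors <= 1) >= 0.95


class TestExtractDwells:
    def test_duration_arithmetic(self):
        period = 0.04
        segs = [
            StateSegment("stall", 0, 9, 10 * period),
            StateSegment("intermediate", 10, 19, 10 * period),
            StateSegment("stall", 20, 39, 20 * period),
            StateSegment("intermediate", 40, 49, 10 * period),
            StateSegment("stall", 50, 79, 30 * period),
            StateSegment("dark", 80, 99, 20 * period),
        ]
        sample = extract_dwells(segs, "stall", Condition(), record_end_frame=99)
        np.testing.assert_allclose(sorted(sample.durations), [0.4, 0.8, 1.2])

    def test_absent_state_gives_none(self):
        segs = [StateSegment("stall", 0, 99, 4.0)]
        assert extract_dwells(segs, "intermediate", Condition()) is None

    def test_record_end_censoring(self):
        segs = [
            StateSegment("intermediate", 0, 9, 0.4),
            StateSegment("stall", 10, 99, 3.6),
        ]
        sample = extract_dwells(segs, "stall", Condition(), record_end_frame=99)
        assert sample.censored_flags.tolist() == [True]

    def test_simulated_stall_dwells_match_truth(self):
        # noiseless round trip: simulate -> segment -> extract equals truth
        scheme = KineticScheme(t0=1e9, k1=1.0, k2=1.0)
        cond = Condition()
        config = TrajectoryConfig(duration=120.0, noise_sd=0.0)
        rng = np.random.default_rng(23)
        extracted, truth_frames = [], []
        for _ in range(60):
            ev = simulate_pathway(scheme, cond, seed=rng)
            traj = render_trajectory(ev, config, cond, seed=rng)
            cp = traj.truth["changepoints"]
            n_super = len(traj.green_frames())
            # completed stall followed by a resolvable intermediate
            if "termination" not in cp or cp["termination"] - cp["sen1_bind"] < 2:
                continue
            segs = segment_trace(traj)
            sample = extract_dwells(segs, "stall", cond, record_end_frame=n_super - 1)
            assert sample is not None
            extracted.extend(sample.uncensored())
            truth_frames.append(cp["sen1_bind"] - cp["stall_start"])
        expected = np.array(truth_frames) * config.channel_period
        got = np.array(extracted)
        assert len(got) == len(expected) > 30
        np.testing.assert_allclose(np.sort(got), np.sort(expected), atol=1e-9)


class TestCodissociation:
    def test_categories(self):
        assert classify_codissociation(100, 100) == ("simultaneous", 0)
        assert classify_codissociation(103, 100) == ("delayed", 3)
        assert classify_codissociation(97, 100) == ("early", -3)
        assert classify_codissociation(102, 100, tol_frames=2)[0] == "simultaneous"

    def test_partition_sums(self, rng):
        lags = rng.integers(-3, 4, 200)
        cats = [classify_codissociation(100 + l, 100)[0] for l in lags]
        total = sum(cats.count(c) for c in ("simultaneous", "delayed", "early"))
        assert total == 200


class TestLagZeroExtrapolation:
    def test_exact_on_noise_free_exponential(self):
        tau = 2.0
        amp = 64.0
        lags = []
        for n in range(1, 6):
            lags.extend([n] * int(round(amp * np.exp(-n / tau))))
        pred, se, info = lag_zero_extrapolation(lags)
        assert info["tau_frames"] == pytest.approx(tau, rel=0.05)
        assert pred == pytest.approx(info["A"], rel=1e-9)
        # counts were rounded; prediction still close to the amplitude
        assert pred == pytest.approx(amp, rel=0.05)

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            lag_zero_extrapolation([1, 2])

    def test_holdout_prediction_matches_zero_bin(self, rng):
        # discrete exponential on n >= 0; hold out the zero bin and predict it
        tau = 1.8
        n = rng.geometric(1 - np.exp(-1 / tau), size=1000) - 1
        zero_count = int((n == 0).sum())
        pred, se, _ = lag_zero_extrapolation(n[n >= 1])
        combined = 3 * (se + np.sqrt(zero_count))
        assert abs(pred - zero_count) < combined


class TestPol2Fate:
    def test_forced_simultaneous(self):
        recs = [
            {"molecule_id": f"m{i}", "rna_end_frame": 100, "pol2_end_frame": 100}
            for i in range(20)
        ]
        fates, counts, mean, se = classify_pol2_fate(recs)
        assert counts == {"simultaneous": 20}
        assert mean is None

    @pytest.mark.parametrize("true_mean,n", [(36.0, 74), (2.1, 120)])
    def test_after_lag_exponential_mean(self, true_mean, n, rng):
        period = 0.04
        lags = rng.exponential(true_mean, n)
        recs = [
            {
                "molecule_id": f"m{i}",
                "rna_end_frame": 500,
                "pol2_end_frame": 500 + max(int(round(l / period)), 1),
            }
            for i, l in enumerate(lags)
        ]
        _, counts, mean, se = classify_pol2_fate(recs, channel_period=period)
        assert counts["after"] == n
        assert abs(mean - true_mean) < 3 * true_mean / np.sqrt(n)

    def test_retained_flag(self):
        recs = [{"molecule_id": "m0", "rna_end_frame": 10, "retained": True}]
        fates, counts, _, _ = classify_pol2_fate(recs)
        assert counts == {"retained": 1}
        assert fates[0].pol2_end_frame is None


class TestTerminationEfficiency:
    @pytest.mark.parametrize(
        "released,total,expected",
        [(170, 350, 0.4857), (166, 406, 0.4089), (0, 10, 0.0)],
    )
    def test_values(self, released, total, expected):
        p, se = termination_efficiency(released, total)
        assert p == pytest.approx(expected, abs=1e-4)
        if released == 0:
            assert se == 0.0
        else:
            assert se == pytest.approx(np.sqrt(p * (1 - p) / total))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            termination_efficiency(0, 0)
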