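"""Trace processing: FRET/PIFE observables, segmentation, dwells, fates.

Turns per-frame ALEX intensity series into the quantities the kinetic
analysis consumes: proximity-ratio FRET (optionally corrected for
protein-induced fluorescence enhancement of the acceptor), PIFE ratios,
threshold-based state segmentation with hysteresis, dwell-time tables with
censoring flags, Sen1/RNA co-dissociation lag classes, Pol II fate classes,
and termination efficiencies.

FRET here is the uncorrected proximity ratio ``i_da / (i_dd + i_da)``;
gamma correction is available separately and off by default.  Segmentation
is automated thresholding (the study selected traces manually); bands and
the 2-frame minimum dwell are configurable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import Condition, DwellSample, FateRecord, StateSegment, Trajectory

__all__ = [
    "compute_fret",
    "correct_fret",
    "gamma_factor",
    "pife_ratio",
    "SegmentThresholds",
    "segment_trace",
    "extract_dwells",
    "classify_codissociation",
    "lag_zero_extrapolation",
    "classify_pol2_fate",
    "termination_efficiency",
]


def compute_fret(i_dd, i_da, floor: float = 1e-9):
    """Element-wise proximity ratio ``i_da / (i_dd + i_da)``.

    Frames whose total intensity falls below ``floor`` (including all-zero
    frames) are returned as NaN rather than computed.
    """
    i_dd = np.asarray(i_dd, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    if i_dd.shape != i_da.shape:
        raise ValueError("i_dd and i_da must have equal length")
    total = i_dd + i_da
    out = np.full(i_dd.shape, np.nan)
    valid = total > floor
    out[valid] = i_da[valid] / total[valid]
    return out if out.ndim else float(out)


def correct_fret(fret, pife_ratio: float):
    """Correct a proximity ratio for acceptor PIFE enhancement.

    ``FRET' = FRET / (r * (1 - FRET) + FRET)`` with ``r`` the PIFE ratio.
    Identity at ``r = 1``; maps [0, 1] onto [0, 1] and is strictly
    increasing in the input.
    """
    f = np.asarray(fret, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fret must lie in [0, 1]")
    if pife_ratio <= 0:
        raise ValueError("pife_ratio must be > 0")
    out = f / (pife_ratio * (1.0 - f) + f)
    return out if out.ndim else float(out)


def gamma_factor(i_a_pre, i_a_post, i_d_pre, i_d_post) -> float:
    """Detection-correction factor from an acceptor photobleaching step.

    ``gamma = (I_A - I'_A) / (I'_D - I_D)`` with primes denoting intensities
    after the acceptor bleaches.
    """
    denom = i_d_post - i_d_pre
    if denom == 0:
        raise ZeroDivisionError("donor intensity unchanged across the bleach step")
    return (i_a_pre - i_a_post) / denom


def pife_ratio(trace, window_a, window_b) -> float:
    """Mean intensity in ``window_a`` over mean intensity in ``window_b``.

    Windows are (start, stop) frame slices into ``trace`` (stop exclusive).
    Quantifies PIFE as the enhanced-region over reference-region Cy5 level.
    """
    trace = np.asarray(trace, dtype=float)
    a = trace[slice(*window_a)]
    b = trace[slice(*window_b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("windows must be non-empty and inside the trace")
    mb = np.nanmean(b)
    if mb == 0:
        raise ZeroDivisionError("reference window has zero mean")
    return float(np.nanmean(a) / mb)


@dataclass
class SegmentThresholds:
    """Band levels and floors for threshold segmentation.

    ``fret_levels`` are the *observed* proximity-ratio levels of the four
    donor-visible states (defaults match the renderer: PIFE-inflated
    pre-elongation/elongation, 0.2 stall, 0.45 intermediate).  Frames whose
    donor-side total drops below ``intensity_floor`` are ``dark`` on the
    green channel; the red channel then decides ``post_termination`` vs
    ``dark``.  Runs shorter than ``min_dwell_frames`` superframes are merged
    into their neighbor; ``median_width`` > 1 applies a running median to
    the FRET series before classification (odd width, preserves noiseless
    changepoints).
    """

    fret_levels: dict = field(
        default_factory=lambda: {
            "pre_elongation": 0.6466,
            "elongation": 0.8102,
            "stall": 0.2,
            "intermediate": 0.45,
        }
    )
    intensity_floor: float = 20.0
    min_dwell_frames: int = 2
    median_width: int = 3

    @classmethod
    def from_config(cls, config) -> "SegmentThresholds":
        """Derive observed band levels from a rendering configuration."""
        levels = {}
        for state in ("pre_elongation", "elongation", "stall", "intermediate"):
            _, f, _ = config.intensity_levels[state]
            if state in config.pife_states and config.pife_on_da:
                r = config.pife_factor
                f = r * f / ((1.0 - f) + r * f)
            levels[state] = f
        return cls(fret_levels=levels, intensity_floor=config.intensity_floor)


def _running_median(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or x.size < width:
        return x
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.median(np.lib.stride_tricks.sliding_window_view(xp, width), axis=-1)


def segment_trace(
    traj: Trajectory, thresholds: Optional[SegmentThresholds] = None
) -> list[StateSegment]:
    """Assign each ALEX superframe a state and return maximal segments.

    One superframe pairs a green-laser frame (donor-side intensities, FRET)
    with the following red-laser frame (acceptor presence).  Donor-visible
    superframes are classified to the nearest FRET band; donor-dark ones are
    ``post_termination`` while the acceptor survives, else ``dark``.  Never
    raises on noisy data: a trace with no classifiable frame returns an
    empty list.
    """
    if thresholds is None:
        thresholds = SegmentThresholds()
    green = traj.green_frames()
    red = traj.red_frames()
    n_super = min(len(green), len(red))
    if n_super == 0:
        return []

    g = green[:n_super]
    r = red[:n_super]
    total_g = traj.i_dd[g] + traj.i_da[g]
    fret = compute_fret(traj.i_dd[g], traj.i_da[g], floor=thresholds.intensity_floor)
    fret = np.where(np.isnan(fret), -1.0, fret)
    fret = _running_median(fret, thresholds.median_width)
    aa = traj.i_aa[r]

    names = list(thresholds.fret_levels)
    levels = np.array([thresholds.fret_levels[s] for s in names])
    states = np.empty(n_super, dtype=object)
    donor_alive = total_g > thresholds.intensity_floor
    acceptor_alive = aa > thresholds.intensity_floor
    for i in range(n_super):
        if donor_alive[i] and fret[i] >= 0:
            states[i] = names[int(np.argmin(np.abs(levels - fret[i])))]
        elif acceptor_alive[i]:
            states[i] = "post_termination"
        else:
            states[i] = "dark"

    # merge runs shorter than the minimum dwell into the preceding state
    runs = []  # (state, start, end) inclusive
    start = 0
    for i in range(1, n_super):
        if states[i] != states[start]:
            runs.append([states[start], start, i - 1])
            start = i
    runs.append([states[start], start, n_super - 1])
    min_dwell = max(1, thresholds.min_dwell_frames)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for idx, run in enumerate(runs):
            if run[2] - run[1] + 1 < min_dwell:
                if idx > 0:
                    runs[idx - 1][2] = run[2]
                else:
                    runs[1][1] = run[1]
                runs.pop(idx)
                # re-merge identical neighbors
                j = 1
                while j < len(runs):
                    if runs[j][0] == runs[j - 1][0]:
                        runs[j - 1][2] = runs[j][2]
                        runs.pop(j)
                    else:
                        j += 1
                changed = True
                break

    period = traj.channel_period
    return [
        StateSegment(state=s, start_frame=a, end_frame=b, duration=(b - a + 1) * period)
        for s, a, b in runs
    ]


def extract_dwells(
    segments: Sequence[StateSegment],
    state: str,
    condition: Condition,
    record_end_frame: Optional[int] = None,
) -> Optional[DwellSample]:
    """Collect durations of the named state from one or more segmentations.

    ``segments`` may be a flat list (one trace) or a list of lists (many
    traces).  A dwell is flagged censored when its segment touches the end
    of the record (``record_end_frame``, or the last segment's end when not
    given) or is cut short by the trace going dark — in both cases the
    underlying kinetic wait was truncated, not completed.
    Returns None when the state never occurs (an ``n = 0`` sample).
    """
    if segments and isinstance(segments[0], StateSegment):
        per_trace = [list(segments)]
    else:
        per_trace = [list(s) for s in segments]
    durations, censored = [], []
    for segs in per_trace:
        if not segs:
            continue
        end = record_end_frame if record_end_frame is not None else segs[-1].end_frame
        for i, seg in enumerate(segs):
            if seg.state != state:
                continue
            durations.append(seg.duration)
            at_end = seg.end_frame >= end
            cut_dark = i + 1 < len(segs) and segs[i + 1].state == "dark" and state not in (
                "intermediate",
                "post_termination",
            )
            censored.append(at_end or cut_dark)
    if not durations:
        return None
    return DwellSample(
        durations=np.array(durations),
        condition=condition,
        state=state,
        censored_flags=np.array(censored, dtype=bool),
    )


def classify_codissociation(
    sen1_end_frame: int, rna_end_frame: int, tol_frames: int = 0
):
    """Classify a Sen1/RNA co-dissociation event by its frame lag.

    Lag = Sen1 disappearance frame minus RNA disappearance frame.  Within
    ``tol_frames`` of zero the dissociation is simultaneous; positive lags
    are delayed Sen1 departures, negative ones early departures.
    """
    lag = int(sen1_end_frame) - int(rna_end_frame)
    if abs(lag) <= tol_frames:
        category = "simultaneous"
    elif lag > 0:
        category = "delayed"
    else:
        category = "early"
    return category, lag


def lag_zero_extrapolation(delayed_lags: Sequence[int]):
    """Extrapolate the expected number of zero-lag events from delayed ones.

    Bins the positive frame lags into unit-frame bins (1 .. max lag), fits
    the per-bin counts to a single exponential ``A * exp(-n / tau)``, and
    extrapolates to ``n = 0``: the prediction is ``A`` with its propagated
    standard error.  Used to test whether apparently simultaneous
    dissociations are merely lags below the temporal resolution.
    """
    lags = np.asarray(delayed_lags, dtype=float)
    if lags.size < 3:
        raise ValueError("need at least 3 delayed events")
    if np.any(lags < 1):
        raise ValueError("delayed lags must be >= 1 frame")
    n_max = int(lags.max())
    bins = np.arange(1, n_max + 1)
    counts = np.array([(np.rint(lags) == n).sum() for n in bins], dtype=float)

    def model(n, A, tau):
        return A * np.exp(-n / tau)

    p0 = [max(counts.max(), 1.0) * math.e, max(lags.mean(), 0.5)]
    popt, pcov = curve_fit(model, bins, counts, p0=p0, maxfev=10000)
    A, tau = popt
    pred = model(0.0, A, tau)
    se = float(np.sqrt(max(pcov[0, 0], 0.0)))
    return float(pred), se, {"A": float(A), "tau_frames": float(tau), "counts": counts}


def classify_pol2_fate(
    records: Sequence[dict],
    channel_period: float = 0.04,
    tol_frames: int = 0,
):
    """Classify per-molecule Pol II fate relative to RNA release.

    ``records`` carry ``molecule_id``, ``rna_end_frame`` and either
    ``pol2_end_frame`` or ``retained=True``.  Categories: Pol II leaves
    ``before``, ``simultaneous`` with (within ``tol_frames``), or ``after``
    RNA release, or is ``retained`` to the end of the record.  For the
    ``after`` class the lag times are summarized by their exponential
    mean ``1/k4`` with SE = mean / sqrt(n).

    Returns ``(fate_records, counts, after_mean_s, after_se_s)``; the mean
    entries are None when no ``after`` events exist.
    """
    out = []
    after_lags = []
    for rec in records:
        rna_end = int(rec["rna_end_frame"])
        if rec.get("retained") or rec.get("pol2_end_frame") is None:
            out.append(FateRecord(rec["molecule_id"], rna_end, None, "retained", None))
            continue
        lag = int(rec["pol2_end_frame"]) - rna_end
        if abs(lag) <= tol_frames:
            cat = "simultaneous"
        elif lag > 0:
            cat = "after"
            after_lags.append(lag * channel_period)
        else:
            cat = "before"
        out.append(
            FateRecord(rec["molecule_id"], rna_end, int(rec["pol2_end_frame"]), cat, lag)
        )
    counts = Counter(r.category for r in out)
    if after_lags:
        mean = float(np.mean(after_lags))
        se = mean / math.sqrt(len(after_lags))
    else:
        mean = se = None
    return out, dict(counts), mean, se


def termination_efficiency(n_released: int, n_total: int):
    """Fraction of complexes whose RNA is released, with binomial SE."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_released <= n_total:
        raise ValueError("n_released must lie in [0, n_total]")
    p = n_released / n_total
    se = math.sqrt(p * (1.0 - p) / n_total)
    return p, se
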