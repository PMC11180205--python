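"""Synthetic-data generator: dwell samples, pathway events, ALEX trajectories.

Every downstream stage of the pipeline (segmentation, dwell extraction,
fitting) is tested against data produced here with known ground truth,
because the study's raw trajectories are not available in machine-usable
form.  The generator follows the termination kinetic scheme: Gaussian
elongation to the stall site, exponential Sen1 arrival at rate
``k_plus * S``, a hypoexponential intermediate lifetime (rates ``k1``,
``k2``), simultaneous Sen1/RNA departure, a branched Pol II fate, an
exponential post-termination Sen1-on-RNA dwell (``k3``), and independent
exponential photobleaching clocks (mean ``t0``) per fluorophore.

Randomness: one named, seedable stream per molecule, spawned from the
dataset seed via ``numpy.random.SeedSequence``, so any subset of molecules
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    FATE_LABELS,
    Condition,
    DwellSample,
    KineticScheme,
    Trajectory,
    TrajectoryConfig,
)
from .models import bp_to_um

__all__ = [
    "PathwayEvents",
    "sample_dwells",
    "simulate_pathway",
    "render_trajectory",
    "simulate_dataset",
]

_DWELL_MODELS = ("single_exp", "exp_bleach", "smmm", "two_step")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_two_step(rng, k1, k2, n):
    # sum of the two sequential exponential waits; valid also at k1 == k2
    return rng.exponential(1.0 / k1, n) + rng.exponential(1.0 / k2, n)


def _sample_smmm(rng, k0, k_minus, k_cat, n):
    """Waiting time of the binding/unbinding/catalysis cycle.

    Mechanistic rejection-free simulation: bind after Exp(k0); the bound
    state resolves after Exp(k_minus + k_cat), committing to catalysis with
    probability k_cat / (k_minus + k_cat), else the cycle restarts.
    """
    out = np.zeros(n)
    pending = np.arange(n)
    k_off = k_minus + k_cat
    p_cat = k_cat / k_off
    while pending.size:
        m = pending.size
        out[pending] += rng.exponential(1.0 / k0, m) + rng.exponential(1.0 / k_off, m)
        done = rng.random(m) < p_cat
        pending = pending[~done]
    return out


def sample_dwells(
    model_id: str,
    scheme: KineticScheme,
    condition: Condition,
    n: int,
    seed=None,
) -> DwellSample:
    """Draw ``n`` i.i.d. dwell durations from the named kinetic density.

    ``single_exp``: Sen1-binding waits at rate ``k_plus * sen1_conc``.
    ``exp_bleach``: the same waits censored by an exponential Cy3 bleach of
    mean ``t0`` (observed dwell = min of the two; censored flagged).
    ``smmm``: full binding/unbinding/catalysis cycle waits, bleach-censored.
    ``two_step``: hypoexponential intermediate lifetimes (``k1`` then ``k2``).

    Ground-truth parameters are attached under ``truth``; a fixed ``seed``
    reproduces the sample exactly.
    """
    if model_id not in _DWELL_MODELS:
        raise ValueError(f"unknown dwell model {model_id!r}; choose from {_DWELL_MODELS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    censored = None
    if model_id in ("single_exp", "exp_bleach"):
        rate = scheme.k_plus * condition.sen1_conc
        if rate <= 0:
            raise ValueError("k_plus * sen1_conc must be > 0")
        waits = rng.exponential(1.0 / rate, n)
        truth = {"model_id": model_id, "rate": rate, "k_plus": scheme.k_plus,
                 "S": condition.sen1_conc}
        if model_id == "exp_bleach":
            bleach = rng.exponential(scheme.t0, n)
            censored = bleach < waits
            waits = np.minimum(waits, bleach)
            truth["t0"] = scheme.t0
    elif model_id == "smmm":
        k0 = scheme.k_plus * condition.sen1_conc
        if k0 <= 0 or scheme.k_cat <= 0:
            raise ValueError("k_plus * sen1_conc and k_cat must be > 0")
        waits = _sample_smmm(rng, k0, scheme.k_minus, scheme.k_cat, n)
        bleach = rng.exponential(scheme.t0, n)
        censored = bleach < waits
        waits = np.minimum(waits, bleach)
        truth = {"model_id": model_id, "k_plus": scheme.k_plus,
                 "S": condition.sen1_conc, "k_minus": scheme.k_minus,
                 "k_cat": scheme.k_cat, "t0": scheme.t0}
    else:  # two_step
        k1 = scheme.k1_at(condition.atp_conc)
        if k1 <= 0 or scheme.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")
        waits = _sample_two_step(rng, k1, scheme.k2, n)
        truth = {"model_id": model_id, "k1": k1, "k2": scheme.k2}
    return DwellSample(
        durations=waits,
        condition=condition,
        state="intermediate" if model_id == "two_step" else "stall",
        censored_flags=censored,
        truth=truth,
    )


@dataclass
class PathwayEvents:
    """Ordered ground-truth event times (s) of one simulated molecule.

    ``termination`` is the simultaneous Sen1+RNA departure; ``pol2_depart``
    is None for the retained-throughout fate.  Bleach times are independent
    clocks recorded regardless of whether they fall inside the record.
    """

    elong_start: float
    stall_start: float
    sen1_bind: float
    termination: float
    fate: str
    pol2_depart: Optional[float]
    sen1_rna_depart: float
    cy3_bleach: float
    cy5_bleach: float

    def as_rows(self):
        rows = [
            ("elong_start", self.elong_start),
            ("stall_start", self.stall_start),
            ("sen1_bind", self.sen1_bind),
            ("termination", self.termination),
            ("sen1_rna_depart", self.sen1_rna_depart),
            ("cy3_bleach", self.cy3_bleach),
            ("cy5_bleach", self.cy5_bleach),
        ]
        if self.pol2_depart is not None:
            rows.append(("pol2_depart", self.pol2_depart))
        return rows


def simulate_pathway(
    scheme: KineticScheme, condition: Condition, seed=None
) -> PathwayEvents:
    """Simulate one molecule through the termination scheme.

    Sequence: a deterministic pre-elongation hold, a Gaussian elongation
    duration (truncated positive), exponential Sen1 arrival at rate
    ``k_plus * sen1_conc``, a hypoexponential intermediate lifetime
    (``k1`` then ``k2``), simultaneous Sen1/RNA release, then a Pol II fate
    drawn from ``fate_fractions``:

    - ``simultaneous``: Pol II leaves with the RNA;
    - ``retained_dissociate``: Pol II leaves after Exp(1/k4);
    - ``retained_throughout``: Pol II never leaves within the record;
    - ``sliding``: Pol II diffuses in 1D and reaches the labeled DNA end
      after an exponential capture time of mean ``L^2 / (2 D)``.

    The post-termination Sen1-on-RNA dwell is Exp(1/k3); Cy3/Cy5 bleach
    times are independent Exp(t0) clocks.
    """
    rng = _rng(seed)
    t_elong_start = scheme.pre_elong_s
    elong = -1.0
    while elong <= 0:
        elong = rng.normal(scheme.elong_mean, scheme.elong_sd)
    t_stall = t_elong_start + elong
    rate_bind = scheme.k_plus * condition.sen1_conc
    if rate_bind <= 0:
        raise ValueError("k_plus * sen1_conc must be > 0")
    t_bind = t_stall + rng.exponential(1.0 / rate_bind)
    k1 = scheme.k1_at(condition.atp_conc)
    t_term = t_bind + _sample_two_step(rng, k1, scheme.k2, 1)[0]

    fate = FATE_LABELS[rng.choice(len(FATE_LABELS), p=scheme.fate_probs())]
    if fate == "simultaneous":
        t_pol2 = t_term
    elif fate == "retained_dissociate":
        t_pol2 = t_term + rng.exponential(1.0 / scheme.k4)
    elif fate == "retained_throughout":
        t_pol2 = None
    else:  # sliding
        L_bp = condition.label_distance_bp
        if L_bp is None:
            L_bp = 49.0  # mid-range end-label construct
        mfpt = float(bp_to_um(L_bp)) ** 2 / (2.0 * scheme.D)
        t_pol2 = t_term + rng.exponential(mfpt)

    t_sen1_rna = t_term + rng.exponential(1.0 / scheme.k3)
    return PathwayEvents(
        elong_start=t_elong_start,
        stall_start=t_stall,
        sen1_bind=t_bind,
        termination=t_term,
        fate=fate,
        pol2_depart=t_pol2,
        sen1_rna_depart=t_sen1_rna,
        cy3_bleach=rng.exponential(scheme.t0),
        cy5_bleach=rng.exponential(scheme.t0),
    )


def _inflate_fret(f: float, r: float) -> float:
    """Proximity ratio observed when donor-excited acceptor emission is
    enhanced by PIFE factor ``r`` (exact inverse of the FRET correction)."""
    return r * f / ((1.0 - f) + r * f)


def _state_at(t: float, ev: PathwayEvents, duration: float) -> str:
    if t < ev.elong_start:
        return "pre_elongation"
    if t < ev.stall_start:
        return "elongation"
    if t < ev.sen1_bind:
        return "stall"
    if t < ev.termination:
        return "intermediate"
    pol2_end = ev.pol2_depart if ev.pol2_depart is not None else duration
    if t < pol2_end:
        return "post_termination"
    return "dark"


def render_trajectory(
    events: PathwayEvents,
    config: TrajectoryConfig,
    condition: Optional[Condition] = None,
    molecule_id: str = "mol_0",
    seed=None,
) -> Trajectory:
    """Render one molecule's event sequence into per-frame ALEX intensities.

    Green-laser frames carry donor-excited emission split between ``i_dd``
    and ``i_da`` by the state's FRET level (PIFE-inflated for PIFE-active
    states when ``pife_on_da`` is set); red-laser frames carry ``i_aa``,
    multiplied by ``pife_factor`` in PIFE-active states.  After a
    fluorophore's bleach or departure its emission is zero: Cy3 bleach (or
    RNA release) kills the donor side, Cy5 bleach (or Pol II/DNA departure)
    kills ``i_aa`` and reroutes donor-excited emission entirely into
    ``i_dd``.  Gaussian noise of sd ``noise_sd`` is added to every measured
    sample.  Ground truth (event times, changepoint superframes, fate) is
    embedded in ``Trajectory.truth``.
    """
    if condition is None:
        condition = Condition()
    rng = _rng(seed if seed is not None else config.seed)
    n_lasers = len(config.alex_pattern)
    n_frames = int(np.floor(config.duration / config.frame_period))
    times = np.arange(n_frames) * config.frame_period
    laser = np.array([config.alex_pattern[i % n_lasers] for i in range(n_frames)])

    i_dd = np.full(n_frames, np.nan)
    i_da = np.full(n_frames, np.nan)
    i_aa = np.full(n_frames, np.nan)

    pol2_end = events.pol2_depart if events.pol2_depart is not None else np.inf
    donor_dark_t = min(events.cy3_bleach, events.termination)
    accept_dark_t = min(events.cy5_bleach, pol2_end)

    for i in range(n_frames):
        t = times[i]
        state = _state_at(t, events, config.duration)
        total, fret, aa = config.intensity_levels[state]
        pife = state in config.pife_states
        donor_alive = t < donor_dark_t and state not in ("post_termination", "dark")
        accept_alive = t < accept_dark_t and state != "dark"
        if laser[i] == "green":
            if not donor_alive:
                i_dd[i], i_da[i] = 0.0, 0.0
            else:
                f = fret
                if pife and config.pife_on_da and accept_alive:
                    f = _inflate_fret(f, config.pife_factor)
                if not accept_alive:
                    f = 0.0  # acceptor gone: all emission through the donor
                i_dd[i] = total * (1.0 - f)
                i_da[i] = total * f
        else:
            if not accept_alive:
                i_aa[i] = 0.0
            else:
                i_aa[i] = aa * (config.pife_factor if pife else 1.0)

    if config.noise_sd > 0:
        for arr in (i_dd, i_da, i_aa):
            measured = ~np.isnan(arr)
            arr[measured] += rng.normal(0.0, config.noise_sd, measured.sum())

    period = config.channel_period

    def to_frame(t):
        # first channel superframe whose green sample time >= t
        return int(np.ceil(t / period))

    truth = {
        "fate": events.fate,
        "events": dict(events.as_rows()),
        "changepoints": {
            name: to_frame(t)
            for name, t in events.as_rows()
            if t < config.duration
        },
        "cy3_dark_s": donor_dark_t,
        "cy5_dark_s": accept_dark_t if np.isfinite(accept_dark_t) else None,
        "cy3_bleached": events.cy3_bleach < min(events.termination, config.duration),
        "cy5_bleached": events.cy5_bleach < min(pol2_end, config.duration),
    }
    return Trajectory(
        times=times,
        laser=laser,
        i_dd=i_dd,
        i_da=i_da,
        i_aa=i_aa,
        condition=condition,
        molecule_id=molecule_id,
        channel_period=period,
        truth=truth,
    )


def simulate_dataset(
    conditions: Sequence[Condition],
    scheme: KineticScheme,
    config: TrajectoryConfig,
    seed: int = 0,
):
    """Simulate a multi-condition trajectory dataset with a truth table.

    Returns ``(trajectories, truth_rows)`` where ``trajectories`` is a flat
    list over conditions and molecules and ``truth_rows`` a list of dicts
    (one per ground-truth event) suitable for a DataFrame.  Per-molecule
    RNG streams are spawned from ``seed`` so the output is deterministic.
    """
    if not conditions:
        raise ValueError("at least one condition required")
    labels = [c.label() for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    root = np.random.SeedSequence(seed)
    cond_seqs = root.spawn(len(conditions))
    trajectories = []
    truth_rows = []
    for cond, cseq in zip(conditions, cond_seqs):
        mol_seqs = cseq.spawn(cond.n_molecules)
        for j, mseq in enumerate(mol_seqs):
            rng = np.random.default_rng(mseq)
            events = simulate_pathway(scheme, cond, seed=rng)
            mol_id = f"{cond.label()}_m{j:04d}"
            traj = render_trajectory(events, config, cond, mol_id, seed=rng)
            trajectories.append(traj)
            base = {
                "molecule_id": mol_id,
                "construct": cond.construct,
                "sen1_conc_nM": cond.sen1_conc * 1e9,
                "atp_conc_uM": cond.atp_conc,
                "rna_ext_length_nt": cond.rna_ext_length,
                "fate": events.fate,
            }
            for name, t in events.as_rows():
                truth_rows.append({**base, "event": name, "time_s": t})
    return trajectories, truth_rows
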