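"""Domain containers for single-molecule termination kinetics.

Ground truth for the simulator is a :class:`KineticScheme` — the rate
constants and branch fractions of Sen1-dependent termination: Sen1 binds a
stalled Pol II elongation complex (second-order rate ``k_plus``), translocates
along the nascent RNA hydrolyzing ATP (``k1``), releases Sen1 and RNA upon a
single catalytic ATP hydrolysis (``k2``), after which Sen1 keeps translocating
on the released RNA (``k3``) and Pol II either leaves DNA simultaneously,
leaves after an exponential delay (``k4``), stays bound, or slides along DNA
in 1D (diffusion coefficient ``D``).  Fluorophores bleach on independent
exponential clocks (mean ``t0``).

Measured data are :class:`Trajectory` objects: frame-indexed donor/acceptor
intensities under alternating green/red excitation (ALEX), from which
downstream modules compute FRET, segment states, and extract dwell times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FATE_LABELS",
    "STATE_LABELS",
    "KineticScheme",
    "Condition",
    "TrajectoryConfig",
    "Trajectory",
    "StateSegment",
    "DwellSample",
    "FateRecord",
]

#: Pol II fates after Sen1/RNA release, in branch-fraction order
FATE_LABELS = ("simultaneous", "retained_dissociate", "retained_throughout", "sliding")

#: trace states assignable by segmentation
STATE_LABELS = (
    "pre_elongation",
    "elongation",
    "stall",
    "intermediate",
    "post_termination",
    "dark",
)


@dataclass
class KineticScheme:
    """Ground-truth rate constants and branch fractions.

    Defaults are the values measured for the Sen1 helicase domain acting on
    stalled yeast Pol II elongation complexes at saturating ATP.

    Parameters
    ----------
    k_plus : float
        Second-order Sen1 binding rate constant, M^-1 s^-1.
    k_minus : float
        Unproductive Sen1 dissociation rate before catalysis, s^-1.
    k_cat : float
        Catalytic turnover rate of the bound intermediate, s^-1.
    k1, k2 : float
        Two-step intermediate lifetime: ATP-dependent translocation rate
        ``k1`` (varies with ATP) and single-ATP catalytic release rate
        ``k2`` (shared across ATP conditions), s^-1.
    k3 : float
        Post-termination Sen1-on-RNA dissociation rate, s^-1.
    k4 : float
        Retained-Pol II dissociation rate, s^-1 (mean retention 1/k4).
    t0 : float
        Cy3 photobleaching mean time, s.
    elong_mean, elong_sd : float
        Gaussian elongation-duration parameters, s.
    pre_elong_s : float
        Deterministic pre-elongation hold rendered before transcription
        starts (baseline zone of the record), s.
    fate_fractions : dict
        Probabilities of the four Pol II fates, keys :data:`FATE_LABELS`;
        must sum to 1.
    D : float
        1D diffusion coefficient of sliding Pol II, µm^2 s^-1.
    f_capture : float
        Distance-independent end-capture fraction for the sliding fate.
    """

    k_plus: float = 5.5e6
    k_minus: float = 0.0
    k_cat: float = 4.04
    k1: float = 5.87
    k2: float = 8.69
    k3: float = 5.46
    k4: float = 1.0 / 36.0
    t0: float = 237.0
    elong_mean: float = 2.9
    elong_sd: float = 1.0
    pre_elong_s: float = 1.0
    fate_fractions: dict = field(
        default_factory=lambda: {
            "simultaneous": 58 / 166,
            "retained_dissociate": 74 / 166,
            "retained_throughout": 34 / 166,
            "sliding": 0.0,
        }
    )
    D: float = 1.3e-4
    f_capture: float = 0.26
    # when set, the translocation rate follows Michaelis-Menten saturation
    # in ATP: k1(ATP) = k1_max * ATP / (K_m_atp + ATP), ATP in µM
    k1_max: Optional[float] = None
    K_m_atp: Optional[float] = None

    def __post_init__(self):
        for name in ("k_plus", "k_minus", "k_cat", "k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")
        if not 0.0 <= self.f_capture <= 1.0:
            raise ValueError("f_capture must be in [0, 1]")
        missing = set(FATE_LABELS) - set(self.fate_fractions)
        if missing:
            raise ValueError(f"fate_fractions missing {sorted(missing)}")
        total = sum(self.fate_fractions[k] for k in FATE_LABELS)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fate_fractions sum to {total}, not 1")

    def fate_probs(self) -> np.ndarray:
        return np.array([self.fate_fractions[k] for k in FATE_LABELS])

    def k1_at(self, atp_conc_uM: float) -> float:
        """Translocation rate at the given ATP concentration (µM)."""
        if self.k1_max is None or self.K_m_atp is None:
            return self.k1
        return self.k1_max * atp_conc_uM / (self.K_m_atp + atp_conc_uM)


@dataclass
class Condition:
    """One experimental condition of a titration or construct series."""

    sen1_conc: float = 10e-9  # M
    atp_conc: float = 1100.0  # µM
    rna_ext_length: float = 28.0  # nt outside the Pol II exit channel
    construct: str = "no_mismatch"
    n_molecules: int = 1
    label_distance_bp: Optional[float] = None  # Cy5 distance from termination site

    def __post_init__(self):
        if self.sen1_conc < 0 or self.atp_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if self.rna_ext_length < 0:
            raise ValueError("rna_ext_length must be >= 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    def label(self) -> str:
        return (
            f"{self.construct}_S{self.sen1_conc * 1e9:g}nM_"
            f"ATP{self.atp_conc:g}uM_L{self.rna_ext_length:g}nt"
        )


# default rendering levels: (total donor-excited emission, true FRET, base i_aa)
_DEFAULT_LEVELS = {
    "pre_elongation": (100.0, 0.5, 100.0),
    "elongation": (100.0, 0.7, 100.0),
    "stall": (100.0, 0.2, 100.0),
    "intermediate": (100.0, 0.45, 100.0),
    "post_termination": (0.0, 0.0, 100.0),
    "dark": (0.0, 0.0, 0.0),
}


@dataclass
class TrajectoryConfig:
    """Rendering parameters for synthetic two-color ALEX trajectories.

    ``frame_period`` is the time per laser frame (20 ms default); with the
    default strict green/red alternation each channel is sampled every
    ``channel_period = frame_period * len(alex_pattern)`` (40 ms).

    ``intensity_levels`` maps state -> (total donor-side counts, true FRET
    level, base acceptor-excited counts).  States in ``pife_states`` carry
    protein-induced fluorescence enhancement: acceptor-excited emission is
    multiplied by ``pife_factor`` and, when ``pife_on_da`` is set, the
    rendered donor-excited proximity ratio is the PIFE-inflated value
    ``r f / (1 - f + r f)`` so that the Eq.-style correction recovers the
    true level.
    """

    frame_period: float = 0.02
    alex_pattern: tuple = ("green", "red")
    duration: float = 60.0
    intensity_levels: dict = field(default_factory=lambda: dict(_DEFAULT_LEVELS))
    noise_sd: float = 0.0
    pife_factor: float = 1.83
    pife_states: frozenset = frozenset({"pre_elongation", "elongation"})
    pife_on_da: bool = True
    intensity_floor: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.frame_period <= 0 or self.duration <= 0:
            raise ValueError("frame_period and duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pife_factor < 1:
            raise ValueError("pife_factor must be >= 1")
        if not self.alex_pattern or set(self.alex_pattern) - {"green", "red"}:
            raise ValueError("alex_pattern must be a nonempty sequence of green/red")

    @property
    def channel_period(self) -> float:
        return self.frame_period * len(self.alex_pattern)


@dataclass
class Trajectory:
    """Per-frame intensity series of one molecule under ALEX illumination.

    ``i_dd``/``i_da`` (donor-excited donor/acceptor emission) are finite on
    green-laser frames and NaN on red frames; ``i_aa`` (acceptor-excited
    acceptor emission) the reverse.  ``truth`` optionally carries the
    ground-truth event times, changepoint frames, bleach times and fate.
    """

    times: np.ndarray
    laser: np.ndarray
    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    condition: Condition
    molecule_id: str = "mol_0"
    channel_period: float = 0.04
    truth: Optional[dict] = None

    def __post_init__(self):
        n = len(self.times)
        for name in ("laser", "i_dd", "i_da", "i_aa"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from times")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def green_frames(self) -> np.ndarray:
        return np.flatnonzero(self.laser == "green")

    def red_frames(self) -> np.ndarray:
        return np.flatnonzero(self.laser == "red")


@dataclass
class StateSegment:
    """A maximal run of frames assigned to one trace state."""

    state: str
    start_frame: int
    end_frame: int  # inclusive, in channel superframes
    duration: float  # s

    def __post_init__(self):
        if self.state not in STATE_LABELS:
            raise ValueError(f"unknown state {self.state!r}")
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")


@dataclass
class DwellSample:
    """Dwell durations of one state under one condition."""

    durations: np.ndarray
    condition: Condition
    state: str = "stall"
    censored_flags: Optional[np.ndarray] = None
    truth: Optional[dict] = None

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.durations <= 0):
            raise ValueError("durations must be > 0")
        if self.censored_flags is None:
            self.censored_flags = np.zeros(len(self.durations), dtype=bool)
        else:
            self.censored_flags = np.asarray(self.censored_flags, dtype=bool)
            if len(self.censored_flags) != len(self.durations):
                raise ValueError("censored_flags length differs from durations")

    @property
    def n(self) -> int:
        return len(self.durations)

    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored_flags]


@dataclass
class FateRecord:
    """Per-molecule Pol II fate relative to RNA release."""

    molecule_id: str
    rna_end_frame: int
    pol2_end_frame: Optional[int]  # None when retained to record end
    category: str
    lag_frames: Optional[int]

    def __post_init__(self):
        if self.category not in ("before", "simultaneous", "after", "retained"):
            raise ValueError(f"unknown fate category {self.category!r}")
        if self.category == "retained":
            if self.pol2_end_frame is not None:
                raise ValueError("retained fate must have pol2_end_frame=None")
        elif self.lag_frames is None:
            raise ValueError("non-retained fate requires lag_frames")
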