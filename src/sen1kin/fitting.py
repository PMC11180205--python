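"""Histogram construction and global model fitting.

Primary dwell-time fits follow the study's scheme: duration histograms from
several conditions are fit simultaneously by weighted least squares, with
concentration values and the photobleaching constant held, kinetic rate
constants shared across conditions, and per-condition amplitudes free.
Histogram bins are weighted by sqrt(max(count, 1)) (Poisson); parameter
standard errors come from the covariance scaled by the reduced chi-square.
A maximum-likelihood route on the normalized densities (with optional
right-censoring) is provided as the default estimator for the two-step
model, which carries no amplitude.

Secondary fits: weighted classical Michaelis-Menten saturation of per-ATP
rates, Gaussian peak fits of elongation durations, single-exponential rates,
and the 1D-vs-3D diffusion model comparison for post-termination Pol II
sliding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import lmfit
from scipy.optimize import curve_fit, minimize

from .core import DwellSample
from .models import bp_to_um, pdf_smmm_bleach, pdf_two_step

__all__ = [
    "Histogram",
    "Param",
    "ModelSpec",
    "FitResult",
    "MMFitPoint",
    "DiffusionDataPoint",
    "build_histogram",
    "merge_sparse_bins",
    "fit_global_ls",
    "fit_mle",
    "fit_mm_weighted",
    "fit_gaussian_peak",
    "fit_exp_rate",
    "fit_diffusion_models",
    "translocation_rate",
    "elongation_rate",
    "catalytic_rate",
    "derive_rates",
]

#: deterministic multi-start spread applied to varying initial values
_START_FACTORS = (1.0, 0.3, 3.0, 0.1, 10.0)


@dataclass
class Histogram:
    """Binned dwell durations of one condition."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts length must be len(edges) - 1")
        if not np.isclose(float(self.counts.sum()), float(self.n), rtol=1e-9):
            raise ValueError("sum(counts) must equal n")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def density(self) -> np.ndarray:
        return self.counts / (self.n * self.widths)


def merge_sparse_bins(hist: Histogram, min_count: int = 5) -> Histogram:
    """Merge under-populated bins into their left neighbor.

    Chi-square histogram fitting assumes approximately Gaussian bin counts;
    sparse tail bins violate that and bias Neyman-weighted (sigma =
    sqrt(count)) fits.  Merging until every bin holds at least
    ``min_count`` events restores the approximation without discarding
    events.  The resulting bins are variable-width.
    """
    edges = list(hist.bin_edges)
    counts = list(hist.counts)
    i = len(counts) - 1
    while i >= 0 and len(counts) > 1:
        if counts[i] < min_count:
            if i == 0:
                counts[1] += counts[0]
                edges.pop(1)
                counts.pop(0)
            else:
                counts[i - 1] += counts[i]
                edges.pop(i)
                counts.pop(i)
        i -= 1
    return Histogram(np.array(edges), np.array(counts), hist.n)


def build_histogram(
    dwells,
    bin_width: Optional[float] = None,
    channel_period: float = 0.04,
    include_censored: bool = False,
    min_count: Optional[int] = None,
) -> Histogram:
    """Bin a dwell sample into a fixed-width histogram starting at 0.

    Default bin width is ``max(channel_period, range / 30)`` — never finer
    than the acquisition resolution.  Censored dwells are excluded by
    default (they end by bleaching or record end, not by the kinetic step
    under study).  ``min_count`` merges sparse tail bins afterwards (see
    :func:`merge_sparse_bins`).  Requires at least 10 events.
    """
    if isinstance(dwells, DwellSample):
        data = dwells.durations if include_censored else dwells.uncensored()
    else:
        data = np.asarray(dwells, dtype=float)
    if data.size < 10:
        raise ValueError("need at least 10 dwells to build a histogram")
    if bin_width is None:
        bin_width = max(channel_period, float(np.ptp(data)) / 30.0)
    n_bins = int(np.ceil(data.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] <= data.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(data, bins=edges)
    hist = Histogram(bin_edges=edges, counts=counts, n=int(counts.sum()))
    if min_count is not None:
        hist = merge_sparse_bins(hist, min_count)
    return hist


@dataclass
class Param:
    """One named model parameter with its fitting role.

    role 'shared': one value fitted jointly across conditions;
    role 'free': one value fitted per condition;
    role 'held': fixed — scalar, or a per-condition sequence (e.g. the
    concentration S of each histogram).
    """

    role: str
    value: object = 1.0

    def __post_init__(self):
        if self.role not in ("shared", "free", "held"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ModelSpec:
    """A dwell-time model with parameter roles for a (global) fit."""

    model_id: str
    params: dict = field(default_factory=dict)

    def held_value(self, name: str, cond_index: int):
        v = self.params[name].value
        if np.ndim(v) > 0:
            return float(np.asarray(v)[cond_index])
        return float(v)


@dataclass
class FitResult:
    """Estimates, standard errors and goodness-of-fit of one model fit."""

    model: ModelSpec
    estimates: dict
    ses: dict
    reduced_chisq: float
    n_points: int
    n_free: int
    success: bool = True
    message: str = ""
    covariance: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# model evaluation for histogram fits

_MODEL_PARAMS = {
    "single_exp": ("A", "k_plus", "S"),
    "exp_bleach": ("A", "k_plus", "S", "B", "t0"),
    "smmm_bleach": ("A", "k_plus", "S", "k_minus", "k_cat", "B", "t0"),
    "two_step": ("k1", "k2"),
}


def _eval_density(model_id: str, tau: np.ndarray, p: dict) -> np.ndarray:
    if model_id == "single_exp":
        return p["A"] * np.exp(-p["k_plus"] * p["S"] * tau)
    if model_id == "exp_bleach":
        return p["A"] * np.exp(-p["k_plus"] * p["S"] * tau) + p["B"] * np.exp(
            -tau / p["t0"]
        )
    if model_id == "smmm_bleach":
        kin = pdf_smmm_bleach(
            tau, p["k_plus"], p["S"], p["k_minus"], p["k_cat"]
        )
        return p["A"] * kin + p["B"] * np.exp(-tau / p["t0"])
    if model_id == "two_step":
        return pdf_two_step(tau, p["k1"], p["k2"])
    raise ValueError(f"unknown model_id {model_id!r}")


def _param_key(name: str, cond_index: int) -> str:
    return f"{name}__c{cond_index}"


def _build_lmfit_params(spec: ModelSpec, n_cond: int) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for name in _MODEL_PARAMS[spec.model_id]:
        if name not in spec.params:
            raise ValueError(f"model {spec.model_id!r} requires parameter {name!r}")
        p = spec.params[name]
        if p.role == "shared":
            params.add(name, value=float(p.value), min=0.0)
        elif p.role == "free":
            init = np.asarray(p.value, dtype=float)
            for c in range(n_cond):
                v = float(init[c]) if init.ndim else float(init)
                params.add(_param_key(name, c), value=v, min=0.0)
        # held values are injected at evaluation time
    return params


def _cond_params(spec: ModelSpec, params, c: int) -> dict:
    out = {}
    for name in _MODEL_PARAMS[spec.model_id]:
        role = spec.params[name].role
        if role == "shared":
            out[name] = float(params[name].value)
        elif role == "free":
            out[name] = float(params[_param_key(name, c)].value)
        else:
            out[name] = spec.held_value(name, c)
    return out


def fit_global_ls(histograms: Sequence[Histogram], spec: ModelSpec) -> FitResult:
    """Global weighted least-squares fit of dwell histograms.

    Minimizes, over conditions c and bins i,
    ``sum(((count_ci - f(tau_i; p_c) * n_c * w_i) / sigma_ci)**2)`` with
    Poisson weights ``sigma = sqrt(max(count, 1))``.  Shared parameters take
    a single value across all conditions; held parameters (concentrations,
    the bleaching constant) stay fixed; free parameters (amplitudes) vary
    per condition.  Five deterministically spread starts guard against
    local minima; non-convergence is flagged on the result, not raised.
    """
    if not histograms:
        raise ValueError("at least one histogram required")
    n_cond = len(histograms)

    def residual(params):
        res = []
        for c, h in enumerate(histograms):
            p = _cond_params(spec, params, c)
            model_counts = _eval_density(spec.model_id, h.centers, p) * h.n * h.widths
            sigma = np.sqrt(np.maximum(h.counts, 1.0))
            res.append((h.counts - model_counts) / sigma)
        return np.concatenate(res)

    base = _build_lmfit_params(spec, n_cond)
    n_free = sum(1 for p in base.values() if p.vary)
    n_points = sum(len(h.counts) for h in histograms)
    if n_points - n_free < 1:
        raise ValueError("insufficient degrees of freedom")

    best = None
    for fac in _START_FACTORS:
        trial = base.copy()
        for p in trial.values():
            if p.vary:
                p.value = max(p.value * fac, 1e-12)
        try:
            out = lmfit.minimize(residual, trial, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        return FitResult(spec, {}, {}, math.nan, n_points, n_free, False, "no start converged")

    estimates, ses = {}, {}
    for name in _MODEL_PARAMS[spec.model_id]:
        role = spec.params[name].role
        if role == "shared":
            estimates[name] = float(best.params[name].value)
            ses[name] = float(best.params[name].stderr or math.nan)
        elif role == "free":
            estimates[name] = [float(best.params[_param_key(name, c)].value) for c in range(n_cond)]
            ses[name] = [float(best.params[_param_key(name, c)].stderr or math.nan) for c in range(n_cond)]
    return FitResult(
        model=spec,
        estimates=estimates,
        ses=ses,
        reduced_chisq=float(best.redchi),
        n_points=n_points,
        n_free=n_free,
        success=bool(best.success),
        message=best.message if isinstance(best.message, str) else "",
        covariance=getattr(best, "covar", None),
    )


# ---------------------------------------------------------------------------
# maximum likelihood on normalized densities

def _logpdf(model_id: str, tau: np.ndarray, p: dict) -> np.ndarray:
    if model_id == "single_exp":
        rate = p["k_plus"] * p["S"]
        return np.log(rate) - rate * tau
    if model_id == "two_step":
        return np.log(np.maximum(pdf_two_step(tau, p["k1"], p["k2"]), 1e-300))
    raise ValueError(f"MLE not implemented for model {model_id!r}")


def _logsf(model_id: str, tau: np.ndarray, p: dict) -> np.ndarray:
    if model_id == "single_exp":
        return -p["k_plus"] * p["S"] * tau
    if model_id == "two_step":
        k1, k2 = p["k1"], p["k2"]
        if abs(k1 - k2) < 1e-8 * max(k1, k2):
            k = 0.5 * (k1 + k2)
            return np.log(np.maximum((1.0 + k * tau) * np.exp(-k * tau), 1e-300))
        sf = (k2 * np.exp(-k1 * tau) - k1 * np.exp(-k2 * tau)) / (k2 - k1)
        return np.log(np.maximum(sf, 1e-300))
    raise ValueError(f"MLE not implemented for model {model_id!r}")


def _hessian_fd(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_mle(
    samples: Sequence[DwellSample],
    spec: ModelSpec,
    censoring: bool = False,
) -> FitResult:
    """Global maximum-likelihood fit of normalized dwell densities.

    Supports ``single_exp`` and ``two_step`` (the models the study fits
    without amplitude).  Right-censored dwells contribute survival terms
    ``log S(tau)`` when ``censoring`` is enabled (otherwise they are
    dropped).  Standard errors come from the inverse observed information
    (finite-difference Hessian of the negative log-likelihood).
    """
    if isinstance(samples, DwellSample):
        samples = [samples]
    if not samples:
        raise ValueError("at least one sample required")
    n_cond = len(samples)
    for s in samples:
        if s.n < 10:
            raise ValueError("need at least 10 dwells per sample")

    names = _MODEL_PARAMS[spec.model_id]
    layout = []  # (param name, cond index or None) per vector slot
    x0 = []
    for name in names:
        p = spec.params[name]
        if p.role == "shared":
            layout.append((name, None))
            x0.append(math.log(float(p.value)))
        elif p.role == "free":
            init = np.asarray(p.value, dtype=float)
            for c in range(n_cond):
                layout.append((name, c))
                x0.append(math.log(float(init[c]) if init.ndim else float(init)))
    x0 = np.array(x0)

    def unpack(x, c):
        p = {}
        for name in names:
            role = spec.params[name].role
            if role == "held":
                p[name] = spec.held_value(name, c)
        for (name, ci), v in zip(layout, x):
            if ci is None or ci == c:
                p[name] = math.exp(v)
        return p

    def nll(x):
        total = 0.0
        for c, s in enumerate(samples):
            p = unpack(x, c)
            obs = s.uncensored()
            total -= float(np.sum(_logpdf(spec.model_id, obs, p)))
            if censoring and s.censored_flags.any():
                cens = s.durations[s.censored_flags]
                total -= float(np.sum(_logsf(spec.model_id, cens, p)))
        return total

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
    xhat = res.x
    # delta method: theta = exp(x); cov_theta = J cov_x J^T with J = diag(theta)
    H = _hessian_fd(nll, xhat)
    try:
        cov_x = np.linalg.inv(H)
        theta = np.exp(xhat)
        cov = cov_x * np.outer(theta, theta)
        se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = None
        se_vec = np.full(len(xhat), math.nan)

    estimates, ses = {}, {}
    for slot, ((name, ci), v) in enumerate(zip(layout, xhat)):
        val, se = math.exp(v), float(se_vec[slot])
        if ci is None:
            estimates[name], ses[name] = val, se
        else:
            estimates.setdefault(name, [None] * n_cond)[ci] = val
            ses.setdefault(name, [None] * n_cond)[ci] = se
    n_points = sum(s.n if censoring else len(s.uncensored()) for s in samples)
    return FitResult(
        model=spec,
        estimates=estimates,
        ses=ses,
        reduced_chisq=math.nan,  # likelihood fit: no chi-square defined
        n_points=n_points,
        n_free=len(xhat),
        success=bool(res.success),
        message=str(res.message),
        covariance=cov,
    )


# ---------------------------------------------------------------------------
# secondary fits

@dataclass
class MMFitPoint:
    """One (substrate concentration, rate, SEM) point of a saturation curve."""

    S: float  # µM
    k: float  # s^-1
    sem: float  # s^-1

    def __post_init__(self):
        if self.S < 0 or self.sem <= 0:
            raise ValueError("require S >= 0 and sem > 0")


def fit_mm_weighted(points: Sequence) -> FitResult:
    """Weighted classical Michaelis-Menten fit, ``k(S) = kmax S / (Km + S)``.

    Weights are 1/sem^2; parameter SEs come from the covariance scaled by
    the reduced chi-square.  Requires at least 3 points at distinct S.
    """
    pts = [p if isinstance(p, MMFitPoint) else MMFitPoint(*p) for p in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    S = np.array([p.S for p in pts])
    k = np.array([p.k for p in pts])
    sem = np.array([p.sem for p in pts])
    if len(np.unique(S)) < 3:
        raise ValueError("need at least 3 distinct concentrations")

    def mm(s, kmax, Km):
        return kmax * s / (Km + s)

    p0 = [k.max() * 1.2, np.median(S)]
    popt, pcov = curve_fit(mm, S, k, p0=p0, sigma=sem, absolute_sigma=False,
                           maxfev=20000)
    resid = (k - mm(S, *popt)) / sem
    dof = len(pts) - 2
    redchi = float(np.sum(resid**2) / dof)
    ses = np.sqrt(np.diag(pcov))
    spec = ModelSpec("mm_curve", {"k_max": Param("shared", popt[0]),
                                  "K_m": Param("shared", popt[1])})
    return FitResult(
        model=spec,
        estimates={"k_max": float(popt[0]), "K_m": float(popt[1])},
        ses={"k_max": float(ses[0]), "K_m": float(ses[1])},
        reduced_chisq=redchi,
        n_points=len(pts),
        n_free=2,
        covariance=pcov,
    )


def fit_gaussian_peak(durations, bin_width: Optional[float] = None):
    """Fit a single Gaussian to a binned duration histogram.

    Returns ``(peak, se)`` — the fitted center and its standard error
    (covariance scaled by the reduced chi-square).  Used for elongation
    durations, which are bell-shaped rather than exponential.
    """
    data = np.asarray(durations, dtype=float)
    if data.size < 30:
        raise ValueError("need at least 30 durations")
    if bin_width is None:
        bin_width = float(np.ptp(data)) / 15.0
    edges = np.arange(data.min() - bin_width, data.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(data, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    p0 = [counts.max(), float(data.mean()), float(data.std() or bin_width)]
    try:
        popt, pcov = curve_fit(gauss, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Gaussian peak fit did not converge: {exc}") from exc
    return float(popt[1]), float(np.sqrt(pcov[1, 1]))


def fit_exp_rate(dwells, method: str = "mle", channel_period: float = 0.04):
    """Single-exponential rate of a dwell sample.

    ``mle``: rate = 1 / sample mean (the closed-form estimator), SE =
    rate / sqrt(n).  ``ls``: weighted least squares on the binned histogram.
    Returns ``(rate, se)``.
    """
    if isinstance(dwells, DwellSample):
        data = dwells.uncensored()
    else:
        data = np.asarray(dwells, dtype=float)
    if data.size < 10:
        raise ValueError("need at least 10 dwells")
    if method == "mle":
        rate = 1.0 / float(data.mean())
        return rate, rate / math.sqrt(data.size)
    if method == "ls":
        h = build_histogram(data, channel_period=channel_period)

        def model(t, A, k):
            return A * np.exp(-k * t)

        sigma = np.sqrt(np.maximum(h.counts, 1.0))
        popt, pcov = curve_fit(model, h.centers, h.counts,
                               p0=[h.counts.max(), 1.0 / data.mean()],
                               sigma=sigma, absolute_sigma=False, maxfev=20000)
        return float(popt[1]), float(np.sqrt(pcov[1, 1]))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class DiffusionDataPoint:
    """Per-distance summary of post-termination Cy5 PIFE appearance."""

    L_bp: float
    mean_lifetime: float  # s
    lifetime_se: float
    fraction: float
    fraction_se: float
    n: int = 0

    def __post_init__(self):
        if self.L_bp < 0 or not 0 <= self.fraction <= 1:
            raise ValueError("require L_bp >= 0 and fraction in [0, 1]")

    @property
    def L_um(self) -> float:
        return float(bp_to_um(self.L_bp))


def fit_diffusion_models(points: Sequence[DiffusionDataPoint]):
    """Jointly fit lifetime- and fraction-vs-distance to 1D and 3D models.

    1D sliding: mean capture time ``L^2 / (2 D)`` with a distance-
    independent fraction ``f``.  3D alternative: ``L^2 / (6 D)`` with
    fraction ``c / L``.  Both are weighted by the per-point SEs; the model
    with the lower reduced chi-square is preferred.

    Returns ``(results, preferred)`` where ``results`` maps model name to
    FitResult.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 distances")
    L = np.array([p.L_um for p in pts])
    t = np.array([p.mean_lifetime for p in pts])
    st = np.array([p.lifetime_se for p in pts])
    f = np.array([p.fraction for p in pts])
    sf = np.array([p.fraction_se for p in pts])

    results = {}
    for name, denom in (("1d", 2.0), ("3d", 6.0)):
        params = lmfit.Parameters()
        D0 = float(np.mean(L[L > 0] ** 2 / (denom * np.maximum(t[L > 0], 1e-12))))
        params.add("D", value=max(D0, 1e-12), min=1e-15)
        if name == "1d":
            params.add("frac", value=float(np.mean(f)), min=0.0, max=1.0)
        else:
            params.add("c", value=float(np.mean(f * L)), min=0.0)

        def residual(p, name=name, denom=denom):
            life = L**2 / (denom * p["D"].value)
            if name == "1d":
                frac = np.full_like(L, p["frac"].value)
            else:
                frac = np.minimum(p["c"].value / np.maximum(L, 1e-12), 1.0)
            return np.concatenate([(life - t) / st, (frac - f) / sf])

        out = lmfit.minimize(residual, params, method="leastsq")
        estimates = {k: float(v.value) for k, v in out.params.items()}
        ses = {k: float(v.stderr or math.nan) for k, v in out.params.items()}
        spec = ModelSpec(f"diffusion_{name}",
                         {k: Param("shared", v) for k, v in estimates.items()})
        results[name] = FitResult(
            model=spec, estimates=estimates, ses=ses,
            reduced_chisq=float(out.redchi),
            n_points=2 * len(pts), n_free=2, success=bool(out.success),
        )
    preferred = min(results, key=lambda k: results[k].reduced_chisq)
    return results, preferred


# ---------------------------------------------------------------------------
# derived-rate calculators

def translocation_rate(k_max: float, step_nt: float) -> float:
    """Helicase translocation rate, nt/s: saturating rate x step length."""
    if k_max <= 0 or step_nt <= 0:
        raise ValueError("inputs must be > 0")
    return k_max * step_nt


def elongation_rate(length_bp: float, duration_s: float) -> float:
    """Polymerase elongation rate, bp/s: template length over duration."""
    if duration_s <= 0 or length_bp <= 0:
        raise ValueError("inputs must be > 0")
    return length_bp / duration_s


def catalytic_rate(mean_dwell_s: float) -> float:
    """Catalytic turnover rate, s^-1: inverse mean intermediate lifetime."""
    if mean_dwell_s <= 0:
        raise ValueError("mean dwell must be > 0")
    return 1.0 / mean_dwell_s


def derive_rates(inputs: dict) -> dict:
    """Compute whichever derived quantities the inputs allow.

    Recognized input pairs: (``k_max``, ``step_nt``) -> ``translocation_nt_s``;
    (``length_bp``, ``duration_s``) -> ``elongation_bp_s``;
    ``mean_intermediate_s`` -> ``k_cat``.
    """
    out = {}
    if "k_max" in inputs and "step_nt" in inputs:
        out["translocation_nt_s"] = translocation_rate(inputs["k_max"], inputs["step_nt"])
    if "length_bp" in inputs and "duration_s" in inputs:
        out["elongation_bp_s"] = elongation_rate(inputs["length_bp"], inputs["duration_s"])
    if "mean_intermediate_s" in inputs:
        out["k_cat"] = catalytic_rate(inputs["mean_intermediate_s"])
    return out
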