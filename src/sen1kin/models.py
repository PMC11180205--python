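"""Closed-form dwell-time densities and secondary-rate curves.

The kinetic scheme behind these models: a Sen1 helicase molecule binds a
stalled Pol II elongation complex with pseudo-first-order rate ``k+ · S``
(``S`` = Sen1 concentration), may dissociate unproductively (``k-``), or
catalyzes termination (``k_cat``).  The waiting time of that binding-catalysis
cycle is the two-exponential "single-molecule Michaelis-Menten" density; when
``k- = 0`` it reduces to a hypoexponential (two sequential exponential steps,
rates ``k1`` and ``k2``).  Observed dwells are additionally censored by Cy3
photobleaching, an independent exponential clock with mean ``t0``, which in
histogram fits appears as an additive background exponential of amplitude
``B``.

Secondary models: the classical Michaelis-Menten saturation curve for
per-ATP rates, and first-passage models for post-termination Pol II sliding
on DNA (1D: mean capture time ``L**2 / (2 D)`` with a distance-independent
capture fraction; a 3D alternative with ``L**2 / (6 D)`` and fraction
``c / L``).

All densities are plain vectorized functions of time ``tau`` in seconds and
rates in 1/s; they are registered by string id in :data:`MODEL_REGISTRY`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pdf_single_exp",
    "pdf_exp_bleach",
    "pdf_smmm_bleach",
    "pdf_two_step",
    "mm_curve",
    "hypoexp_mean",
    "diffusion_lifetime",
    "diffusion_fraction",
    "bp_to_um",
    "MODEL_REGISTRY",
    "NM_PER_BP",
]

#: B-DNA helical rise, nm per base pair.
NM_PER_BP = 0.34

#: relative |k1 - k2| below which the degenerate (Erlang) limit is used
_DEGENERATE_RTOL = 1e-8


def _check_tau(tau):
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("dwell time tau must be >= 0")
    return tau


def pdf_single_exp(tau, A, k_plus, S):
    """Single-exponential dwell density ``A * exp(-k_plus * S * tau)``.

    Describes Sen1 binding-limited termination waits: ``k_plus`` is the
    second-order binding rate constant (M^-1 s^-1) and ``S`` the Sen1
    concentration (M), so ``k_plus * S`` is the pseudo-first-order rate.
    """
    tau = _check_tau(tau)
    rate = k_plus * S
    if rate <= 0:
        raise ValueError("k_plus * S must be > 0")
    return A * np.exp(-rate * tau)


def pdf_exp_bleach(tau, A, k_plus, S, B, t0):
    """Single exponential plus photobleaching background.

    ``A * exp(-k_plus*S*tau) + B * exp(-tau/t0)`` — the kinetic decay with an
    additive exponential of the dye bleaching time constant ``t0`` (s),
    accounting for dwells ended by bleaching rather than termination.
    """
    tau = _check_tau(tau)
    if t0 <= 0:
        raise ValueError("t0 must be > 0")
    return pdf_single_exp(tau, A, k_plus, S) + B * np.exp(-tau / t0)


def pdf_two_step(tau, k1, k2):
    """Hypoexponential density of two sequential exponential steps.

    ``f(tau) = k1 k2 / (k2 - k1) * (exp(-k1 tau) - exp(-k2 tau))``, the
    waiting-time density of ATP-dependent translocation (rate ``k1``)
    followed by single-ATP catalytic release (rate ``k2``).  Symmetric under
    exchange of the two rates; at ``k1 == k2`` the Erlang limit
    ``k**2 * tau * exp(-k tau)`` is returned (switched when the rates agree
    to within 1e-8 relative, avoiding catastrophic cancellation).
    Normalized: integrates to 1 on [0, inf).
    """
    tau = _check_tau(tau)
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates k1, k2 must be > 0")
    if abs(k1 - k2) < _DEGENERATE_RTOL * max(k1, k2):
        k = 0.5 * (k1 + k2)
        return k * k * tau * np.exp(-k * tau)
    pref = k1 * k2 / (k2 - k1)
    return pref * (np.exp(-k1 * tau) - np.exp(-k2 * tau))


def pdf_smmm_bleach(tau, k_plus, S, k_minus, k_cat, B=0.0, t0=np.inf):
    """Single-molecule Michaelis-Menten dwell density with bleach background.

    Kinetic part: ``(k0 kcat / 2a) * (exp((a+b) tau) - exp((b-a) tau))`` with
    ``k0 = k_plus * S``, ``b = -(k0 + k_minus + k_cat)/2`` and
    ``a = sqrt(b**2 - k0 kcat)``; plus ``B * exp(-tau/t0)``.

    For nonnegative rates ``a`` is real and ``0 <= a <= |b|`` so both
    exponents are nonpositive and the kinetic part integrates to 1.  The
    degenerate case ``a == 0`` (``k0 == k_cat``, ``k_minus == 0``) is the
    Erlang limit ``k**2 tau exp(-k tau)``; handled via a stable sinh(x)/x
    evaluation rather than a separate branch.
    """
    tau = _check_tau(tau)
    k0 = k_plus * S
    if k0 <= 0:
        raise ValueError("k_plus * S must be > 0")
    if k_cat <= 0:
        raise ValueError("k_cat must be > 0")
    if k_minus < 0:
        raise ValueError("k_minus must be >= 0")
    b = -0.5 * (k0 + k_minus + k_cat)
    a2 = b * b - k0 * k_cat
    a = np.sqrt(max(a2, 0.0))
    # both exponents b+a and b-a are <= 0; the direct difference is stable
    # except for small a*tau, where the series of sinh avoids cancellation
    if a == 0.0:
        kin = k0 * k_cat * tau * np.exp(b * tau)
    else:
        at = np.asarray(a * tau)
        series = k0 * k_cat * tau * np.exp(b * tau) * (1.0 + at * at / 6.0)
        with np.errstate(over="ignore", invalid="ignore"):
            direct = (k0 * k_cat / (2.0 * a)) * (
                np.exp((b + a) * tau) - np.exp((b - a) * tau)
            )
        kin = np.where(at < 1e-6, series, direct)
    if B == 0.0:
        return kin
    if t0 <= 0 or not np.isfinite(t0):
        raise ValueError("t0 must be a positive finite number when B != 0")
    return kin + B * np.exp(-tau / t0)


def mm_curve(S, k_max, K_m):
    """Classical Michaelis-Menten saturation ``k_max * S / (K_m + S)``."""
    S = np.asarray(S, dtype=float)
    if K_m <= 0:
        raise ValueError("K_m must be > 0")
    if np.any(S < 0):
        raise ValueError("S must be >= 0")
    return k_max * S / (K_m + S)


def hypoexp_mean(k1, k2):
    """Mean of the two-step (hypoexponential) dwell, ``1/k1 + 1/k2``."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates k1, k2 must be > 0")
    return 1.0 / k1 + 1.0 / k2


def bp_to_um(length_bp):
    """Contour length of ``length_bp`` base pairs of B-DNA, in micrometers."""
    return np.asarray(length_bp, dtype=float) * NM_PER_BP * 1e-3


def diffusion_lifetime(L_um, D, model="1d"):
    """Mean first-passage time (s) to a target at distance ``L_um`` (µm).

    ``1d``: sliding along DNA, MFPT = L^2 / (2 D).
    ``3d``: the alternative comparison model, L^2 / (6 D).
    ``D`` in µm^2/s.  Scales quadratically with distance in both cases.
    """
    L = np.asarray(L_um, dtype=float)
    if D <= 0:
        raise ValueError("D must be > 0")
    if np.any(L < 0):
        raise ValueError("L must be >= 0")
    if model == "1d":
        return L * L / (2.0 * D)
    if model == "3d":
        return L * L / (6.0 * D)
    raise ValueError(f"unknown diffusion model {model!r}")


def diffusion_fraction(L_um, model="1d", f_capture=0.26, c=None):
    """Fraction of post-termination events that reach the labeled DNA end.

    ``1d``: a distance-independent constant ``f_capture`` (a 1D random walker
    reaches either end with probability 1; the constant absorbs detection
    and labeling efficiency).  ``3d``: capture probability falls off as
    ``c / L`` with distance (diffusion-limited target finding).
    """
    L = np.asarray(L_um, dtype=float)
    if model == "1d":
        return np.broadcast_to(np.asarray(f_capture, dtype=float), L.shape).copy()
    if model == "3d":
        if c is None:
            raise ValueError("3d fraction model requires the constant c")
        with np.errstate(divide="ignore"):
            return np.minimum(c / L, 1.0)
    raise ValueError(f"unknown diffusion model {model!r}")


#: dwell/secondary model ids usable in fit specifications and config files
MODEL_REGISTRY = {
    "single_exp": pdf_single_exp,
    "exp_bleach": pdf_exp_bleach,
    "smmm_bleach": pdf_smmm_bleach,
    "two_step": pdf_two_step,
    "mm_curve": mm_curve,
    "diffusion_1d": lambda L, D: diffusion_lifetime(L, D, "1d"),
    "diffusion_3d": lambda L, D: diffusion_lifetime(L, D, "3d"),
}
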