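"""Core ODE model of the activator–repressor genetic oscillator.

The circuit is a two-gene negative feedback loop: a sigma factor (the
activator ``a``) drives expression of a repressor (``h``, a TetR analogue)
which in turn shuts down transcription of the activator.  Explicit mRNA
species (``r_a``, ``r_h``) provide the delay needed for sustained
oscillations.  The reactor removes every species at a dilution rate
``delta``, which sets the intrinsic timescale of the clock
(``T ≈ C·π/δ`` with ``C`` close to one).

Internal unit system: concentrations in nM, time in seconds.  Parameter
fields keep the units they are usually quoted in (transcription rates in
pM/s, mRNA lifetimes in minutes); properties convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError

__all__ = [
    "OscillatorParams",
    "CircuitState",
    "STATE_CHANNELS",
    "hill_repression",
    "hill_activation",
    "ode_rhs",
    "dilution_rate",
    "lambda_parameter",
    "refresh_for_lambda",
    "predicted_period",
    "nullclines",
    "fixed_point",
]

#: order of the state vector used throughout the package
STATE_CHANNELS = ("r_a", "a", "r_h", "h", "rep_a", "rep_h", "x_in", "ref")

_PM_PER_NM = 1000.0
_S_PER_MIN = 60.0
_S_PER_H = 3600.0


@dataclass(frozen=True)
class OscillatorParams:
    """Kinetic and regulatory constants of the oscillator plus dilution rate.

    Parameters
    ----------
    alpha_a, alpha_h : float
        Transcription rates of the activator / repressor gene, pM s⁻¹.
        Proportional to template DNA concentration (control parameters).
    K_a, K_h : float
        Hill threshold constants of activation / repression, nM.
    n_a, n_h : float
        Hill coefficients (dimensionless).
    k_TL_a, k_TL_h : float
        Translation rates, s⁻¹.
    tau_m_a, tau_m_h : float
        mRNA lifetimes, minutes.
    delta : float
        Dilution rate, s⁻¹ (control parameter; dominates the period).
    """

    alpha_a: float
    alpha_h: float
    K_a: float
    K_h: float
    n_a: float
    n_h: float
    k_TL_a: float
    k_TL_h: float
    tau_m_a: float
    tau_m_h: float
    delta: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{f.name} must be strictly positive, got {v!r}")

    @classmethod
    def uniform(cls, *, alpha: float, K_a: float, K_h: float, n: float,
                k_TL: float, tau_m: float, delta: float) -> "OscillatorParams":
        """Constructor with uniform activator/repressor kinetics.

        Enforces ``alpha_a = alpha_h``, ``n_a = n_h``, ``k_TL_a = k_TL_h`` and
        ``tau_m_a = tau_m_h`` — the standard simplification that preserves the
        qualitative dynamics while halving the parameter count.
        """
        return cls(alpha_a=alpha, alpha_h=alpha, K_a=K_a, K_h=K_h,
                   n_a=n, n_h=n, k_TL_a=k_TL, k_TL_h=k_TL,
                   tau_m_a=tau_m, tau_m_h=tau_m, delta=delta)

    # -- unit conversions (internal system: nM, s) --
    @property
    def alpha_a_nM_s(self) -> float:
        return self.alpha_a / _PM_PER_NM

    @property
    def alpha_h_nM_s(self) -> float:
        return self.alpha_h / _PM_PER_NM

    @property
    def tau_m_a_s(self) -> float:
        return self.tau_m_a * _S_PER_MIN

    @property
    def tau_m_h_s(self) -> float:
        return self.tau_m_h * _S_PER_MIN

    def with_delta(self, delta: float) -> "OscillatorParams":
        return replace(self, delta=delta)

    def perturbed(self, name: str, factor: float) -> "OscillatorParams":
        """Return a copy with one parameter multiplied by ``factor``."""
        if name not in {f.name for f in fields(self)}:
            raise ParameterError(f"unknown parameter {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass
class CircuitState:
    """Species concentrations at one instant (nM; ``ref`` in arbitrary units).

    ``rep_a``/``rep_h`` are the fluorescent reporter proteins co-expressed
    from the activator/repressor mRNAs; ``x_in`` is the exogenously supplied
    input species (added repressor protein, or inducer); ``ref`` is the
    reference dye used to monitor the realised refresh ratio.
    """

    r_a: float = 0.0
    a: float = 0.0
    r_h: float = 0.0
    h: float = 0.0
    rep_a: float = 0.0
    rep_h: float = 0.0
    x_in: float = 0.0
    ref: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in STATE_CHANNELS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CircuitState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(STATE_CHANNELS),):
            raise ParameterError(f"state vector must have shape ({len(STATE_CHANNELS)},)")
        return cls(**dict(zip(STATE_CHANNELS, arr)))


def _check_hill_params(K: float, n: float) -> None:
    if not (K > 0 and n > 0):
        raise ParameterError(f"Hill parameters must be positive (K={K}, n={n})")


def hill_repression(h_eff, K_h: float, n_h: float):
    """Repressive Hill transfer function ``1/(1+(h/K_h)^n_h)`` in (0, 1].

    Evaluated in the overflow-safe form ``K^n/(K^n + h^n)``; monotonically
    non-increasing in the repressor concentration ``h_eff``.
    """
    _check_hill_params(K_h, n_h)
    h = np.asarray(h_eff, dtype=float)
    if np.any(h < 0):
        raise ParameterError("repressor concentration must be non-negative")
    Kn = K_h ** n_h
    out = Kn / (Kn + h ** n_h)
    return out if out.ndim else float(out)


def hill_activation(a, K_a: float, n_a: float):
    """Activating Hill transfer function ``1/(1+(K_a/a)^n_a)`` in [0, 1).

    ``a = 0`` is defined by its limit, 0 (empty reactors are a valid start);
    evaluated as ``a^n/(a^n + K^n)``.
    """
    _check_hill_params(K_a, n_a)
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ParameterError("activator concentration must be non-negative")
    an = a ** n_a
    out = an / (an + K_a ** n_a)
    return out if out.ndim else float(out)


def effective_repressor(h: float, x_in: float, forcing_mode: str) -> float:
    """Repressor concentration seen by the activator promoter.

    ``repressor`` forcing pools exogenous repressor into the repression term;
    ``inducer`` forcing sequesters endogenous repressor 1:1 (floored at 0).
    """
    if forcing_mode == "none":
        return h
    if forcing_mode == "repressor":
        return h + x_in
    if forcing_mode == "inducer":
        return max(h - x_in, 0.0)
    raise ParameterError(f"unknown forcing_mode {forcing_mode!r}")


def ode_rhs(state, params: OscillatorParams, forcing_mode: str = "none",
            dilution: bool = True) -> np.ndarray:
    """Time derivative (per second) of the full state vector.

    The four core equations (activator mRNA/protein, repressor mRNA/protein)
    are augmented by two reporter proteins translated from the same mRNAs,
    and by the passively diluting input species and reference dye.

    With ``dilution=False`` the continuous δ-removal terms are dropped; the
    semi-continuous reactor uses this variant because dilution is applied
    there through the discrete per-cycle map instead.
    """
    y = np.asarray(state, dtype=float)
    if y.ndim == 1 and y.shape[0] == len(STATE_CHANNELS):
        pass
    else:
        raise ParameterError("state must be a length-8 vector")
    if np.any(y < 0):
        raise ParameterError("state components must be non-negative")
    return _rhs(y, params, forcing_mode, dilution)


def _rhs(y: np.ndarray, params: OscillatorParams, forcing_mode: str,
         dilution: bool) -> np.ndarray:
    """Unchecked right-hand side; clamps tiny negative excursions of the
    integrator to zero before evaluating the Hill terms."""
    r_a, a, r_h, h, rep_a, rep_h, x_in, ref = y
    d = params.delta if dilution else 0.0
    h_eff = effective_repressor(max(h, 0.0), max(x_in, 0.0), forcing_mode)
    f_rep = hill_repression(h_eff, params.K_h, params.n_h)
    f_act = hill_activation(max(a, 0.0), params.K_a, params.n_a)
    return np.array([
        params.alpha_a_nM_s * f_rep - (d + 1.0 / params.tau_m_a_s) * r_a,
        params.k_TL_a * r_a - d * a,
        params.alpha_h_nM_s * f_act - (d + 1.0 / params.tau_m_h_s) * r_h,
        params.k_TL_h * r_h - d * h,
        params.k_TL_a * r_a - d * rep_a,
        params.k_TL_h * r_h - d * rep_h,
        -d * x_in,
        -d * ref,
    ])


def dilution_rate(R: float, t_int: float = 15.0) -> float:
    """Dilution rate δ = −ln(1−R)/t_int in s⁻¹.

    ``R`` is the refresh ratio (volume fraction replaced per feed),
    ``t_int`` the feed interval in minutes.
    """
    if not (0.0 < R < 1.0):
        raise ParameterError(f"refresh ratio must be in (0,1), got {R}")
    if t_int <= 0:
        raise ParameterError("t_int must be positive")
    return -math.log1p(-R) / (t_int * _S_PER_MIN)


def lambda_parameter(R: float, k: int) -> float:
    """Bifurcation parameter λ = T_in/T ≈ k·(−ln(1−R))/π.

    λ is the ratio of the forcing period ``T_in = k·t_int`` to the intrinsic
    period ``T ≈ π/δ``; it is independent of ``t_int``.
    """
    if not (0.0 < R < 1.0):
        raise ParameterError(f"refresh ratio must be in (0,1), got {R}")
    if k < 1:
        raise ParameterError("k must be a positive integer")
    return k * (-math.log1p(-R)) / math.pi


def refresh_for_lambda(lam: float, k: int) -> float:
    """Inverse of :func:`lambda_parameter`: refresh ratio giving λ at fixed k."""
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    if k < 1:
        raise ParameterError("k must be a positive integer")
    R = -math.expm1(-math.pi * lam / k)
    if not R < 1.0:
        raise ParameterError("requested lambda not reachable with R < 1")
    return R


def predicted_period(delta: float, C: float = 1.0) -> float:
    """Phenomenological period T ≈ C·π/δ, returned in hours."""
    if delta <= 0 or C <= 0:
        raise ParameterError("delta and C must be positive")
    return C * math.pi / delta / _S_PER_H


def _a_nullcline(h, params: OscillatorParams):
    scale = params.alpha_a_nM_s / params.delta * params.k_TL_a * params.tau_m_a_s
    return scale * hill_repression(h, params.K_h, params.n_h)


def _h_nullcline(a, params: OscillatorParams):
    scale = params.alpha_h_nM_s / params.delta * params.k_TL_h * params.tau_m_h_s
    return scale * hill_activation(a, params.K_a, params.n_a)


def nullclines(params: OscillatorParams, h_grid, a_grid):
    """Protein-space nullclines a(h) and h(a) (valid for δ ≪ 1/τ_m).

    Returns the pair of curves evaluated on the supplied grids (nM).  The
    Hill parameters set the *shape* of each curve while α/δ set its *scale*.
    """
    h_grid = np.asarray(h_grid, dtype=float)
    a_grid = np.asarray(a_grid, dtype=float)
    if h_grid.size == 0 or a_grid.size == 0:
        raise ParameterError("nullcline grids must be non-empty")
    return _a_nullcline(h_grid, params), _h_nullcline(a_grid, params)


def fixed_point(params: OscillatorParams) -> CircuitState:
    """Intersection of the two nullclines, by 1-D root finding on h ↦ h(a(h)).

    Returns the protein (and quasi-steady mRNA) coordinates of the unique
    fixed point of the monotone nullcline pair.
    """
    h_max = params.alpha_h_nM_s / params.delta * params.k_TL_h * params.tau_m_h_s

    def residual(h):
        return _h_nullcline(_a_nullcline(h, params), params) - h

    lo, hi = 0.0, h_max * (1 + 1e-9) + 1e-9
    if residual(lo) < 0 or residual(hi) > 0:
        raise ParameterError("no sign change on the fixed-point search bracket")
    h_star = brentq(residual, lo, hi, xtol=1e-12, rtol=1e-12)
    a_star = float(_a_nullcline(h_star, params))
    r_a = params.alpha_a_nM_s * hill_repression(h_star, params.K_h, params.n_h) * params.tau_m_a_s
    r_h = params.alpha_h_nM_s * hill_activation(a_star, params.K_a, params.n_a) * params.tau_m_h_s
    return CircuitState(r_a=r_a, a=a_star, r_h=r_h, h=float(h_star))
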