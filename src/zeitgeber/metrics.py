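"""Trace-level analyses: period estimation, phase-diagram metrics,
return maps, instantaneous refresh ratio, intensity normalization and
Hill transfer-curve fitting.

All estimators accept a plain 1-D signal plus its sampling interval in
hours, or a :class:`~zeitgeber.reactor.TimeTrace` together with a channel
name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import CalibrationError, EstimationError, ParameterError
from .reactor import TimeTrace

__all__ = [
    "PeriodEstimate", "PhaseMetrics", "RefreshSeries", "IntensityRecord",
    "HillFit", "acf_period", "damped_cosine_period", "fit_period_scaling",
    "phase_metrics",
    "return_map", "instantaneous_refresh", "normalize_intensity", "fit_hill",
]

#: default peak prominence, as a fraction of a channel's dynamic range
PROMINENCE_FRAC = 0.02


def _as_series(trace, channel=None, dt_h=None):
    if isinstance(trace, TimeTrace):
        if channel is None:
            if len(trace.channels) != 1:
                raise ParameterError("specify a channel for a multi-channel trace")
            channel = next(iter(trace.channels))
        return np.asarray(trace.channel(channel), dtype=float), trace.dt_h
    y = np.asarray(trace, dtype=float)
    if dt_h is None:
        raise ParameterError("dt_h is required when passing a bare array")
    return y, float(dt_h)


def _find_maxima(y, prominence_frac=PROMINENCE_FRAC):
    span = np.ptp(y)
    if span == 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(y, prominence=prominence_frac * span)
    return peaks


@dataclass
class PeriodEstimate:
    """An oscillation period with method and quality metadata.

    ``uncertainty_h`` is the systematic term T / (number of signal maxima):
    short records that contain few complete cycles carry proportionally
    larger period uncertainty.
    """

    period_h: float
    method: str
    first_acf_max_lag_h: float
    n_maxima_used: int
    uncertainty_h: float


def _normalized_acf(y):
    x = y - y.mean()
    acf = np.correlate(x, x, mode="full")[len(x) - 1:]
    if acf[0] <= 0:
        return None
    return acf / acf[0]


def acf_period(trace, channel=None, dt_h=None, upsample: int = 32,
               prominence_frac: float = PROMINENCE_FRAC):
    """Period from the first maximum of the autocorrelation function.

    The signal is mean-subtracted, its biased autocorrelation normalized to
    the lag-0 value, smoothly interpolated with a cubic spline on an
    ``upsample``-times finer lag grid, and the lag of the first local
    maximum at positive lag is returned as the period.

    Returns ``None`` when the ACF has no interior maximum (a non-oscillatory
    trace); raises only on invalid input.
    """
    y, dt = _as_series(trace, channel, dt_h)
    if y.size < 8 or not np.all(np.isfinite(y)):
        raise ParameterError("need >= 8 finite samples for period estimation")
    acf = _normalized_acf(y)
    if acf is None:
        return None
    lags = np.arange(y.size) * dt
    spline = CubicSpline(lags, acf)
    fine = np.linspace(0.0, lags[-1], y.size * upsample)
    acf_fine = spline(fine)
    # the ACF starts at its global maximum (lag 0); the period is the first
    # genuine maximum beyond it, i.e. after the ACF has passed its first dip
    minima, _ = find_peaks(-acf_fine)
    if minima.size == 0:
        return None
    peaks, _ = find_peaks(acf_fine)
    peaks = peaks[peaks > minima[0]]
    if peaks.size == 0:
        return None
    period = float(fine[peaks[0]])
    n_max = int(_find_maxima(y, prominence_frac).size)
    uncertainty = period / n_max if n_max else float("inf")
    return PeriodEstimate(period, "acf", period, n_max, uncertainty)


def damped_cosine_period(trace, channel=None, dt_h=None,
                         exclude_initial_h: float = 0.0):
    """Period from a decaying-cosine fit to the autocorrelation function.

    Fits ``A·exp(−t/τ)·cos(2πt/T + φ) + c`` to ACF lags beyond
    ``exclude_initial_h``.  Cross-check for :func:`acf_period`; the two
    agree on well-sampled oscillatory traces.
    """
    y, dt = _as_series(trace, channel, dt_h)
    if y.size < 8 or not np.all(np.isfinite(y)):
        raise ParameterError("need >= 8 finite samples for period estimation")
    acf = _normalized_acf(y)
    if acf is None:
        raise EstimationError("flat trace: autocorrelation undefined")
    lags = np.arange(y.size) * dt
    sel = lags >= exclude_initial_h
    if sel.sum() < 6:
        raise ParameterError("exclude_initial leaves too few ACF lags")
    t, z = lags[sel], acf[sel]

    seed = acf_period(y, dt_h=dt)
    T0 = seed.period_h if seed is not None else max(4 * dt, lags[-1] / 4)

    def model(t, A, tau, T, phi, c):
        return A * np.exp(-t / tau) * np.cos(2 * np.pi * t / T + phi) + c

    try:
        popt, pcov = curve_fit(
            model, t, z, p0=[1.0, lags[-1] / 2, T0, 0.0, 0.0],
            bounds=([0, dt, 2 * dt, -np.pi, -1], [10, np.inf, np.inf, np.pi, 1]),
            maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise EstimationError(f"damped-cosine fit did not converge: {err}") from err
    A, tau, T, phi, c = popt
    if T > lags[-1] or A < 1e-3:
        raise EstimationError(
            f"damped-cosine fit is decay-dominated (T={T:.3g} h, A={A:.3g}); "
            "the trace is not oscillatory")
    n_max = int(_find_maxima(y).size)
    uncertainty = T / n_max if n_max else float("inf")
    return PeriodEstimate(float(T), "damped_cosine", float(T), n_max, uncertainty)


def fit_period_scaling(deltas, estimates) -> float:
    """Weighted slope C of the scaling law T = C·π/δ.

    ``estimates`` are :class:`PeriodEstimate` objects (entries may be
    ``None`` for non-oscillatory runs and are skipped).  The fit is
    inverse-variance weighted with each period's systematic uncertainty
    σ_T = T/n_maxima, so short records containing few complete cycles —
    whose ACF period is dominated by the initial transient — contribute
    little.
    """
    x, y, w = [], [], []
    for delta, est in zip(deltas, estimates):
        if est is None or not np.isfinite(est.period_h):
            continue
        sigma = est.uncertainty_h if est.uncertainty_h > 0 else est.period_h
        if not np.isfinite(sigma):
            continue
        x.append(np.pi / delta / 3600.0)
        y.append(est.period_h)
        w.append(1.0 / sigma ** 2)
    if len(x) < 2:
        raise EstimationError("need at least two oscillatory runs to fit C")
    x, y, w = map(np.asarray, (x, y, w))
    return float(np.sum(w * x * y) / np.sum(w * x * x))


@dataclass
class PhaseMetrics:
    """Damping classification of a free-running trace.

    ``A_inf`` — half the peak-to-trough span of the final full oscillation,
    normalized by the global maximum; ``gamma`` — mean ratio of successive
    maxima ⟨y_i/y_{i+1}⟩ (γ≈1 sustained, γ>1 damped); ``tau_eq`` —
    exponential equilibration time, used when fewer than two maxima exist.
    """

    A_inf: float | None
    gamma: float | None
    tau_eq_h: float | None
    regime: str
    n_maxima: int


def phase_metrics(trace, channel=None, dt_h=None, horizon_h: float = 48.0,
                  gamma_tol: float = 0.05,
                  prominence_frac: float = PROMINENCE_FRAC) -> PhaseMetrics:
    """Classify a free-running trace as sustained / damped / overdamped."""
    y, dt = _as_series(trace, channel, dt_h)
    n = min(y.size, int(round(horizon_h / dt)))
    y = y[:n]
    t = np.arange(n) * dt
    peaks = _find_maxima(y, prominence_frac)

    if peaks.size >= 2:
        heights = y[peaks]
        # a reactor filling from empty overshoots on its first maximum;
        # the damping ratio describes the approach to the attractor, so
        # the overshoot is excluded whenever enough maxima remain
        if heights.size >= 3:
            heights = heights[1:]
        gamma = float(np.mean(heights[:-1] / heights[1:]))
        lo, hi = peaks[-2], peaks[-1]
        trough = y[lo:hi + 1].min()
        A_inf = float(0.5 * (y[hi] - trough) / y.max()) if y.max() > 0 else 0.0
        regime = "sustained" if gamma <= 1.0 + gamma_tol else "damped"
        return PhaseMetrics(A_inf, gamma, None, regime, int(peaks.size))

    # fewer than two maxima: exponential equilibration
    if np.ptp(y) == 0:
        return PhaseMetrics(None, None, None, "overdamped", int(peaks.size))

    def expo(t, x_inf, x0, tau):
        return x_inf + (x0 - x_inf) * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(expo, t, y, p0=[y[-1], y[0], max(t[-1] / 4, dt)],
                            maxfev=10000)
        tau_eq = float(abs(popt[2]))
    except (RuntimeError, ValueError):
        tau_eq = None
    return PhaseMetrics(None, None, tau_eq, "overdamped", int(peaks.size))


def return_map(maxima) -> np.ndarray:
    """Lag-1 pairs (y_i, y_{i+1}) of a maxima sequence, in order.

    An exact m-cycle occupies exactly m distinct points of the map.
    """
    m = np.asarray(maxima, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ParameterError("need at least two maxima for a return map")
    return np.column_stack([m[:-1], m[1:]])


@dataclass
class RefreshSeries:
    """Per-cycle instantaneous refresh ratio R_t = 1 − I_{t+1}/I_t.

    ``mask`` marks pairs whose predecessor intensity exceeded the detection
    threshold; ``flagged`` marks masked pairs whose value falls outside the
    plausible band (−0.5, 1) — typically pairs spanning a feed spike —
    which are excluded from summaries.
    """

    cycle: np.ndarray
    time_h: np.ndarray
    R_t: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.mask & ~self.flagged

    def summary(self, t_start_h: float = 0.0, t_end_h: float = 24.0) -> float:
        """Mean R_t over valid points in the window [t_start, t_end) hours."""
        sel = self.valid & (self.time_h >= t_start_h) & (self.time_h < t_end_h)
        if not sel.any():
            return float("nan")
        return float(self.R_t[sel].mean())


def instantaneous_refresh(trace, channel=None, dt_h=None,
                          frac_threshold: float = 0.3) -> RefreshSeries:
    """Realized refresh ratio from a reference-dye decay trace.

    R_t is evaluated for every consecutive pair whose first intensity
    exceeds ``frac_threshold`` of the global maximum; spike-spanning pairs
    (strongly negative R_t) are reported but flagged.
    """
    y, dt = _as_series(trace, channel, dt_h)
    if y.size < 2:
        raise ParameterError("need at least two samples")
    if np.any(y < 0):
        raise ParameterError("reference intensities must be non-negative")
    i_max = y.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        R_t = 1.0 - y[1:] / y[:-1]
    mask = y[:-1] > frac_threshold * i_max
    flagged = ~((R_t > -0.5) & (R_t < 1.0)) | ~np.isfinite(R_t)
    cycles = np.arange(y.size - 1)
    return RefreshSeries(cycles, cycles * dt, R_t, mask, flagged)


@dataclass
class IntensityRecord:
    """Raw intensities and the calibration constants to convert them.

    ``I``/``B`` — sample and background intensity (``I`` may be an array);
    ``I0``/``B0`` — calibration-dye measurement of the same reactor;
    ``*_ref`` — one-point reference measurements (1 μM reporter, and the
    calibration dye under identical conditions).
    """

    I: np.ndarray | float
    B: float
    I0: float
    B0: float
    I_ref: float
    B_ref: float
    I0_ref: float
    B0_ref: float


def normalize_intensity(rec: IntensityRecord):
    """Convert raw intensity to concentration in μM.

    ``c = (I−B)/(I0−B0) · (I0_ref−B0_ref)/(I_ref−B_ref) · 1 μM`` —
    background-subtracted intensity normalized per-reactor by its dye
    calibration and scaled by the one-point reference, making
    concentrations comparable across experiments.
    """
    denom1 = rec.I0 - rec.B0
    denom2 = rec.I_ref - rec.B_ref
    if denom1 == 0 or denom2 == 0:
        raise CalibrationError("calibration denominators must be nonzero")
    I = np.asarray(rec.I, dtype=float)
    c = (I - rec.B) / denom1 * (rec.I0_ref - rec.B0_ref) / denom2
    return c if c.ndim else float(c)


@dataclass
class HillFit:
    """Fitted Hill transfer-curve parameters with 68% confidence intervals."""

    K: float
    n: float
    K_err: float
    n_err: float
    scale: float
    offset: float
    mode: str


def fit_hill(conc, response, mode: str) -> HillFit:
    """Least-squares Hill fit of a titration table (free scale and offset).

    ``mode='repression'`` fits ``c0 + A·K^n/(K^n + x^n)``;
    ``mode='activation'`` fits ``c0 + A·x^n/(x^n + K^n)``.  Reported errors
    are 1σ (68%) intervals from the fit covariance.
    """
    if mode not in ("repression", "activation"):
        raise ParameterError(f"unknown mode {mode!r}")
    x = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ParameterError("conc and response must be matching 1-D arrays")
    if x.size < 4:
        raise EstimationError("need >= 4 titration points spanning the transition")
    if np.any(x < 0):
        raise ParameterError("concentrations must be non-negative")

    def model(x, K, n, A, c0):
        xn = np.power(x, n)
        Kn = np.power(K, n)
        frac = Kn / (Kn + xn) if mode == "repression" else xn / (xn + Kn)
        return c0 + A * frac

    pos = x[x > 0]
    K0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    A0 = float(np.ptp(y)) or 1.0
    c00 = float(y.min())
    try:
        popt, pcov = curve_fit(model, x, y, p0=[K0, 2.0, A0, c00],
                               bounds=([1e-12, 0.05, 1e-12, -np.inf],
                                       [np.inf, 50.0, np.inf, np.inf]),
                               maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise EstimationError(f"Hill fit did not converge: {err}") from err
    perr = np.sqrt(np.diag(pcov))
    K, n = float(popt[0]), float(popt[1])
    K_err, n_err = float(perr[0]), float(perr[1])
    # identifiability: the titration must traverse the transition — the
    # fitted curve must sweep a substantial part of its own amplitude on
    # the sampled grid, and the errors must be finite and meaningful
    fitted = model(x, *popt)
    coverage = np.ptp(fitted) / abs(popt[2]) if popt[2] else 0.0
    if (not np.all(np.isfinite([K_err, n_err])) or K_err > K
            or coverage < 0.5):
        raise EstimationError(
            f"Hill parameters unidentifiable from this titration "
            f"(K={K:.3g}±{K_err:.3g} nM, transition coverage "
            f"{coverage:.0%} on [{x.min():.3g}, {x.max():.3g}] nM)")
    return HillFit(K, n, K_err, n_err, float(popt[2]), float(popt[3]), mode)
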