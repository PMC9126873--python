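"""Synthetic pseudo-experimental datasets.

Generates datasets with the statistical structure of the microfluidic
measurements so the full analysis chain is testable without any recorded
data: fluorescence time traces in raw-intensity space (invertible through
the intensity calibration), a periodically spiked exponentially decaying
reference-dye channel, late-run reactor fatigue (a small decline of the
refresh ratio), and noisy Hill titration tables.

Noise is applied in intensity space — multiplicative lognormal (imaging
gain/shot noise) followed by additive background noise — because the
experiment measures fluorescence, not concentration.  Identical seeds
yield bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .metrics import IntensityRecord
from .model import OscillatorParams
from .reactor import ReactorProtocol, TimeTrace, run_reactor

__all__ = ["NoiseModel", "FatigueModel", "Calibration", "SyntheticExperiment",
           "generate_experiment", "generate_titration",
           "generate_reference_trace", "recover_concentrations"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic intensities.

    ``cv_mult`` — coefficient of variation of the multiplicative lognormal
    component; ``sigma_add`` — additive Gaussian noise (a.u.);
    ``background_level`` — constant background B added to every intensity.
    """

    cv_mult: float = 0.05
    sigma_add: float = 1.0
    background_level: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.cv_mult < 0 or self.sigma_add < 0:
            raise ParameterError("noise magnitudes must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Multiplicative lognormal (unit mean) then additive noise."""
        out = np.asarray(intensity, dtype=float).copy()
        if self.cv_mult > 0:
            sigma = np.sqrt(np.log1p(self.cv_mult ** 2))
            out *= rng.lognormal(-0.5 * sigma ** 2, sigma, size=out.shape)
        out += self.background_level
        if self.sigma_add > 0:
            out += rng.normal(0.0, self.sigma_add, size=out.shape)
        return out


@dataclass(frozen=True)
class FatigueModel:
    """Late-run decline of the realised refresh ratio.

    After ``onset_h`` hours the refresh ratio drops by ``drop`` (absolute,
    default one percentage point) — either as a step or as a linear ramp
    over ``ramp_h`` hours.  Emulates reactor fatigue seen in long
    recordings; R never falls below a small positive floor.
    """

    onset_h: float = 36.0
    drop: float = 0.01
    shape: str = "step"
    ramp_h: float = 12.0

    def __post_init__(self):
        if self.shape not in ("step", "linear"):
            raise ParameterError(f"unknown fatigue shape {self.shape!r}")
        if self.drop < 0:
            raise ParameterError("drop must be non-negative")

    def refresh_schedule(self, R0: float, time_h: np.ndarray) -> np.ndarray:
        t = np.asarray(time_h, dtype=float)
        if self.shape == "step":
            decline = np.where(t >= self.onset_h, self.drop, 0.0)
        else:
            frac = np.clip((t - self.onset_h) / self.ramp_h, 0.0, 1.0)
            decline = self.drop * frac
        return np.maximum(R0 - decline, 1e-3)


@dataclass(frozen=True)
class Calibration:
    """Intensity calibration constants shared by all synthetic channels.

    Chosen so that 1 μM of reporter maps to ``(I0−B0)·(I_ref−B_ref) /
    (I0_ref−B0_ref)`` a.u. above background.
    """

    I0: float = 1200.0
    B0: float = 200.0
    I_ref: float = 2100.0
    B_ref: float = 100.0
    I0_ref: float = 1500.0
    B0_ref: float = 500.0

    def encode(self, conc_nM: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Exact inverse of the intensity-normalization formula: nM → a.u."""
        c_uM = np.asarray(conc_nM, dtype=float) / 1000.0
        gain = (self.I0 - self.B0) * (self.I_ref - self.B_ref) / (self.I0_ref - self.B0_ref)
        return background + c_uM * gain

    def record(self, I, background: float) -> IntensityRecord:
        return IntensityRecord(I=I, B=background, I0=self.I0, B0=self.B0,
                               I_ref=self.I_ref, B_ref=self.B_ref,
                               I0_ref=self.I0_ref, B0_ref=self.B0_ref)


@dataclass
class SyntheticExperiment:
    """Raw dataset plus its noise-free ground truth."""

    raw: TimeTrace
    truth: TimeTrace
    calibration: Calibration
    noise: NoiseModel
    R_schedule: np.ndarray
    protocol: ReactorProtocol
    params: OscillatorParams = None


#: channels that the synthetic microscope "sees"
_FLUORESCENT = ("rep_a", "rep_h", "ref")


def generate_experiment(params: OscillatorParams, protocol: ReactorProtocol,
                        noise: NoiseModel, fatigue: FatigueModel | None = None,
                        calibration: Calibration | None = None,
                        truth: TimeTrace | None = None) -> SyntheticExperiment:
    """Simulate a recording: reactor run → intensities → seeded noise.

    The reactor is run with a per-cycle refresh ratio from the fatigue
    model (constant R when ``fatigue`` is ``None``); the fluorescent
    channels are converted to raw intensities by the exact inverse of the
    normalization formula and degraded with seeded noise.  The noise-free
    ground-truth trace is returned alongside, so recovered quantities can
    always be compared to their true values.

    A precomputed ``truth`` trace (from an identical reactor run) may be
    supplied to skip re-integration when only the noise realisation varies.
    """
    cal = calibration or Calibration()
    cycles = np.arange(protocol.n_cycles)
    time_h = (cycles + 1) * protocol.t_int / 60.0
    if fatigue is None:
        R_schedule = np.full(protocol.n_cycles, protocol.R)
    else:
        R_schedule = fatigue.refresh_schedule(protocol.R, time_h)
    if truth is None:
        truth = run_reactor(params, protocol, R_schedule=R_schedule)
    rng = noise.rng()
    raw_channels = {}
    for ch in _FLUORESCENT:
        I = cal.encode(truth.channel(ch))
        raw_channels[ch] = noise.apply(I, rng)
    raw = TimeTrace(truth.cycle.copy(), truth.time_h.copy(), raw_channels)
    return SyntheticExperiment(raw, truth, cal, noise, R_schedule, protocol, params)


def recover_concentrations(raw: TimeTrace, calibration: Calibration,
                           background: float) -> TimeTrace:
    """Analysis-side inverse: raw intensities → concentrations (nM).

    Applies the intensity-normalization formula with the dataset's
    calibration block; with zero noise this is the exact inverse of
    :func:`generate_experiment`'s encoding.
    """
    from .metrics import normalize_intensity

    channels = {}
    for ch, I in raw.channels.items():
        c_uM = normalize_intensity(calibration.record(I, background))
        channels[ch] = np.asarray(c_uM, dtype=float) * 1000.0
    return TimeTrace(raw.cycle.copy(), raw.time_h.copy(), channels)


def generate_titration(mode: str, K: float, n: float, conc_grid,
                       noise: NoiseModel | None = None,
                       response_sigma: float = 0.02):
    """Noisy Hill titration table (regulator concentration vs response).

    Evaluates the matching Hill form on ``conc_grid`` (normalized response
    in [0, 1]) and adds seeded noise: multiplicative with ``noise.cv_mult``
    plus additive with ``response_sigma`` (the dominant term for
    normalized fluorescence).  Returns ``(conc, response)`` arrays.
    """
    from .model import hill_activation, hill_repression

    if mode not in ("repression", "activation"):
        raise ParameterError(f"unknown mode {mode!r}")
    x = np.asarray(conc_grid, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ParameterError("conc_grid must be a non-empty 1-D array")
    f = hill_repression(x, K, n) if mode == "repression" else hill_activation(x, K, n)
    noise = noise or NoiseModel(cv_mult=0.0, sigma_add=0.0, background_level=0.0)
    rng = noise.rng()
    y = np.asarray(f, dtype=float).copy()
    if noise.cv_mult > 0:
        sigma = np.sqrt(np.log1p(noise.cv_mult ** 2))
        y *= rng.lognormal(-0.5 * sigma ** 2, sigma, size=y.shape)
    if response_sigma > 0:
        y += rng.normal(0.0, response_sigma, size=y.shape)
    return x, y


def generate_reference_trace(protocol: ReactorProtocol, noise: NoiseModel,
                             fatigue: FatigueModel | None = None,
                             spike: float = 1000.0) -> tuple[TimeTrace, TimeTrace]:
    """Reference-dye channel alone: spikes plus geometric decay, plus noise.

    Pure tracer dynamics need no ODE solve: the dye is spiked by ``spike``
    (a.u.) on every k-th feed and multiplied by (1−R_i) on every feed.
    Returns ``(noisy, clean)`` single-channel traces in intensity space.
    """
    cycles = np.arange(protocol.n_cycles)
    time_h = (cycles + 1) * protocol.t_int / 60.0
    if fatigue is None:
        R_schedule = np.full(protocol.n_cycles, protocol.R)
    else:
        R_schedule = fatigue.refresh_schedule(protocol.R, time_h)
    ref = np.empty(protocol.n_cycles)
    x = 0.0
    for i in range(protocol.n_cycles):
        ref[i] = x  # sample at interval end, before the feed
        x *= 1.0 - R_schedule[i]
        if i % protocol.k == 0:
            x += spike
    clean = TimeTrace(cycles, time_h, {"ref": ref})
    noisy = TimeTrace(cycles.copy(), time_h.copy(),
                      {"ref": noise.apply(ref, noise.rng())})
    return noisy, clean
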