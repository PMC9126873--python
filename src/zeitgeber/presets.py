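"""Bundled parameter presets and flat YAML/JSON config (de)serialization.

Two presets cover the regimes the package is built around:

``free``
    Free-running oscillator used for the phase diagram, period-vs-δ
    sweep and sensitivity analysis: n = 3, K_a = 20 nM, K_h = 2 nM,
    k_TL = 0.02 s⁻¹, τ_m = 12 min, α = 3 pM s⁻¹ (α is the tunable
    expression strength, proportional to template concentration).

``forced``
    Periodically forced oscillator used for entrainment, period-doubling
    and bifurcation scans: same system parameters except α = 5 pM s⁻¹ and
    n = 4, driven by a 50 nM repressor spike every 16th feed
    (T_in = 4 h at t_int = 15 min).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ParameterError
from .model import OscillatorParams, dilution_rate
from .reactor import ReactorProtocol

__all__ = ["PRESETS", "get_preset", "params_from_config", "protocol_from_config",
           "load_config", "save_config"]


def _free_params(alpha: float = 3.0, R: float = 0.25, t_int: float = 15.0) -> OscillatorParams:
    return OscillatorParams.uniform(alpha=alpha, K_a=20.0, K_h=2.0, n=3.0,
                                    k_TL=0.02, tau_m=12.0,
                                    delta=dilution_rate(R, t_int))


def _forced_params(R: float = 0.25, t_int: float = 15.0) -> OscillatorParams:
    return OscillatorParams.uniform(alpha=5.0, K_a=20.0, K_h=2.0, n=4.0,
                                    k_TL=0.02, tau_m=12.0,
                                    delta=dilution_rate(R, t_int))


PRESETS = {
    "free": lambda: (_free_params(),
                     ReactorProtocol(R=0.25, n_cycles=192)),
    "forced": lambda: (_forced_params(),
                       ReactorProtocol(R=0.25, n_cycles=1012,
                                       input_species="repressor",
                                       A_in=50.0, k=16, ref_spike=500.0)),
}


def get_preset(name: str):
    """Return a fresh ``(OscillatorParams, ReactorProtocol)`` pair."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory()


_PARAM_KEYS = [f.name for f in dataclasses.fields(OscillatorParams)]
_PROTOCOL_KEYS = [f.name for f in dataclasses.fields(ReactorProtocol)]


def params_from_config(cfg: dict) -> OscillatorParams:
    return OscillatorParams(**{k: cfg[k] for k in _PARAM_KEYS})


def protocol_from_config(cfg: dict) -> ReactorProtocol:
    kwargs = {k: cfg[k] for k in _PROTOCOL_KEYS if k in cfg}
    return ReactorProtocol(**kwargs)


def load_config(path) -> dict:
    """Load a flat key–value config (YAML, which subsumes JSON)."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError("config file must contain a flat mapping")
    return cfg


def save_config(params: OscillatorParams, protocol: ReactorProtocol, path) -> None:
    cfg = {**dataclasses.asdict(params), **dataclasses.asdict(protocol)}
    with open(Path(path), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
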