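"""Shared fixtures: presets and cached forced-oscillator runs.

Forced runs with full equilibration are the expensive ingredient (about a
second each); they are simulated once per session and shared between the
unit tests and the acceptance tests.
"""

from dataclasses import replace

import pytest
from hypothesis import settings

from zeitgeber import (OscillatorParams, dilution_rate, refresh_for_lambda,
                       run_reactor)
from zeitgeber.presets import get_preset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def free_preset():
    return get_preset("free")


@pytest.fixture(scope="session")
def forced_preset():
    return get_preset("forced")


@pytest.fixture(scope="session")
def forced_run():
    """Factory for equilibrated forced runs, cached per (λ, n, n_cycles)."""
    cache = {}
    _, template = get_preset("forced")

    def factory(lam, n=4.0, n_cycles=1012):
        key = (lam, n, n_cycles)
        if key not in cache:
            R = refresh_for_lambda(lam, template.k)
            params = OscillatorParams.uniform(
                alpha=5.0, K_a=20.0, K_h=2.0, n=n, k_TL=0.02, tau_m=12.0,
                delta=dilution_rate(R, template.t_int))
            protocol = replace(template, R=R, n_cycles=n_cycles)
            cache[key] = run_reactor(params, protocol)
        return cache[key]

    return factory


@pytest.fixture(scope="session")
def free_trace(free_preset):
    """Default 48-h free-oscillator recording (α = 3 pM/s, R = 0.25)."""
    params, protocol = free_preset
    return run_reactor(params, protocol)
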