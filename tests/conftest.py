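"""Shared fixtures: small synthetic window sets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import interfep as ifp


@pytest.fixture(scope="session")
def double_well_model():
    """Hydrophilic-like surface: well -10 kJ/mol, bulk -4 kJ/mol."""
    return ifp.PotentialModel(g_bulk=-4.0, g_surface_min=-10.0)


@pytest.fixture(scope="session")
def flat_model():
    return ifp.PotentialModel()


@pytest.fixture(scope="session")
def scheme84():
    return ifp.make_window_scheme(7, 1.0, 12, -3.5, 3.5)


def _sample_scheme(model, scheme, seed, n_steps, stride=10):
    windows = [
        ifp.UmbrellaWindow(center=c, force_constant=2000.0)
        for c in scheme.centers()
    ]
    cfg = ifp.SamplerConfig(seed=seed, n_steps=n_steps, stride=stride)
    windows = ifp.sample_windows(model, windows, cfg)
    return [ifp.discard_equilibration(w) for w in windows]


@pytest.fixture(scope="session")
def small_window_set(double_well_model, scheme84):
    """84 windows at reduced sampling: fast, adequate for structural tests."""
    return _sample_scheme(double_well_model, scheme84, seed=101, n_steps=60_000)


@pytest.fixture(scope="session")
def small_fit(small_window_set):
    model = ifp.UmbrellaSampling(small_window_set)
    return model.fit()


@pytest.fixture(scope="session")
def analytic_profile(double_well_model):
    """Fine-grid profile computed directly from the generating surface."""
    z = np.arange(-3.6 + 0.005, 3.6, 0.01)
    g = double_well_model.value(z)
    prof = ifp.FreeEnergyProfile(z=z, g=g, temperature=300.0)
    return ifp.set_reference(prof, (3.0, 3.5))
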