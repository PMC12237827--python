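"""Shared fixtures: virtual landscapes and fitted comparisons.

Heavy end-to-end fits are session-scoped so the recovery checks share one
computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from nicheshift.models import NicheShiftModel
from nicheshift.pipeline import simulate_species
from nicheshift.synthetic import generate_landscape

logging.getLogger("nicheshift").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def landscape2():
    """64x64 two-variable landscape (0.1 deg cells near the equator)."""
    return generate_landscape(64, 64, 2, smoothness=6.0, seed=11)


@pytest.fixture(scope="session")
def landscape6():
    """64x64 six-variable landscape used by the end-to-end recovery fits."""
    return generate_landscape(64, 64, 6, smoothness=6.0, seed=8)


@pytest.fixture(scope="session")
def zero_shift_fit(landscape6):
    """End-to-end fit of a virtual species whose introduced population has
    the same niche as the native one (no injected shift, breadth scale 1)."""
    occ, niche_native, niche_introduced = simulate_species(
        landscape6, "virtualis", 1000, 1000,
        shift_sigma=0.0, breadth_scale=1.0, seed=5,
    )
    model = NicheShiftModel(occ=occ, stack=landscape6, n_pa_reps=2)
    result = model.fit(seed=5)
    return {
        "result": result,
        "niche_native": niche_native,
        "niche_introduced": niche_introduced,
        "stack": landscape6,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
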