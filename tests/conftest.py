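"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cryptomorph import ShapeSimSpec, gpa, simulate_shapes

HEXAGON = np.array(
    [
        (1.0, 0.0),
        (0.5, 0.9),
        (-0.5, 0.9),
        (-1.0, 0.0),
        (-0.5, -0.9),
        (0.5, -0.9),
    ]
)


def hexagon_spec(**kw) -> ShapeSimSpec:
    """A fast 6-landmark simulation spec for statistical tests."""
    defaults = dict(
        template=HEXAGON / np.sqrt(np.sum((HEXAGON - HEXAGON.mean(0)) ** 2)),
        n_species=2,
        n_sites=1,
        n_specimens=10,
        n_replicates=2,
        species_effect_scale=0.0,
        site_effect_scale=0.0,
        sigma=0.01,
        sigma_rep=0.003,
        seed=0,
    )
    defaults.update(kw)
    return ShapeSimSpec(**defaults)


@pytest.fixture(scope="session")
def small_aligned():
    """A small aligned dataset with a planted species difference."""
    spec = hexagon_spec(
        species_effect_scale=0.03,
        site_effect_scale=0.01,
        n_sites=2,
        n_specimens=8,
        seed=7,
    )
    return gpa(simulate_shapes(spec))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
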