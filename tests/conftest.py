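"""Shared fixtures: small deterministic datasets built in proxy space
(protein from the package's own filter, synthesis rate from a known GRF),
plus the heavier ODE-generated fixtures, cached per session."""

import math

import numpy as np
import pytest

from grfkit.dataio import GeneTimeSeries, Kind, default_grid
from grfkit.grf_models import GRFForm, GRFSpec, evaluate
from grfkit.protein_proxy import Propagator
from grfkit.synthetic_data import make_fixture

LAM_TRUE = math.log(2) / 20.0


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def tf_mrna(grid):
    """Oscillating TF mRNA trace on the default grid (60-min period)."""
    t = grid.times
    return GeneTimeSeries("TF", Kind.mrna_level,
                          1.0 + 0.8 * np.sin(2 * np.pi * t / 60.0), grid)


@pytest.fixture(scope="session")
def tf_protein(tf_mrna):
    """Protein proxy of the TF at the canonical true rate."""
    return Propagator(tf_mrna, lam_min=LAM_TRUE).values(LAM_TRUE)


def proxy_target(name, spec, proteins, grid, noise_sigma=0.0, seed=0):
    """Synthesis-rate series that is exactly consistent with the package's
    proxy construction: s = GRF(p) with p from the Propagator."""
    s = np.asarray(evaluate(spec, proteins), float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = s * np.exp(noise_sigma * rng.standard_normal(s.size))
    return GeneTimeSeries(name, Kind.synthesis_rate, s, grid)


@pytest.fixture(scope="session")
def act_target(tf_mrna, tf_protein, grid):
    """Noise-free activator-driven target with known parameters."""
    spec = GRFSpec(GRFForm.ACT, b=0.1, alpha=2.0, K=(1.0,), n=(3.0,),
                   inputs=("TF",))
    return proxy_target("T_ACT", spec, [tf_protein], grid), spec


@pytest.fixture(scope="session")
def single_activator_ds():
    return make_fixture("single_activator", seed=1)


@pytest.fixture(scope="session")
def two_input_and_ds():
    return make_fixture("two_input_and", seed=1)


@pytest.fixture(scope="session")
def ring_ds():
    return make_fixture("ring_oscillator_5", seed=1)
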