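"""Shared fixtures: small synthetic recordings reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from calnetdyn.synthetic import astro_like, generate_network, neuron_like, render_traces

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def astro_truth():
    """Independent astro-like cells with well-separated events (no network)."""
    spec = astro_like(n_cells=10, edge_density=0.0, refractory_s=40.0,
                      duration_s=600.0, seed=11)
    return generate_network(spec)


@pytest.fixture(scope="session")
def astro_traces(astro_truth):
    return render_traces(astro_truth)


@pytest.fixture(scope="session")
def network_truth():
    """Neuron-like feed-forward network (the connectivity benchmark regime)."""
    spec = neuron_like(n_cells=30, edge_density=0.1, transmission_prob=0.9,
                       event_rate_per_min=2.0, seed=5)
    return generate_network(spec)


@pytest.fixture(scope="session")
def network_traces(network_truth):
    return render_traces(network_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
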