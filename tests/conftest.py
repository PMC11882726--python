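"""Shared fixtures: synthetic panels and LDSC stacks at desk scale."""

from __future__ import annotations

import numpy as np
import pytest

from factorgwas import ldsc as L
from factorgwas import simulate as sim


def reverse_coded_back(panel, config):
    """Undo the generator's raw-scale sign flips, as the analysis does."""
    Z = panel.Z.copy()
    for i, tr in enumerate(config.traits):
        if tr.reverse_coded:
            Z[:, i] = -Z[:, i]
    return type(panel)(panel.snps, list(panel.traits), Z, panel.N)


@pytest.fixture(scope="session")
def demo_config_small():
    return sim.default_demo_config(m_snps=20_000, seed=0)


@pytest.fixture(scope="session")
def demo_panel_small(demo_config_small):
    panel, ldscores = sim.simulate_panel(demo_config_small)
    return reverse_coded_back(panel, demo_config_small), ldscores


@pytest.fixture(scope="session")
def demo_stack_small(demo_config_small, demo_panel_small):
    panel, ldscores = demo_panel_small
    return L.build_covariance_stack(panel, ldscores, demo_config_small.m_snps,
                                    n_blocks=100)


@pytest.fixture(scope="session")
def sample_sizes(demo_config_small):
    return np.array([t.n for t in demo_config_small.traits], float)
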