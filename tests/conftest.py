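"""Shared fixtures: small synthetic datasets and a trained toy marker.

Session-scoped fixtures keep the expensive pieces (ensemble training) to a
single run; everything is generated programmatically from fixed seeds.
"""

from dataclasses import replace

import numpy as np
import pytest

import fcmarker as fm


@pytest.fixture(scope="session")
def tiny_config():
    """Two-site, 12-ROI configuration with a strong planted effect."""
    return replace(
        fm.default_config(seed=11),
        roi_count=12,
        sites=(fm.SiteSpec("s1", 30, 12), fm.SiteSpec("s2", 30, 12)),
        n_effect_edges=8,
        effect_d=1.2,
    )


@pytest.fixture(scope="session")
def tiny_family(tiny_config):
    return fm.simulate_family(tiny_config, n_validation=1)


@pytest.fixture(scope="session")
def tiny_discovery(tiny_family):
    return tiny_family[0]


@pytest.fixture(scope="session")
def tiny_harmonized(tiny_discovery):
    harmonized, _ = fm.harmonize(tiny_discovery)
    return harmonized


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_harmonized):
    """5 folds x 2 subsamples = 10 classifiers on the tiny discovery set."""
    return fm.train_ensemble(tiny_harmonized, k_folds=5, n_subsamples=2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
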