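"""Shared fixtures.

The expensive artifacts (featurized datasets, trained cascades) are
session-scoped and sized for speed: unit tests run on a reduced replicate
design and a smaller forest, which preserves every contract under test;
the acceptance tests build their own full-size inputs.
"""

import pytest

import serstax as sx
from serstax.taxonomy import TaxonomyHyperparams


@pytest.fixture(scope="session")
def cfg():
    return sx.SyntheticConfig()


@pytest.fixture(scope="session")
def cfg_quiet(cfg):
    """All noise sources off."""
    return cfg.noise_free()


@pytest.fixture(scope="session")
def mini_hp():
    """Reduced forest for fast unit tests of the cascade contracts."""
    return TaxonomyHyperparams(n_trees=100)


@pytest.fixture(scope="session")
def mini_dataset(cfg):
    """14 classes x 6 replicates at the top concentration."""
    return sx.generate_dataset(cfg, seed=101, replicates=6)


@pytest.fixture(scope="session")
def mini_features(mini_dataset):
    return sx.featurize_dataset(mini_dataset)


@pytest.fixture(scope="session")
def quiet_features(cfg_quiet):
    """Noise-free 14 x 10 feature table (classes are point masses; sized so
    stratified 80/20 splits keep every class on both sides)."""
    sset = sx.generate_dataset(cfg_quiet, seed=7, replicates=10)
    return sx.featurize_dataset(sset)


@pytest.fixture(scope="session")
def mini_model(mini_features, mini_hp):
    return sx.train_taxonomy(mini_features, mini_hp, seed=0)


@pytest.fixture()
def blank_spectrum(cfg):
    sp = sx.generate_spectrum(sx.AnalyteLabel.blank(), cfg.c_max, cfg,
                              seed=3)
    return sx.preprocess_spectrum(sp)
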