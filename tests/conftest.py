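"""Shared fixtures: small synthetic cohorts and one trained model per session."""

import numpy as np
import pytest

import gsae
from gsae.model import NetworkConfig


@pytest.fixture(scope="session")
def subtype_cohort():
    """Default two-group subtype cohort (300 x 400, 30 sets, delta = 2)."""
    spec = gsae.FixtureSpec(seed=0)
    collection = gsae.make_collection(spec)
    expr, labels, planted = gsae.make_subtype_data(spec, collection)
    return spec, collection, expr, labels, planted


@pytest.fixture(scope="session")
def trained_autoencoder(subtype_cohort):
    """A gene-superset autoencoder trained once on the subtype cohort."""
    _, collection, expr, _, _ = subtype_cohort
    mask, kept = gsae.build_mask(collection, expr)
    model = gsae.fit_autoencoder(expr, mask, NetworkConfig.small_cohort(seed=100))
    scores = gsae.encode(model, expr)
    return model, mask, scores


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
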