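"""Shared fixtures: small synthetic cohorts and one full-size reference fit."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from matchrank.matching import match_case_control
from matchrank.model import build_model_input, fit_matched_model
from matchrank.simulate import SyntheticConfig, generate_matched_cohort

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny matched cohort (8 pairs x 10 features) for unit tests."""
    cfg = SyntheticConfig(n_pairs=8, d=10, seed=5)
    table, metadata, truth = generate_matched_cohort(cfg)
    pairs = match_case_control(metadata)
    return table, metadata, truth, pairs


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A quick matched-model fit on the tiny cohort."""
    table, metadata, truth, pairs = small_cohort
    mi = build_model_input(table, pairs, metadata)
    post = fit_matched_model(mi, {"chains": 2, "warmup": 300, "draws": 400, "seed": 6})
    return post, truth


@pytest.fixture(scope="session")
def reference_fit():
    """The benchmark matched-cohort fit: 30 pairs x 50 features, default MCMC.

    Shared across the convergence, recovery and effect-size checks so the
    expensive sampling runs once per session.
    """
    cfg = SyntheticConfig(n_pairs=30, d=50, seed=42)
    table, metadata, truth = generate_matched_cohort(cfg)
    pairs = match_case_control(metadata)
    mi = build_model_input(table, pairs, metadata)
    post = fit_matched_model(mi, {"chains": 4, "warmup": 1000, "draws": 1000, "seed": 7})
    return post, truth, table, metadata, pairs
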