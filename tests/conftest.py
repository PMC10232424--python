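from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pmalink import (
    CVConfig,
    FusionConfig,
    LearnerConfig,
    generate_synthetic_dataset,
    run_kfold_cv,
    shuffle_associations,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """Compact planted-block bundle for fast functional tests."""
    return generate_synthetic_dataset(
        n_p=40, n_m=30, n_blocks=3, p_within=0.4, p_between=0.05,
        n_conditions=8, expr_noise_sd=0.5, genes_per_block=30,
        gene_overlap=0.1, targets_per_mirna=12, seed=11,
    )


@pytest.fixture()
def fast_learner():
    return LearnerConfig(n_estimators=40, n_learners=3, seed=0)


@pytest.fixture()
def fast_fusion():
    return FusionConfig(n_iterations=5)


@pytest.fixture(scope="session")
def study_bundle():
    """The planted-block bundle at the scale used for headline evaluation."""
    return generate_synthetic_dataset(seed=7)


@pytest.fixture(scope="session")
def sweep_reports(study_bundle):
    """Default-config fivefold CV at each training fraction (1.0 = full run)."""
    out = {}
    for tf in (0.25, 0.5, 0.75, 1.0):
        out[tf] = run_kfold_cv(
            study_bundle,
            CVConfig(k=5, seed=1, training_fraction=tf),
            FusionConfig(),
            LearnerConfig(),
        )
    return out


@pytest.fixture(scope="session")
def null_report(study_bundle):
    """Fivefold CV on the association-shuffled null bundle."""
    null = shuffle_associations(study_bundle, seed=1)
    return run_kfold_cv(null, CVConfig(k=5, seed=1), FusionConfig(), LearnerConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
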