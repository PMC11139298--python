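"""Shared fixtures: small synthetic cohorts and cached feature frames.

Cohorts are generated once per session; sizes are kept small so the whole
suite runs on one CPU in minutes while preserving the statistical structure
the assertions probe.
"""

import numpy as np
import pandas as pd
import pytest

import voiceaudit as va


@pytest.fixture(scope="session")
def null_cohort():
    """Pathology and biases all off: labels exchangeable by construction."""
    return va.generate_cohort(va.CohortSpec.null(n_per_group=10, seed=11))


@pytest.fixture(scope="session")
def biased_cohort():
    """Pathology + duration/gain biases on (the emulated study conditions)."""
    return va.generate_cohort(va.CohortSpec.default_biased(n_per_group=8,
                                                           seed=7))


@pytest.fixture(scope="session")
def biased_features(biased_cohort):
    """Cached 88-feature frame for the biased cohort (all recordings)."""
    return va.extract_feature_frame(biased_cohort.recordings, "egemaps88")


@pytest.fixture(scope="session")
def biased_table(biased_cohort, biased_features):
    return va.build_feature_table(biased_cohort.recordings,
                                  biased_cohort.manifest, "egemaps88",
                                  "reading+vowel", features=biased_features)


@pytest.fixture(scope="session")
def category_map():
    return va.load_category_map()


def toy_table(n_per_group=15, n_features=5, signal=1.5, seed=0,
              feature_set="egemaps88", task="reading"):
    """Tabular-only labelled feature table (no audio): Gaussian features with
    a group shift of ``signal`` SDs on feature 0."""
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n_per_group)] + \
          [f"c{i}" for i in range(n_per_group)]
    y = pd.Series([1] * n_per_group + [0] * n_per_group, index=ids,
                  name="label")
    X = pd.DataFrame(rng.standard_normal((2 * n_per_group, n_features)),
                     index=ids,
                     columns=[f"feat_{j}" for j in range(n_features)])
    X.iloc[:, 0] += signal * y.to_numpy()
    groups = pd.Series(ids, index=ids, name="participant_id")
    return va.FeatureTable(X, y, groups, feature_set, task)


def toy_participants(n_per_group=15):
    return pd.DataFrame({
        "id": [f"p{i}" for i in range(n_per_group)]
              + [f"c{i}" for i in range(n_per_group)],
        "group": ["UVFP"] * n_per_group + ["control"] * n_per_group})
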