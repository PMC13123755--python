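"""Shared fixtures: small cohorts for unit tests, and one full-size trained
pipeline (session-scoped) reused by the heavier end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from surgdur.cohort import default_spec, generate_cohort
from surgdur.evaluation import split_dataset
from surgdur.features import CohortFeaturizer
from surgdur.models import MultiheadMLPRegressor


@pytest.fixture(scope="session")
def small_cohort():
    """300 cases with all the messy-text machinery on."""
    return generate_cohort(default_spec(n_cases=300, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    feat = CohortFeaturizer().fit(small_cohort.records)
    return feat, feat.transform(small_cohort.records)


@pytest.fixture(scope="session")
def default_run():
    """The study-scale run: default 4526-case cohort, 15/15/70 split, the
    multihead model trained with early stopping. Built once per session."""
    cohort = generate_cohort(default_spec(seed=42))
    split = split_dataset(len(cohort.records), test_frac=0.15, seed=0)
    feat = CohortFeaturizer()
    train_recs = [cohort.records[i] for i in split.train]
    feat.fit(train_recs)
    btr = feat.transform(train_recs)
    bva = feat.transform([cohort.records[i] for i in split.validation])
    bte = feat.transform([cohort.records[i] for i in split.test])
    model = MultiheadMLPRegressor(seed=0)
    model.fit((btr.tabular, btr.text), btr.y_min,
              validation=((bva.tabular, bva.text), bva.y_min))
    return {
        "cohort": cohort,
        "split": split,
        "featurizer": feat,
        "train": btr,
        "validation": bva,
        "test": bte,
        "model": model,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
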