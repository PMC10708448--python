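"""Shared fixtures: synthetic studies and the expensive cross-validation reports.

The default-design study (9 classes, 16 per herbicide + 32 controls per
round, 2 rounds, 7 days, 5 outliers) and its day-1 leave-one-out
reports are computed once per session and shared between the
classification, validation and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hsisoa.classify import REDUCED_GRID
from hsisoa.evaluate import day_to_day, exclude_outliers, loo_experiment
from hsisoa.synthetic import StudyConfig, generate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def default_study():
    """Full default-design synthetic study (320 samples x 7 days)."""
    return generate_study(StudyConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def clean_table(default_study):
    """Default study with the injected outlier plants excluded."""
    return exclude_outliers(default_study.table)


@pytest.fixture(scope="session")
def svm_loo_day1(clean_table):
    """OVO-SVM leave-one-out report on 1 DAT (coarse hyperparameter grid)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return loo_experiment(clean_table, learner="svm", dat=1, grid=REDUCED_GRID)


@pytest.fixture(scope="session")
def plsda_loo_day1(clean_table):
    """OVO-PLSDA leave-one-out report on 1 DAT."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return loo_experiment(clean_table, learner="plsda", dat=1)


@pytest.fixture(scope="session")
def svm_day1_to_day2(clean_table):
    """Day-to-day validation: ensemble trained on 1 DAT, tested on 2 DAT."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return day_to_day(clean_table, 1, 2, learner="svm", grid=REDUCED_GRID)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
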