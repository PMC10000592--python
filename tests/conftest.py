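import numpy as np
import pytest

from ctgkit.classify import FeatureEncoder, aggregate_annotations
from ctgkit.features import CTGFeatureExtractor
from ctgkit.synth import generate_cohort

COHORT_SEED = 2024
COHORT_N = 300
RATER_CONCORDANCE = 0.9


@pytest.fixture(scope="session")
def cohort300():
    """Stage-1 synthetic cohort with imperfect (0.9-concordant) raters."""
    return generate_cohort(
        COHORT_N, seed=COHORT_SEED, rater_concordance=RATER_CONCORDANCE
    )


@pytest.fixture(scope="session")
def feature_table300(cohort300):
    records = [rec for rec, _ in cohort300]
    return CTGFeatureExtractor().fit_transform(records)


@pytest.fixture(scope="session")
def encoded300(feature_table300, cohort300):
    """(X, y_majority, y_true) for the shared cohort."""
    X = FeatureEncoder().fit_transform(feature_table300).to_numpy()
    y = np.array([aggregate_annotations(t.rater_labels) for _, t in cohort300])
    y_true = np.array([t.label for _, t in cohort300])
    return X, y, y_true
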