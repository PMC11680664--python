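import collections

import numpy as np
import pytest

from forgetting.classify import categorize
from forgetting.fitting import RetentionDataset, fit_all
from forgetting.models import FunctionFamily, _raw_evaluate
from forgetting.simulate import GeneratorConfig, generate_corpus

#: The nine predictors retained after the collinearity screen.
RETAINED_PREDICTORS = [
    "year",
    "complexity",
    "multiple_study",
    "distractor",
    "design",
    "amount_of_data",
    "n_retention_intervals",
    "longest_ri",
    "initial_memory",
]


def exact_dataset(family, a, b, times, dataset_id="exact"):
    """A noise-free dataset generated exactly from one family."""
    t = np.asarray(times, dtype=float)
    m = _raw_evaluate(FunctionFamily(family), a, b, t)
    assert np.all((m >= 0) & (m <= 1)), "choose parameters inside [0,1]"
    return RetentionDataset(dataset_id, tuple(t.tolist()), tuple(m.tolist()))


@pytest.fixture(scope="session")
def recovery_corpus():
    """The 500-dataset recovery-study corpus: noise sd .01, 5 log-spaced
    retention intervals per dataset, fixed seed."""
    return generate_corpus(
        GeneratorConfig(n_datasets=500, noise_sd=0.01, n_intervals=(5, 5), seed=42)
    )


@pytest.fixture(scope="session")
def recovery_assignments(recovery_corpus):
    """Category assignment for every dataset of the recovery corpus."""
    out = {}
    for ds, _sc in recovery_corpus.records:
        fs = fit_all(ds) if float(np.ptp(ds.m)) > 0.0 else None
        out[ds.dataset_id] = categorize(ds, fs)
    return out


@pytest.fixture(scope="session")
def recovery_confusion(recovery_corpus, recovery_assignments):
    """(truth, assigned) confusion counts on the recovery corpus."""
    conf = collections.Counter()
    for dataset_id, assignment in recovery_assignments.items():
        truth = recovery_corpus.labels[dataset_id].value
        conf[(truth, assignment.category.value)] += 1
    return conf


@pytest.fixture(scope="session")
def covariate_corpus():
    """A 400-dataset corpus (default design) for the characteristics
    analyses: covariate associations planted per category profile."""
    return generate_corpus(GeneratorConfig(n_datasets=400, seed=7))
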