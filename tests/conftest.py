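import numpy as np
import pytest

from connectomotif import (
    AnswerCounts,
    BehavioralTable,
    ConnectivityMatrix,
    ConnectomeCohort,
    Parcellation,
    SimulationParams,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def parcellation_abc():
    return Parcellation(("A", "B", "C"))


def make_cohort(values_by_key, labels, hemisphere="left",
                subjects=None, scans=None):
    """Cohort from a {(subject, scan): 2-D array} mapping."""
    parc = Parcellation(tuple(labels), hemisphere=hemisphere)
    matrices = {
        (s, sc): ConnectivityMatrix(np.asarray(v, dtype=float), s, sc, hemisphere)
        for (s, sc), v in values_by_key.items()
    }
    return ConnectomeCohort(parcellation=parc, matrices=matrices,
                            subjects=subjects or [], scans=scans or [])


@pytest.fixture
def small_params():
    """Reduced cohort for fast pipeline tests: 12 subjects, 20 regions."""
    return SimulationParams(n_subjects=12, n_regions=20, scans=("a", "b"),
                            seed=11)


@pytest.fixture
def small_cohort(small_params):
    return generate_cohort(small_params)


def behavior_from_performances(subjects, day_perfs, sentence_type="double",
                               n_trials=33):
    """Behavioral table with given per-day performance fractions.

    ``day_perfs`` maps day -> list of per-subject performance values;
    counts are n_correct = round(p * n_trials), the rest incorrect.
    """
    records = []
    for day, perfs in day_perfs.items():
        for subj, p in zip(subjects, perfs):
            c = int(round(p * n_trials))
            records.append(
                AnswerCounts(subject=subj, day=day, sentence_type=sentence_type,
                             n_correct=c, n_incorrect=n_trials - c, n_missed=0)
            )
    return BehavioralTable.from_records(records)
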