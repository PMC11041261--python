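from datetime import date, datetime

import numpy as np
import pytest

from vox2mets.compendium import default_compendium
from vox2mets.parser import Utterance
from vox2mets.simulate import CohortSpec, NoiseSpec, generate_schedule


@pytest.fixture(scope="session")
def table():
    return default_compendium()


@pytest.fixture
def utterance():
    def make(text, uid="u1", when=datetime(2020, 1, 6, 12, 0), participant="P01"):
        return Utterance(id=uid, text=text, input_time=when, participant=participant)

    return make


@pytest.fixture(scope="session")
def small_cohort(table):
    """6 participants x 3 days of true schedules (fast test cohort)."""
    return generate_schedule(
        CohortSpec(n_participants=6, n_days=3), seed=123, table=table
    )


@pytest.fixture(scope="session")
def study_cohort(table):
    """20 participants x 7 days — the study's design size."""
    return generate_schedule(CohortSpec(), seed=123, table=table)


def nonwear_oracle(zero: np.ndarray) -> np.ndarray:
    """Brute-force run scan: per-minute wear mask from zero-count epochs.

    Independent of the implementation: walks the epoch array, marks
    maximal zero runs strictly longer than 360 epochs as non-wear, and
    calls a minute non-wear iff all 6 of its epochs are in such runs.
    """
    n = zero.size
    nonwear = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i > 360:
                nonwear[i:j] = True
            i = j
        else:
            i += 1
    return ~nonwear.reshape(1440, 6).all(axis=1)


@pytest.fixture(scope="session")
def brute_force_wear():
    return nonwear_oracle
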