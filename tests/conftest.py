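import math

import numpy as np
import pytest

from fallscreen import (
    Cohort,
    ParticipantRecord,
    ReferenceWeights,
    Stratum,
    default_params,
    generate_cohort,
    generate_reference_weights,
)


@pytest.fixture(scope="session")
def four_person_cohort() -> Cohort:
    """Hand-enumerable cohort: one recurrent faller, one abnormal single
    faller (both prospective fallers), one no-trigger person and one normal
    single faller (both non-fallers); one faller and one non-faller per sex."""
    return Cohort.from_records(
        [
            ParticipantRecord("a", 80, "female", prior_falls="2+", prospective_falls=1),
            ParticipantRecord("b", 72, "male", prior_falls="1", tug=20.0, prospective_falls=2),
            ParticipantRecord("c", 68, "female", prior_falls="0", walking_difficulty=False,
                              prospective_falls=0),
            ParticipantRecord("d", 90, "male", prior_falls="1", tug=10.0, prospective_falls=0),
        ]
    )


@pytest.fixture(scope="session")
def single_band_weights() -> ReferenceWeights:
    """One open-ended band per sex, equal weight: standardization reduces to
    the sex-balanced mean of per-sex fractions."""
    return ReferenceWeights(
        [Stratum(65.0, math.inf, "female", 0.5), Stratum(65.0, math.inf, "male", 0.5)]
    )


@pytest.fixture(scope="session")
def default_weights() -> ReferenceWeights:
    return generate_reference_weights()


@pytest.fixture(scope="session")
def synth_cohort() -> Cohort:
    """Mid-sized default-calibration cohort shared by read-only tests."""
    return generate_cohort(default_params(n=4000, seed=7))


def empirical_weights(cohort: Cohort, weights: ReferenceWeights) -> ReferenceWeights:
    """Reference weights equal to the cohort's own stratum shares."""
    idx = weights.stratum_indices(cohort.df["age"].to_numpy(), cohort.df["sex"].to_numpy())
    counts = np.bincount(idx, minlength=len(weights))
    return ReferenceWeights(
        [
            Stratum(s.age_lo, s.age_hi, s.sex, c / len(cohort))
            for s, c in zip(weights.strata, counts)
        ]
    )
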