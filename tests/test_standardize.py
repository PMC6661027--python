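import math

import numpy as np
import pytest

from fallscreen import (
    Cohort,
    CohortError,
    ParticipantRecord,
    ReferenceWeights,
    ScreeningConfig,
    Stratum,
    screen_cohort,
    standardize,
    standardized_confusion,
)
from conftest import empirical_weights


def _two_stratum_setup():
    """Ten women under 75 (indicator 0.1) and ten 75+ (indicator 0.3)."""
    recs = [ParticipantRecord(f"y{i}", 70, "female") for i in range(10)] + [
        ParticipantRecord(f"o{i}", 80, "female") for i in range(10)
    ]
    weights = ReferenceWeights(
        [
            Stratum(65, 75, "female", 0.5),
            Stratum(75, math.inf, "female", 0.5),
            Stratum(65, math.inf, "male", 0.0),
        ]
    )
    ind = np.array([0.1] * 10 + [0.3] * 10)
    return Cohort.from_records(recs), weights, ind


def test_constant_indicator_invariant_under_any_weights(default_weights, synth_cohort):
    for c in (0.0, 0.25, 1.0):
        sf = standardize(np.full(len(synth_cohort), c), synth_cohort, default_weights)
        assert sf.value == pytest.approx(c, abs=1e-12)


def test_two_stratum_arithmetic():
    cohort, weights, ind = _two_stratum_setup()
    assert standardize(ind, cohort, weights).value == pytest.approx(0.2, abs=1e-12)


def test_weights_concentrated_on_one_stratum_give_its_crude_fraction():
    cohort, _, ind = _two_stratum_setup()
    w = ReferenceWeights(
        [
            Stratum(65, 75, "female", 1.0),
            Stratum(75, math.inf, "female", 0.0),
            Stratum(65, math.inf, "male", 0.0),
        ]
    )
    assert standardize(ind, cohort, w).value == pytest.approx(0.1, abs=1e-15)


def test_empty_strata_dropped_and_renormalized(caplog):
    cohort, _, ind = _two_stratum_setup()
    # half the female mass sits on an unoccupied 65-68 band -> dropped
    w = ReferenceWeights(
        [
            Stratum(65, 68, "female", 0.25),
            Stratum(68, 75, "female", 0.25),
            Stratum(75, math.inf, "female", 0.5),
            Stratum(65, math.inf, "male", 0.0),
        ]
    )
    with caplog.at_level("INFO"):
        sf = standardize(ind, cohort, w)
    # renormalized weights: (0.25, 0.5)/0.75
    assert sf.value == pytest.approx((0.25 * 0.1 + 0.5 * 0.3) / 0.75, abs=1e-12)
    assert sf.dropped_strata == ("[65,68):female",)
    assert any("dropping empty strata" in r.message for r in caplog.records)


def test_identity_weights_reproduce_crude_fractions(synth_cohort, default_weights):
    """Reference weights equal to the cohort's own stratum shares leave the
    crude fraction unchanged."""
    w = empirical_weights(synth_cohort, default_weights)
    rng = np.random.default_rng(3)
    ind = rng.uniform(size=len(synth_cohort))
    assert standardize(ind, synth_cohort, w).value == pytest.approx(ind.mean(), abs=1e-12)


def test_indicator_validation(synth_cohort, default_weights):
    n = len(synth_cohort)
    with pytest.raises(CohortError, match="in \\[0, 1\\]"):
        standardize(np.full(n, 1.5), synth_cohort, default_weights)
    with pytest.raises(CohortError, match="length"):
        standardize(np.zeros(n - 1), synth_cohort, default_weights)


def brute_force_standardize(ind, cohort, weights):
    """Independent per-person enumeration: each person carries
    (renormalized stratum weight) / (stratum count)."""
    idx = weights.stratum_indices(cohort.df["age"].to_numpy(), cohort.df["sex"].to_numpy())
    counts = np.bincount(idx, minlength=len(weights))
    w = weights.weights.copy()
    w[counts == 0] = 0.0
    w /= w.sum()
    return sum(ind[i] * w[idx[i]] / counts[idx[i]] for i in range(len(ind)))


def test_standardization_equals_per_person_enumeration(default_weights):
    """On small random cohorts the stratum-rate formula agrees with the
    brute-force per-person weighting to 1e-12."""
    rng = np.random.default_rng(29)
    for trial in range(20):
        n = rng.integers(1, 51)
        recs = [
            ParticipantRecord(
                f"t{trial}p{i}", float(rng.uniform(65, 100)),
                "female" if rng.uniform() < 0.5 else "male",
            )
            for i in range(n)
        ]
        cohort = Cohort.from_records(recs)
        ind = rng.uniform(size=n)
        got = standardize(ind, cohort, default_weights).value
        assert got == pytest.approx(brute_force_standardize(ind, cohort, default_weights), abs=1e-12)


# --------------------------------------------------- standardized confusion


def test_hand_enumerated_confusion(four_person_cohort, single_band_weights):
    """Fallers are exactly the two high-risk persons, one per sex: a perfect
    classifier with standardized TP = TN = 0.5."""
    res = screen_cohort(four_person_cohort, ScreeningConfig())
    conf = standardized_confusion(res, single_band_weights, "ge1")
    assert conf.tp == pytest.approx(0.5, abs=1e-12)
    assert conf.tn == pytest.approx(0.5, abs=1e-12)
    assert conf.fp == conf.fn == 0.0
    assert conf.indeterminate == 0.0


def test_confusion_fractions_partition_population(synth_cohort, default_weights):
    for outcome in ("ge1", "ge2"):
        conf = standardized_confusion(screen_cohort(synth_cohort), default_weights, outcome)
        total = conf.tp + conf.fp + conf.fn + conf.tn + conf.indeterminate
        assert total == pytest.approx(1.0, abs=1e-9)


def test_prevalence_is_classifier_independent(synth_cohort, default_weights):
    """TP + FN equals the standardized >=1-fall prevalence whatever the
    cutoff (conservation), as long as the determinate subset is the same."""
    prevs = []
    for cutoff in (-math.inf, math.inf):
        conf = standardized_confusion(
            screen_cohort(synth_cohort, ScreeningConfig(cutoff=cutoff)), default_weights, "ge1"
        )
        prevs.append(conf.prevalence)
    assert prevs[0] == pytest.approx(prevs[1], abs=1e-12)


def test_all_low_classifier_puts_prevalence_in_fn(four_person_cohort, single_band_weights):
    res = screen_cohort(four_person_cohort, ScreeningConfig(cutoff=math.inf))
    conf = standardized_confusion(res, single_band_weights, "ge1")
    # the recurrent faller stays high; the assessed faller becomes FN
    assert conf.fn == pytest.approx(0.25, abs=1e-12)
    assert conf.tp + conf.fn == pytest.approx(0.5, abs=1e-12)


def test_ge2_outcome_definition(four_person_cohort, single_band_weights):
    res = screen_cohort(four_person_cohort, ScreeningConfig())
    conf = standardized_confusion(res, single_band_weights, "ge2")
    # only participant b (2 prospective falls) is a multiple faller
    assert conf.tp == pytest.approx(0.25, abs=1e-12)
    assert conf.prevalence == pytest.approx(0.25, abs=1e-12)


def test_missing_outcome_goes_to_indeterminate(single_band_weights):
    recs = [
        ParticipantRecord("a", 70, "female", prior_falls="2+", prospective_falls=1),
        ParticipantRecord("b", 70, "male", prior_falls="2+"),  # outcome unobserved
    ]
    res = screen_cohort(Cohort.from_records(recs))
    conf = standardized_confusion(res, single_band_weights, "ge1")
    assert conf.indeterminate == pytest.approx(0.5, abs=1e-12)
    assert conf.tp == pytest.approx(0.5, abs=1e-12)
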