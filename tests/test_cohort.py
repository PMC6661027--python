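import math
import textwrap

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from fallscreen import (
    Cohort,
    CohortError,
    ParticipantRecord,
    ReferenceWeights,
    RowError,
    SchemaError,
    Stratum,
    read_cohort,
    read_reference_weights,
    write_cohort,
    write_reference_weights,
)


# ---------------------------------------------------------------- records


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(age=-1), "age"),
        (dict(sex="other"), "sex"),
        (dict(prior_falls="many"), "prior_falls"),
        (dict(tug=0.0), "tug"),
        (dict(tug=-3.0), "tug"),
        (dict(sppb=13), "sppb"),
        (dict(sppb=-1), "sppb"),
        (dict(sppb=7.5), "sppb"),
        (dict(gait_speed=-0.1), "gait_speed"),
        (dict(prospective_falls=-2), "prospective_falls"),
        (dict(prospective_falls=1.5), "prospective_falls"),
    ],
)
def test_invalid_record_fields_rejected(kwargs, match):
    base = dict(id="x", age=70, sex="female")
    with pytest.raises(ValueError, match=match):
        ParticipantRecord(**{**base, **kwargs})


def test_prior_fall_counts_absorb_into_two_plus():
    assert ParticipantRecord("x", 70, "f", prior_falls="5").prior_falls == "2+"
    assert ParticipantRecord("x", 70, "f", prior_falls="2").prior_falls == "2+"
    assert ParticipantRecord("x", 70, "f", prior_falls="1").prior_falls == "1"


def test_sex_synonyms_normalized():
    assert ParticipantRecord("x", 70, "F").sex == "female"
    assert ParticipantRecord("x", 70, "Male").sex == "male"


def test_duplicate_ids_rejected():
    recs = [ParticipantRecord("same", 70, "female"), ParticipantRecord("same", 80, "male")]
    with pytest.raises(CohortError, match="duplicate"):
        Cohort.from_records(recs)


# ---------------------------------------------------------------- cohort CSV


def _write(tmp_path, text):
    p = tmp_path / "cohort.csv"
    p.write_text(textwrap.dedent(text))
    return p


def test_read_well_formed_csv(tmp_path):
    p = _write(
        tmp_path,
        """\
        id,age,sex,prior_falls,walking_difficulty,tug_s,sppb,gait_speed_mps,prospective_falls
        p1,70,female,0,0,9.5,12,1.3,0
        p2,81,male,2+,1,15.0,6,0.7,3
        p3,68,female,1,,NA,9,,1
        """,
    )
    cohort = read_cohort(p)
    assert len(cohort) == 3
    r3 = cohort.records[2]
    assert r3.tug is None and r3.gait_speed is None and r3.walking_difficulty is None
    assert cohort.records[1].prior_falls == "2+"


def test_missing_mandatory_column_names_it(tmp_path):
    p = _write(tmp_path, "id,age\np1,70\n")
    with pytest.raises(SchemaError, match="sex"):
        read_cohort(p)


def test_non_numeric_tug_reports_row(tmp_path):
    p = _write(tmp_path, "id,age,sex,tug_s\np1,70,female,9.5\np2,71,male,slow\n")
    with pytest.raises(RowError, match="row 1"):
        read_cohort(p)


def test_out_of_range_sppb_reports_row_and_bound(tmp_path):
    p = _write(tmp_path, "id,age,sex,sppb\np1,70,female,15\n")
    with pytest.raises(RowError, match=r"row 0.*\[0, 12\]"):
        read_cohort(p)


def test_dialect_maps_foreign_column_names(tmp_path):
    p = _write(tmp_path, "subject,years,gender\nA,77,male\n")
    cohort = read_cohort(p, dialect={"id": "subject", "age": "years", "sex": "gender"})
    assert cohort.records[0].id == "A" and cohort.records[0].age == 77


@pytest.mark.parametrize(
    "records",
    [
        [ParticipantRecord(f"p{i}", 65 + 2.5 * i, "female" if i % 2 else "male",
                           prior_falls=("0", "1", "2+")[i % 3],
                           walking_difficulty=bool(i % 2),
                           tug=7.0 + 0.1 * i, sppb=i % 13, gait_speed=0.5 + 0.01 * i,
                           prospective_falls=i % 4)
         for i in range(10)],
        [ParticipantRecord("only", 91.25, "male")],  # all screening items missing
        [],
    ],
    ids=["mixed", "all-missing", "empty"],
)
def test_cohort_round_trip(tmp_path, records):
    cohort = Cohort.from_records(records)
    path = tmp_path / "rt.csv"
    write_cohort(cohort, path)
    assert read_cohort(path) == cohort


@settings(derandomize=True, max_examples=30, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(
    ages=st.lists(st.floats(65, 105, allow_nan=False), min_size=1, max_size=6),
    seed=st.integers(0, 10_000),
)
def test_round_trip_is_bit_exact_on_arbitrary_floats(tmp_path, ages, seed):
    """Full-precision floats survive write -> read unchanged."""
    rng = np.random.default_rng(seed)
    recs = [
        ParticipantRecord(
            f"p{i}", a + rng.uniform(0, 1e-9), "female",
            tug=float(np.exp(rng.normal(2.5, 0.4))),
            gait_speed=float(rng.uniform(0, 2)),
        )
        for i, a in enumerate(ages)
    ]
    cohort = Cohort.from_records(recs)
    path = tmp_path / f"bits{seed}.csv"
    write_cohort(cohort, path)
    back = read_cohort(path)
    assert back == cohort
    assert all(b.tug == r.tug and b.age == r.age for b, r in zip(back.records, recs))


# ---------------------------------------------------------------- weights


def _weights_csv(tmp_path, rows, header="age_lo,age_hi,sex,weight"):
    p = tmp_path / "w.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


def test_read_weights_and_percent_renormalization(tmp_path):
    rows = []
    for lo, hi in [(65, 70), (70, 75), (75, 80), (80, 85), (85, 90), (90, "")]:
        for sex, w in (("female", 9), ("male", 7.6666666666666667)):
            rows.append(f"{lo},{hi},{sex},{w}")
    w = read_reference_weights(_weights_csv(tmp_path, rows))
    assert len(w) == 12
    assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_overlapping_bands_rejected(tmp_path):
    rows = ["65,75,female,0.3", "70,,female,0.3", "65,,male,0.4"]
    with pytest.raises(CohortError, match="overlap"):
        read_reference_weights(_weights_csv(tmp_path, rows))


def test_band_gap_rejected():
    with pytest.raises(CohortError, match="gap"):
        ReferenceWeights(
            [Stratum(65, 70, "female", 0.3), Stratum(75, math.inf, "female", 0.3),
             Stratum(65, math.inf, "male", 0.4)]
        )


def test_all_zero_weights_rejected():
    with pytest.raises(CohortError, match="zero"):
        ReferenceWeights(
            [Stratum(65, math.inf, "female", 0.0), Stratum(65, math.inf, "male", 0.0)]
        )


def test_last_band_must_be_open_ended():
    with pytest.raises(CohortError, match="open-ended"):
        ReferenceWeights(
            [Stratum(65, 90, "female", 0.5), Stratum(65, math.inf, "male", 0.5)]
        )


def test_stratum_lookup_and_below_band_error(default_weights):
    idx = default_weights.stratum_indices(np.array([65.0, 69.999, 92.0]), ["female"] * 3)
    labels = [default_weights.strata[i].label for i in idx]
    assert labels == ["[65,70):female", "[65,70):female", "[90,inf):female"]
    with pytest.raises(CohortError, match="below the youngest"):
        default_weights.stratum_indices(np.array([60.0]), ["male"])


def test_weights_round_trip(tmp_path, default_weights):
    path = tmp_path / "w.csv"
    write_reference_weights(default_weights, path)
    back = read_reference_weights(path)
    assert [s.label for s in back.strata] == [s.label for s in default_weights.strata]
    np.testing.assert_allclose(back.weights, default_weights.weights, rtol=0, atol=0)
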