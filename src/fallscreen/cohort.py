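"""Core data containers: participant records, cohorts, and reference weights.

A cohort is a table of community-dwelling older adults (65+), one row per
person, holding the inputs of the AGS/BGS fall-risk screening flowchart
(prior-fall history, self-reported walking difficulty, functional test
results) together with the prospectively ascertained 12-month fall count.
Reference weights describe the age-band x sex composition of a reference
population and drive direct standardization.

Internally a :class:`Cohort` is backed by a :class:`pandas.DataFrame` so
that screening, standardization and bootstrap resampling stay vectorized;
:class:`ParticipantRecord` offers a validated per-person view.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortError",
    "SchemaError",
    "RowError",
    "ParticipantRecord",
    "Cohort",
    "ReferenceWeights",
    "read_cohort",
    "write_cohort",
    "read_reference_weights",
    "write_reference_weights",
    "DEFAULT_BANDS",
    "COHORT_COLUMNS",
]

PRIOR_FALLS_CATEGORIES = ("0", "1", "2+")
SEXES = ("female", "male")

#: canonical cohort CSV column order
COHORT_COLUMNS = (
    "id",
    "age",
    "sex",
    "prior_falls",
    "walking_difficulty",
    "tug_s",
    "sppb",
    "gait_speed_mps",
    "prospective_falls",
)

#: default age bands: 5-year bands from 65, last band open-ended
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (65.0, 70.0),
    (70.0, 75.0),
    (75.0, 80.0),
    (80.0, 85.0),
    (85.0, 90.0),
    (90.0, math.inf),
)

DEFAULT_NA_SENTINELS = ("", "NA")


class CohortError(ValueError):
    """Base class for cohort/weights validation and parsing failures."""


class SchemaError(CohortError):
    """A required column is absent or the file layout is unusable."""


class RowError(CohortError):
    """A specific row holds an invalid value; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def _norm_sex(value: str) -> str:
    v = str(value).strip().lower()
    if v in ("female", "f"):
        return "female"
    if v in ("male", "m"):
        return "male"
    raise ValueError(f"sex must be one of {SEXES}, got {value!r}")


@dataclass(frozen=True)
class ParticipantRecord:
    """One person's screening inputs and prospective fall outcome.

    ``None`` denotes a missing item.  ``prior_falls`` is the trichotomy
    used by the screening flowchart ("0", "1", "2+"); counts above two are
    absorbed into "2+" at construction.
    """

    id: str
    age: float
    sex: str
    prior_falls: str | None = None
    walking_difficulty: bool | None = None
    tug: float | None = None
    sppb: int | None = None
    gait_speed: float | None = None
    prospective_falls: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "id", str(self.id))
        if not (isinstance(self.age, (int, float)) and math.isfinite(self.age) and self.age >= 0):
            raise ValueError(f"age must be a finite number >= 0, got {self.age!r}")
        object.__setattr__(self, "sex", _norm_sex(self.sex))
        if self.prior_falls is not None:
            pf = str(self.prior_falls)
            if pf.isdigit() and int(pf) >= 2:
                pf = "2+"
            if pf not in PRIOR_FALLS_CATEGORIES:
                raise ValueError(
                    f"prior_falls must be one of {PRIOR_FALLS_CATEGORIES}, got {self.prior_falls!r}"
                )
            object.__setattr__(self, "prior_falls", pf)
        if self.walking_difficulty is not None:
            object.__setattr__(self, "walking_difficulty", bool(self.walking_difficulty))
        if self.tug is not None and not self.tug > 0:
            raise ValueError(f"tug must be > 0 s, got {self.tug!r}")
        if self.sppb is not None:
            s = self.sppb
            if not (float(s).is_integer() and 0 <= s <= 12):
                raise ValueError(f"sppb must be an integer in [0, 12], got {self.sppb!r}")
            object.__setattr__(self, "sppb", int(s))
        if self.gait_speed is not None and not self.gait_speed >= 0:
            raise ValueError(f"gait_speed must be >= 0 m/s, got {self.gait_speed!r}")
        if self.prospective_falls is not None:
            p = self.prospective_falls
            if not (float(p).is_integer() and p >= 0):
                raise ValueError(
                    f"prospective_falls must be a non-negative integer, got {self.prospective_falls!r}"
                )
            object.__setattr__(self, "prospective_falls", int(p))


# numeric cohort columns stored as float64 with NaN = missing
_NUMERIC_COLS = ("age", "walking_difficulty", "tug_s", "sppb", "gait_speed_mps", "prospective_falls")
_FIELD_OF_COL = {
    "tug_s": "tug",
    "gait_speed_mps": "gait_speed",
    "sppb": "sppb",
    "walking_difficulty": "walking_difficulty",
    "prospective_falls": "prospective_falls",
}


class Cohort:
    """An ordered collection of participants with unique ids.

    Backed by a DataFrame with columns :data:`COHORT_COLUMNS`; numeric
    columns are float64 with NaN for missing, ``prior_falls`` is the
    string trichotomy (or None), ``walking_difficulty`` is 0.0/1.0/NaN.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "<memory>", *, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.provenance = provenance
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[ParticipantRecord], provenance: str = "<memory>") -> "Cohort":
        recs = list(records)
        df = pd.DataFrame(
            {
                "id": [r.id for r in recs],
                "age": np.array([r.age for r in recs], dtype=float),
                "sex": [r.sex for r in recs],
                "prior_falls": [r.prior_falls for r in recs],
                "walking_difficulty": np.array(
                    [np.nan if r.walking_difficulty is None else float(r.walking_difficulty) for r in recs],
                    dtype=float,
                ),
                "tug_s": np.array([np.nan if r.tug is None else r.tug for r in recs], dtype=float),
                "sppb": np.array([np.nan if r.sppb is None else float(r.sppb) for r in recs], dtype=float),
                "gait_speed_mps": np.array(
                    [np.nan if r.gait_speed is None else r.gait_speed for r in recs], dtype=float
                ),
                "prospective_falls": np.array(
                    [np.nan if r.prospective_falls is None else float(r.prospective_falls) for r in recs],
                    dtype=float,
                ),
            },
            columns=list(COHORT_COLUMNS),
        )
        return cls(df, provenance)

    def _validate(self) -> None:
        df = self.df
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"cohort is missing columns: {missing_cols}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise CohortError(f"duplicate participant id {dup!r}")
        self._check_values(df)

    @staticmethod
    def _check_values(df: pd.DataFrame) -> None:
        def first_bad(mask: pd.Series, msg: str) -> None:
            if mask.any():
                raise RowError(int(np.flatnonzero(mask.to_numpy())[0]), msg)

        age = df["age"]
        first_bad(age.isna() | (age < 0), "age must be a number >= 0")
        first_bad(~df["sex"].isin(SEXES), f"sex must be one of {SEXES}")
        pf = df["prior_falls"]
        first_bad(pf.notna() & ~pf.isin(PRIOR_FALLS_CATEGORIES), f"prior_falls must be one of {PRIOR_FALLS_CATEGORIES}")
        wd = df["walking_difficulty"]
        first_bad(wd.notna() & ~wd.isin([0.0, 1.0]), "walking_difficulty must be 0 or 1")
        tug = df["tug_s"]
        first_bad(tug.notna() & ~(tug > 0), "tug_s must be > 0")
        sppb = df["sppb"]
        first_bad(sppb.notna() & (~(sppb == sppb.round()) | (sppb < 0) | (sppb > 12)), "sppb must be an integer in [0, 12]")
        gs = df["gait_speed_mps"]
        first_bad(gs.notna() & ~(gs >= 0), "gait_speed_mps must be >= 0")
        fl = df["prospective_falls"]
        first_bad(fl.notna() & (~(fl == fl.round()) | (fl < 0)), "prospective_falls must be a non-negative integer")

    # -- container protocol -------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[ParticipantRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                ParticipantRecord(
                    id=row.id,
                    age=row.age,
                    sex=row.sex,
                    prior_falls=None if row.prior_falls is None or (isinstance(row.prior_falls, float) and math.isnan(row.prior_falls)) else row.prior_falls,
                    walking_difficulty=None if math.isnan(row.walking_difficulty) else bool(row.walking_difficulty),
                    tug=None if math.isnan(row.tug_s) else row.tug_s,
                    sppb=None if math.isnan(row.sppb) else int(row.sppb),
                    gait_speed=None if math.isnan(row.gait_speed_mps) else row.gait_speed_mps,
                    prospective_falls=None if math.isnan(row.prospective_falls) else int(row.prospective_falls),
                )
            )
        return out

    def take(self, indices: np.ndarray, provenance: str | None = None) -> "Cohort":
        """Positional subset/resample (ids may repeat; used by the bootstrap)."""
        return Cohort(
            self.df.take(np.asarray(indices)),
            provenance or f"{self.provenance}[take]",
            validate=False,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if len(self) != len(other):
            return False
        a, b = self.df[list(COHORT_COLUMNS)], other.df[list(COHORT_COLUMNS)]
        for c in COHORT_COLUMNS:
            ca, cb = a[c], b[c]
            if c in _NUMERIC_COLS:
                if not np.array_equal(ca.to_numpy(), cb.to_numpy(), equal_nan=True):
                    return False
            else:
                if not (ca.fillna("\0") == cb.fillna("\0")).all():
                    return False
        return True


# ---------------------------------------------------------------------
# cohort CSV I/O


def _parse_float_col(raw: pd.Series, col: str, na: frozenset) -> pd.Series:
    vals = np.full(len(raw), np.nan)
    for i, cell in enumerate(raw):
        s = cell.strip() if isinstance(cell, str) else cell
        if s in na or s is None:
            continue
        try:
            vals[i] = float(s)
        except (TypeError, ValueError):
            raise RowError(i, f"column {col!r}: cannot parse {cell!r} as a number") from None
    return pd.Series(vals)


def read_cohort(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    na_values: Sequence[str] = DEFAULT_NA_SENTINELS,
) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with (a subset of) the canonical columns; ``age`` and
        ``sex`` are mandatory.
    dialect
        Optional map from canonical column name to the column name used
        in the file, for foreign layouts.
    na_values
        Cell values treated as missing (default: empty cell or ``NA``).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        rename = {file_col: canon for canon, file_col in dialect.items()}
        raw = raw.rename(columns=rename)
    for col in ("age", "sex"):
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} absent from {path}")
    na = frozenset(na_values)
    n = len(raw)

    out = pd.DataFrame(index=range(n), columns=list(COHORT_COLUMNS))
    out["id"] = raw["id"].astype(str) if "id" in raw.columns else [str(i) for i in range(n)]
    out["age"] = _parse_float_col(raw["age"], "age", na)
    sexes = []
    for i, cell in enumerate(raw["sex"]):
        try:
            sexes.append(_norm_sex(cell))
        except ValueError as e:
            raise RowError(i, str(e)) from None
    out["sex"] = sexes

    if "prior_falls" in raw.columns:
        pf = []
        for i, cell in enumerate(raw["prior_falls"]):
            s = cell.strip() if isinstance(cell, str) else cell
            if s in na:
                pf.append(None)
                continue
            if s.isdigit() and int(s) >= 2:
                s = "2+"
            if s not in PRIOR_FALLS_CATEGORIES:
                raise RowError(i, f"prior_falls must be one of {PRIOR_FALLS_CATEGORIES}, got {cell!r}")
            pf.append(s)
        out["prior_falls"] = pf
    else:
        out["prior_falls"] = None

    for col in ("walking_difficulty", "tug_s", "sppb", "gait_speed_mps", "prospective_falls"):
        out[col] = _parse_float_col(raw[col], col, na) if col in raw.columns else np.nan

    out = out.astype({c: float for c in _NUMERIC_COLS})
    try:
        Cohort._check_values(out)
    except RowError:
        raise
    return Cohort(out, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that round-trips bit-exactly through :func:`read_cohort`.

    Floats are serialized with ``repr`` (shortest exact representation),
    integers without a decimal part, missing values as empty cells.
    """
    df = cohort.df
    out = pd.DataFrame(index=df.index)
    out["id"] = df["id"]

    def fmt_float(v: float) -> str:
        return "" if math.isnan(v) else repr(float(v))

    def fmt_int(v: float) -> str:
        return "" if math.isnan(v) else str(int(v))

    out["age"] = df["age"].map(fmt_float)
    out["sex"] = df["sex"]
    out["prior_falls"] = df["prior_falls"].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else v)
    out["walking_difficulty"] = df["walking_difficulty"].map(fmt_int)
    out["tug_s"] = df["tug_s"].map(fmt_float)
    out["sppb"] = df["sppb"].map(fmt_int)
    out["gait_speed_mps"] = df["gait_speed_mps"].map(fmt_float)
    out["prospective_falls"] = df["prospective_falls"].map(fmt_int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------
# reference weights


@dataclass(frozen=True)
class Stratum:
    """One age-band x sex cell of the reference population."""

    age_lo: float
    age_hi: float  # math.inf for the open-ended last band
    sex: str
    weight: float

    @property
    def label(self) -> str:
        hi = "inf" if math.isinf(self.age_hi) else f"{self.age_hi:g}"
        return f"[{self.age_lo:g},{hi}):{self.sex}"


class ReferenceWeights:
    """Age-band x sex weights of a reference population (direct standardization).

    Weights are non-negative and are renormalized to sum to one; within
    each sex the bands must be disjoint and cover ``[65, inf)`` with
    half-open intervals ``[lo, hi)``.
    """

    def __init__(self, strata: Sequence[Stratum]):
        strata = sorted(strata, key=lambda s: (s.sex, s.age_lo))
        if not strata:
            raise CohortError("reference weights need at least one stratum")
        w = np.array([s.weight for s in strata], dtype=float)
        if (w < 0).any() or not np.isfinite(w).all():
            raise CohortError("weights must be finite and >= 0")
        total = w.sum()
        if total <= 0:
            raise CohortError("weights are all zero")
        if abs(total - 1.0) > 1e-9:
            logger.info("reference weights sum to %g; renormalizing to 1", total)
        w = w / total
        self.strata = tuple(dataclasses.replace(s, weight=wi) for s, wi in zip(strata, w))
        self._validate_bands()
        # per-sex sorted band edges for vectorized stratum lookup
        self._edges = {}
        self._index = {}
        for sex in SEXES:
            sex_strata = [(i, s) for i, s in enumerate(self.strata) if s.sex == sex]
            self._edges[sex] = np.array([s.age_lo for _, s in sex_strata])
            self._index[sex] = np.array([i for i, _ in sex_strata])

    def _validate_bands(self) -> None:
        for sex in SEXES:
            bands = sorted((s.age_lo, s.age_hi) for s in self.strata if s.sex == sex)
            if not bands:
                raise CohortError(f"no strata for sex {sex!r}")
            if bands[0][0] > 65:
                raise CohortError(f"{sex} bands start at {bands[0][0]}, must cover [65, inf)")
            for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
                if lo2 < hi1:
                    raise CohortError(f"overlapping {sex} bands [{lo1},{hi1}) and starting {lo2}")
                if lo2 > hi1:
                    raise CohortError(f"gap in {sex} bands between {hi1} and {lo2}")
            if not math.isinf(bands[-1][1]):
                raise CohortError(f"last {sex} band must be open-ended to cover [65, inf)")

    def __len__(self) -> int:
        return len(self.strata)

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.strata])

    def stratum_indices(self, age: np.ndarray, sex: Sequence[str]) -> np.ndarray:
        """Map each (age, sex) to its stratum index; error below the youngest band."""
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=object)
        out = np.empty(len(age), dtype=int)
        for s in SEXES:
            mask = sex == s
            if not mask.any():
                continue
            edges = self._edges[s]
            pos = np.searchsorted(edges, age[mask], side="right") - 1
            if (pos < 0).any():
                bad = np.flatnonzero(mask)[np.flatnonzero(pos < 0)[0]]
                raise CohortError(
                    f"record {bad}: age {age[bad]:g} below the youngest {s} band ({edges[0]:g})"
                )
            out[mask] = self._index[s][pos]
        return out


def read_reference_weights(path: str | Path) -> ReferenceWeights:
    """Read a weights CSV with columns age_lo, age_hi (empty = open-ended), sex, weight."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("age_lo", "age_hi", "sex", "weight"):
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} absent from {path}")
    strata = []
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            lo = float(row.age_lo)
            hi = math.inf if str(row.age_hi).strip() in ("", "inf") else float(row.age_hi)
            strata.append(Stratum(lo, hi, _norm_sex(row.sex), float(row.weight)))
        except ValueError as e:
            raise RowError(i, str(e)) from None
    return ReferenceWeights(strata)


def write_reference_weights(weights: ReferenceWeights, path: str | Path) -> None:
    rows = [
        {
            "age_lo": repr(float(s.age_lo)),
            "age_hi": "" if math.isinf(s.age_hi) else repr(float(s.age_hi)),
            "sex": s.sex,
            "weight": repr(float(s.weight)),
        }
        for s in weights.strata
    ]
    pd.DataFrame(rows, columns=["age_lo", "age_hi", "sex", "weight"]).to_csv(path, index=False)
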