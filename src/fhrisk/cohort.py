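"""Patient data model for ASCVD cohorts.

One row per patient: demographics, the admission lipid panel, personal and
first-degree family histories of premature vascular disease, and the potency
of any lipid-lowering therapy. This module owns

* :class:`PatientRecord` and its validation / exclusion rules,
* :class:`DerivedFlags` — the premature-event indicators (``pCHD``,
  ``pCHDTW``, family-history variants, premature stroke / PVD) and the
  untreated-LDL estimate that every diagnostic criterion consumes,
* CSV round-tripping with a configurable column dictionary.

Premature-age conventions
-------------------------
Two sex-specific cutoff sets are in use by the shipped criteria: the DLCN
convention (men < 55 y, women < 60 y) and the stricter Taiwan convention
(men < 45 y, women < 55 y).  An onset age *equal* to the cutoff is not
premature.  Premature stroke and peripheral-vascular-disease flags default
to the DLCN cutoffs (they feed DLCN-family point items) and are
configurable.

Untreated LDL
-------------
Diagnostic criteria were developed on therapy-naive lipid values, so the
observed LDL-C of a treated patient is divided back by the expected
proportional reduction of the therapy's potency class:
``ldl_untreated = ldl_c / (1 - r)``, with default reduction fractions
r = {none: 0, low: 0.20, medium: 0.35, high: 0.50} (overridable in config;
the factors used are logged into every report).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("fhrisk")

SEXES = ("male", "female")
SMOKING_LEVELS = ("never", "ex", "current")
DRINKING_LEVELS = ("never", "ex", "current")
THERAPY_LEVELS = ("none", "low", "medium", "high")
GENETIC_LEVELS = ("positive", "negative", "not_done")

#: default proportional LDL-C reduction per therapy-potency class
DEFAULT_LDL_REDUCTION = {"none": 0.0, "low": 0.20, "medium": 0.35, "high": 0.50}

#: sex-specific premature-onset cutoffs (strict "<"), years
DLCN_PREMATURE_AGE = {"male": 55, "female": 60}
TW_PREMATURE_AGE = {"male": 45, "female": 55}

#: default cutoff configuration consumed by :func:`derive_flags`
DEFAULT_CUTOFFS = {
    "chd": DLCN_PREMATURE_AGE,
    "chd_tw": TW_PREMATURE_AGE,
    "stroke": DLCN_PREMATURE_AGE,
    "pvd": DLCN_PREMATURE_AGE,
}


class CohortError(ValueError):
    """Fatal cohort-level input problem (unparseable file, bad config)."""


class RowError(ValueError):
    """Row-level input problem; carries the offending row index."""

    def __init__(self, index, message: str):
        self.index = index
        super().__init__(f"row {index}: {message}")


@dataclass(frozen=True)
class PatientRecord:
    """Raw clinical variables for one adult ASCVD patient.

    Lipids are mmol/L except ``lp_a`` (mg/L); ``ldl_c`` is the highest
    LDL-C during admission.  Optional onset ages are ``None`` when the
    event/history is absent.
    """

    id: str
    age: int
    sex: str
    ldl_c: float
    tc: float
    hdl_c: float | None = None
    tg: float | None = None
    lp_a: float | None = None
    bmi: float | None = None
    smoking: str | None = None
    drinking: str | None = None
    tendon_xanthomata: bool = False
    arcus_cornealis: bool = False
    chd_onset_age: int | None = None
    stroke_onset_age: int | None = None
    pvd_onset_age: int | None = None
    hyperlipemia: bool = False
    diabetes: bool = False
    hypertension: bool = False
    therapy_level: str = "none"
    therapy_duration_years: float | None = None  # recorded, unused downstream
    fh_chd_onset_age: int | None = None
    fh_chd_relative_sex: str | None = None
    fh_stroke_onset_age: int | None = None
    fh_stroke_relative_sex: str | None = None
    fh_hyperlipemia: bool = False
    fh_xanthomata: bool = False
    genetic_test: str = "not_done"

    def __post_init__(self):
        if self.age < 18:
            raise ValueError("age must be >= 18 (adult cohort)")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        for name in ("ldl_c", "tc", "hdl_c", "tg", "lp_a"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.therapy_level not in THERAPY_LEVELS:
            raise ValueError(f"unknown therapy_level {self.therapy_level!r}")
        if self.genetic_test not in GENETIC_LEVELS:
            raise ValueError(f"unknown genetic_test {self.genetic_test!r}")
        if self.smoking is not None and self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"unknown smoking level {self.smoking!r}")
        if self.drinking is not None and self.drinking not in DRINKING_LEVELS:
            raise ValueError(f"unknown drinking level {self.drinking!r}")
        for name in ("chd_onset_age", "stroke_onset_age", "pvd_onset_age"):
            v = getattr(self, name)
            if v is not None and v > self.age:
                raise ValueError(f"{name}={v} exceeds age {self.age}")
        for name in ("fh_chd_relative_sex", "fh_stroke_relative_sex"):
            v = getattr(self, name)
            if v is not None and v not in SEXES:
                raise ValueError(f"unknown {name} {v!r}")


@dataclass(frozen=True)
class DerivedFlags:
    """Premature-event indicators and the untreated-LDL estimate.

    ``pCHD``/``pCHDTW`` use the DLCN / Taiwan cutoffs respectively, so
    ``pCHDTW`` implies ``pCHD`` (the Taiwan cutoffs are strictly stricter);
    likewise for the family-history pair.
    """

    pCHD: bool
    pCHDTW: bool
    pCHD_fh: bool
    pCHD_fhTW: bool
    pStroke: bool
    pStroke_fh: bool
    pPVD: bool
    ldl_untreated: float


def adjust_ldl(observed: float, therapy_level: str,
               factors: Mapping[str, float] | None = None) -> float:
    """Back-correct an on-treatment LDL-C to its untreated estimate.

    ``observed / (1 - r)`` where ``r`` is the reduction fraction of the
    therapy potency class; ``r("none") == 0`` so untreated values pass
    through unchanged.
    """
    if observed <= 0:
        raise ValueError(f"observed LDL-C must be > 0, got {observed}")
    factors = DEFAULT_LDL_REDUCTION if factors is None else factors
    try:
        r = factors[therapy_level]
    except KeyError:
        raise CohortError(f"no LDL reduction factor for therapy {therapy_level!r}")
    if not 0.0 <= r < 1.0:
        raise CohortError(f"LDL reduction fraction must be in [0, 1), got {r}")
    return observed / (1.0 - r)


def _premature(onset_age: int | None, sex: str,
               cutoffs: Mapping[str, int]) -> bool:
    return onset_age is not None and onset_age < cutoffs[sex]


def derive_flags(record: PatientRecord,
                 cutoffs: Mapping[str, Mapping[str, int]] | None = None,
                 ldl_factors: Mapping[str, float] | None = None) -> DerivedFlags:
    """Compute the premature-event flags and untreated LDL for one record.

    Deterministic in the record and configs. Family-history flags need the
    relative's sex; if an onset age is recorded without it the flag is
    treated as absent (False) with a warning.
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)

    def fam(onset, rel_sex, cutset) -> bool:
        if onset is None:
            return False
        if rel_sex is None:
            warnings.warn(
                f"patient {record.id}: family onset age without relative sex; "
                "flag treated as absent", stacklevel=3)
            return False
        return _premature(onset, rel_sex, cutset)

    return DerivedFlags(
        pCHD=_premature(record.chd_onset_age, record.sex, cut["chd"]),
        pCHDTW=_premature(record.chd_onset_age, record.sex, cut["chd_tw"]),
        pCHD_fh=fam(record.fh_chd_onset_age, record.fh_chd_relative_sex, cut["chd"]),
        pCHD_fhTW=fam(record.fh_chd_onset_age, record.fh_chd_relative_sex, cut["chd_tw"]),
        pStroke=_premature(record.stroke_onset_age, record.sex, cut["stroke"]),
        pStroke_fh=fam(record.fh_stroke_onset_age, record.fh_stroke_relative_sex,
                       cut["stroke"]),
        pPVD=_premature(record.pvd_onset_age, record.sex, cut["pvd"]),
        ldl_untreated=adjust_ldl(record.ldl_c, record.therapy_level, ldl_factors),
    )


# ---------------------------------------------------------------------------
# CSV input / output

_BOOL_FIELDS = frozenset(
    f.name for f in dc_fields(PatientRecord) if f.type in ("bool",))
_INT_FIELDS = frozenset((
    "age", "chd_onset_age", "stroke_onset_age", "pvd_onset_age",
    "fh_chd_onset_age", "fh_stroke_onset_age"))
_FLOAT_FIELDS = frozenset((
    "ldl_c", "tc", "hdl_c", "tg", "lp_a", "bmi", "therapy_duration_years"))
_CAT_FIELDS = {
    "sex": SEXES, "smoking": SMOKING_LEVELS, "drinking": DRINKING_LEVELS,
    "therapy_level": THERAPY_LEVELS, "genetic_test": GENETIC_LEVELS,
    "fh_chd_relative_sex": SEXES, "fh_stroke_relative_sex": SEXES,
}
_REQUIRED = ("id", "age", "sex", "ldl_c", "tc")
FIELD_NAMES = tuple(f.name for f in dc_fields(PatientRecord))


def default_dictionary() -> dict[str, str]:
    """Identity column dictionary (file column -> record field)."""
    return {name: name for name in FIELD_NAMES}


def load_dictionary(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    bad = set(mapping.values()) - set(FIELD_NAMES)
    if bad:
        raise CohortError(f"column dictionary maps to unknown fields: {sorted(bad)}")
    return dict(mapping)


def _coerce(name: str, raw, index) -> object:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    if name in _BOOL_FIELDS:
        s = str(raw).strip().lower()
        if s in ("1", "true", "yes"):
            return True
        if s in ("0", "false", "no"):
            return False
        raise RowError(index, f"{name}: expected 0/1 boolean, got {raw!r}")
    if name in _INT_FIELDS:
        return int(float(raw))
    if name in _FLOAT_FIELDS:
        return float(raw)
    if name in _CAT_FIELDS:
        s = str(raw).strip().lower()
        if s not in _CAT_FIELDS[name]:
            raise RowError(index, f"{name}: unknown level {raw!r}")
        return s
    return str(raw)


def record_from_mapping(row: Mapping[str, object], index=None) -> PatientRecord:
    kwargs = {}
    for name in FIELD_NAMES:
        if name in row:
            value = _coerce(name, row[name], index)
            if value is not None:
                kwargs[name] = value
    try:
        return PatientRecord(**kwargs)
    except (TypeError, ValueError) as exc:
        raise RowError(index, str(exc)) from exc


def read_cohort(path: str | Path,
                dictionary: Mapping[str, str] | None = None,
                ) -> tuple[list[PatientRecord], dict[str, int]]:
    """Read a cohort CSV, applying the study exclusion rules.

    Rows missing LDL-C or TC, or aged under 18, are dropped and counted per
    reason in the returned exclusion dict (keys ``missing_ldl``,
    ``missing_tc``, ``under_age``); other malformed rows raise
    :class:`RowError` with the row index.

    Returns ``(records, exclusions)``.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # unparseable file is fatal
        raise CohortError(f"cannot parse cohort file {path}: {exc}") from exc
    dictionary = dictionary or default_dictionary()
    unknown = set(dictionary.values()) - set(FIELD_NAMES)
    if unknown:
        raise CohortError(f"dictionary maps to unknown fields: {sorted(unknown)}")
    frame = frame.rename(columns=dict(dictionary))

    records: list[PatientRecord] = []
    exclusions = {"missing_ldl": 0, "missing_tc": 0, "under_age": 0}
    for index, row in frame.iterrows():
        data = row.to_dict()
        if str(data.get("ldl_c", "")).strip() == "":
            exclusions["missing_ldl"] += 1
            continue
        if str(data.get("tc", "")).strip() == "":
            exclusions["missing_tc"] += 1
            continue
        age_raw = str(data.get("age", "")).strip()
        if age_raw and float(age_raw) < 18:
            exclusions["under_age"] += 1
            continue
        records.append(record_from_mapping(data, index=index))
    dropped = sum(exclusions.values())
    if dropped:
        logger.info("read_cohort: excluded %d rows %s", dropped, exclusions)
    return records, exclusions


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as the documented CSV (booleans 0/1, missing empty)."""
    frame = cohort_to_frame(records)
    frame.to_csv(path, index=False)


def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {}
        for name in FIELD_NAMES:
            v = getattr(rec, name)
            if name in _BOOL_FIELDS and v is not None:
                v = int(v)
            row[name] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=FIELD_NAMES)


def flags_to_frame(records: Sequence[PatientRecord],
                   flags: Sequence[DerivedFlags]) -> pd.DataFrame:
    """Tabulate derived flags alongside patient ids."""
    data = {"id": [r.id for r in records]}
    for name in ("pCHD", "pCHDTW", "pCHD_fh", "pCHD_fhTW",
                 "pStroke", "pStroke_fh", "pPVD"):
        data[name] = [int(getattr(f, name)) for f in flags]
    data["ldl_untreated"] = [f.ldl_untreated for f in flags]
    return pd.DataFrame(data)
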