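"""Stage orchestration: cohort -> criteria -> assessment -> HYR -> models.

Functions here are the programmatic pipeline the command-line interface
wraps. Every JSON report embeds a digest of the configuration that produced
it, so a report is reproducible from config + seed alone; no timestamps are
written, making repeated runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import assessment, criteria as criteria_mod, hybrid
from .cohort import DerivedFlags, PatientRecord, derive_flags

logger = logging.getLogger("fhrisk")

#: candidate variables offered to the selection stage (Table-style encoding)
CANDIDATE_VARIABLES = (
    "age", "sex_male", "bmi", "smoking_ex", "smoking_current",
    "drinking_ex", "drinking_current", "ldl_c", "hdl_c", "tc", "tg", "lp_a",
    "tendon_xanthomata", "arcus_cornealis", "hyperlipemia", "diabetes",
    "hypertension", "therapy_level", "pCHD", "pCHDTW", "pCHD_fh",
    "pCHD_fhTW", "pStroke", "pStroke_fh", "pPVD", "fh_hyperlipemia",
    "fh_xanthomata",
)
CATEGORICAL_VARIABLES = frozenset(
    v for v in CANDIDATE_VARIABLES
    if v not in ("age", "bmi", "ldl_c", "hdl_c", "tc", "tg", "lp_a"))

_THERAPY_ORD = {"none": 0, "low": 1, "medium": 2, "high": 3}


def derive_all(records: Sequence[PatientRecord],
               cutoffs=None, ldl_factors=None) -> list[DerivedFlags]:
    return [derive_flags(r, cutoffs=cutoffs, ldl_factors=ldl_factors)
            for r in records]


def encode_features(records: Sequence[PatientRecord],
                    flags: Sequence[DerivedFlags],
                    variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Numeric feature matrix: indicators for categories, ordinal therapy."""
    rows = []
    for rec, fl in zip(records, flags):
        rows.append({
            "age": rec.age,
            "sex_male": int(rec.sex == "male"),
            "bmi": rec.bmi if rec.bmi is not None else np.nan,
            "smoking_ex": int(rec.smoking == "ex"),
            "smoking_current": int(rec.smoking == "current"),
            "drinking_ex": int(rec.drinking == "ex"),
            "drinking_current": int(rec.drinking == "current"),
            "ldl_c": rec.ldl_c,
            "hdl_c": rec.hdl_c if rec.hdl_c is not None else np.nan,
            "tc": rec.tc,
            "tg": rec.tg if rec.tg is not None else np.nan,
            "lp_a": rec.lp_a if rec.lp_a is not None else np.nan,
            "tendon_xanthomata": int(rec.tendon_xanthomata),
            "arcus_cornealis": int(rec.arcus_cornealis),
            "hyperlipemia": int(rec.hyperlipemia),
            "diabetes": int(rec.diabetes),
            "hypertension": int(rec.hypertension),
            "therapy_level": _THERAPY_ORD[rec.therapy_level],
            "pCHD": int(fl.pCHD),
            "pCHDTW": int(fl.pCHDTW),
            "pCHD_fh": int(fl.pCHD_fh),
            "pCHD_fhTW": int(fl.pCHD_fhTW),
            "pStroke": int(fl.pStroke),
            "pStroke_fh": int(fl.pStroke_fh),
            "pPVD": int(fl.pPVD),
            "fh_hyperlipemia": int(rec.fh_hyperlipemia),
            "fh_xanthomata": int(rec.fh_xanthomata),
        })
    frame = pd.DataFrame(rows, columns=CANDIDATE_VARIABLES)
    if variables is not None:
        frame = frame[list(variables)]
    return frame


def score_stage(records: Sequence[PatientRecord],
                flags: Sequence[DerivedFlags],
                names: Sequence[str] = criteria_mod.CRITERION_NAMES,
                ) -> pd.DataFrame:
    """Level indices per patient x criterion (plus the level labels)."""
    defs = {n: criteria_mod.load_builtin(n) for n in names}
    results = criteria_mod.score_cohort(defs, records, flags)
    data = {"id": [r.id for r in records]}
    for name in names:
        data[name] = [res.level_index for res in results[name]]
    return pd.DataFrame(data)


def assess_stage(levels: pd.DataFrame, reference: str = "DLCN",
                 names: Sequence[str] | None = None) -> dict:
    """Binarize every tool, cross-tabulate against the reference, pick."""
    names = [c for c in levels.columns if c != "id"] if names is None else list(names)
    defs = {n: criteria_mod.load_builtin(n) for n in names}
    ref_def = defs[reference]
    flags = {}
    for name in names:
        n_levels = defs[name].n_levels
        scheme = criteria_mod.default_scheme(n_levels)
        flags[name] = [idx >= n_levels - (1 if scheme == "top1" else 2)
                       for idx in levels[name]]
    perfs = {n: assessment.performance(
        assessment.cross_tabulate(flags[n], flags[reference]))
        for n in names if n != reference}
    picks = assessment.select_candidates(perfs, reference=reference)
    ref_positives = int(sum(flags[reference]))
    return {
        "reference": reference,
        "reference_positives": ref_positives,
        "n": len(levels),
        "rows": [assessment.performance_row(n, p) for n, p in perfs.items()],
        "sensitivity_pick": picks.sensitivity_pick,
        "specificity_pick": picks.specificity_pick,
        "excluded": list(picks.excluded),
        "_performances": perfs,
    }


def hybridize_stage(levels: pd.DataFrame, voters: Sequence[str]) -> pd.DataFrame:
    """Add hyr_level / hyr_high_risk columns from the three voters."""
    four_level = [v for v in voters]
    labels = hybrid.hybridize([levels[v].tolist() for v in four_level])
    out = levels.copy()
    out["hyr_level"] = [lab.level_index for lab in labels]
    out["hyr_high_risk"] = [int(lab.high_risk) for lab in labels]
    return out


def config_digest(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report(payload: Mapping, path: str | Path, config: Mapping) -> None:
    """Atomic JSON report with the producing config and its digest."""
    path = Path(path)
    body = dict(payload)
    body["config"] = dict(config)
    body["config_digest"] = config_digest(config)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(body, indent=2, sort_keys=True, default=_jsonify))
    tmp.replace(path)
    logger.info("wrote %s", path)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
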