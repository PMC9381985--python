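"""Declarative engine for FH diagnostic criteria.

A criterion definition is a small YAML document, loaded into an immutable
:class:`CriterionDefinition`. Two modes exist:

``points``
    Items carry point values and fire on predicates over the patient record
    plus derived flags; total points are banded into ordered levels (the
    DLCN family: score < 3 unlikely, 3–5 possible, 6–8 probable, > 8
    definite). Items sharing a ``group`` are mutually exclusive — only the
    highest-scoring firing item in a group counts (LDL bands, family
    history).

``rules``
    Each level above the lowest is a boolean combinator (``all_of``,
    ``any_of``, ``any_k``) over named items; the highest satisfied level
    wins and the lowest level is the default.

Predicates are nested ``all`` / ``any`` / ``not`` combinators whose leaves
compare one field (record or derived flag) against a constant with
``eq/ne/gt/ge/lt/le/in``. A missing (``None``) field fails its leaf, so
absent optional data simply means "item not met" — never an error.

Eleven definitions ship in ``fhrisk/data/criteria``: SBR, DLCN, MEDPED,
JFHMC, LDLC_TC, AHA, SCCFH, LPA_DLCN, MDLCN, TW and CHC. All numeric
cutoffs live in those files, none in code. Scoring always uses the
untreated-LDL estimate (``ldl_untreated``), not the raw on-treatment value.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cohort import DerivedFlags, PatientRecord

_LEAF_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "in": lambda a, b: a in b,
}

CRITERION_NAMES = ("SBR", "DLCN", "MEDPED", "JFHMC", "LDLC_TC", "AHA",
                   "SCCFH", "LPA_DLCN", "MDLCN", "TW", "CHC")


class CriterionConfigError(ValueError):
    """Invalid criterion definition file."""


@dataclass(frozen=True)
class Item:
    id: str
    when: Mapping
    points: float | None = None
    group: str | None = None


@dataclass(frozen=True)
class CriterionDefinition:
    """An immutable diagnostic criterion (see module docstring)."""

    name: str
    mode: str  # {"points", "rules"}
    levels: tuple[str, ...]  # ordered, lowest = unlikely / less-risk
    items: tuple[Item, ...]
    level_thresholds: Mapping[str, tuple[float | None, float | None]] | None = None
    rules: Mapping[str, Mapping] | None = None
    source: str | None = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def max_points(self) -> float:
        """Highest achievable total (one item per group, all firing)."""
        if self.mode != "points":
            raise ValueError("max_points only defined for points mode")
        best: dict[str, float] = {}
        for it in self.items:
            key = it.group or it.id
            best[key] = max(best.get(key, 0.0), it.points)
        return sum(best.values())


@dataclass(frozen=True)
class CriterionResult:
    criterion: str
    level_index: int
    level: str
    points: float | None
    fired_items: tuple[str, ...]


# ---------------------------------------------------------------------------
# predicate evaluation

def _lookup(field: str, record: PatientRecord, flags: DerivedFlags):
    if hasattr(flags, field):
        return getattr(flags, field)
    if hasattr(record, field):
        return getattr(record, field)
    raise CriterionConfigError(f"predicate references unknown field {field!r}")


def evaluate_predicate(pred: Mapping, record: PatientRecord,
                       flags: DerivedFlags) -> bool:
    """Evaluate one (possibly nested) predicate; absent fields fail."""
    if "all" in pred:
        return all(evaluate_predicate(p, record, flags) for p in pred["all"])
    if "any" in pred:
        return any(evaluate_predicate(p, record, flags) for p in pred["any"])
    if "not" in pred:
        return not evaluate_predicate(pred["not"], record, flags)
    if "field" not in pred:
        raise CriterionConfigError(f"malformed predicate {pred!r}")
    value = _lookup(pred["field"], record, flags)
    ops = [(k, v) for k, v in pred.items() if k != "field"]
    if not ops:
        raise CriterionConfigError(f"predicate for {pred['field']!r} has no operator")
    for op, target in ops:
        if op not in _LEAF_OPS:
            raise CriterionConfigError(f"unknown predicate operator {op!r}")
        if value is None:
            return False
        if not _LEAF_OPS[op](value, target):
            return False
    return True


def _validate_predicate(pred: Mapping) -> None:
    """Structural check at load time (unknown operators / fields fail fast)."""
    if not isinstance(pred, Mapping):
        raise CriterionConfigError(f"predicate must be a mapping, got {pred!r}")
    for key in ("all", "any"):
        if key in pred:
            for sub in pred[key]:
                _validate_predicate(sub)
            return
    if "not" in pred:
        _validate_predicate(pred["not"])
        return
    if "field" not in pred:
        raise CriterionConfigError(f"malformed predicate {pred!r}")
    field = pred["field"]
    from .cohort import FIELD_NAMES
    flag_fields = tuple(DerivedFlags.__dataclass_fields__)
    if field not in FIELD_NAMES and field not in flag_fields:
        raise CriterionConfigError(f"predicate references unknown field {field!r}")
    for op in (k for k in pred if k != "field"):
        if op not in _LEAF_OPS:
            raise CriterionConfigError(f"unknown predicate operator {op!r}")


# ---------------------------------------------------------------------------
# loading

def _parse_thresholds(raw: Mapping, levels: Sequence[str]):
    if set(raw) != set(levels):
        raise CriterionConfigError(
            f"level_thresholds {sorted(raw)} must cover exactly levels {list(levels)}")
    parsed = {}
    for level in levels:
        lo, hi = raw[level]
        parsed[level] = (None if lo is None else float(lo),
                         None if hi is None else float(hi))
    # partition check: ordered, non-overlapping, contiguous (integer points)
    prev_hi = None
    for i, level in enumerate(levels):
        lo, hi = parsed[level]
        if lo is not None and hi is not None and lo > hi:
            raise CriterionConfigError(f"level {level!r}: empty range [{lo}, {hi}]")
        if i == 0 and lo is not None and lo > 0:
            raise CriterionConfigError("lowest level must cover zero points")
        if i > 0:
            if lo is None:
                raise CriterionConfigError(f"level {level!r}: open lower bound overlaps")
            if prev_hi is None or lo <= prev_hi:
                raise CriterionConfigError(
                    f"level {level!r} overlaps the level below (lo={lo}, prev hi={prev_hi})")
            if lo > prev_hi + 1:
                raise CriterionConfigError(
                    f"gap between levels below {level!r}: {prev_hi} .. {lo}")
        if i == len(levels) - 1 and hi is not None:
            raise CriterionConfigError("highest level must be open above")
        prev_hi = hi
    return parsed


_RULE_KEYS = {"all_of", "any_of", "any_k"}


def _validate_rule(rule: Mapping, item_ids: set[str]) -> None:
    keys = set(rule) & _RULE_KEYS
    if len(keys) != 1:
        raise CriterionConfigError(f"rule must have exactly one combinator: {rule!r}")
    key = keys.pop()
    if key == "any_k":
        spec = rule["any_k"]
        members, k = spec["of"], spec["k"]
        if not 1 <= k <= len(members):
            raise CriterionConfigError(f"any_k: k={k} out of range for {members}")
    else:
        members = rule[key]
    for m in members:
        if isinstance(m, Mapping):
            _validate_rule(m, item_ids)
        elif m not in item_ids:
            raise CriterionConfigError(f"rule references unknown item {m!r}")


def load_criterion(config) -> CriterionDefinition:
    """Load a definition from a path or a pre-parsed mapping."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    name = config.get("name")
    mode = config.get("mode")
    levels = tuple(config.get("levels", ()))
    if not name or mode not in ("points", "rules"):
        raise CriterionConfigError("definition needs a name and mode in {points, rules}")
    if not 2 <= len(levels) <= 4:
        raise CriterionConfigError(f"{name}: need 2-4 ordered levels, got {levels}")
    items = []
    seen: set[str] = set()
    for raw in config.get("items", ()):
        item_id = raw.get("id")
        if not item_id or item_id in seen:
            raise CriterionConfigError(f"{name}: missing or duplicate item id {item_id!r}")
        seen.add(item_id)
        _validate_predicate(raw.get("when", {}))
        points = raw.get("points")
        if mode == "points" and points is None:
            raise CriterionConfigError(f"{name}: item {item_id!r} lacks points")
        items.append(Item(id=item_id, when=raw["when"],
                          points=None if points is None else float(points),
                          group=raw.get("group")))
    thresholds = rules = None
    if mode == "points":
        thresholds = _parse_thresholds(config.get("level_thresholds", {}), levels)
    else:
        rules = dict(config.get("rules", {}))
        unknown = set(rules) - set(levels[1:])
        if unknown:
            raise CriterionConfigError(f"{name}: rules for unknown levels {sorted(unknown)}")
        if levels[0] in rules:
            raise CriterionConfigError(f"{name}: lowest level is the default, no rule allowed")
        for level in levels[1:]:
            if level not in rules:
                raise CriterionConfigError(f"{name}: level {level!r} lacks a rule")
            _validate_rule(rules[level], seen)
    return CriterionDefinition(name=name, mode=mode, levels=levels,
                               items=tuple(items), level_thresholds=thresholds,
                               rules=rules, source=config.get("source"))


def builtin_criterion_path(name: str) -> Path:
    return Path(resources.files("fhrisk").joinpath(f"data/criteria/{name}.yaml"))


def load_builtin(name: str) -> CriterionDefinition:
    """Load one of the 11 shipped criterion definitions by name."""
    if name not in CRITERION_NAMES:
        raise CriterionConfigError(f"unknown builtin criterion {name!r}")
    return load_criterion(builtin_criterion_path(name))


def load_all_builtin() -> dict[str, CriterionDefinition]:
    return {name: load_builtin(name) for name in CRITERION_NAMES}


# ---------------------------------------------------------------------------
# scoring

def _fired_items(criterion: CriterionDefinition, record: PatientRecord,
                 flags: DerivedFlags) -> list[Item]:
    return [it for it in criterion.items
            if evaluate_predicate(it.when, record, flags)]


def score(criterion: CriterionDefinition, record: PatientRecord,
          flags: DerivedFlags) -> CriterionResult:
    """Score one patient: total points (points mode) and ordinal level."""
    fired = _fired_items(criterion, record, flags)
    if criterion.mode == "points":
        by_group: dict[str, Item] = {}
        for it in fired:
            key = it.group or it.id
            if key not in by_group or it.points > by_group[key].points:
                by_group[key] = it
        counted = list(by_group.values())
        points = sum(it.points for it in counted)
        idx = 0
        for i, level in enumerate(criterion.levels):
            lo, hi = criterion.level_thresholds[level]
            if (lo is None or points >= lo) and (hi is None or points <= hi):
                idx = i
                break
        return CriterionResult(criterion=criterion.name, level_index=idx,
                               level=criterion.levels[idx], points=points,
                               fired_items=tuple(it.id for it in counted))
    fired_ids = {it.id for it in fired}
    idx = 0
    for i in range(len(criterion.levels) - 1, 0, -1):  # highest satisfied wins
        if _rule_satisfied(criterion.rules[criterion.levels[i]], fired_ids):
            idx = i
            break
    return CriterionResult(criterion=criterion.name, level_index=idx,
                           level=criterion.levels[idx], points=None,
                           fired_items=tuple(sorted(fired_ids)))


def _rule_satisfied(rule: Mapping, fired: set[str]) -> bool:
    def member_ok(m) -> bool:
        return _rule_satisfied(m, fired) if isinstance(m, Mapping) else m in fired

    if "all_of" in rule:
        return all(member_ok(m) for m in rule["all_of"])
    if "any_of" in rule:
        return any(member_ok(m) for m in rule["any_of"])
    spec = rule["any_k"]
    return sum(member_ok(m) for m in spec["of"]) >= spec["k"]


def binarize(result: CriterionResult, n_levels: int, scheme: str = "top2") -> bool:
    """Collapse an ordinal verdict to a risky/less-risk flag.

    ``scheme`` is ``top1`` / ``top2`` / ``top3``: the flag is true iff the
    level sits within the top-k labels. Two-level criteria use ``top1``.
    """
    try:
        k = {"top1": 1, "top2": 2, "top3": 3}[scheme]
    except KeyError:
        raise ValueError(f"unknown binarization scheme {scheme!r}")
    if k >= n_levels:
        raise ValueError(f"scheme {scheme} too deep for {n_levels}-level criterion")
    return result.level_index >= n_levels - k


def default_scheme(n_levels: int) -> str:
    """Comparison convention: 4- and 3-level tools top2, 2-level top1."""
    return "top1" if n_levels == 2 else "top2"


def score_cohort(criteria: Mapping[str, CriterionDefinition],
                 records: Sequence[PatientRecord],
                 flags: Sequence[DerivedFlags]):
    """Score every record under every criterion.

    Returns ``{criterion: [CriterionResult, ...]}`` in record order.
    """
    return {name: [score(defn, r, f) for r, f in zip(records, flags)]
            for name, defn in criteria.items()}
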