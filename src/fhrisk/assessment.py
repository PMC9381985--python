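"""Head-to-head evaluation of diagnostic tools against a reference.

Each candidate tool's binary risky/less-risk flags are cross-tabulated
against the reference criterion's flags (the reference binarized over its
top two levels), giving exact 2x2 counts and the five-metric block:
sensitivity, specificity, PPV, NPV and AUC, plus flagged prevalence.

For a hard binary decision the ROC has a single interior operating point,
so its area is the balanced accuracy ``(Sen + Spe) / 2`` — that is the AUC
convention used throughout this module. Undefined metrics (zero
denominator) are reported as ``None``, never as 0. Internal values stay at
full precision; percentages are rounded half-up to two decimals only at
report time.

Candidate selection mirrors a sensitivity/specificity double pick: tools
flagging nobody are excluded outright; the remaining field yields the
highest-sensitivity tool (ties broken by specificity, then AUC, then
declaration order) and the highest-specificity tool (ties broken by
sensitivity, then AUC), which must be distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence


@dataclass(frozen=True)
class Confusion2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn

    @property
    def flagged(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class ToolPerformance:
    """Sen/Spe/PPV/NPV/AUC as proportions in [0, 1]; None if undefined."""

    sen: float | None
    spe: float | None
    ppv: float | None
    npv: float | None
    auc: float | None
    prevalence: float
    confusion: Confusion2x2


def cross_tabulate(tool_flags: Sequence[bool], ref_flags: Sequence[bool],
                   ids: Sequence | None = None,
                   ref_ids: Sequence | None = None) -> Confusion2x2:
    """Exact 2x2 counts of tool vs reference flags, aligned by patient."""
    if ids is not None and ref_ids is not None and list(ids) != list(ref_ids):
        raise ValueError("patient id mismatch between tool and reference flags")
    if len(tool_flags) != len(ref_flags):
        raise ValueError("flag vectors differ in length")
    tp = fp = fn = tn = 0
    for t, r in zip(tool_flags, ref_flags):
        if t and r:
            tp += 1
        elif t:
            fp += 1
        elif r:
            fn += 1
        else:
            tn += 1
    return Confusion2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def performance(c: Confusion2x2) -> ToolPerformance:
    """The five-metric block for one 2x2; AUC = (Sen + Spe) / 2."""
    if c.n == 0:
        raise ValueError("empty 2x2")
    sen = _ratio(c.tp, c.tp + c.fn)
    spe = _ratio(c.tn, c.tn + c.fp)
    auc = (sen + spe) / 2 if sen is not None and spe is not None else None
    return ToolPerformance(
        sen=sen, spe=spe,
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        auc=auc,
        prevalence=c.flagged / c.n,
        confusion=c,
    )


def round_percent(value: float | None, digits: int = 2) -> float | None:
    """Report-time half-up rounding of a proportion, as a percentage."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value) * 100)).quantize(q, rounding=ROUND_HALF_UP))


def performance_row(name: str, perf: ToolPerformance) -> dict:
    """Flat report row (percentages to 2 decimals + raw counts)."""
    c = perf.confusion
    return {
        "tool": name,
        "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
        "prevalence_pct": round_percent(perf.prevalence),
        "sen_pct": round_percent(perf.sen),
        "spe_pct": round_percent(perf.spe),
        "ppv_pct": round_percent(perf.ppv),
        "npv_pct": round_percent(perf.npv),
        "auc_pct": round_percent(perf.auc),
    }


@dataclass(frozen=True)
class CandidateSelection:
    sensitivity_pick: str
    specificity_pick: str
    excluded: tuple[str, ...]


def select_candidates(perfs: Mapping[str, ToolPerformance],
                      reference: str | None = None) -> CandidateSelection:
    """Pick the sensitivity and specificity champions among candidate tools.

    ``perfs`` preserves declaration order (dict order), which breaks exact
    ties deterministically. Tools flagging zero patients are excluded (they
    cannot identify high-risk cases).
    """
    names = [n for n in perfs if n != reference]
    if len(names) < 2:
        raise ValueError("need at least two non-reference tools")
    excluded = tuple(n for n in names if perfs[n].confusion.flagged == 0)
    field = [n for n in names if n not in excluded]
    if not field:
        raise ValueError("all tools excluded (none flags any patient)")

    def key_sen(n):
        p = perfs[n]
        return (p.sen or 0.0, p.spe or 0.0, p.auc or 0.0)

    def key_spe(n):
        p = perfs[n]
        return (p.spe or 0.0, p.sen or 0.0, p.auc or 0.0)

    sen_pick = max(field, key=key_sen)
    spe_pick = max(field, key=key_spe)
    if sen_pick == spe_pick:
        # the double pick must yield two distinct voters
        others = [n for n in field if n != sen_pick]
        if not others:
            raise ValueError("cannot pick two distinct tools from one candidate")
        spe_pick = max(others, key=key_spe)
    return CandidateSelection(sensitivity_pick=sen_pick,
                              specificity_pick=spe_pick, excluded=excluded)


def assess_tools(tool_flags: Mapping[str, Sequence[bool]],
                 ref_flags: Sequence[bool]) -> dict[str, ToolPerformance]:
    """Cross-tabulate and score every tool against the reference flags."""
    return {name: performance(cross_tabulate(flags, ref_flags))
            for name, flags in tool_flags.items()}
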