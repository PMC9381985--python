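"""Majority-vote hybridization of three 4-level FH tools into the HYR label.

Three ordinal verdicts on the same unlikely/possible/probable/definite
scale are combined by taking their **ordinal median** (the sorted middle
element). When any two voters agree the median equals that majority label,
and the binary high-risk outcome — level at least "possible" — is exactly
"at least two of the three votes are above unlikely".

The combining rule is pluggable (pass any callable mapping a sorted level
triple to a level index) so an explicit combination table can replace the
median verbatim. The canonical voters are the reference criterion plus the
sensitivity and specificity picks from the assessment stage, but any three
criteria sharing a 4-level scale are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

HYR_LEVELS = ("unlikely", "possible", "probable", "definite")


@dataclass(frozen=True)
class HybridLabel:
    level_index: int
    level: str
    high_risk: bool
    votes: tuple[int, int, int]  # the three input level indices, input order


def median_rule(sorted_votes: Sequence[int]) -> int:
    """Default combining rule: the middle of the three sorted votes."""
    return sorted_votes[1]


def vote(levels: Sequence[int], scale: Sequence[str] = HYR_LEVELS,
         rule: Callable[[Sequence[int]], int] = median_rule) -> HybridLabel:
    """Combine three ordinal verdicts (level indices on ``scale``)."""
    if len(levels) != 3:
        raise ValueError("the hybrid takes exactly three voters")
    levels = tuple(int(v) for v in levels)
    if any(not 0 <= v < len(scale) for v in levels):
        raise ValueError(f"votes {levels} outside the {len(scale)}-level scale")
    idx = rule(sorted(levels))
    return HybridLabel(level_index=idx, level=scale[idx],
                       high_risk=idx >= 1, votes=levels)


def hybridize(vote_columns: Sequence[Sequence[int]],
              scale: Sequence[str] = HYR_LEVELS,
              rule: Callable[[Sequence[int]], int] = median_rule,
              ) -> list[HybridLabel]:
    """Vote per patient over three aligned per-tool level-index vectors."""
    a, b, c = vote_columns
    if not len(a) == len(b) == len(c):
        raise ValueError("voter columns differ in length")
    return [vote((x, y, z), scale=scale, rule=rule) for x, y, z in zip(a, b, c)]
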