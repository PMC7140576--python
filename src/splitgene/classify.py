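"""Threshold-based calls on candidate M2f values and cross-comparison checks.

A candidate's M2f below the merged-null 10th percentile supports the
single (merged) gene model; above the split-null 90th percentile it
supports the separate (split) gene models; anything else — including
exact threshold equality — is ambiguous.  When one gene anchors
candidates in two different pairwise comparisons, the two calls can be
checked for consistency (conflict = one comparison supports merging, the
other supports splitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .nulls import Thresholds

logger = logging.getLogger(__name__)

MERGE = "merge_supported"
SPLIT = "split_supported"
AMBIGUOUS = "ambiguous"

#: monotone order of calls along the M2f axis
CALL_ORDER = {MERGE: 0, AMBIGUOUS: 1, SPLIT: 2}


@dataclass(frozen=True)
class Call:
    candidate_id: str
    m2f: float
    call: str
    thresholds: Thresholds

    @property
    def supported_annotation(self) -> str:
        """Which side's model the call supports: 'merged', 'split' or 'none'."""
        return {MERGE: "merged", SPLIT: "split", AMBIGUOUS: "none"}[self.call]


@dataclass(frozen=True)
class DualComparison:
    anchor_gene: str
    calls: tuple[Call, Call]
    status: str  # consistent | partial | conflict


def classify(m2f: float, t: Thresholds, candidate_id: str = "") -> Call:
    """Call one candidate from its M2f value with strict inequalities.

    merge_supported iff m2f < t_merge, split_supported iff m2f > t_split,
    otherwise ambiguous.  A value equal to either threshold is ambiguous.
    In the degenerate regime t_merge > t_split (well-separated nulls) a
    value satisfying both strict conditions fits neither null and is
    likewise called ambiguous.
    """
    below_merge = m2f < t.t_merge
    above_split = m2f > t.t_split
    if below_merge and not above_split:
        call = MERGE
    elif above_split and not below_merge:
        call = SPLIT
    else:
        call = AMBIGUOUS
    return Call(candidate_id=candidate_id, m2f=m2f, call=call, thresholds=t)


def cross_compare(calls_by_anchor: dict[str, list[Call]]) -> list[DualComparison]:
    """Pair up the two calls per anchor gene and grade their consistency.

    Anchors with other than exactly two calls are excluded with a warning.
    consistent = identical calls; conflict = one merge_supported and one
    split_supported; partial = one decisive call plus one ambiguous.
    """
    out = []
    for anchor in sorted(calls_by_anchor):
        calls = calls_by_anchor[anchor]
        if len(calls) != 2:
            logger.warning(
                "anchor %s has %d calls (need exactly 2); excluded", anchor, len(calls)
            )
            continue
        kinds = {calls[0].call, calls[1].call}
        if len(kinds) == 1:
            status = "consistent"
        elif kinds == {MERGE, SPLIT}:
            status = "conflict"
        else:
            status = "partial"
        out.append(DualComparison(anchor, (calls[0], calls[1]), status))
    return out


def joint_call_table(comparisons: list[DualComparison]) -> pd.DataFrame:
    """3x3 joint distribution of the two calls across dual comparisons."""
    order = [MERGE, AMBIGUOUS, SPLIT]
    table = pd.DataFrame(0, index=order, columns=order)
    for dc in comparisons:
        table.loc[dc.calls[0].call, dc.calls[1].call] += 1
    return table
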