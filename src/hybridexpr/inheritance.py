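"""Inheritance-mode classification of hybrid transcript expression.

Each transcript expressed in all three pairwise comparisons of a hybrid
zone (parentA vs parentB, parentA vs hybrid, parentB vs hybrid) is placed
in exactly one mode:

- conserved: no significant difference in any of the three comparisons;
- transgressive_up / transgressive_down: the hybrid is significantly
  higher / lower than both parents;
- additive: the hybrid is significantly higher than one parent and
  significantly lower than the other (between the parents);
- dominantA / dominantB: the hybrid is indistinguishable from one parent
  and significantly different from the other;
- ambiguous: the leftover pattern (the parents differ but the hybrid is
  indistinguishable from both) — kept explicit so mode counts always sum
  to the number of classified transcripts.

Significance uses the same DET gates as the differential-expression
module (FDR and fold-change thresholds), since classification operates on
DET calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexpr import DEResult

MODES = (
    "conserved",
    "additive",
    "dominantA",
    "dominantB",
    "transgressive_up",
    "transgressive_down",
    "ambiguous",
)

_DIRECTIONS = ("first_higher", "second_higher", "none")


@dataclass(frozen=True)
class PairwiseOutcome:
    """Significance and direction of one pairwise comparison.

    direction refers to the comparison's own ordering: "first_higher"
    means the first-named group is expressed higher.
    """

    significant: bool
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.significant == (self.direction == "none"):
            raise ValueError(
                "direction must be 'none' exactly when not significant"
            )


def classify_transcript(
    ab: PairwiseOutcome, ah: PairwiseOutcome, bh: PairwiseOutcome
) -> str:
    """Mode of one transcript from outcomes (A vs B, A vs H, B vs H)."""
    if not (ab.significant or ah.significant or bh.significant):
        return "conserved"
    h_above_a = ah.significant and ah.direction == "second_higher"
    h_below_a = ah.significant and ah.direction == "first_higher"
    h_above_b = bh.significant and bh.direction == "second_higher"
    h_below_b = bh.significant and bh.direction == "first_higher"
    if ah.significant and bh.significant:
        if h_above_a and h_above_b:
            return "transgressive_up"
        if h_below_a and h_below_b:
            return "transgressive_down"
        return "additive"  # higher than one parent, lower than the other
    if not ah.significant and bh.significant:
        return "dominantA"  # hybrid matches parent A, differs from B
    if ah.significant and not bh.significant:
        return "dominantB"
    return "ambiguous"  # parents differ, hybrid matches both


def _outcome_from_row(is_det: bool, logfc: float) -> PairwiseOutcome:
    # logfc is second-over-first in every DEResult
    if not is_det:
        return PairwiseOutcome(False, "none")
    return PairwiseOutcome(True, "second_higher" if logfc > 0 else "first_higher")


def classify_zone(
    de_ab: DEResult, de_ah: DEResult, de_bh: DEResult
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every transcript expressed in all three comparisons.

    de_ab compares parentA (first) vs parentB; de_ah parentA vs hybrid;
    de_bh parentB vs hybrid.  Returns the per-transcript calls and a
    mode-count summary (including the transgressive up/down split and
    total).
    """
    tables = {}
    for name, de in (("ab", de_ab), ("ah", de_ah), ("bh", de_bh)):
        tables[name] = de.table.set_index("transcript")[["is_det", "logfc"]]
    common = tables["ab"].index.intersection(tables["ah"].index).intersection(
        tables["bh"].index
    )
    if len(common) == 0:
        raise ValueError("comparisons share no expressed transcripts")
    records = []
    for t in common:
        outs = {
            name: _outcome_from_row(
                bool(tab.at[t, "is_det"]), float(tab.at[t, "logfc"])
            )
            for name, tab in tables.items()
        }
        mode = classify_transcript(outs["ab"], outs["ah"], outs["bh"])
        records.append(
            {
                "transcript": t,
                "mode": mode,
                "ab_outcome": _describe(outs["ab"]),
                "ah_outcome": _describe(outs["ah"]),
                "bh_outcome": _describe(outs["bh"]),
            }
        )
    calls = pd.DataFrame.from_records(records)
    return calls, summarize_modes(calls)


def _describe(o: PairwiseOutcome) -> str:
    return o.direction if o.significant else "ns"


def summarize_modes(calls: pd.DataFrame) -> pd.Series:
    """Mode counts plus the transgressive total (up + down)."""
    counts = calls["mode"].value_counts()
    summary = {mode: int(counts.get(mode, 0)) for mode in MODES}
    summary["transgressive_total"] = (
        summary["transgressive_up"] + summary["transgressive_down"]
    )
    summary["n_classified"] = int(len(calls))
    return pd.Series(summary)
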