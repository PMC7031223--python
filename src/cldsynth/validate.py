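"""Likert survey scoring and selection of the user-preferred diagram.

Respondents rate every candidate diagram on four statements — easy to
understand (``ease``), could describe it to others (``describe``), can
see my own contribution in it (``own_contribution``), useful for thinking
about interventions (``useful``) — on an eleven-point scale from -5
(strongly disagree) through 0 to +5 (strongly agree).

Selection rule (*diff from best means*): compute the mean score per
(candidate, item); for each item find the best mean across candidates;
a candidate's deficit is the sum over the four items of (best mean -
its mean).  The candidate with the smallest summed deficit is the user-
preferred *converged diagram*.  The rule is invariant to adding a
constant to every candidate on one item, and a candidate's deficit is
zero iff it attains the maximum on all four items.

``rounding="table"`` rounds means to one decimal before differencing,
which reproduces arithmetic done on a printed summary table;
full precision is the default for new studies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import CldError

__all__ = [
    "ITEMS",
    "ValidationSummary",
    "validate_survey",
    "item_means",
    "diff_from_best",
    "select_preferred",
    "summarize_survey",
    "WORKED_EXAMPLE_MEANS",
]

ITEMS = ("ease", "describe", "own_contribution", "useful")

SCORE_MIN, SCORE_MAX = -5, 5


@dataclass(frozen=True)
class ValidationSummary:
    """Item means, per-candidate deficits and the selected candidate."""

    item_means: pd.DataFrame      #: candidates x items
    best_means: pd.Series         #: per-item maxima across candidates
    diffs: pd.Series              #: candidate -> summed difference from best
    preferred: str
    tied: Tuple[str, ...] = ()    #: all candidates at the minimal deficit

    def to_frame(self) -> pd.DataFrame:
        """Table-1-style summary: means, diff and a preferred flag."""
        out = self.item_means.copy()
        out["diff_from_best"] = self.diffs
        out = out.sort_values(["diff_from_best", "candidate_id"]
                              if "candidate_id" in out.columns
                              else "diff_from_best")
        out["preferred"] = [idx == self.preferred for idx in out.index]
        return out


def validate_survey(sr: pd.DataFrame) -> pd.DataFrame:
    """Check ranges, item tokens and (respondent, candidate, item) uniqueness."""
    required = ["respondent_id", "candidate_id", "item", "score"]
    missing = [c for c in required if c not in sr.columns]
    if missing:
        raise CldError(f"survey is missing columns {missing}")
    bad_items = sorted(set(sr["item"]) - set(ITEMS))
    if bad_items:
        raise CldError(f"unknown survey items {bad_items}; expected {list(ITEMS)}")
    scores = pd.to_numeric(sr["score"], errors="raise")
    out_of_range = sr[(scores < SCORE_MIN) | (scores > SCORE_MAX)]
    if len(out_of_range):
        raise CldError(
            f"{len(out_of_range)} score(s) outside [{SCORE_MIN}, {SCORE_MAX}]"
        )
    dup = sr.duplicated(subset=["respondent_id", "candidate_id", "item"])
    if dup.any():
        rows = sr[dup][["respondent_id", "candidate_id", "item"]].head()
        raise CldError(f"duplicate (respondent, candidate, item) rows, e.g.\n{rows}")
    return sr


def item_means(sr: pd.DataFrame, allow_missing: bool = False,
               round_to: Optional[int] = None) -> pd.DataFrame:
    """Arithmetic mean per (candidate, item), full precision by default.

    Every candidate must have at least one response per item; gaps are a
    hard error unless ``allow_missing`` (then means are over the available
    responses, with a warning left to the caller's logging).
    """
    validate_survey(sr)
    means = (
        sr.pivot_table(index="candidate_id", columns="item", values="score",
                       aggfunc="mean")
        .reindex(columns=list(ITEMS))
    )
    gaps = [
        (cand, item)
        for cand in means.index
        for item in ITEMS
        if pd.isna(means.loc[cand, item])
    ]
    if gaps and not allow_missing:
        raise CldError(f"missing (candidate, item) cells: {gaps}")
    means.columns.name = None
    means.index.name = "candidate_id"
    if round_to is not None:
        means = means.round(round_to)
    return means


def diff_from_best(means: pd.DataFrame, rounding: str = "full") -> pd.Series:
    """Summed difference from the per-item best mean, per candidate.

    ``rounding="table"`` rounds means to one decimal first (printed-table
    arithmetic); ``"full"`` uses the means as given.
    """
    if rounding not in ("full", "table"):
        raise CldError(f"rounding must be 'full' or 'table', got {rounding!r}")
    if means.empty:
        raise CldError("diff_from_best needs at least one candidate")
    m = means[list(ITEMS)].astype(float)
    if rounding == "table":
        m = m.round(1)
    diffs = (m.max(axis=0) - m).sum(axis=1)
    diffs.name = "diff_from_best"
    return diffs


_K_PATTERN = re.compile(r"\((\d+)")


def _candidate_k(candidate_id: str) -> float:
    match = _K_PATTERN.search(candidate_id)
    return int(match.group(1)) if match else float("inf")


def select_preferred(diffs: pd.Series, tol: float = 1e-9) -> Tuple[str, Tuple[str, ...]]:
    """Argmin of the deficit; ties broken by smaller k, then lexicographic.

    Returns ``(preferred, tied)`` where ``tied`` lists every candidate
    within ``tol`` of the minimum (length > 1 signals a reported tie).
    """
    if diffs.empty:
        raise CldError("select_preferred needs at least one candidate")
    minimum = diffs.min()
    tied = sorted(
        (cid for cid in diffs.index if diffs[cid] <= minimum + tol),
        key=lambda cid: (_candidate_k(cid), cid),
    )
    return tied[0], tuple(tied)


def summarize_survey(sr: pd.DataFrame, rounding: str = "full",
                     allow_missing: bool = False) -> ValidationSummary:
    """Means -> deficits -> preferred candidate, in one step."""
    means = item_means(sr, allow_missing=allow_missing)
    shown = means.round(1) if rounding == "table" else means
    diffs = diff_from_best(means, rounding=rounding)
    preferred, tied = select_preferred(diffs)
    return ValidationSummary(
        item_means=shown,
        best_means=shown.max(axis=0),
        diffs=diffs,
        preferred=preferred,
        tied=tied,
    )


#: Worked example used throughout the docs and tests: mean item scores for
#: the eleven candidates of a small community study on the drivers of
#: sugar-sweetened-beverage consumption (13 diagrams, 9 survey respondents
#: — the scale this package's synthetic defaults emulate).  Feeding these
#: means through :func:`diff_from_best` with table rounding yields deficits
#: 0.3 .. 18.5 and selects "DEMATEL (8)".
WORKED_EXAMPLE_MEANS = pd.DataFrame(
    {
        "ease":             [4.1, 4.1, 4.0, 4.0, 3.8, 4.0, 3.6, 3.2, 3.3, 1.4, -0.1],
        "describe":         [3.9, 3.8, 4.0, 3.9, 3.9, 3.9, 3.8, 3.6, 3.6, 2.0, -0.3],
        "own_contribution": [2.0, 1.9, 2.1, 2.1, 2.1, 1.8, 1.8, 1.6, 1.7, 0.7, -1.9],
        "useful":           [3.7, 3.8, 3.4, 3.4, 3.6, 3.7, 3.6, 3.4, 3.1, 0.7, -2.2],
    },
    index=pd.Index(
        [
            "DEMATEL (8)",
            "Betweenness (10)",
            "DEMATEL (15)",
            "Degree (10)",
            "DEMATEL (10)",
            "Eigencentrality (10)",
            "Degree (15)",
            "Eigencentrality (15)",
            "Betweenness (15)",
            "Closeness (15)",
            "Closeness (10)",
        ],
        name="candidate_id",
    ),
)
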