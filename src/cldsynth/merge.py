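"""Standardise variable names and collapse many diagrams into one.

Participants name the same construct differently ("proximity to fast food"
vs "distance to junk food restaurant"); a curated synonym map — produced by
expert consensus, not by string matching — rewrites raw labels to canonical
ones.  After standardisation all diagrams are collapsed into a single
*merged diagram* containing every unique variable and connection anyone
proposed, with per-edge provenance (which diagrams contributed it) and a
record of polarity conflicts (pairs proposed with both signs).

Downstream analyses use binary (presence) adjacency; edge support is kept
as metadata only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .model import CausalDiagram, CldError, SynonymMap, slugify

__all__ = [
    "PolarityConflict",
    "MergedDiagram",
    "apply_synonym_map",
    "merge_diagrams",
    "resolve_polarity_conflicts",
    "write_merged",
    "read_merged",
    "POLICIES",
]

POLICIES = ("majority_positive_tiebreak", "keep_first", "drop")

EdgeKey = Tuple[str, str]


@dataclass(frozen=True)
class PolarityConflict:
    """An ordered pair proposed with both polarities across diagrams."""

    source: str
    target: str
    positive_count: int
    negative_count: int
    #: polarity proposed by the earliest contributing diagram (for keep_first)
    first_polarity: int = +1
    #: polarity the active policy settled on; None when the edge was dropped
    resolved: Optional[int] = None


@dataclass
class MergedDiagram:
    """Union of all participants' diagrams, with provenance.

    ``edge_support`` counts the distinct diagrams contributing each retained
    ordered pair (regardless of the sign they proposed); ``conflicts`` lists
    exactly the pairs for which both polarities were proposed.
    """

    diagram: CausalDiagram
    edge_support: Dict[EdgeKey, int] = field(default_factory=dict)
    edge_contributors: Dict[EdgeKey, FrozenSet[str]] = field(default_factory=dict)
    conflicts: List[PolarityConflict] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return self.diagram.n_variables

    @property
    def n_edges(self) -> int:
        return self.diagram.n_edges

    @property
    def variable_ids(self) -> Tuple[str, ...]:
        return self.diagram.variable_ids


def apply_synonym_map(d: CausalDiagram, m: SynonymMap) -> CausalDiagram:
    """Rewrite raw labels to canonical ones, fusing variables that collide.

    Edges are re-pointed to the fused variables and deduplicated.  Labels
    absent from the map pass through unchanged (their slug is still the id).
    Idempotent whenever the map's canonical labels are fixed points.
    """
    out = CausalDiagram(diagram_id=d.diagram_id, problem=d.problem)
    rename: Dict[str, str] = {}
    for vid in d.variable_ids:
        canonical = m.canonical(d.label_of(vid))
        rename[vid] = out.add_variable(canonical).id
    for e in d.sorted_edges():
        # edges are a set, so re-pointed duplicates collapse automatically
        out.add_edge(rename[e.source], rename[e.target], e.polarity)
    return out


def resolve_polarity_conflicts(
    pairs: Sequence[PolarityConflict],
    policy: str = "majority_positive_tiebreak",
) -> Dict[EdgeKey, Optional[int]]:
    """One polarity per conflicted ordered pair, per policy.

    Policies: ``majority_positive_tiebreak`` (+1 on a tie), ``keep_first``
    (the earliest proposer's sign), ``drop`` (remove the pair entirely,
    mapped to None).
    """
    if policy not in POLICIES:
        raise CldError(f"unknown conflict policy {policy!r}; choose from {POLICIES}")
    resolved: Dict[EdgeKey, Optional[int]] = {}
    for c in pairs:
        if c.positive_count < 1 and c.negative_count < 1:
            raise CldError(f"conflict record {c.source}->{c.target} has no proposers")
        if policy == "majority_positive_tiebreak":
            resolved[(c.source, c.target)] = +1 if c.positive_count >= c.negative_count else -1
        elif policy == "keep_first":
            resolved[(c.source, c.target)] = c.first_polarity
        else:  # drop
            resolved[(c.source, c.target)] = None
    return resolved


def merge_diagrams(
    ds: Sequence[CausalDiagram],
    m: Optional[SynonymMap] = None,
    policy: str = "majority_positive_tiebreak",
) -> MergedDiagram:
    """Collapse ``ds`` into one merged diagram after standardisation.

    The merged variable set is the union of canonical variables; the merged
    edge set is the union of unique ordered pairs, each with one resolved
    polarity.  With the default (majority) policy the result is invariant
    under permutation of ``ds``; ``keep_first`` deliberately is not.
    """
    if not ds:
        raise CldError("merge_diagrams requires at least one diagram")
    if m is None:
        m = SynonymMap()
    standardised = [apply_synonym_map(d, m) for d in ds]

    problems = {d.problem for d in standardised if d.problem}
    if len(problems) > 1:
        warnings.warn(f"diagrams describe different problems: {sorted(problems)}")

    merged = CausalDiagram(
        diagram_id="merged",
        problem=standardised[0].problem,
    )
    # first-seen label wins per id; iterate in a deterministic order
    for d in standardised:
        for vid in d.variable_ids:
            merged.add_variable(d.label_of(vid), id=vid)

    by_sign: Dict[EdgeKey, Dict[int, set]] = {}
    first_sign: Dict[EdgeKey, int] = {}
    for order, d in enumerate(standardised):
        for e in d.sorted_edges():
            slot = by_sign.setdefault(e.key, {+1: set(), -1: set()})
            slot[e.polarity].add(d.diagram_id)
            first_sign.setdefault(e.key, e.polarity)

    conflicts: List[PolarityConflict] = []
    for key in sorted(by_sign):
        pos, neg = by_sign[key][+1], by_sign[key][-1]
        if pos and neg:
            conflicts.append(
                PolarityConflict(
                    source=key[0], target=key[1],
                    positive_count=len(pos), negative_count=len(neg),
                    first_polarity=first_sign[key],
                )
            )
    resolution = resolve_polarity_conflicts(conflicts, policy)
    conflicts = [
        PolarityConflict(
            source=c.source, target=c.target,
            positive_count=c.positive_count, negative_count=c.negative_count,
            first_polarity=c.first_polarity,
            resolved=resolution[(c.source, c.target)],
        )
        for c in conflicts
    ]

    support: Dict[EdgeKey, int] = {}
    contributors: Dict[EdgeKey, FrozenSet[str]] = {}
    for key in sorted(by_sign):
        pos, neg = by_sign[key][+1], by_sign[key][-1]
        if pos and neg:
            polarity = resolution[key]
            if polarity is None:  # drop policy
                continue
        else:
            polarity = +1 if pos else -1
        merged.add_edge(key[0], key[1], polarity)
        contributors[key] = frozenset(pos | neg)
        support[key] = len(contributors[key])

    return MergedDiagram(
        diagram=merged.validate(),
        edge_support=support,
        edge_contributors=contributors,
        conflicts=conflicts,
    )


# ---------------------------------------------------------------------------
# persistence


def write_merged(md: MergedDiagram, path) -> None:
    """Write a merged diagram (graph + provenance) as JSON."""
    from .io import diagram_to_dict

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "diagram": diagram_to_dict(md.diagram),
        "edge_support": [
            [s, t, md.edge_support[(s, t)]] for s, t in sorted(md.edge_support)
        ],
        "edge_contributors": [
            [s, t, sorted(md.edge_contributors[(s, t)])]
            for s, t in sorted(md.edge_contributors)
        ],
        "conflicts": [
            {
                "source": c.source, "target": c.target,
                "positive_count": c.positive_count,
                "negative_count": c.negative_count,
                "first_polarity": c.first_polarity,
                "resolved": c.resolved,
            }
            for c in md.conflicts
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_merged(path) -> MergedDiagram:
    path = Path(path)
    payload = json.loads(path.read_text(encoding="utf-8"))
    d = CausalDiagram(
        diagram_id=payload["diagram"].get("diagram_id", "merged"),
        problem=payload["diagram"].get("problem", ""),
    )
    for entry in payload["diagram"]["variables"]:
        d.add_variable(label=entry["label"], id=entry["id"])
    for entry in payload["diagram"]["edges"]:
        d.add_edge(entry["source"], entry["target"], entry["polarity"])
    return MergedDiagram(
        diagram=d.validate(),
        edge_support={(s, t): n for s, t, n in payload.get("edge_support", [])},
        edge_contributors={
            (s, t): frozenset(ids) for s, t, ids in payload.get("edge_contributors", [])
        },
        conflicts=[PolarityConflict(**c) for c in payload.get("conflicts", [])],
    )
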