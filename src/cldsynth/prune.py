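"""Cut rankings to top-k sets and induce candidate diagrams.

Each analytical technique's ranking is cut at fixed points (10 and 15
variables by default) and the merged diagram is restricted to the retained
variables: a *candidate diagram* is the plain induced subgraph — every
merged edge whose endpoints both survive, with its stored polarity.  The
DEMATEL ranking additionally admits an analysis-driven cut at the size of
the leading prominence cluster, giving eleven candidates in the default
configuration (five techniques x two fixed cuts, plus the cluster cut).

Some rankings select variables that are barely connected to one another in
the merged diagram; the induced candidate then falls apart into fragments
and stops reading as a causal diagram.  ``viable`` reports this (largest
weak component covering >= 80% of the retained variables and at least
k - 1 edges); it is a report, not a filter — every candidate proceeds to
the validation survey.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .io import to_networkx
from .merge import MergedDiagram
from .model import CausalDiagram, CldError
from .ranking import (
    DISPLAY_NAMES,
    TECHNIQUES,
    DEMATELResult,
    NoClusterError,
    RankingResult,
    dematel,
    find_cluster_cutpoint,
    rank,
)

__all__ = [
    "CandidateDiagram",
    "CandidateConfig",
    "candidate_name",
    "top_k",
    "induce_candidate",
    "generate_candidates",
]


def candidate_name(technique: str, k: int, cluster: bool = False) -> str:
    """Display id like ``"DEMATEL (8)"``; cluster-cut duplicates of a fixed
    cut are disambiguated with a suffix."""
    base = f"{DISPLAY_NAMES[technique]} ({k})"
    return f"{base} [cluster]" if cluster else base


@dataclass(frozen=True)
class CandidateDiagram:
    """An induced subgraph of the merged diagram at one cut point."""

    candidate_id: str
    diagram: CausalDiagram
    technique: str
    k: int
    #: weakly-connected component sizes, descending (undirected projection)
    components: Tuple[int, ...]
    viable: bool
    #: "fixed" for predetermined cut points, "cluster" for the analysis-driven one
    provenance: str = "fixed"

    @property
    def n_variables(self) -> int:
        return self.diagram.n_variables

    @property
    def n_edges(self) -> int:
        return self.diagram.n_edges


@dataclass(frozen=True)
class CandidateConfig:
    """Which candidates to generate and how viability is judged."""

    techniques: Tuple[str, ...] = TECHNIQUES
    cuts: Tuple[int, ...] = (10, 15)
    include_cluster_cut: bool = True
    max_cluster_k: int = 15
    #: fraction of retained variables the largest component must cover
    viability_coverage: float = 0.8


def top_k(r: RankingResult, k: int) -> List[str]:
    """The first min(k, n) variable ids of the ranking's ordering."""
    if k < 1:
        raise CldError(f"k must be >= 1, got {k}")
    return list(r.ordering[:k])


def induce_candidate(
    md: MergedDiagram,
    ids: Sequence[str],
    technique: str,
    k: int,
    provenance: str = "fixed",
    viability_coverage: float = 0.8,
    candidate_id: Optional[str] = None,
) -> CandidateDiagram:
    """Restrict the merged diagram to ``ids`` with polarities intact."""
    id_set = set(ids)
    if not id_set:
        raise CldError("cannot induce a candidate on an empty variable set")
    unknown = id_set - set(md.variable_ids)
    if unknown:
        raise CldError(f"ids not in the merged diagram: {sorted(unknown)}")

    merged = md.diagram
    sub = CausalDiagram(
        diagram_id=candidate_id or candidate_name(technique, k),
        problem=merged.problem,
    )
    for vid in sorted(id_set):
        sub.add_variable(merged.label_of(vid), id=vid)
    for e in merged.sorted_edges():
        if e.source in id_set and e.target in id_set:
            sub.add_edge(e.source, e.target, e.polarity)

    comp_sizes = tuple(
        sorted(
            (len(c) for c in nx.weakly_connected_components(to_networkx(sub))),
            reverse=True,
        )
    )
    viable = (
        comp_sizes[0] >= viability_coverage * len(id_set)
        and sub.n_edges >= len(id_set) - 1
    )
    return CandidateDiagram(
        candidate_id=sub.diagram_id,
        diagram=sub.validate(),
        technique=technique,
        k=k,
        components=comp_sizes,
        viable=viable,
        provenance=provenance,
    )


def generate_candidates(
    md: MergedDiagram,
    config: CandidateConfig = CandidateConfig(),
    dematel_result: Optional[DEMATELResult] = None,
) -> List[CandidateDiagram]:
    """All candidates for the configured techniques and cut points.

    Default configuration: {degree, betweenness, eigencentrality,
    closeness, dematel} x {10, 15} fixed cuts plus the DEMATEL cluster
    cut — eleven candidates.  If no prominence cluster is detectable the
    cluster candidate is skipped with a warning (ten candidates).
    A precomputed ``dematel_result`` may be passed to avoid recomputation.
    """
    n = md.n_variables
    if n <= max(config.cuts, default=0):
        warnings.warn(
            f"merged diagram has only {n} variables; cut points >= {n} "
            "return the whole diagram"
        )

    candidates: List[CandidateDiagram] = []
    rankings: Dict[str, RankingResult] = {}
    for technique in config.techniques:
        if technique == "dematel":
            if dematel_result is None:
                dematel_result = dematel(md)
            rankings[technique] = dematel_result.ranking()
        else:
            rankings[technique] = rank(md, technique)
        for k in config.cuts:
            candidates.append(
                induce_candidate(
                    md, top_k(rankings[technique], k), technique, k,
                    viability_coverage=config.viability_coverage,
                )
            )

    if config.include_cluster_cut and "dematel" in config.techniques:
        try:
            kc = find_cluster_cutpoint(
                dematel_result, max_k=min(config.max_cluster_k, n - 1)
            )
        except NoClusterError as exc:
            warnings.warn(f"cluster cut skipped: {exc}")
        else:
            if kc in config.cuts:
                warnings.warn(
                    f"cluster cut k={kc} duplicates a fixed cut point; "
                    "kept as a separately named candidate"
                )
            candidates.append(
                induce_candidate(
                    md, top_k(rankings["dematel"], kc), "dematel", kc,
                    provenance="cluster",
                    viability_coverage=config.viability_coverage,
                    # suffix only when it would collide with a fixed-cut id
                    candidate_id=candidate_name("dematel", kc,
                                                cluster=(kc in config.cuts)),
                )
            )
    return candidates
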