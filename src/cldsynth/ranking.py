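"""Variable importance scoring on the merged diagram.

Five techniques, each yielding one score per merged variable:

* ``degree`` — total incident edges (in-degree + out-degree).
* ``betweenness`` — directed shortest-path betweenness, endpoints
  excluded, unnormalised.
* ``eigencentrality`` — eigenvector centrality on the undirected
  projection (the directed variant is zero everywhere outside the
  terminal strongly connected component, which is uninformative for
  causal maps), rescaled to unit maximum.
* ``closeness`` — harmonic closeness on the directed graph,
  ``score(v) = sum over u of 1/dist(v, u)``; unreachable pairs contribute
  0, so sparsely connected maps stay well-defined instead of degenerate.
* ``dematel`` — DEMATEL total-relation analysis (below); the ranking
  score is *prominence*.

DEMATEL
-------
DEMATEL (Decision Making Trial and Evaluation Laboratory) treats the
binary direct-influence matrix ``A`` as the first step of an influence
process and accumulates all indirect paths:

    s = max(max row sum of A, max column sum of A)
    X = A / s                         (normalised direct influence)
    T = X (I - X)^-1 = X + X^2 + ...  (total relation)

``D`` (row sums of T) is the influence a variable dispatches, ``R``
(column sums) the influence it receives; ``D + R`` (*prominence*) is its
net total importance in the system and ``D - R`` (*relation*) says
whether it is an overall influencer (positive) or receiver (negative).
Inverse-polarity connections are used with unit absolute weight here —
DEMATEL is undefined for negative influence entries — and their stored
signs are restored on any diagram derived from the ranking.

A cluster of strong influencers/receivers at the top of the prominence
ranking can justify an extra, analysis-driven cut point; see
:func:`find_cluster_cutpoint`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np

from .io import to_adjacency, to_networkx
from .merge import MergedDiagram
from .model import CausalDiagram, CldError

__all__ = [
    "TECHNIQUES",
    "DISPLAY_NAMES",
    "RankingResult",
    "DEMATELResult",
    "NoClusterError",
    "ConvergenceError",
    "degree_scores",
    "betweenness_scores",
    "eigencentrality_scores",
    "closeness_scores",
    "dematel",
    "dematel_scores",
    "find_cluster_cutpoint",
    "rank",
]

TECHNIQUES = ("degree", "betweenness", "eigencentrality", "closeness", "dematel")

DISPLAY_NAMES = {
    "degree": "Degree",
    "betweenness": "Betweenness",
    "eigencentrality": "Eigencentrality",
    "closeness": "Closeness",
    "dematel": "DEMATEL",
}

DiagramLike = Union[MergedDiagram, CausalDiagram]


class NoClusterError(CldError):
    """No prominence cluster found (e.g. all scores equal)."""


class ConvergenceError(RuntimeError):
    """An iterative computation failed to converge within its cap."""


@dataclass(frozen=True)
class RankingResult:
    """Scores for one technique plus the deterministic ordering.

    Ordering is by score descending, ties broken by variable id ascending.
    """

    technique: str
    scores: Dict[str, float]
    ordering: Tuple[str, ...]

    @classmethod
    def from_scores(cls, technique: str, scores: Dict[str, float]) -> "RankingResult":
        ordering = tuple(sorted(scores, key=lambda vid: (-scores[vid], vid)))
        return cls(technique=technique, scores=dict(scores), ordering=ordering)


def _as_diagram(md: DiagramLike) -> CausalDiagram:
    return md.diagram if isinstance(md, MergedDiagram) else md


def _digraph(md: DiagramLike, drop_self_loops: bool = False) -> nx.DiGraph:
    g = to_networkx(_as_diagram(md))
    if drop_self_loops:
        loops = list(nx.selfloop_edges(g))
        if loops:
            warnings.warn(
                f"{len(loops)} self-loop(s) excluded from path-based centrality"
            )
            g.remove_edges_from(loops)
    return g


# ---------------------------------------------------------------------------
# network-analysis techniques


def degree_scores(md: DiagramLike) -> RankingResult:
    """Total incident edges per variable (each directed edge counted once)."""
    g = _digraph(md)
    return RankingResult.from_scores("degree", {v: float(deg) for v, deg in g.degree()})


def betweenness_scores(md: DiagramLike) -> RankingResult:
    """Directed shortest-path betweenness, endpoints excluded, unnormalised."""
    g = _digraph(md, drop_self_loops=True)
    scores = nx.betweenness_centrality(g, normalized=False)
    return RankingResult.from_scores("betweenness", {v: float(s) for v, s in scores.items()})


def eigencentrality_scores(md: DiagramLike, max_iter: int = 1000,
                           tol: float = 1e-10) -> RankingResult:
    """Eigenvector centrality on the undirected projection, unit maximum.

    Power iteration from a uniform start vector: deterministic, and on
    disconnected graphs the uniform start spreads mass over components
    rather than collapsing arbitrarily onto one of a degenerate pair.
    """
    g = _digraph(md).to_undirected()
    if g.number_of_edges() == 0:
        return RankingResult.from_scores(
            "eigencentrality", {v: 0.0 for v in g.nodes()}
        )
    try:
        raw = nx.eigenvector_centrality(g, max_iter=max_iter, tol=tol)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(
            f"eigenvector centrality did not converge within {max_iter} iterations"
        ) from exc
    top = max(raw.values())
    scale = 1.0 / top if top > 0 else 1.0
    return RankingResult.from_scores(
        "eigencentrality", {v: float(s) * scale for v, s in raw.items()}
    )


def closeness_scores(md: DiagramLike) -> RankingResult:
    """Directed harmonic closeness: sum of 1/dist(v, u) over reachable u.

    networkx's harmonic centrality sums over *incoming* distances, so the
    graph is reversed to score outgoing reach.
    """
    g = _digraph(md, drop_self_loops=True)
    scores = nx.harmonic_centrality(g.reverse(copy=False))
    return RankingResult.from_scores("closeness", {v: float(s) for v, s in scores.items()})


# ---------------------------------------------------------------------------
# DEMATEL


@dataclass(frozen=True)
class DEMATELResult:
    """All DEMATEL matrices and per-variable statistics.

    Arrays are indexed by ``ordering`` (variable ids sorted ascending).
    """

    ordering: Tuple[str, ...]
    A: np.ndarray        #: binary direct-influence matrix
    s: float             #: normalisation scalar
    X: np.ndarray        #: normalised direct influence, A / s
    T: np.ndarray        #: total-relation matrix X (I - X)^-1
    D: np.ndarray        #: row sums of T — influence dispatched
    R: np.ndarray        #: column sums of T — influence received
    prominence: np.ndarray   #: D + R, net total importance
    relation: np.ndarray     #: D - R, influencer (+) vs receiver (-)

    def by_id(self, stat: str) -> Dict[str, float]:
        values = getattr(self, stat)
        return {vid: float(values[i]) for i, vid in enumerate(self.ordering)}

    def ranking(self) -> RankingResult:
        return RankingResult.from_scores("dematel", self.by_id("prominence"))


def dematel(md: DiagramLike, epsilon: float = 1e-6) -> DEMATELResult:
    """Run DEMATEL on the merged diagram's binary influence structure.

    Inverse-polarity edges enter with unit absolute weight (negative
    influence entries are undefined in DEMATEL); stored polarities are
    untouched and reappear on any diagram induced from the ranking.

    If ``I - X`` is singular or numerically near-singular — possible for
    strongly cyclic binary maps where the spectral radius of X reaches 1 —
    the normalisation scalar is inflated once by ``1 + epsilon`` with a
    warning; if that still fails a numerical error is raised.
    """
    d = _as_diagram(md)
    if d.n_variables < 1:
        raise CldError("DEMATEL requires at least one variable")
    a, ordering = to_adjacency(d, mode="absolute")
    n = len(ordering)
    s = float(max(a.sum(axis=1).max(initial=0.0), a.sum(axis=0).max(initial=0.0)))
    if s == 0.0:
        t = np.zeros_like(a)
        x = np.zeros_like(a)
    else:
        x, t = _total_relation(a, s)
        if t is None:
            warnings.warn(
                f"(I - X) is numerically singular; rescaling s by (1 + {epsilon:g})"
            )
            x, t = _total_relation(a, s * (1.0 + epsilon))
            if t is None:
                raise ConvergenceError(
                    "(I - X) remained singular after the epsilon rescale"
                )
            s = s * (1.0 + epsilon)
    dd = t.sum(axis=1)
    rr = t.sum(axis=0)
    return DEMATELResult(
        ordering=tuple(ordering), A=a, s=s, X=x, T=t,
        D=dd, R=rr, prominence=dd + rr, relation=dd - rr,
    )


_COND_CAP = 1e12


def _total_relation(a: np.ndarray, s: float):
    x = a / s
    m = np.eye(a.shape[0]) - x
    if np.linalg.cond(m) > _COND_CAP:
        return x, None
    return x, x @ np.linalg.inv(m)


def dematel_scores(md: DiagramLike, epsilon: float = 1e-6) -> RankingResult:
    """DEMATEL ranking: prominence (D + R) descending."""
    return dematel(md, epsilon=epsilon).ranking()


def find_cluster_cutpoint(r: DEMATELResult, max_k: Optional[int] = None) -> int:
    """Analysis-driven cut point from the prominence profile.

    Sorts prominence descending and returns the k (searched over
    2..max_k, default max_k = min(15, n - 1)) just above the largest
    consecutive gap, i.e. the size of the leading cluster of strong
    influencers/receivers.  Ties go to the smallest k.  Raises
    :class:`NoClusterError` when no positive gap exists in the search
    range (e.g. all prominences equal).
    """
    n = len(r.ordering)
    if n < 3:
        raise CldError("cluster cut point needs at least 3 variables")
    if max_k is None:
        max_k = min(15, n - 1)
    if not (2 <= max_k <= n - 1):
        raise CldError(f"max_k must be in [2, {n - 1}], got {max_k}")
    prom = sorted(r.by_id("prominence").values(), reverse=True)
    # noise floor relative to the profile's magnitude, so numerically flat
    # profiles (e.g. symmetric cycles) are not split on rounding error
    tol = 1e-9 * max(1.0, abs(prom[0]), abs(prom[-1]))
    best_k, best_gap = None, tol
    for k in range(2, max_k + 1):
        gap = prom[k - 1] - prom[k]
        if gap > best_gap + tol:
            best_k, best_gap = k, gap
    if best_k is None:
        raise NoClusterError(
            f"no prominence gap found in positions 2..{max_k}"
        )
    return best_k


# ---------------------------------------------------------------------------
# dispatch


def rank(md: DiagramLike, technique: str) -> RankingResult:
    """Score every merged variable with the named technique."""
    try:
        fn = {
            "degree": degree_scores,
            "betweenness": betweenness_scores,
            "eigencentrality": eigencentrality_scores,
            "closeness": closeness_scores,
            "dematel": dematel_scores,
        }[technique]
    except KeyError:
        raise CldError(f"unknown technique {technique!r}; choose from {TECHNIQUES}")
    return fn(md)
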