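"""Connection-circle placement and crossing-minimising untangling.

The connection-circle exercise starts with every driver on a plain
circle; causal links are then drawn as chords.  ``untangle`` turns that
view into a conventional causal-diagram drawing with spring-force
iterations constrained so the number of edge crossings never increases:
a proposed global position update is accepted only if it does not add
crossings, otherwise the step is halved (up to a retry cap) and finally
skipped.  Variables that share a simple directed cycle attract each
other more strongly, pulling feedback loops into compact, visually
prominent clusters.

The spring model itself (attraction along edges toward an ideal length,
pairwise repulsion, the cycle-attraction multiplier, step halving) is
this package's own mechanism for meeting those two objectives —
fewer crossings, emphasised loops — and every constant is exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .io import to_networkx
from .model import CausalDiagram, CldError

__all__ = [
    "LayoutState",
    "circle_layout",
    "count_crossings",
    "detect_feedback_loops",
    "untangle",
]

Point = Tuple[float, float]


@dataclass(frozen=True)
class LayoutState:
    positions: Dict[str, Point]
    crossings: int
    iteration: int = 0


def circle_layout(d: CausalDiagram) -> LayoutState:
    """Variables equally spaced on the unit circle, in variable-id order.

    The first variable sits at angle 0 (point (1, 0)) and the rest follow
    counter-clockwise.
    """
    ids = d.variable_ids
    if not ids:
        raise CldError("circle layout needs at least one variable")
    n = len(ids)
    positions = {
        vid: (math.cos(2 * math.pi * i / n), math.sin(2 * math.pi * i / n))
        for i, vid in enumerate(ids)
    }
    return LayoutState(positions=positions, crossings=count_crossings(d, positions))


def _orient(p: Point, q: Point, r: Point) -> float:
    """Signed area of the triangle pqr (positive = counter-clockwise)."""
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _properly_cross(p1: Point, p2: Point, q1: Point, q2: Point) -> bool:
    """True iff the open segments p1p2 and q1q2 intersect in their interiors."""
    d1 = _orient(q1, q2, p1)
    d2 = _orient(q1, q2, p2)
    d3 = _orient(p1, p2, q1)
    d4 = _orient(p1, p2, q2)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def count_crossings(d: CausalDiagram, positions: Dict[str, Point]) -> int:
    """Pairs of edges (not sharing an endpoint) whose segments properly cross.

    Edges are straight segments between their endpoint positions;
    direction and polarity are irrelevant to the geometry.  Pairs sharing
    an endpoint variable — including an edge and its reverse — never count,
    and neither do collinear overlaps or touchings at a point.
    """
    missing = [vid for vid in d.variables if vid not in positions]
    if missing:
        raise CldError(f"positions missing for variables {sorted(missing)}")
    edges = [e for e in d.sorted_edges() if not e.is_self_loop]
    crossings = 0
    for i in range(len(edges)):
        a = edges[i]
        for b in edges[i + 1:]:
            if {a.source, a.target} & {b.source, b.target}:
                continue
            if _properly_cross(
                positions[a.source], positions[a.target],
                positions[b.source], positions[b.target],
            ):
                crossings += 1
    return crossings


def detect_feedback_loops(d: CausalDiagram, max_len: int = 6) -> List[Tuple[str, ...]]:
    """All simple directed cycles of length <= ``max_len``.

    Each cycle is reported once, rotated so its lexicographically smallest
    variable id comes first; the list is sorted by (length, ids) and is
    therefore independent of variable insertion order.  Self-loops (length
    1) are included when present.
    """
    if max_len < 2:
        raise CldError(f"max_len must be >= 2, got {max_len}")
    g = to_networkx(d)
    canonical = set()
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        pivot = cycle.index(min(cycle))
        canonical.add(tuple(cycle[pivot:] + cycle[:pivot]))
    return sorted(canonical, key=lambda c: (len(c), c))


def _cycle_mate_pairs(d: CausalDiagram, max_len: int) -> set:
    """Unordered pairs of variables that appear together in a simple cycle."""
    pairs = set()
    for cycle in detect_feedback_loops(d, max_len=max_len):
        for i, u in enumerate(cycle):
            for v in cycle[i + 1:]:
                pairs.add(frozenset((u, v)))
    return pairs


def untangle(
    d: CausalDiagram,
    init: LayoutState,
    iterations: int = 50,
    seed: int = 0,
    *,
    spring_length: float = 1.0,
    attraction: float = 0.5,
    repulsion: float = 0.15,
    step: float = 0.1,
    loop_attraction: float = 2.0,
    max_halvings: int = 5,
    max_loop_len: int = 6,
) -> LayoutState:
    """Crossing-monotone spring iterations from ``init``.

    Per iteration a global displacement is computed (edge attraction
    toward ``spring_length``, all-pairs repulsion, attraction multiplied
    by ``loop_attraction`` on edges inside a simple cycle and applied at
    half strength between non-adjacent cycle mates) and the update is
    accepted only if the crossing count does not increase; otherwise the
    step is halved up to ``max_halvings`` times and, failing that, the
    iteration is skipped.  Deterministic for a fixed seed (used only to
    jitter coincident points apart).  The final crossing count is
    therefore never above the initial one.
    """
    if iterations < 0:
        raise CldError(f"iterations must be >= 0, got {iterations}")
    ids = list(d.variable_ids)
    if not ids:
        raise CldError("untangle needs at least one variable")
    if iterations == 0:
        return init

    rng = np.random.default_rng(seed)
    index = {vid: i for i, vid in enumerate(ids)}
    pos = np.array([init.positions[vid] for vid in ids], dtype=float)

    plain_edges: List[Tuple[int, int, float]] = []
    mates = _cycle_mate_pairs(d, max_loop_len)
    seen = set()
    for e in d.sorted_edges():
        if e.is_self_loop or (e.source, e.target) in seen or (e.target, e.source) in seen:
            continue
        seen.add((e.source, e.target))
        weight = loop_attraction if frozenset((e.source, e.target)) in mates else 1.0
        plain_edges.append((index[e.source], index[e.target], weight))
    # non-adjacent cycle mates: gentle pull so whole loops contract
    adjacent = {frozenset((ids[i], ids[j])) for i, j, _ in plain_edges}
    for pair in sorted(mates - adjacent, key=sorted):
        u, v = sorted(pair)
        plain_edges.append((index[u], index[v], 0.5 * loop_attraction))

    crossings = count_crossings(d, dict(zip(ids, map(tuple, pos))))

    for iteration in range(1, iterations + 1):
        # pairwise repulsion ~ 1/dist^2, directed away from the neighbour
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        if (dist < 1e-9).sum() > len(ids):  # off-diagonal coincidences
            pos = pos + rng.normal(scale=1e-6, size=pos.shape)
            delta = pos[:, None, :] - pos[None, :, :]
            dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        dist = np.maximum(dist, 1e-9)
        disp = ((repulsion / dist**3)[:, :, None] * delta).sum(axis=1)
        # edge attraction toward the ideal spring length
        for i, j, weight in plain_edges:
            d_vec = pos[j] - pos[i]
            length = max(float(np.linalg.norm(d_vec)), 1e-9)
            force = attraction * weight * (length - spring_length) * d_vec / length
            disp[i] += force
            disp[j] -= force

        accepted = False
        trial_step = step
        for _ in range(max_halvings + 1):
            candidate = pos + trial_step * disp
            trial_crossings = count_crossings(
                d, dict(zip(ids, map(tuple, candidate)))
            )
            if trial_crossings <= crossings:
                pos, crossings = candidate, trial_crossings
                accepted = True
                break
            trial_step /= 2.0
        # if never accepted, keep the previous positions for this iteration

    return LayoutState(
        positions={vid: (float(x), float(y)) for vid, (x, y) in zip(ids, pos)},
        crossings=crossings,
        iteration=iterations,
    )
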