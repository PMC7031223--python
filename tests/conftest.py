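"""Shared builders, random-graph helpers and hypothesis settings."""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from cldsynth import CausalDiagram

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def diagram_from_edges(
    edges: Sequence[Tuple[str, str, int]],
    extra_vars: Iterable[str] = (),
    diagram_id: str = "d",
    problem: str = "",
) -> CausalDiagram:
    """Build a diagram from (source_label, target_label, polarity) triples.

    Lowercase single-word labels double as ids.
    """
    d = CausalDiagram(diagram_id=diagram_id, problem=problem)
    for s, t, _ in edges:
        d.add_variable(s)
        d.add_variable(t)
    for v in extra_vars:
        d.add_variable(v)
    for s, t, p in edges:
        d.add_edge(d.add_variable(s).id, d.add_variable(t).id, p)
    return d.validate()


def random_digraph(
    rng: np.random.Generator,
    n: int,
    p: float = 0.3,
    negative_prob: float = 0.25,
    diagram_id: str = "rand",
) -> CausalDiagram:
    """G(n, p)-style signed digraph without self-loops or parallel pairs."""
    d = CausalDiagram(diagram_id=diagram_id)
    ids = [d.add_variable(f"v{i:02d}").id for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                polarity = -1 if rng.random() < negative_prob else +1
                d.add_edge(ids[i], ids[j], polarity)
    return d.validate()


# hypothesis strategy: small diagrams with unique ordered pairs
@st.composite
def small_diagrams(draw, max_nodes: int = 8, self_loops: bool = False):
    n = draw(st.integers(min_value=1, max_value=max_nodes))
    ids = [f"v{i}" for i in range(n)]
    pairs = [(s, t) for s in ids for t in ids if self_loops or s != t]
    chosen = draw(
        st.lists(st.sampled_from(pairs), unique=True, max_size=min(len(pairs), 16))
        if pairs else st.just([])
    )
    d = CausalDiagram(diagram_id="hyp")
    for vid in ids:
        d.add_variable(vid)
    for s, t in chosen:
        d.add_edge(s, t, draw(st.sampled_from((1, -1))))
    return d.validate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
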