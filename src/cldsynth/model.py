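"""Core data model for signed causal diagrams.

A causal (loop) diagram is a directed graph whose nodes are perceived
drivers of a complex problem and whose edges are signed causal claims:
polarity ``+1`` for a same-direction influence ("more A leads to more B")
and ``-1`` for an inverse one ("more A leads to less B").  Diagrams are
drawn independently by participants, so variable labels are free text;
downstream stages standardise them through a :class:`SynonymMap` and merge
the diagrams into one union graph.

Variable identifiers are slugs of the (canonical) label — lowercase with
internal whitespace collapsed and spaces replaced by underscores — so that
the same construct receives the same id in every diagram and across
read/write round trips.  Label matching throughout the package is
case-insensitive after trimming and whitespace collapsing; the original
casing of the first occurrence is preserved for display.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

__all__ = [
    "CldError",
    "ParseError",
    "SynonymMapError",
    "Variable",
    "Edge",
    "CausalDiagram",
    "SynonymMap",
    "normalize_label",
    "label_key",
    "slugify",
]

_WS = re.compile(r"\s+")


class CldError(ValueError):
    """Base class for all validation and parse errors in this package."""


class ParseError(CldError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: object = None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class SynonymMapError(CldError):
    """A synonym map is not functional (one raw label, two canonical labels)."""


def normalize_label(label: str) -> str:
    """Trim and collapse internal whitespace; casing is preserved."""
    return _WS.sub(" ", str(label).strip())


def label_key(label: str) -> str:
    """Case-insensitive matching key for a label."""
    return normalize_label(label).lower()


def slugify(label: str) -> str:
    """Stable variable id derived from a label: lowercase, spaces to underscores."""
    return label_key(label).replace(" ", "_")


@dataclass(frozen=True, order=True)
class Variable:
    """A named driver of the problem under consideration."""

    id: str
    label: str

    def __post_init__(self) -> None:
        if not self.id:
            raise CldError("variable id must be non-empty")
        if not normalize_label(self.label):
            raise CldError(f"variable {self.id!r} has an empty label")


@dataclass(frozen=True, order=True)
class Edge:
    """A signed causal claim from ``source`` to ``target``.

    ``polarity`` is +1 for a positive (same-direction) causal relationship
    and -1 for an inverse one.
    """

    source: str
    target: str
    polarity: int

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise CldError(
                f"edge {self.source!r}->{self.target!r}: polarity must be +1 or -1, "
                f"got {self.polarity!r}"
            )
        if not self.source or not self.target:
            raise CldError("edge endpoints must be non-empty variable ids")

    @property
    def key(self) -> Tuple[str, str]:
        """The ordered (source, target) pair, ignoring polarity."""
        return (self.source, self.target)

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


@dataclass
class CausalDiagram:
    """One participant's signed directed graph of problem drivers.

    Invariants: every edge endpoint refers to a declared variable; the edge
    set contains no duplicate ``(source, target, polarity)`` triples (it is
    a :class:`set`).  Self-loops are permitted on input — participants may
    draw them — but path-based centralities exclude them later.
    """

    diagram_id: str
    problem: str = ""
    variables: Dict[str, Variable] = field(default_factory=dict)
    edges: Set[Edge] = field(default_factory=set)

    # -- construction -------------------------------------------------

    def add_variable(self, label: str, id: Optional[str] = None) -> Variable:
        """Declare a variable; re-declaring the same id returns the original.

        The first label seen for an id wins (its casing is kept for display).
        """
        vid = id if id is not None else slugify(label)
        existing = self.variables.get(vid)
        if existing is not None:
            return existing
        var = Variable(id=vid, label=normalize_label(label))
        self.variables[vid] = var
        return var

    def add_edge(self, source: str, target: str, polarity: int) -> Edge:
        for endpoint in (source, target):
            if endpoint not in self.variables:
                raise CldError(
                    f"diagram {self.diagram_id!r}: edge endpoint {endpoint!r} "
                    "is not a declared variable"
                )
        edge = Edge(source=source, target=target, polarity=int(polarity))
        if edge.is_self_loop:
            warnings.warn(
                f"diagram {self.diagram_id!r}: self-loop on {source!r} retained "
                "(excluded from path-based centralities)",
                stacklevel=2,
            )
        self.edges.add(edge)
        return edge

    # -- views ---------------------------------------------------------

    @property
    def variable_ids(self) -> Tuple[str, ...]:
        """Variable ids in the deterministic (sorted) order used everywhere."""
        return tuple(sorted(self.variables))

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def label_of(self, vid: str) -> str:
        return self.variables[vid].label

    def sorted_edges(self) -> Tuple[Edge, ...]:
        return tuple(sorted(self.edges))

    # -- validation & comparison --------------------------------------

    def validate(self) -> "CausalDiagram":
        """Check referential integrity; returns self for chaining."""
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.variables:
                    raise CldError(
                        f"diagram {self.diagram_id!r}: edge endpoint {endpoint!r} "
                        "is not a declared variable"
                    )
        return self

    def same_structure(self, other: "CausalDiagram") -> bool:
        """Structural equality: same variables and edges, ignoring metadata."""
        return self.variables == other.variables and self.edges == other.edges

    def copy(self, diagram_id: Optional[str] = None) -> "CausalDiagram":
        return CausalDiagram(
            diagram_id=self.diagram_id if diagram_id is None else diagram_id,
            problem=self.problem,
            variables=dict(self.variables),
            edges=set(self.edges),
        )


class SynonymMap:
    """A functional mapping from raw variable labels to canonical labels.

    Raw labels are matched case-insensitively after whitespace normalisation.
    Identity rows (a canonical label mapping to itself) are allowed.  Labels
    absent from the map pass through unchanged.
    """

    def __init__(self, entries: Mapping[str, str] | Iterable[Tuple[str, str]] = ()):
        pairs = entries.items() if isinstance(entries, Mapping) else entries
        self._entries: Dict[str, str] = {}
        for raw, canonical in pairs:
            key = label_key(raw)
            canonical = normalize_label(canonical)
            if not key or not canonical:
                raise SynonymMapError(
                    f"synonym map entry {raw!r} -> {canonical!r} has an empty label"
                )
            prior = self._entries.get(key)
            if prior is not None and label_key(prior) != label_key(canonical):
                raise SynonymMapError(
                    f"raw label {raw!r} maps to both {prior!r} and {canonical!r}"
                )
            self._entries[key] = canonical

    def canonical(self, label: str) -> str:
        """Canonical label for ``label`` (the label itself if unmapped)."""
        return self._entries.get(label_key(label), normalize_label(label))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return label_key(label) in self._entries

    def items(self) -> Iterable[Tuple[str, str]]:
        return sorted(self._entries.items())

    def __repr__(self) -> str:  # pragma: no cover
        return f"SynonymMap({len(self._entries)} entries)"
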