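"""Readers and writers for diagrams, synonym maps and survey files.

On-disk formats
---------------
* ``csv_edgelist`` — header ``source,target,polarity``; polarity tokens
  ``+``, ``-``, ``+1``, ``-1``; UTF-8.  Source/target cells hold labels;
  ids are derived by slugging.  Being an edge list, the format cannot
  carry variables that have no edges (JSON can).
* ``json`` — ``{"diagram_id", "problem", "variables": [{"id","label"}],
  "edges": [{"source","target","polarity"}]}``.
* ``graphml`` / ``dot`` — export only; polarity carried as an edge
  attribute, DOT additionally styles edges solid (+1) / dashed (-1), the
  drawing convention for causal diagrams.
* synonym map CSV — header ``raw_label,canonical_label``.
* survey CSV — header ``respondent_id,candidate_id,item,score``.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .model import CausalDiagram, Edge, ParseError, SynonymMap, slugify

__all__ = [
    "read_diagram",
    "write_diagram",
    "to_adjacency",
    "read_synonym_map",
    "write_synonym_map",
    "read_survey",
    "write_survey",
]

_POLARITY_TOKENS = {"+": 1, "+1": 1, "1": 1, "-": -1, "-1": -1, "−": -1, "−1": -1}

_SUFFIX_FORMAT = {
    ".json": "json",
    ".csv": "csv_edgelist",
    ".graphml": "graphml",
    ".dot": "dot",
    ".gv": "dot",
}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ParseError(f"cannot infer diagram format from suffix {path.suffix!r}", path)


def parse_polarity(token: str) -> int:
    tok = str(token).strip()
    if tok not in _POLARITY_TOKENS:
        raise ValueError(f"unknown polarity token {token!r} (expected +, -, +1 or -1)")
    return _POLARITY_TOKENS[tok]


def read_diagram(path, format: Optional[str] = None) -> CausalDiagram:
    """Read a causal diagram from ``path`` (format inferred from the suffix).

    Variables referenced only in edges are auto-declared with label = id.
    Duplicate (source, target, polarity) rows are deduplicated with a warning.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv_edgelist":
        return _read_csv_edgelist(path)
    raise ParseError(f"unsupported read format {fmt!r}", path)


def _read_json(path: Path) -> CausalDiagram:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc.msg}", path, exc.lineno) from exc
    if not isinstance(payload, dict):
        raise ParseError("top-level JSON value must be an object", path)
    d = CausalDiagram(
        diagram_id=str(payload.get("diagram_id", path.stem)),
        problem=str(payload.get("problem", "")),
    )
    for entry in payload.get("variables", []):
        try:
            d.add_variable(label=entry["label"], id=entry.get("id"))
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed variable entry {entry!r}", path) from exc
    for entry in payload.get("edges", []):
        try:
            source, target = str(entry["source"]), str(entry["target"])
            polarity = int(entry["polarity"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed edge entry {entry!r}", path) from exc
        for endpoint in (source, target):
            if endpoint not in d.variables:
                d.add_variable(label=endpoint, id=endpoint)
        _add_edge_dedup(d, source, target, polarity, path)
    return d.validate()


def _read_csv_edgelist(path: Path) -> CausalDiagram:
    d = CausalDiagram(diagram_id=path.stem)
    with path.open(newline="", encoding="utf-8-sig") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file (expected header source,target,polarity)", path, 1)
        if [h.strip().lower() for h in header[:3]] != ["source", "target", "polarity"]:
            raise ParseError(
                f"expected header source,target,polarity, got {','.join(header)!r}", path, 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise ParseError(f"expected 3 fields, got {len(row)}", path, lineno)
            source_label, target_label, tok = row[0], row[1], row[2]
            if not source_label.strip() or not target_label.strip():
                raise ParseError("empty source or target label", path, lineno)
            try:
                polarity = parse_polarity(tok)
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from exc
            source = d.add_variable(source_label).id
            target = d.add_variable(target_label).id
            _add_edge_dedup(d, source, target, polarity, path, lineno)
    return d.validate()


def _add_edge_dedup(d: CausalDiagram, source: str, target: str, polarity: int,
                    path: Path, lineno: Optional[int] = None) -> None:
    edge = Edge(source=source, target=target, polarity=polarity)
    if edge in d.edges:
        where = f"{path}" + (f":{lineno}" if lineno else "")
        warnings.warn(f"duplicate edge {source}->{target} ({polarity:+d}) deduplicated [{where}]",
                      stacklevel=3)
        return
    d.add_edge(source, target, polarity)


# ---------------------------------------------------------------------------
# writing


def write_diagram(d: CausalDiagram, path, format: Optional[str] = None) -> None:
    """Write ``d`` to ``path`` as json, csv_edgelist, graphml or dot."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(json.dumps(diagram_to_dict(d), indent=2) + "\n", encoding="utf-8")
    elif fmt == "csv_edgelist":
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["source", "target", "polarity"])
            for e in d.sorted_edges():
                writer.writerow([d.label_of(e.source), d.label_of(e.target), f"{e.polarity:+d}"])
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(d), path)
    elif fmt == "dot":
        path.write_text(to_dot(d), encoding="utf-8")
    else:
        raise ParseError(f"unsupported write format {fmt!r}", path)


def diagram_to_dict(d: CausalDiagram) -> dict:
    return {
        "diagram_id": d.diagram_id,
        "problem": d.problem,
        "variables": [
            {"id": v.id, "label": v.label} for v in sorted(d.variables.values())
        ],
        "edges": [
            {"source": e.source, "target": e.target, "polarity": e.polarity}
            for e in d.sorted_edges()
        ],
    }


def to_networkx(d: CausalDiagram) -> nx.DiGraph:
    """Directed graph with node attr ``label`` and edge attr ``polarity``.

    A pair carrying both polarities keeps the positive one in this simple-
    graph view (merged diagrams have already resolved such conflicts).
    """
    g = nx.DiGraph(diagram_id=d.diagram_id, problem=d.problem)
    for vid in d.variable_ids:
        g.add_node(vid, label=d.label_of(vid))
    for e in d.sorted_edges():
        g.add_edge(e.source, e.target, polarity=e.polarity)
    return g


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(d: CausalDiagram, positions: Optional[Dict[str, Tuple[float, float]]] = None) -> str:
    """Graphviz DOT text; +1 edges solid, -1 edges dashed.

    If ``positions`` is given, nodes carry pinned ``pos`` attributes (inches)
    so ``neato -n`` reproduces a computed layout.
    """
    lines = [f"digraph {_dot_quote(d.diagram_id)} {{"]
    for vid in d.variable_ids:
        attrs = [f"label={_dot_quote(d.label_of(vid))}"]
        if positions is not None and vid in positions:
            x, y = positions[vid]
            attrs.append(f'pos="{x:.4f},{y:.4f}!"')
        lines.append(f"  {_dot_quote(vid)} [{', '.join(attrs)}];")
    for e in d.sorted_edges():
        style = "solid" if e.polarity > 0 else "dashed"
        lines.append(
            f"  {_dot_quote(e.source)} -> {_dot_quote(e.target)} "
            f"[style={style}, polarity={e.polarity}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# adjacency


def to_adjacency(d: CausalDiagram, mode: str = "absolute") -> Tuple[np.ndarray, List[str]]:
    """Square adjacency matrix and the (sorted-id) variable ordering used.

    Entry (i, j) is the edge polarity in ``signed`` mode, or 1 in
    ``absolute`` mode, when the edge i->j exists; 0 otherwise.  If a pair
    carries both polarities (possible only in a raw, unmerged diagram) the
    signed entries sum to 0 for that cell.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    ordering = list(d.variable_ids)
    index = {vid: i for i, vid in enumerate(ordering)}
    a = np.zeros((len(ordering), len(ordering)), dtype=float)
    for e in d.edges:
        if mode == "signed":
            a[index[e.source], index[e.target]] += e.polarity
        else:
            a[index[e.source], index[e.target]] = 1.0
    return a, ordering


# ---------------------------------------------------------------------------
# synonym maps and surveys


def read_synonym_map(path) -> SynonymMap:
    """Read a ``raw_label,canonical_label`` CSV into a :class:`SynonymMap`."""
    path = Path(path)
    pairs: List[Tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8-sig") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty synonym map file", path, 1)
        if [h.strip().lower() for h in header[:2]] != ["raw_label", "canonical_label"]:
            raise ParseError(
                f"expected header raw_label,canonical_label, got {','.join(header)!r}",
                path, 1,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ParseError(f"expected 2 fields, got {len(row)}", path, lineno)
            pairs.append((row[0], row[1]))
    return SynonymMap(pairs)


def write_synonym_map(m: SynonymMap, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["raw_label", "canonical_label"])
        for raw, canonical in m.items():
            writer.writerow([raw, canonical])


def read_survey(path) -> pd.DataFrame:
    """Read Likert validation responses; columns
    ``respondent_id,candidate_id,item,score``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"respondent_id": str, "candidate_id": str, "item": str})
    expected = ["respondent_id", "candidate_id", "item", "score"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"survey file missing columns {missing}", path)
    return df[expected]


def write_survey(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
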