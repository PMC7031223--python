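"""One-call orchestration: merge -> rank -> prune -> validate.

Reads a directory of participant diagrams (JSON or CSV edge lists), an
optional synonym map and an optional survey file; writes every stage
artifact under an output directory and returns a :class:`PipelineReport`
whose counts match the on-disk artifacts.  Deterministic for fixed
inputs and seed (the analysis itself is deterministic; the seed feeds
any stochastic stage, e.g. a layout request).
"""

from __future__ import annotations

import csv
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import io as cio
from .merge import MergedDiagram, merge_diagrams, write_merged
from .model import CausalDiagram, CldError, SynonymMap, label_key
from .prune import CandidateConfig, CandidateDiagram, generate_candidates
from .ranking import TECHNIQUES, dematel, rank
from .validate import ValidationSummary, summarize_survey

log = logging.getLogger("cldsynth")

__all__ = ["PipelineReport", "run_pipeline", "read_diagram_dir"]


@dataclass
class PipelineReport:
    """Counts and outcomes of one pipeline run."""

    diagrams_read: int
    variables_raw: int          #: distinct raw labels before standardisation
    variables_merged: int       #: canonical variables in the merged diagram
    merged_edges: int
    polarity_conflicts: int
    candidates: List[dict] = field(default_factory=list)
    preferred: Optional[str] = None
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "diagrams_read": self.diagrams_read,
            "variables_raw": self.variables_raw,
            "variables_merged": self.variables_merged,
            "merged_edges": self.merged_edges,
            "polarity_conflicts": self.polarity_conflicts,
            "candidates": self.candidates,
            "preferred": self.preferred,
            "warnings": self.warnings,
        }


def read_diagram_dir(diagrams_dir) -> List[CausalDiagram]:
    """All ``*.json`` and ``*.csv`` diagrams in a directory, sorted by name."""
    diagrams_dir = Path(diagrams_dir)
    paths = sorted(
        p for p in diagrams_dir.iterdir()
        if p.suffix.lower() in (".json", ".csv")
    )
    if not paths:
        raise CldError(f"no diagram files (*.json, *.csv) found in {diagrams_dir}")
    return [cio.read_diagram(p) for p in paths]


def _write_scores(path: Path, result) -> None:
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["variable", "score", "rank"])
        for position, vid in enumerate(result.ordering, start=1):
            writer.writerow([vid, f"{result.scores[vid]:.6g}", position])


def run_pipeline(
    diagrams_dir,
    synonyms_path=None,
    survey_path=None,
    out_dir="pipeline_out",
    seed: int = 17,
    candidate_config: CandidateConfig = CandidateConfig(),
    conflict_policy: str = "majority_positive_tiebreak",
    rounding: str = "full",
) -> PipelineReport:
    """Run merge -> rank -> prune (-> validate) and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    captured: List[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        t0 = time.perf_counter()
        diagrams = read_diagram_dir(diagrams_dir)
        raw_labels = {
            label_key(v.label) for d in diagrams for v in d.variables.values()
        }
        synonym_map = (
            cio.read_synonym_map(synonyms_path) if synonyms_path else SynonymMap()
        )
        md = merge_diagrams(diagrams, synonym_map, policy=conflict_policy)
        write_merged(md, out / "merged.json")
        cio.write_diagram(md.diagram, out / "merged.dot")
        log.info(
            "merge: %d diagrams, %d raw labels -> %d canonical variables, "
            "%d edges (%.2fs)",
            len(diagrams), len(raw_labels), md.n_variables, md.n_edges,
            time.perf_counter() - t0,
        )

        t0 = time.perf_counter()
        dem = dematel(md)
        for technique in candidate_config.techniques:
            result = dem.ranking() if technique == "dematel" else rank(md, technique)
            _write_scores(out / f"scores_{technique}.csv", result)
        detail = pd.DataFrame(
            {
                "variable": dem.ordering,
                "D": dem.D, "R": dem.R,
                "prominence": dem.prominence, "relation": dem.relation,
            }
        )
        detail.to_csv(out / "dematel_detail.csv", index=False)
        log.info("rank: %d techniques (%.2fs)",
                 len(candidate_config.techniques), time.perf_counter() - t0)

        t0 = time.perf_counter()
        candidates = generate_candidates(md, candidate_config, dematel_result=dem)
        candidate_dir = out / "candidates"
        candidate_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for c in candidates:
            stem = c.candidate_id.replace(" ", "").replace("(", "_").replace(")", "") \
                                 .replace("[", "").replace("]", "").lower()
            cio.write_diagram(c.diagram, candidate_dir / f"{stem}.json")
            cio.write_diagram(c.diagram, candidate_dir / f"{stem}.dot")
            manifest_rows.append(
                {
                    "candidate_id": c.candidate_id,
                    "technique": c.technique,
                    "k": c.k,
                    "n_edges": c.n_edges,
                    "n_components": len(c.components),
                    "viable": c.viable,
                }
            )
        pd.DataFrame(manifest_rows).to_csv(out / "candidates_manifest.csv", index=False)
        log.info("prune: %d candidates (%.2fs)",
                 len(candidates), time.perf_counter() - t0)

        preferred = None
        if survey_path is not None:
            t0 = time.perf_counter()
            survey = cio.read_survey(survey_path)
            summary = summarize_survey(survey, rounding=rounding)
            frame = summary.item_means.copy()
            frame["diff_from_best"] = summary.diffs.round(6)
            frame["preferred"] = [
                cid == summary.preferred for cid in frame.index
            ]
            frame.sort_values("diff_from_best").to_csv(out / "validation_summary.csv")
            preferred = summary.preferred
            log.info("validate: preferred %r (%.2fs)",
                     preferred, time.perf_counter() - t0)

        captured = [str(w.message) for w in caught]

    report = PipelineReport(
        diagrams_read=len(diagrams),
        variables_raw=len(raw_labels),
        variables_merged=md.n_variables,
        merged_edges=md.n_edges,
        polarity_conflicts=len(md.conflicts),
        candidates=manifest_rows,
        preferred=preferred,
        warnings=captured,
    )
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    return report
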