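"""Synthetic multi-participant mapping studies.

Emulates the structure of a small community study of the drivers of
sugar-sweetened-beverage consumption: ~13 participants independently
draw signed causal diagrams over a shared (but inconsistently named)
vocabulary, yielding ~48 canonical variables after synonym
standardisation, and 9 respondents later score eleven candidate diagrams
on four Likert items.

The generator plants a *core* of high-connectivity variables: each core
variable enters a participant's diagram with high probability and edges
preferentially attach to core variables, so the core ends up central
under any reasonable ranking — giving the pipeline a recoverable ground
truth.  A fraction of the vocabulary has one deterministic label variant
("X" -> "amount of X" etc.); participants use the variant with some
probability, and the ground-truth synonym map undoes exactly those
variants.  No attempt is made to model richer drawing behaviour (ordering
effects, fatigue, idiosyncratic vocabularies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import CausalDiagram, CldError, SynonymMap, label_key, slugify
from .prune import CandidateDiagram
from .validate import ITEMS

__all__ = ["StudyConfig", "SyntheticStudy", "generate_study", "generate_survey", "VOCABULARY"]

#: Plausible community-nominated drivers of sugar-sweetened-beverage
#: consumption (synthetic labels, not study data).
VOCABULARY = [
    "soft drink price", "advertising exposure", "supermarket promotions",
    "availability at home", "availability at school", "vending machines",
    "fast food outlets nearby", "sports club sponsorship", "peer pressure",
    "social media marketing", "celebrity endorsement", "brand loyalty",
    "taste preference", "sugar craving", "habit strength",
    "thirst on hot days", "water fountain access", "tap water trust",
    "milk price", "juice perceived as healthy", "energy drink culture",
    "caffeine dependence", "parental modelling", "family drinking rules",
    "pocket money", "household income", "food insecurity",
    "discount pricing", "serving size", "upsizing offers",
    "checkout placement", "convenience store density", "school canteen policy",
    "sports drink marketing", "screen time", "gaming culture",
    "sleep deprivation", "stress levels", "emotional comfort eating",
    "nutrition knowledge", "label literacy", "health campaign reach",
    "dental health awareness", "weight concern", "diet drink substitution",
    "community sport participation", "active transport", "hot climate",
    "cultural celebrations", "fundraising sausage sizzles", "workplace norms",
    "cafe culture", "meal deal bundling", "loyalty card rewards",
    "television viewing", "online delivery apps", "late night trading",
    "youth disposable income", "flavour innovation", "packaging appeal",
    "refillable bottle use", "school water policy", "gp advice",
    "public health messaging", "sugar tax debate", "portion norms",
    "supermarket layout", "impulse buying", "road side billboards",
    "community role models", "team sport hydration habits", "festival stalls",
]

_VARIANT_TEMPLATES = (
    "amount of {}",
    "{} level",
    "level of {}",
    "{} in the community",
    "local {}",
)


@dataclass(frozen=True)
class StudyConfig:
    """Shape of a synthetic study; defaults mirror the small community
    study the pipeline was designed around."""

    n_participants: int = 13
    #: 54 shared labels with the default per-diagram draw yields ~48
    #: canonical variables in a typical merged diagram
    vocab_size: int = 54
    #: fraction of the vocabulary with one label variant; also the
    #: probability a participant uses the variant instead of the canonical
    synonym_rate: float = 0.3
    core_size: int = 8
    vars_per_diagram: Tuple[int, int] = (8, 14)
    edges_per_diagram: Tuple[int, int] = (10, 18)
    negative_polarity_prob: float = 0.2
    n_respondents: int = 9
    seed: int = 0
    problem: str = "sugar-sweetened beverage consumption"
    #: sampling weight of a core vs a peripheral variable (0.8 vs 0.2)
    core_weight: float = 0.8
    periphery_weight: float = 0.2

    def validate(self) -> "StudyConfig":
        if min(self.n_participants, self.vocab_size, self.core_size,
               self.n_respondents) < 1:
            raise CldError("all counts must be positive")
        if not (0.0 <= self.synonym_rate <= 1.0
                and 0.0 <= self.negative_polarity_prob <= 1.0):
            raise CldError("probabilities must lie in [0, 1]")
        if self.core_size > self.vocab_size:
            raise CldError("core_size cannot exceed vocab_size")
        lo, hi = self.vars_per_diagram
        if not (1 <= lo <= hi <= self.vocab_size):
            raise CldError(f"vars_per_diagram range {self.vars_per_diagram} infeasible")
        elo, ehi = self.edges_per_diagram
        if not (0 <= elo <= ehi):
            raise CldError(f"edges_per_diagram range {self.edges_per_diagram} infeasible")
        if ehi > hi * (hi - 1):
            raise CldError(
                f"edges_per_diagram upper bound {ehi} exceeds the complete-digraph "
                f"bound {hi * (hi - 1)} for {hi} variables"
            )
        return self


@dataclass(frozen=True)
class SyntheticStudy:
    """Diagrams plus the generator's ground-truth bookkeeping."""

    config: StudyConfig
    diagrams: Tuple[CausalDiagram, ...]
    synonym_map: SynonymMap
    #: canonical ids of the planted high-connectivity core
    core_ids: FrozenSet[str]
    #: canonical labels actually used by at least one participant
    canonical_labels_used: FrozenSet[str]


def _vocabulary(cfg: StudyConfig) -> List[str]:
    if cfg.vocab_size <= len(VOCABULARY):
        return VOCABULARY[: cfg.vocab_size]
    extra = [f"community factor {i:02d}" for i in range(cfg.vocab_size - len(VOCABULARY))]
    return VOCABULARY + extra


def _variant_for(label: str, taken: set) -> str:
    for template in _VARIANT_TEMPLATES:
        candidate = template.format(label)
        if label_key(candidate) not in taken:
            return candidate
    return f"{label} (alt)"  # pragma: no cover - templates collide only if crafted


def generate_study(cfg: StudyConfig = StudyConfig()) -> SyntheticStudy:
    """Draw one full synthetic study, deterministically for a fixed seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vocab = _vocabulary(cfg)
    taken = {label_key(v) for v in vocab}

    core_idx = set(rng.choice(cfg.vocab_size, size=cfg.core_size, replace=False).tolist())
    weights = np.array(
        [cfg.core_weight if i in core_idx else cfg.periphery_weight
         for i in range(cfg.vocab_size)]
    )

    n_variants = int(round(cfg.synonym_rate * cfg.vocab_size))
    variant_idx = rng.choice(cfg.vocab_size, size=n_variants, replace=False)
    variants: Dict[int, str] = {}
    for i in variant_idx.tolist():
        variants[i] = _variant_for(vocab[i], taken)
        taken.add(label_key(variants[i]))
    synonym_map = SynonymMap(
        [(variants[i], vocab[i]) for i in sorted(variants)]
    )

    diagrams: List[CausalDiagram] = []
    used_canonical: set = set()
    for p in range(cfg.n_participants):
        d = CausalDiagram(
            diagram_id=f"participant_{p + 1:02d}", problem=cfg.problem
        )
        lo, hi = cfg.vars_per_diagram
        n_vars = int(rng.integers(lo, hi + 1))
        probs = weights / weights.sum()
        chosen = rng.choice(cfg.vocab_size, size=n_vars, replace=False, p=probs)
        chosen = sorted(chosen.tolist())
        local_weight = {}
        id_of = {}
        for i in chosen:
            label = vocab[i]
            used_canonical.add(label)
            if i in variants and rng.random() < cfg.synonym_rate:
                label = variants[i]
            id_of[i] = d.add_variable(label).id
            local_weight[i] = cfg.core_weight if i in core_idx else cfg.periphery_weight

        elo, ehi = cfg.edges_per_diagram
        max_edges = n_vars * (n_vars - 1)
        n_edges = min(int(rng.integers(elo, ehi + 1)), max_edges)
        w = np.array([local_weight[i] for i in chosen])
        pair_weights = np.outer(w, w).astype(float)
        np.fill_diagonal(pair_weights, 0.0)
        flat = pair_weights.ravel()
        picked = rng.choice(flat.size, size=n_edges, replace=False, p=flat / flat.sum())
        for idx in sorted(picked.tolist()):
            si, ti = divmod(idx, n_vars)
            polarity = -1 if rng.random() < cfg.negative_polarity_prob else +1
            d.add_edge(id_of[chosen[si]], id_of[chosen[ti]], polarity)
        diagrams.append(d.validate())

    return SyntheticStudy(
        config=cfg,
        diagrams=tuple(diagrams),
        synonym_map=synonym_map,
        core_ids=frozenset(slugify(vocab[i]) for i in sorted(core_idx)),
        canonical_labels_used=frozenset(used_canonical),
    )


def generate_survey(
    candidates: Sequence[CandidateDiagram],
    cfg: StudyConfig = StudyConfig(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Likert responses for every (respondent, candidate, item).

    Each candidate gets a latent quality driven by how coherently it hangs
    together — the fraction of its variables inside the largest weak
    component, plus a small bonus when it passes the viability report —
    so fragmented candidates score visibly worse, as human respondents do
    to diagrams that no longer read as causal maps.  Item-level offsets
    make "can see my own contribution" systematically harder to earn than
    the other items on a heavily pruned diagram.  Integer scores are the
    latent quality plus Gaussian noise, rounded and clamped to [-5, +5].
    """
    if not candidates:
        raise CldError("generate_survey needs at least one candidate")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    item_offsets = {"ease": 0.3, "describe": 0.1, "own_contribution": -1.6, "useful": 0.0}
    rows = []
    for c in candidates:
        coverage = c.components[0] / c.n_variables if c.components else 0.0
        quality = 6.0 * coverage - 2.5 + (0.5 if c.viable else 0.0)
        for r in range(cfg.n_respondents):
            respondent = f"respondent_{r + 1:02d}"
            for item in ITEMS:
                raw = quality + item_offsets[item] + rng.normal(scale=1.2)
                score = int(np.clip(round(raw), -5, 5))
                rows.append((respondent, c.candidate_id, item, score))
    return pd.DataFrame(
        rows, columns=["respondent_id", "candidate_id", "item", "score"]
    )
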