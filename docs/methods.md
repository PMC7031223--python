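# Methods

This note documents the models, parameters and numerical choices behind
`cldsynth`, and what its synthetic tests do and do not demonstrate about
real participatory-mapping data.

## The pipeline's object of study

The unit of input is a signed directed graph drawn by one participant:
variables are free-text labels for perceived drivers of a complex
problem, and an edge carries polarity +1 (same-direction influence) or
−1 (inverse influence).  All analysis operates on the *merged diagram* —
the union of every participant's variables and connections after label
standardisation — and treats connections as unweighted: an edge is
present or absent, and the number of participants proposing it
(`edge_support`) is provenance metadata only.  This follows the practice
of analysing participant maps as plain diagrams rather than weighted
influence networks; support-weighted adjacency would be a
straightforward extension but changes every downstream score.

## Standardisation and merging

Label matching is case-insensitive after trimming and collapsing
internal whitespace; variable ids are label slugs (lowercase, spaces to
underscores), so identical constructs align across diagrams and across
read/write round trips.  Synonym resolution is deliberately *not*
automated: the package consumes a curated raw→canonical map (expert
consensus is how such maps are actually produced; string-similarity or
embedding matching is out of scope).  A raw label mapping to two
canonical labels is a hard error.

Polarity conflicts — an ordered pair proposed with both signs — have no
standard treatment, so the package records every conflict and resolves
it by policy.  The default, majority with a positive tie-break, is
order-invariant and keeps exactly one polarity per ordered pair, which
downstream adjacency construction requires.  `keep_first` and `drop`
are available for sensitivity analysis; `keep_first` is intentionally
order-dependent.

Self-loops are accepted on input (participants do draw them) with a
warning, and excluded from path-based centralities, where they carry no
information.  Parallel opposite edges (`A -> B` and `B -> A`) are
distinct directed claims and both are retained.

## Ranking techniques

Directionality is not standardised in the participatory-mapping
literature, so each metric uses the convention that keeps it informative
on sparse, weakly connected merged diagrams:

* **degree** — in-degree + out-degree, each directed edge counted once.
* **betweenness** — directed shortest-path betweenness, endpoints
  excluded, unnormalised (absolute path counts are comparable within one
  diagram; normalisation would only rescale the ranking).
* **closeness** — *harmonic* closeness on the directed graph:
  `score(v) = Σ_{u≠v} 1/dist(v,u)`, unreachable pairs contributing 0.
  Classic closeness is undefined or degenerate on disconnected digraphs,
  which merged diagrams frequently are; the harmonic form degrades
  gracefully and makes the "closeness selects mutually unreachable
  variables" failure mode visible rather than undefined.
* **eigenvector centrality** — on the undirected projection, because the
  directed variant is supported only on the terminal strongly connected
  component and is identically zero elsewhere, which is useless for
  mostly acyclic cause-effect maps.  Computed by power iteration from a
  uniform start (deterministic; degenerate dominant eigenspaces on
  disconnected graphs resolve to the symmetric solution), rescaled to
  unit maximum.  Non-convergence within the iteration cap (default
  1000) raises an error naming the cap.
* **DEMATEL** — see below; the ranking score is prominence.

All orderings break score ties by variable id ascending, so every stage
is deterministic.

## DEMATEL

The direct-influence matrix `A` is the binary absolute adjacency of the
merged diagram: inverse-polarity connections enter with unit weight,
because the total-relation algebra is undefined for negative influence
entries, and their stored signs are restored on any diagram induced from
the ranking.  The canonical normalisation and total-relation form is
used:

    s = max(max_i Σ_j A_ij, max_j Σ_i A_ij)
    X = A / s
    T = X (I − X)^{-1} = Σ_{k≥1} X^k

`D = Σ_j T_ij` is influence dispatched, `R = Σ_i T_ij` influence
received; prominence `D + R` and relation `D − R` are the two axes on
which results are reported.  Identities used as test oracles: for
acyclic diagrams `X` is nilpotent and `T` equals the finite Neumann sum
exactly; `Σ D = Σ R = Σ T` always; transposing the diagram swaps `D`
and `R`, preserves prominence and negates relation.

For strongly cyclic binary maps the spectral radius of `X` can reach 1
(e.g. a pure 2-cycle), making `I − X` singular.  If its condition number
exceeds 1e12 the scalar `s` is inflated once by `1 + ε` (ε = 1e-6) with
a warning; if that fails, a numerical error is raised.  An edgeless
diagram takes the convention `s = 0 ⇒ T = 0`.

### Cluster cut point

Beyond the predetermined 10- and 15-variable cuts, DEMATEL admits an
analysis-driven cut: prominence is sorted descending and the cut is
placed just above the largest consecutive gap, searched over positions
2..max_k (default `max_k = min(15, n−1)`; published cut points of this
kind do not exceed 15).  Ties go to the smallest k.  The gap must exceed
a noise floor of 1e-9 relative to the profile's magnitude — numerically
flat profiles (e.g. vertex-transitive cycles, where prominence is equal
by symmetry up to rounding in the near-singular inverse) correctly
signal "no cluster" instead of being split on floating-point noise.

## Candidates and viability

A candidate is the plain induced subgraph of the merged diagram on a
ranking's top-k set: no edge re-routing or transitive closure, so a
ranking that selects mutually unconnected variables yields a visibly
fragmented candidate — which is exactly the information the viability
report conveys.  `viable` is true when the largest weakly connected
component covers at least 80% of the retained variables *and* the
candidate has at least k−1 edges (the minimum for weak connectivity).
Both thresholds are configurable; viability is reporting only and never
filters — all candidates proceed to the validation survey.  When the
cluster cut coincides with a fixed cut the candidate is still produced,
suffixed `[cluster]` to keep ids unique, and flagged with a warning.

## Survey validation

Respondents score each candidate on four items on the eleven-point
scale −5..+5.  Means are computed per (candidate, item); a missing
(candidate, item) cell is a hard error by default (means over partial
data silently distort the selection rule), with `allow_missing` opt-in.
The selection rule sums, over items, each candidate's distance from the
per-item best mean; the minimiser wins, ties broken by smaller cut size
then lexicographic id and reported as ties.  `rounding="table"` rounds
means to one decimal before differencing, reproducing arithmetic done on
a printed one-decimal summary table; full precision is the default.
The package carries one such printed table (eleven candidates × four
items, `WORKED_EXAMPLE_MEANS`) as a worked example; feeding it through
the rule yields deficits 0.3–18.5 and selects `DEMATEL (8)`.

## Layout

`circle_layout` spaces variables uniformly on the unit circle in id
order — the connection-circle exercise's starting view.  Crossings are
counted over unordered edge pairs not sharing an endpoint, using the
strict orientation test (proper interior intersections only; touchings
and collinear overlaps do not count), and the count is invariant under
rotation and uniform scaling.

`untangle` runs spring-force iterations with a crossing-monotone
acceptance rule.  Forces per iteration: attraction along each edge
toward ideal length 1.0 (gain 0.5), repulsion `0.15/d²` between all
pairs, attraction multiplied by 2.0 on edges inside a simple cycle
(length ≤ 6, enumerated exhaustively) and applied at half that strength
between non-adjacent cycle members, so feedback loops contract into
compact clusters.  The global update `x + step·F` (step 0.1) is accepted
only if the crossing count does not increase; otherwise the step is
halved up to 5 times and then the iteration is skipped.  This makes
"crossings never increase" a structural guarantee rather than an
empirical tendency, at the cost of sometimes stalling in a local
minimum.  The seed only jitters exactly coincident points apart; runs
are deterministic given seed and inputs.  The mechanism (spring model,
acceptance rule, constants) is this package's own design for the two
published objectives — minimise arrow crossover, emphasise feedback
loops — not a reconstruction of any particular tool's internals.

## Synthetic studies

`generate_study` emulates the scale of a small community study: 13
participants over a 54-label vocabulary, 8–14 variables and 10–18 edges
per diagram, 20% inverse polarity, 9 survey respondents.  A planted core
of 8 variables is sampled into each diagram with weight 0.8 against 0.2
for the periphery, and edge endpoints are drawn with the same weights
(so core-core connections dominate), making the core recoverable by any
reasonable importance ranking.  30% of the vocabulary has one
deterministic label variant (templated paraphrase, e.g. "amount of X");
participants use the variant with the same probability, and the
ground-truth synonym map undoes exactly those variants.  With these
defaults the merged diagram holds ≈48 canonical variables (mean 48.35
over seeds 0–19), matching the scale the pipeline is designed around.

The survey generator gives each candidate a latent quality increasing in
the fraction of its variables inside its largest component (plus a small
viability bonus), item offsets that make "can see my own contribution"
systematically hardest to earn on a heavily pruned diagram, and unit-ish
Gaussian noise, rounded and clamped to the scale.

What passing the synthetic end-to-end tests shows: the pipeline's
plumbing is correct, rankings recover genuinely central structure, the
cluster cut finds a planted prominence gap, and fragmented candidates
lose the simulated survey.  What it does not show: anything about human
label semantics (variants are templates, not language), about real
participants' drawing styles or responses, or about studies whose core
is contested rather than planted.  On the default configuration the
generated maps are dense enough that even closeness candidates are often
connected; the characteristic "non-viable closeness candidate" pattern
appears on sparser configurations.

End-to-end regression guards were frozen from 20-seed oracle runs of
the generator at its defaults: mean DEMATEL top-8 core recovery ≥ 6 of
8, and median detected cluster cut within [6, 10].

## Problem sizes

Default test and acceptance runs use merged diagrams of ~50 variables /
~150 edges, 8-node random digraphs for exhaustive path-enumeration
oracles (200 instances), 100 seeded untangling runs, and 20 synthetic
replicates for the end-to-end guards; the whole suite completes in a few
seconds on one core.

## Known limitations

* Synonym mapping is input, not inference; mis-mapped labels propagate.
* Binary adjacency discards edge support; a heavily contested connection
  counts the same as a unanimous one.
* The untangler optimises a proxy (crossings, loop compactness), not
  readability; it has no label-overlap handling or curved-edge routing.
* DEMATEL on near-singular cyclic maps depends on the ε rescale; the
  resulting prominence magnitudes are then scale-dominated and only the
  ordering is meaningful.
* Survey aggregation is plain means on an ordinal scale, by design
  (matching field practice), with no inter-rater reliability modelling.
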