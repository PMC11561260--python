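# Methods

## The plasticity measure

The package treats differentiation as a continuum: a cell's identity is a
probability vector over discrete reference types, and commitment between
two fates A and B is summarized by the per-cell fate bias

    bias(A vs B) = Prob.A / (Prob.A + Prob.B),

the conditional weight of A given that the cell's fate is one of the pair.
The bias lives in [0, 1]; 0.5 is the equal-commitment (hybrid) point, and
the symmetric complement bias(B vs A) = 1 − bias(A vs B) holds per cell. A
signed variant (Prob.A − Prob.B)/(Prob.A + Prob.B), which places the hybrid
point at 0, is implemented behind `formula="signed"` for audit; the ratio
form is the default because every downstream convention (the [0.4, 0.6]
hybrid window, its [0.35, 0.65] and [0.45, 0.55] sensitivity companions)
is centered at 0.5.

The plasticity of a transition is the proportion of hybrid cells

    P_hc = N / M,

with M the eligible population and N the count of eligible cells whose bias
falls in the closed window. Two eligibility conventions are supported:
reference-labeled members of the pair (the default, appropriate for
atlas-style tables where each (group, window) row is reported per fate
pair), or an explicit cell list (appropriate when scoring one trajectory
edge against its own denominator, as the recovery experiments do). Cells
with Prob.A + Prob.B = 0 carry no information about the pair and are
excluded from M; the constrained deconvolution backend produces exact zeros
for irrelevant types, so this exclusion is well defined rather than
float-noise-driven.

Window endpoints are inclusive. Nested windows therefore give monotone
P_hc by construction, which doubles as a structural sanity check on every
reported table.

Ambiguity of a single type is read from per-group ECDF curves of that
type's probability column; the scalar summary is the fraction of cells
strictly below a 0.5 threshold. Identity stability is read from the
row-normalized overlap (confusion) matrix between reference and predicted
labels; rows sum to 1 exactly, and a diagonal below 0.8 flags a "flexible"
identity.

## Probability provider

All statistics consume only a per-cell probability simplex, so the
annotator is pluggable. External probability tables are ingested from CSV;
rows within 1e-3 of unit sum are renormalized (probability emitters often
round), larger deviations are rejected cell-by-cell.

The built-in classifier shares one feature pipeline: per-cell scaling to a
fixed library size (default 10,000) with log1p, then either one
mean-expression score per GMT gene set or the top-variance genes (default
200) used directly, then z-scoring with training-set statistics. Genes
absent from a query contribute zero, with a warning past 20% missingness.

Two backends:

* **centroid** (default): each cell's standardized feature vector is
  decomposed by non-negative least squares into a convex combination of
  class centroids; the mixture weights are the probabilities. Centroids
  are per-feature medians, followed by one purification pass re-estimating
  each centroid from members with mixture weight ≥ 0.9. The purification
  matters on a continuum: a labeled class contains partially committed
  cells, and a contaminated centroid compresses the probability scale by
  roughly 15%, biasing P_hc downward. The design also carries one free,
  signed, simplex-exempt component along the standardized image of a
  uniform log-expression shift. Per-cell compositional normalization moves
  all log-features of a cell by a common offset that depends on how much
  of the library its active programs absorb; that nuisance direction is
  outside the centroid span, and without it the fit leaks the offset into
  mixture weights near decision boundaries. Mixture deconvolution is the
  appropriate instrument here because a genuinely intermediate cell
  *should* receive intermediate weights — the probability is a composition
  estimate, not a posterior bet on a hard label.
* **multinomial**: L2-regularized multinomial logistic regression
  (scikit-learn) on the same features. On well-separated references its
  posteriors saturate near 0/1 — a faithful hard annotator and a useful
  cross-check, but a poor hybrid meter, which is why it is not the
  default.

Training reports a stratified 80/20 held-out hard-label accuracy in the
model's log (diagnostic only; the shipped model is refit on all cells) and
is deterministic under a fixed seed. Models serialize to a single pickle
archive with bitwise-stable bytes for identical inputs.

## Synthetic branching data

The simulator emulates a Lin⁻-like differentiation continuum on a
five-type tree (HSC → GMP → Pro_NE, HSC → MEP → Pro_Mast). Each type owns
a disjoint program of `genes_per_program` genes. A cell on edge
parent → child has a latent fate-mixture weight `w` (child weight); its
log mean expression adds `effect × (1 − w)` to the parent program and
`effect × w` to the child program on top of lognormal per-gene baselines,
means are renormalized per cell, and counts are gamma–Poisson (negative
binomial) with lognormal library sizes. Program activation follows a
logistic switch in pseudotime with the cell placed so that activation
equals `w`; expression is therefore log-linear in the mixture weight,
which makes the planted quantity identifiable by a linear deconvolution.

Hybrid cells (a per-edge Bernoulli fraction `hybrid_fraction_target`) draw
`w` uniformly in the truth window [0.4, 0.6]. Committed cells draw `w`
from a U-shaped Beta(0.2, 0.2) truncated outside a guard band
[0.35, 0.65]: committed states behave as metastable attractors near the
endpoints, and the gap keeps truth-committed and truth-hybrid cells
distinguishable under count noise — without it, no finite-noise pipeline
can report exactly zero hybrids when none are planted. Reference labels
follow the truth deterministically (weight ≥ 0.5 → downstream type).

Defaults — 250 genes, 40 genes per program, effect size 2.0 (≈ 7.4-fold
activation of a full program, typical of strong lineage markers),
library-size mean 8,000 with lognormal σ 0.35 (deeply sequenced
droplet-style libraries), NB size 8 (moderate overdispersion) — were fixed
once while calibrating the measurement chain end to end and are the
conditions all recovery statements refer to. With them, a 2,000-cell
dataset recovers planted per-edge hybrid fractions of 5/10/20% within
about one percentage point (mean over 20 seeds), and the no-hybrid,
effect-4.0 limit yields exactly 0% on every pair.

What the simulator deliberately does not model: real marker-gene identity
or overlap between programs, doublets, ambient RNA, batch effects,
cell-cycle structure, or more than two flanking fates per cell. Passing
recovery tests therefore demonstrates that the statistic and its
probability provider are faithful under a clean branching continuum — not
that any particular biological dataset has a given plasticity level.

## Knockouts and reversal calls

A knockout zeroes the raw-count columns of a gene set's members
(case-sensitive symbol match by default; case-insensitive behind a flag),
*before* normalization, so library-size factors are recomputed from
post-knockout totals — zeroing after normalization would leak pre-knockout
totals into every surviving gene. The trained model is never refit;
re-prediction uses identical parameters, so differences are attributable
to the zeroed genes alone. Knockouts are idempotent, and a knockout that
changes no nonzero entry reproduces baseline outputs bit-exactly.

The reversal call compares a perturbed P_hc against a control and a
disease value: inside the closed control–disease band is
`partially_reversed` (boundary equality included, so float-level ties do
not flip calls), overshooting past the control value is `reversed`,
anything else is `not_reversed`. The same rule applies to ECDF levels at
the 0.5 threshold.

## Numerical choices and edge cases

* Simplex tolerance 1e-6 inside containers; import renormalization
  tolerance 1e-3; Matrix Market written at 17 significant digits (bit
  round-trip for counts, 1e-9-relative for reals).
* NNLS sum-to-one is imposed by a weighted constraint row (weight 1e3)
  and then enforced exactly by renormalization; an all-zero solution
  falls back to the uniform vector.
* Argmax label assignment breaks ties toward the first label in sorted
  vocabulary order.
* All-zero cells cannot be library-normalized and are dropped with a
  warning; all-zero gene sets are rejected at parse time; duplicate GMT
  set names are fatal.
* One global seed fans out to stage seeds via SHA-256 of the stage name
  into a `SeedSequence` spawn key (all seeds < 2^31), so stages are
  independently reproducible.
* Problem sizes used by the shipped experiments — 100 × (200 cells, 5
  classes) oracle trials, 1,600-cell separation runs, 20 × 2,000-cell
  recovery runs per planted fraction — were chosen to put Monte-Carlo
  error well inside the stated tolerances while a full run of the suite
  and the acceptance script stays in the tens of seconds.

## Known limitations

* The probability scale of the centroid backend is anchored by purified
  centroids; with fewer than ~20 confident cells per class the
  purification pass is skipped and P_hc values compress somewhat.
* Gene-set score features average within sets; strongly anti-correlated
  genes inside one set dilute the score.
* The statistic is descriptive. No multiple-testing machinery is applied
  across pairs or windows, by design.
* Embeddings (UMAP/FA) are not computed; bias maps render only over
  user-supplied coordinates.
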