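# Methods

## The model

`phylobias` segments a four-species alignment into regions that did or
did not experience GC-biased gene conversion (gBGC) on the lineage of a
designated *target* genome, while jointly accounting for evolutionary
conservation. It is a hidden Markov model whose four states — neutral
(*n*), neutral+gBGC (*b*), conserved (*c*), conserved+gBGC (*cb*) — emit
alignment columns under four phylogenetic substitution models.

**Neutral process.** HKY85 on a fixed rooted tree
`(((human, chimpanzee), orangutan), rhesus)`. The instantaneous rate from
base *i* to *j* is κ·π_j for transitions and π_j for transversions, and
the matrix is normalized to one expected substitution per unit branch
length at stationarity. Branch-length *proportions* are fixed (see
defaults below); a single scale factor λ adapts them to the local
mutation rate.

**Conservation.** As in conserved-element HMMs, the conserved states
scale every branch by ρ < 1. Negative selection is assumed uniform
across lineages; positive selection is ignored (it is rare at these
evolutionary distances and does not produce a sustained W→S bias, the
signal used here).

**gBGC.** Modeled as a selection-like force of population-scaled
strength B (the GC-disparity) acting only on the terminal branch to the
target, because gene conversion tracts are transient and effectively
lineage-specific. Rates of weak→strong changes ({A,T}→{C,G}) are
multiplied by the relative fixation factor

    f(B) = B / (1 − e^(−B)),      f(0) = 1,   f(B)/f(−B) = e^B,

and strong→weak rates by f(−B). W→W and S→S rates are untouched. The
modified matrix is **not** renormalized: gBGC genuinely accelerates W→S
substitution on that branch, and renormalizing would erase the signal.
Equilibrium frequencies of the other branches and the root stay at the
neutral π (gBGC is treated as transient, not as a shifted equilibrium).
f is evaluated via `expm1` with a series expansion near 0, so B → 0
degrades gracefully to the neutral model.

**Transitions.** The 4×4 state-transition matrix is the Kronecker
product of an independent conservation chain [[1−ν, ν], [μ, 1−μ]] and a
gBGC chain [[1−β, β], [α, 1−α]]; e.g. P(n→cb) = ν·β. The initial
distribution is the stationary distribution of this chain (the model is
silent about the first column; stationarity is the natural prior).

## Inference

Per alignment block:

1. **Neutral fit.** π is set to observed base frequencies over
   non-missing symbols; (κ, λ) maximize the summed column
   log-likelihoods under the neutral model, by L-BFGS-B on
   (log κ, log λ) from (κ=4, λ=1), converged when the log-likelihood
   improves by < 1e-6. This empirical-Bayes step assumes conserved
   elements and gBGC tracts are too sparse to distort block-level
   averages.
2. **Emissions.** Column log-likelihoods by Felsenstein pruning with
   missing data ('N', absent species, non-target gaps) marginalized.
   Columns are deduplicated into ≤ 5⁴ = 625 patterns, so emission cost
   is independent of block length.
3. **EM for β.** Baum–Welch restricted to the single free transition
   parameter: β̂ = E[# transitions from {n,c} into {b,cb}] /
   E[# transitions out of {n,c}], iterated until the log-likelihood
   gain is < 1e-4 (max 100 iterations). The initial distribution is
   held at the stationary distribution of the *starting* parameters
   during EM; with it tied to the current β the closed-form M-step is
   not exact and the likelihood can oscillate at the 1e-4 level. A β̂
   collapsing below 1e-7 is clamped to 1e-8 with a warning (no gBGC
   signal in the block).
4. **Decoding.** Scaled forward–backward (per-column scaling constants;
   no underflow at any block length; the scan kernels are numba-compiled
   so multi-megabase blocks decode in well under a second). Tracts are
   maximal runs with P(b) + P(cb) ≥ 0.5, threshold inclusive. Viterbi is
   available for diagnostics but never used for calling: probability
   mass spread over many near-equivalent paths around uncertain tract
   endpoints makes max-product decoding miss tracts whose marginal
   posterior is near one.

Filtered columns leave holes in the reference coordinates; a run of
above-threshold columns is kept intact across holes up to 1 kb (the same
limit used for block-boundary placement) and broken at larger jumps.
Optionally, called tracts within 1 kb of each other can be merged
(`merge_gap`), which counteracts over-fragmentation when analyzing tract
spacing; it is off by default since fragmentation is rare in practice.

## Parameter defaults

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| ρ | conserved branch scale | 0.31 | inherited from conserved-element HMM practice |
| μ | conserved→neutral | 0.022 | idem |
| ν | neutral→conserved | 0.0095 | idem |
| α | gBGC→non-gBGC | 0.001 | prior expected tract length 1/α = 1 kb, matching empirical mammalian conversion-tract sizes |
| B | GC-disparity for prediction | 3 | tuning parameter; {2,3,4,5,10} exposed, coverage decreases as B grows |
| β | non-gBGC→gBGC | EM per block | floor 1e-8 |
| κ, π, λ | neutral HKY | fit per block | init κ=4, λ=1 |
| block size | re-partitioning target | 10 Mb | boundaries restricted to runs ≥ 1 kb uninformative about the target lineage |

Default branch proportions (substitutions/site): human 0.0066,
chimpanzee 0.0073, their ancestor 0.0244, orangutan 0.0189, the
great-ape ancestor 0.0138, rhesus 0.0365 — primate estimates of the
kind obtained from fourfold-degenerate sites; λ rescales them jointly,
so only their ratios matter. The default π (A,C,G,T) =
(0.295, 0.205, 0.205, 0.295) reflects ~41% genomic GC.

## Numerical choices

* Transition matrices P(t) = exp(Qt) via eigendecomposition with a
  scipy `expm` fallback when the decomposition is numerically defective;
  rows are stochastic to ≤ 1e-12.
* Forward–backward uses linear-space scaling with per-column constants
  (max-shifted emissions), exact to enumeration at 1e-10.
* Mann–Whitney U is computed from midranks; ties count one half. The
  DAF-skew confidence interval is a percentile bootstrap over SNPs
  (1000 resamples) — conservative, given that the statistic's sampling
  distribution under dependence within tracts is unknown.
* GC bins for control-region matching are 100 equal-width bins on
  [0,1]; all-N regions are excluded from matching with a warning;
  after 1e5 rejections the GC constraint relaxes to the nearest
  populated bin (warned). Empirical p-values report "< 1/N" when no
  control is as extreme as the observation.

## The simulator

Two modes, all randomness from one seeded generator:

* **De novo**: a root sequence is drawn from π and evolved down every
  branch with per-column category models — all eight combinations of
  conservation (× ρ), CpG (× an 8-fold λ multiplier) and gBGC (target
  branch, strength B_sim). Conserved elements are planted as
  geometric-length runs (default 5% of columns, mean 100 bp); gBGC
  tracts are fixed-length, non-overlapping, uniformly placed until the
  configured coverage (default 0.1%) is reached.
* **Conditional resimulation**: any alignment (real or de novo) keeps
  its non-target rows bit-exact, and only the target row is redrawn
  column-by-column from P(target | other leaves) under the column's
  assigned category model. This reproduces the evaluation protocol in
  which only the target genome is synthetic, so rate variation, missing
  data and composition of the scaffold are preserved.

What the simulator does **not** emulate: indels and alignment error
(columns are generated aligned), neighbor-dependent CpG hypermutation
(CpG is a flat rate multiplier), regional mutation-rate variation beyond
the planted categories, and non-equilibrium base composition. Passing
simulation tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to every
artifact of real alignments — the conditional mode narrows that gap when
given real scaffolds.

## Accuracy, and a known limitation

On ~2 Mb simulations with 3200 bp tracts planted at 1% coverage under
strong gBGC (B_sim = 5) and predicted with B = 3, base-level TPR and PPV
are both above 80% (typically 96–99% and 82–92% across seeds; see
`scripts/acceptance.py`). Power degrades for shorter or weaker tracts,
and most residual error is boundary overhang around true tracts.

The caller's base-level false positive rate on *fully null* simulations
(no gBGC anywhere) is of order 1e-4 to 1e-3, not zero: in megabases of
neutral sequence, random clusters of weak→strong substitutions on the
target lineage occasionally accumulate (e.g. 8 W→S and 0 S→W changes
within a few hundred bp) and are indistinguishable, by construction,
from genuine short conversion tracts; per-block EM then fits a small
positive β to them. Such marginal calls carry low posterior scores
(just above 0.5), so downstream analyses can filter on score when a
stricter error rate is needed. Users comparing tract sets against
genomic features should rely on the matched-control machinery rather
than on raw counts for exactly this reason.

Other limitations: a single target lineage per run; B is a tuning
constant, not estimated; no rate variation across sites beyond the
conserved/CpG categories; the four-taxon tree is assumed correct and
fixed.
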