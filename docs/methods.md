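# Methods

This note documents the generative models, the estimators, the numerical
choices, and the limits of what the test suite shows. It states no result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Community assembly model

All simulated samples follow dispersal-limited neutral sampling. Given a
niche's eligible species (those whose traits cover the niche's required
set), a metacommunity composition *p* over those species, migration rate
*m* ∈ (0, 1] and depth *N*, each sample's relative abundances are drawn
from a Dirichlet with concentration vector *N·m·q*, where *q* ∝ *p·w* and
*w* are fitness multipliers; reads are then multinomial at depth *N*. The
marginal of one taxon is Beta(*N·m·q*, *N·m·(1−q)*) — the same law the
neutral fitter assumes, which closes the loop between generator and test
(checked in `test_assembly.py` and the parameter-recovery acceptance
test).

Selective mechanisms extend this core:

* **Advantage** (scenario 6): a multiplicative fitness weight *w* shifts a
  taxon's expected share to *p·w*/Σ*p·w* **and** multiplies its
  establishment concentration by *w* (drawn by a stick-breaking Beta;
  exactly the Dirichlet when *w* = 1). The concentration term is essential:
  a pure mean shift is absorbed by the Dirichlet's aggregation property and
  is mathematically indistinguishable from a more abundant neutral taxon,
  so no occupancy-based test could ever detect it. Biologically the boost
  reads as reliable establishment: a superior competitor is present more
  consistently than a neutral taxon of the same mean abundance.
* **Stabilized establishment** (the "selective" scenario): a concentration
  multiplier without the mean shift, applied clade-wise.
* **Environmental filtering**: optional per-sample Gaussian weights around
  species optima along a scalar gradient (available in `NicheSpec`; the
  shipped scenarios do not use it by default — see below).

Degenerate draws are guarded: gamma underflow at extreme dispersal
limitation (all concentrations ≪ 1) falls back to a single winner chosen
proportionally to concentration.

## Scenarios and their study conditions

Two regimes are generated, with all defaults fixed here:

**Four-species cartoons** (scenarios 1–5, default): the family
((SA,SB)G1,(SC,SD)G2)F with branch lengths calibrated so that expected
within-genus sequence identity is 0.985 and cross-genus 0.945 — genera
cluster at the 0.97 rung and the family at 0.92. Case A carries conserved
traits only (rectangle on the root branch, triangle on G1, diamond on G2);
case B adds four distinct star traits sharing one function, convergent on
SA/SC/SD and horizontally transferred to SB from the SC lineage. Defaults:
30 samples, depth 300, m = 5·10⁻⁴. The strong dispersal limitation is
deliberate: per-species occupancy sits near 0.4–0.7, so no single species
— and, over 30 samples, no genus in scenario 1 — is present everywhere,
which is precisely what makes the PCG ladder resolve the niche-defining
clade rather than individual sequences. A realized fixture whose sequence
identities violate the calibration margins is redrawn deterministically.

**Regional-pool datasets** (default for scenarios 6, "selective",
"niche_construction"; available for 1–5 via `pool_size`): a 256-tip Yule
tree in which a clade of roughly 40% of the pool is the focal family
(children = genera G1, G2), rescaled so the family spans ~0.94 expected
identity. Metacommunity abundances are lognormal (σ = 1.5). Defaults: 60
samples (120 for scenario 4 — the same effort per niche), depth 1000,
m = 0.05. Scenario 6 places a 5× advantage on a guild of 8 taxa drawn from
the rare-to-intermediate prevalence band (quantiles 0.15–0.45 of *p*),
where an occupancy excess is statistically visible — abundant taxa sit at
occupancy 1 under neutrality already, so selection on them is
undetectable in principle. One advantaged tip is renamed SA;
`n_advantaged=1` reproduces the single-species textbook case. The
"selective" scenario assigns three establishment tiers (×1/×10/×100) to
balanced subclades of the family at m = 0.01 with a narrower metacommunity
(σ = 0.8, selection evens out regional abundances): no single migration
rate fits the three occupancy–abundance curves at once, so neutrality is
rejected community-wide while the taxa remain one clade (clustered NTI).
"niche_construction" couples two maximally spread 8-taxon guilds with a
tight Beta(100,100) split and small lognormal wobble.

A deliberate property of "niche_construction": its abundance distributions
are *compatible with a neutral fit* (the pipeline reads it as a neutral
nonphylo-niche). This mirrors the known theoretical result that
syntrophic, self-structuring communities can masquerade as neutral; the
truth label keeps the generating mechanism (`other_interactions`) and is
flagged ambiguous, and the tests do not claim the pipeline can recover it.
An earlier design of "selective" used a smooth environmental gradient; it
was abandoned because gradient data violate the discrete-class assumption
of the β-diversity stage (the class finder carves the gradient into
locally-neutral slices), which is exactly the continuous-gradient caveat
the class-based strategy carries.

## Neutral-model fitting

`predicted_occupancy(p, N, m, d)` is the Beta survival function above a
relative-abundance detection limit *d*. `sloan_fit` by default predicts
detection as the exact probability of at least one read in a multinomial
sample of the Beta abundance, 1 − B(*a*, *b*+*N*)/B(*a*, *b*), evaluated
with log-Beta functions. The sharp-threshold approximation at *d* = 1/*N*
systematically underestimates occupancy near the detection scale and
biases *m̂* upward by 15–25% under the package's own generative law; the
exact form makes recovery unbiased (median |*m̂* − *m*| ≈ 0.002–0.01 at
200 samples × depth 2000; see the acceptance output). An explicit
`detection_limit` switches to the survival-function form.

*m* is fitted by bounded scalar minimization of the squared
occupancy–frequency error on log *m* ∈ [ln 10⁻⁴, 0] (xatol 10⁻⁶);
boundary estimates are flagged. Fit quality is the generalized R² (1 −
SSE/SST). Per-taxon intervals are the wider of (i) the central binomial
interval at the predicted occupancy and (ii) a normal interval whose
variance adds the delta-method propagation of the sampling noise in the
estimated mean abundance — without (ii), rare taxa generate ~10% false
departure calls purely from noise in *p̂* and the verdict's type-I error
is far off its nominal rate. Verdict thresholds (5% / 50% departing) and
the CI level (0.95) are configurable constants.

## Community classes

Bray–Curtis (on relative abundances) or Jaccard (presence/absence)
dissimilarities; average-linkage hierarchy; k ∈ [2, 8] chosen by maximum
mean silhouette; the winning partition is accepted only if (i) mean
silhouette ≥ 0.25 and (ii) a label-permutation test of mean
between-class minus mean within-class distance rejects at α = 0.05 with
p = (1 + #{perm ≥ obs})/(1 + n_perm); otherwise k = 1. The silhouette
floor guards the permutation test against post-selection inflation: labels
chosen by clustering the very matrix under test are not exchangeable, and
on small, highly noisy matrices (n ≲ 16) the selected partition can reach
silhouettes near 0.3 by chance. The floor is the standard cluster-strength
guard; with realistic community tables at the shipped sample sizes the
false-class rate is small (checked on neutral data), but callers analyzing
fewer than ~20 samples should treat any k > 1 with caution. Fewer than 4
samples returns an explicit "undecidable" status.

## Dispersion

MNTD uses patristic distances from the input tree (cached). The NTI null
draws equally many tips uniformly without replacement from the pool —
unweighted, as is standard for a presence-based index; with ≤ `n_null`
distinct subsets the null is enumerated exhaustively (`method="auto"`).
z-scores use the population SD of the null; a degenerate null (taxa =
pool) yields the call "undefined". Calls use |z| ≥ 2. The between-
community variant averages directed nearest-taxon distances both ways
(shared taxa contribute zero) against a null that redraws both
memberships. The pipeline's decision table consumes the *within* (class-
level) NTI: the between variant conflates membership overlap with
phylogenetic turnover when two samples share many taxa, which would
mislabel nonphylo-niches; it is still computed and reported as supporting
evidence for the homogeneous/heterogeneous selection axis. The pool
defaults to all tips of the input tree (the regional pool); when the tree
spans exactly the observed taxa, a class covering every taxon is
undecidable by construction.

## PCG search

Complete linkage guarantees the identity threshold is a within-cluster
floor. Partitions are computed on lexicographically sorted ids, making
them invariant to input order; the ladder (1.00, 0.99, 0.97, 0.95, 0.92,
0.90) and the presence rule (summed member counts ≥ 1 in every sample)
are flags. Sequences must be pre-aligned and equal-length; alignment is
out of scope. Per-class searches run independently per class; classes
with one sample are computed but flagged unreliable.

## Seeds and determinism

Every generator and every randomized test statistic derives its stream
from one integer seed through named `SeedSequence` children, so any
artifact is reproducible from (function, seed) alone; identical inputs and
seeds give byte-identical pipeline reports.

## What passing tests do and do not show

The simulator realizes the assumptions the detectors test for — Beta
marginals, independent samples, equal depths, a correct tree, aligned
full-length markers. Real surveys add compositional biases, depth
variation, sequencing error, chimeras and tree uncertainty that are not
modeled; recovery rates here are upper bounds on field performance, and
the fixture calibration (identity rungs at 0.97/0.92) stands in for the
messier identity structure of real 16S data. Scenario truth labels are
statements about the generating mechanism; for "niche_construction" (and
scenario 5 in its four-species form) the mechanism is not identifiable
from the data by design, and the labels carry an `ambiguous` flag.
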