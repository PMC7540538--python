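# Methods

`lakeassembly` quantifies how much of the temporal turnover in a
bacterioplankton community is attributable to deterministic (selection-driven)
versus stochastic (dispersal- and drift-driven) assembly.  This note
describes the statistical models the package implements, the synthetic data
it validates itself on, and the numerical and design choices a user should
know about.

## The inference framework

**Input data.** A sample × ASV count table, a rooted phylogeny with branch
lengths covering the ASVs, and per-sample metadata (date, lake, sampling
scale, environmental measurements).  QC removes taxa labelled Archaea,
chloroplast or unclassified, then samples with fewer than 10,000 reads
(taxa first: the taxon screen acts on reads before sample totals are
judged).  A median-of-ratios size-factor normalization with a shifted log2
transform is provided for ordination use; all dissimilarity-based statistics
operate on relative abundances of the raw QC'd counts.

**Phylogenetic turnover (βMNTD, βNTI).** For communities *k*, *l* with
relative abundances *f* and patristic distances *d(i, j)*,

    βMNTD(k,l) = ½ [ Σ_i f_ik · min_{j∈l} d(i,j) + Σ_j f_jl · min_{i∈k} d(j,i) ]

βNTI is the z-score of the observed βMNTD against 999 randomizations of the
tip labels among the taxa of the analysed table (abundances untouched).  The
null standard deviation uses the population (ddof = 0) convention; with 999
draws the distinction from the n−1 convention is negligible, but the
convention is fixed so that a z-score can be reproduced from the null draws
exactly.  Pairs whose null distribution has spread at floating-point noise
level (e.g. identical memberships, star-shaped trees) are flagged undefined
and excluded from summaries, with the count reported.  βNTI is invariant to
a uniform rescaling of branch lengths.

**Taxonomic turnover (RCbray).** The Raup–Crick standardization of
Bray–Curtis: null communities preserve each sample's observed richness and
read total; taxa are drawn without replacement with probability proportional
to their occurrence frequency across the table, each drawn taxon receives
one individual, and the remaining reads are allocated multinomially in
proportion to mean relative abundance.  RCbray = ((#{null < obs} + ½ ties) /
n_null − 0.5) × 2 ∈ [−1, 1].  Ties get half weight.  Null streams are
derived per pair from the master seed by counter-based spawning, so results
do not depend on iteration order.

**Classification.** Each pair receives exactly one process label:
βNTI > +2 → variable selection; βNTI < −2 → homogeneous selection;
otherwise RCbray > +0.95 → dispersal limitation, RCbray < −0.95 →
homogenizing dispersal, |RCbray| ≤ 0.95 → drift (undominated).  The
published inequalities are strict on both sides and leave the exact
boundary values unassigned; here boundaries fall to the stochastic /
undominated side, isolated in one function (`categorize_pair`) and tested
explicitly.  Pairs are formed within lake × scale groups only; summary
fractions are percentages per group and sum to 100.

**Precondition screen.** The framework is only interpretable if habitat
association carries phylogenetic signal.  Each taxon's abundance-weighted
environmental optimum (Σ count·env / Σ count over occupied samples) is
screened with a Moran's I correlogram over equal-frequency patristic
distance classes (10 by default), with a two-sided 95% envelope from 999
tip permutations; signal is declared when I exceeds the envelope in the
shortest class.  The pipeline warns but continues when signal is absent.

**Supporting multivariate stages.** Bray–Curtis (with a percent-similarity
view), non-metric MDS (SMACOF with isotonic regression, Kruskal stress-1,
best of 20 random starts plus a classical-scaling start), ANOSIM on ranked
dissimilarities, a betadisper-style homogeneity-of-dispersion test (PCoA
embedding with imaginary-axis correction for negative eigenvalues, distances
to group spatial centroids, permutation F-test), least-squares environmental
vector fitting, the exhaustive BIOENV subset search (z-scored variables,
Spearman rank correlation of Euclidean distances with community
dissimilarities, combinatorial guard at 20 variables), distance-based
Moran's eigenvector maps on sampling dates (largest nearest-neighbour-gap
truncation, distances beyond t* replaced by 4 t*, positive-eigenvalue
eigenvectors, unit-scaled), and PCA of the jointly standardized abiotic
variables plus temporal eigenvectors (ice cover encoded 0/1).  All
permutation p-values follow (1 + #{null ≥ obs}) / (n_perm + 1).

**Drivers of selection.** The βNTI matrix, min–max normalized to [0, 1]
(undefined pairs imputed at the null mean, z = 0), is embedded by principal
coordinates on its positive axes and regressed on the PCA axes
(distance-based RDA).  Forward selection proceeds by adjusted-R² gain with
three safeguards: a global permutation pre-test of the full model (selection
only starts if the full model is significant — this controls the
best-of-many-candidates inflation of per-step tests), a per-step permutation
test at the chosen α, and a double-stopping cap at the full model's adjusted
R².  The cap halts *further* additions once crossed; the crossing step
itself is kept, because a submodel's adjusted R² can legitimately exceed the
full model's (whose extra terms cost degrees of freedom) while the step has
already passed its permutation gate.  A selected axis is reported as a
*measured* driver when any measured variable loads ≥ 0.4 (|correlation
loading|) on it, otherwise as an *unmeasured* one; the threshold is
configurable and echoed in the output.

**Diversity profile.** Per sample: observed richness, singleton/doubleton
counts, bias-corrected Chao1 (S_obs + F1(F1−1)/(2(F2+1)), defined when
F2 = 0), the asymptotic Shannon diversity as a Hill number (low-bias entropy
estimator combining the observed harmonic-sum term with a
singleton/doubleton-driven correction for undetected taxa, exponentiated),
the unbiased inverse-Simpson Hill number 1/Σ[x(x−1)/(n(n−1))], and Faith's
PD (branch length of the subtree spanning the present taxa and the root,
computed on presence/absence of raw QC'd counts).  Only asymptotic point
estimates are provided — no rarefaction/extrapolation curves or bootstrap
intervals.

## The synthetic-data generator

The generator is first-class, tested code: it produces communities whose
true assembly process is known, so every inference stage can be validated
end to end.  It emulates the structure of a two-year, two-lake 16S ASV
study (monthly to daily spacing, ≥10,000 reads per sample, thousands of
ASVs in the field — scaled to 30–300 taxa here) but not its raw reads:
sequences, chimeras and sequencing error are out of scope, and the simulator
is not fitted to any real lake.

**Phylogeny.** Pure-birth (Yule) trees scaled to unit depth.  Scenario
trees additionally carry one or two *recent radiations* — shallow Yule
subtrees (depth 0.12) grafted in place of a tip, holding ~25% of the taxa
each.  Radiations reproduce the bursts of near-identical variants that real
ASV phylogenies contain, and they matter quantitatively: on a plain
64-tip Yule tree even a perfectly clade-confined community cannot push
βNTI much below −2, because no sufficiently tight clade exists.

**Niche traits.** Environmental optima evolve on the tree.  The basic
generator is Brownian motion (rate σ² = 25 on the unit-depth tree → tip
SD ≈ 5 °C for the thermal optimum); scenarios use an early-burst clock
(rate ∝ e^{rt}, r = −4) so divergence concentrates between deep clades and
close relatives keep near-identical optima — the clade-level habitat
conservatism the framework presupposes.  Scenarios evolve three independent
traits (temperature plus two latent niche axes): with a one-dimensional
trait, distant clades converge on similar values so often that no niche
window isolates a clade at desk scale; convergence in three dimensions at
once is rare.

**Metacommunity.** A log-series rank-abundance curve (shape θ) with ranks
shuffled across taxa, optionally tempered by an evenness exponent
(π ∝ (θ^r/r)^γ; γ = 1 is the pure log-series, γ = 0 a uniform pool).

**Local dynamics.** Wright–Fisher: per sampling step, a fraction *m* of the
local community (N individuals) is replaced from the selection-weighted
metacommunity, followed by neutral multinomial resampling generations;
observed counts are a multinomial read-depth draw (10,000 reads), keeping
row sums exact.  Two useful limits hold exactly: with w = 0 and m = 1 the
expected composition equals the metacommunity, and as w → ∞ under a constant
environment only the taxon nearest the optimum persists.

**Regimes.** The five presets encode the process definitions generatively:

| regime | mechanism | expected signature |
|---|---|---|
| homogeneous selection | constant environment at the niche centroid of the most coherent 10–24-tip clade (radiation); niche breadth = the clade's own RMS trait radius; small establishment bottleneck (N = 12) churns membership within the clade | βNTI ≪ −2 |
| variable selection | square-wave seasonality alternating between the two most niche-separated disjoint clades | βNTI ≫ +2 across seasons |
| homogenizing dispersal | w = 0, m = 0.95, very large local community, no drift generations: dispersal overwhelms drift | RCbray < −0.95, \|βNTI\| < 2 |
| dispersal limitation | w = 0, m = 0: each sample an independent lineage founded by 100 colonists from a uniform pool, then expanded — founder lotteries make proportions jagged while richness stays near the pool size | RCbray > +0.95, \|βNTI\| < 2 |
| drift | w = 0, small community (N = 1,000), weak immigration (m = 0.05), 50 drift generations per step | \|βNTI\| < 2, \|RCbray\| ≤ 0.95 |

Two of these mechanisms deserve justification because they are not the
naive parameterizations.  First, homogenizing dispersal with drift
generations retained produces RCbray ≈ 0, not < −0.95: local drift noise
raises observed turnover to the null's level, contradicting the regime's
own definition (dispersal high enough to overwhelm other processes), so the
preset removes the drift generations.  Second, pure neutral drift of
isolated lineages never exceeds the Raup–Crick null at any drift intensity:
as lineages diverge they converge exactly onto the null's own
random-membership distribution (and the extinction of rare taxa inflates
the null's spread in step with the observed divergence).  What dispersal
limitation means generatively is *founder-limited colonization* — few
colonists seed each locality — and that is what the preset implements.

Several knobs (local sizes, founder counts, θ, evenness) were set so that,
at the package's test scale of 64 taxa and 20 samples, each regime is
recovered as the modal process class; across 18 development seeds the
recovery rate is 16/18 for homogeneous selection, 17/18 for variable
selection and 18/18 for the three stochastic regimes.  The selection
regimes sit near the intrinsic detection ceiling of a 64-taxon pool (a
perfect clade community yields βNTI ≈ −2.5), so occasional seed failures
are expected and are a property of the scale, not of the method.

**What passing tests do and do not show.** The generator demonstrates that
the implementation recovers known processes under idealized conditions:
perfectly conserved multi-trait niches, clean radiations, exact multinomial
sampling and no sequencing error.  Real data differ in pool size (thousands
of ASVs — which makes the null contrasts *stronger*, not weaker),
compositional noise, taxonomically structured artefacts and unmeasured
environmental drivers; recovery rates here do not translate into error
rates on field data.

## Numerical choices and degenerate inputs

* Ties in RCbray nulls count ½; permutation p-values never return 0.
* Undefined βNTI pairs (degenerate nulls) are dropped from classification
  with their count reported; in the driver analysis they are imputed at
  z = 0 before min–max normalization.
* The BIOENV search refuses > 20 variables unless the guard is raised;
  subsets whose distances are constant get an undefined (NaN) correlation
  and rank last.
* PCoA eigenvectors get a deterministic sign (largest-magnitude element
  positive); retained dbMEM eigenvalues must be strictly positive.
* NMDS convergence: stress change < 1e-6, 500 iterations max.
* The db-RDA requires at least two more samples than predictors; the
  pipeline truncates the PCA axes to n − 3 predictors.
* QC drops any sample left without reads by the taxon screen even when
  `min_reads = 0`; sample subsets keep all-zero taxon columns because the
  table's full taxon set defines the null-model pool.
* Size factors fall back to total-count ratios (with a warning) when no
  taxon is present in all samples.

## Problem sizes

Default analysis settings are 999 randomizations for both null models and
999 permutations for every test, as in the study design this package
follows.  The bundled validation suite runs the same statistics at reduced,
documented sizes chosen for desk-scale work: 64-taxon, 20-sample scenarios
for regime recovery, a 200-taxon pool for the homogenizing-dispersal
contract (per-sample richness ≈ 80 of a 200-taxon pool, a realistic
richness-to-pool ratio; at 64 taxa the pool is too small for the RCbray
signature to reach the −0.95 threshold for most pairs even under the
regime's defining conditions), 500 replicates for permutation-test
calibration, and a 24-sample two-lake fixture for pipeline determinism.

## Known limitations

* The framework quantifies five aggregate processes; it does not parse
  sub-classes of selection (competition, trophic interactions) or separate
  historical contingency from dispersal limitation.
* The DESeq2-style normalization here is size factors + shifted log2, not
  the full dispersion-trend variance-stabilizing transform.
* Asymptotic diversity is reported as point estimates only.
* Whether to compute RCbray on raw or transformed counts is not settled in
  the literature this follows; raw counts are used.
* Replicate samples are kept as individual samples, never averaged before
  pairing.
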