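# Methods

## Scope and data model

The package operates on samples × OTUs integer count tables, one per
microbial domain (bacteria, fungi, archaea), together with sample metadata
(disturbance C/P/PL, surface G/N/O/B/I, block, site) and an
environment/function table (pH, conductivity, NH₄-N, NO₃-N, SOC, TN, total
vegetation coverage, wet weight, dry weight). Everything downstream —
diversity, networks, multifunctionality, inference — consumes these three
objects. Raw read processing (merging, chimera removal, OTU picking,
taxonomy assignment) is upstream of the package and out of scope, as are
tree-dependent beta-diversity metrics (UniFrac) and ordination.

## Rarefaction and filtering

Rarefaction subsamples every sample to a common depth without replacement
(multivariate hypergeometric draw), so retained row sums equal the depth
exactly; samples below depth are dropped with a logged warning rather than
upsampled. Dominant-OTU filtering keeps OTUs whose *mean relative abundance
across the samples of the table being networked* is strictly greater than
the threshold (default 10⁻⁴, i.e. 0.01 %). Because networks are built per
sample group, the filter is applied per group after subsetting; note that
filtering per domain and then merging is *not* equivalent to filtering the
merged table, which is why the pipeline fixes the order
subset → filter → merge.

## Diversity

Chao1 uses the classic estimator S_obs + F1²/(2 F2) when doubletons exist
and the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) when F2 = 0
(variants disagree here, so the branch rule is explicit and tested).
Shannon entropy uses the natural log by default (a `base` argument exists;
only relative comparisons matter downstream). Simpson is reported as
Gini-Simpson 1 − Σp², with the raw dominance D behind a flag. Bray-Curtis
is computed on the rarefied counts; community similarity is its complement
to 1, and the group-level similarity summary is the mean ± SD over all
within-group sample pairs (the choice of summary is a convention; the
pairwise mean is the most common one).

## Co-occurrence networks

Correlations are Spearman rank correlations with average ranks for ties,
computed on relative abundances of the rarefied, dominance-filtered table;
after rarefaction row totals are equal, so the rank correlations are
identical on counts — the choice is made explicit rather than load-bearing.
Two-sided p-values use the t-distribution approximation. OTUs with zero
variance across the group's samples have undefined rank correlation and are
excluded with a logged report. An edge requires |ρ| > 0.7 *and* p < 0.05;
both inequalities are strict. No multiple-testing correction is applied by
default — at |ρ| > 0.7 the correlation threshold dominates and the measured
false-edge rate under the null generator is below 10⁻³ — but
Benjamini-Hochberg is available via `correction="BH"`.

Nodes with no surviving edge are dropped from the network by default (node
counts then describe connected OTUs, the convention of interactive network
tools); `keep_isolated=True` retains them. Cross-domain networks delete
every within-domain edge; the operation is idempotent, and intra- plus
inter-domain edge counts partition the original edge set.

Topology: density 2E/N(N−1); average degree 2E/N; mean local clustering
coefficient with degree < 2 nodes contributing 0; average path length and
diameter over connected (ordered) pairs only, so disconnected graphs do not
produce infinities; modularity is Newman's Q of the partition found by
Louvain on the unweighted simple graph with a fixed seed and resolution 1.
Louvain is stochastic, hence the seed is part of the pipeline provenance.
All of these are cross-checked in the test suite against brute-force
triangle counting and all-pairs BFS on small random graphs.

## Ecosystem multifunctionality

EMF(sample) = mean over the seven function variables of
(x − mean)/SD, with sample SD (n−1) and standardization over **all**
samples jointly rather than within groups: the index is used to compare
group means on a common scale, which joint standardization provides (a
per-group flag would destroy comparability and is deliberately absent; the
standardization population is the only genuinely open choice here).
Consequences used as invariants: each Z-column has mean 0 and SD 1, the
grand mean of EMF is 0 to machine precision, the index is invariant to
affine rescaling of any input variable and to permutation of the seven
functions. Missing values are refused by default; column-mean imputation is
available and logged.

## Permutation inference

PERMANOVA uses SS_total = Σ_{i<j} d²ᵢⱼ/n, within-group sums analogously,
and pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)); R² = SS_between/SS_total.
Group labels are permuted unrestrictedly by default; block-restricted
permutation (`strata=`) is available because blocked designs may warrant
it. Mantel correlates the upper-triangle entries (Pearson default,
Spearman by flag) and permutes one matrix's rows and columns jointly. MRM
regresses the unfolded response triangle on predictor triangles with an
intercept by OLS; coefficient p-values come from permuting the response
matrix and refitting, two-sided on |coefficient|; collinear predictors are
flagged and returned as a minimum-norm solution.

Sampled permutation p-values use the add-one convention
p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm), so p ≥ 1/(n_perm+1). For
tiny problems every test also supports `permutations="exhaustive"`: all
distinct label arrangements (PERMANOVA) or all n! sample permutations
(Mantel/MRM) are enumerated and the exact permutation p is reported — e.g.
two perfectly separated groups of three give p = 2/20 = 0.1. Observed and
permuted statistics are computed by the same expression so exhaustive ties
are exact, not float-dependent.

Mann-Whitney U uses the exact distribution for n_x+n_y ≤ 12 without ties
and the tie-corrected normal approximation with continuity correction
otherwise. Enrichment ratios test each OTU by one-way ANOVA on relative
abundance between focal group and control meadow; an OTU counts as
enriched only if p < α *and* its focal mean exceeds the control mean —
plain ANOVA is direction-blind and the quantity of interest is enrichment,
not difference. OTUs absent from both groups are excluded from the
denominator. No multiple-testing correction is applied to the ratios by
default, matching the conventional "(all P < 0.05)" reporting; a BH flag
exists.

Measured calibration (≥1000 null simulations per test, 999 permutations
where applicable, α = 0.05): rejection rates of PERMANOVA, Mantel, MRM
coefficients, ANOVA and Mann-Whitney all fall in [0.03, 0.07]; the
Mann-Whitney rate sits slightly below 0.05 because of the continuity
correction.

## The synthetic generator

The generator emulates the blocked field design: 2 blocks × 5 sites for
each treatment, one meadow quadrat per C site (surface label G, so
surface-level contrasts include the undisturbed meadow) and one quadrat per
surface type per P/PL site — 110 samples by default.

Counts follow a latent Gaussian model chosen so correlation, enrichment and
abundance structure can be controlled independently:

1. Expected log-abundances sit on a deterministic Gaussian quantile ladder
   with SD `base_abundance_shape` (default 1.0) — a log-normal-shaped
   abundance distribution without between-run randomness in who is rare.
2. Each OTU receives a correlated cross-sample latent deviate with SD
   `latent_scale` (default 0.7). Planted correlation blocks share a common
   factor: members load √|ρ| on the factor, giving every within-block pair
   latent correlation ρ (alternating loadings for ρ < 0, since a fully
   negative block of >2 members is not a valid correlation matrix).
3. Independent noise with SD `noise_sd` (default 0.15) is added, plus
   log2-fold-change shifts for planted enriched sets in their target
   metadata groups.
4. Softmax gives the composition; counts are multinomial at a
   negative-binomial library size (mean 10 000, dispersion 20 — depths of
   the order used in amplicon surveys of these soils).

The defaults are the reference condition of the validation suite: with a
ρ = 0.9 block of five mid-ladder OTUs and 50 samples, thresholded-network
recall is ≈ 0.95 and precision 1.0 (20 seeds); with 20 % of OTUs planted at
+2 log₂ fold change and 20 samples per group, the recovered enrichment
ratio is ≈ 0.18–0.19; a +1 SD shift of all seven functions in one group is
detected by group EMF essentially always. `latent_scale` and `noise_sd`
trade off against each other — relative noise attenuates rank correlations
while total log-scale variance sets ANOVA power on the skewed raw-abundance
scale — and the defaults are a single fixed compromise, not per-experiment
dials.

What the generator does *not* emulate: phylogenetic structure, explicit
zero-inflation beyond multinomial sampling zeros, spatial autocorrelation
between sites, and taxon-specific depth biases. Passing recovery tests
therefore show the estimators work under a calibrated compositional
log-normal world, not that field data meet those assumptions. One known
real-world feature the model *does* reproduce: compositional closure — the
largest OTUs show mildly negative rank correlations with everything else,
so null "p < 0.05" fractions run slightly above 5 % even though false
*edges* (which also need |ρ| > 0.7) remain ≈ 0.

Environment variables are intercept + per-surface offset + Gaussian noise;
default offsets plant declining vegetation and C/N pools along
G → N → O → B with rising pH and conductivity, magnitudes chosen to be
plausible for alpine meadow topsoil rather than fitted to anything.

## Pipeline and reproducibility

Stages run in the fixed order synthesize/load → rarefy → diversity →
per-group networks → cross-domain networks → EMF → inference. Every stage
draws from its own RNG stream derived from the master seed by SHA-256
hashing of `"{seed}:{stage}"`, so adding a stage never perturbs earlier
draws; identical config + seed yields byte-identical outputs, verified by
content hashes in the run report. Problem sizes in the validation suite
(e.g. 50-OTU communities, 1000–3000 null simulations, 20 recovery seeds)
are chosen to give decisive margins at desk scale; all thresholds the suite
asserts are stated in the tests themselves.

## Known limitations

- Spearman-threshold networks inherit all caveats of correlation networks
  on compositions; no SparCC/SPIEC-EASI-style compositional correction is
  implemented, deliberately — the target workflow uses plain Spearman.
- PERMANOVA assumes exchangeability under the null; with strong dispersion
  differences between groups its p-values conflate location and dispersion.
- The Louvain partition is a heuristic; modularity values are reproducible
  only jointly with the recorded community seed.
- BIOM support covers the v1 JSON schema (dense and sparse), not BIOM 2 HDF5.
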