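# Methods

## Scope and data model

`riverepi` analyses population structure of three marker systems measured
on the same set of sampling sites: MS-AFLP epiloci (individuals × loci
over four methylation conditions), codominant diploid microsatellites
(individual genotypes), and pooled-sequencing SNPs (population-level
allele frequencies only). Distance matrices (differentiation,
environmental, riparian) are labelled, symmetric, zero-diagonal square
matrices (`skbio.DistanceMatrix`); all alignment between matrices is by
site label, never by position.

## Four-state scoring

A fragment is called present when its peak height is ≥ the RFU threshold
(default 750) and its size lies inside the inclusive window
(default [150, 500] bp). Both boundaries are taken inclusive: the source
conventions ("at 750", "between 150 and 500") do not exclude the
boundary, and both are configurable. Fragment sizes are assumed
pre-binned to integers; re-binning of near-equal sizes is deliberately
out of scope because it is an instrument-specific manual curation step
that cannot be made reproducible.

The (MspI, HpaII) presence pair maps to conditions
(1,1)→I, (1,0)→II, (0,1)→III, (0,0)→IV. Condition IV is retained as an
informative fourth state in *all* downstream statistics — it reflects
hypermethylation or restriction-site loss, either of which is a
population-level signal — and is never recoded as missing. A separate
missing code (NaN in memory, `NA` on disk) exists for unscored cells;
frequencies and distances then use reduced denominators.

The locus filter removes a locus iff its Condition-IV count exceeds
`max_iv_fraction` (default 0.95) of individuals *strictly*; a locus at
exactly the threshold is retained, taking "more than 95%" literally.
Polymorphism screening (optional) treats a locus as polymorphic when at
least one scored individual differs — no minor-state count threshold, the
most literal reading and the least destructive default.

## Environmental ordination

The 14 site variables mix units (m³·s⁻¹, mg·L⁻¹, %, °C…), so the default
PCA standardises each variable (correlation PCA, ddof = 1); covariance
PCA is available but would be dominated by high-variance variables such
as flow. Loading signs are arbitrary in PCA; each column is flipped so
its largest-magnitude entry is positive, making reports deterministic.
Three axes are retained by default (a cumulative-variance rule is also
provided). Each retained axis yields the one-dimensional Euclidean
distance |score(a) − score(b)|, giving one environmental predictor per
gradient rather than one pooled environmental distance — the axes have
distinct ecological readings (eutrophication, upstream–downstream,
altitude/nutrient) and should enter the regression separately.

## Standardised differentiation G″ST

For a pair of populations, per locus: H_S is the mean of the two
within-population gene diversities 1 − Σp², H_T the diversity of the
mean frequency vector. H_S and H_T are averaged across loci **before**
forming

    G″ST = k(H_T − H_S) / ((k·H_T − H_S)(1 − H_S)),  k = 2.

Averaging before the ratio is the standard estimator convention; a
per-locus-ratio mode exists for sensitivity analysis and differs on
heterogeneous loci. Loci monomorphic within a pair contribute
H_S = H_T = 0 and stay in the averages (they dilute numerator and
denominator symmetrically). A pair fixed for the same state everywhere
(H_T = 0) returns 0 with a degenerate-pair warning.

The default estimator is the plugin (no small-sample correction) so
epiloci, microsatellites and SNP pools — for which no sample size exists —
are computed identically and are directly comparable. The plugin
estimator has a known positive finite-sample bias under weak structure;
a `nei_unbiased` mode (Nei–Chesson correction, with the harmonic-mean
sample size; n in individuals for haploid-coded epiloci, allele copies
for microsatellites) is provided for data with sample sizes and is the
right choice when absolute calibration around zero matters.

Epiloci are treated as haploid four-allele loci (one condition per
individual), microsatellites as codominant diploid (allele-copy
counting, n = 2 × scored individuals), SNP pools as frequency-only.
This "one engine, three marker systems" design is what makes the
epigenetic-vs-genetic comparison on a single differentiation scale
possible.

## Distance-based AMOVA

Squared inter-individual distances: for epiloci, the count of loci with
differing conditions; for microsatellites, the per-locus count of
non-shared allele copies (0, 1 or 2) summed over loci. The epilocus
mismatch count is exactly squared-Euclidean on (locus, state) indicator
codings scaled by 1/√2, which licenses the nested-ANOVA decomposition
and is verified against a brute-force indicator-coded oracle to 1e-9.
Pairs with missing loci use the mean per-locus distance over compared
loci rescaled to the full locus count. Both metrics are pluggable; the
exact metric used by legacy software for four-state data is not
standardised, so results on real data may differ slightly between
implementations.

Two-level components follow the classical formulas (see the AMOVA module
docstring); σ²_a uses the unbalanced-design coefficient n₀. Negative
σ²_a estimates are reported as computed — clamping is a display choice
(`AmovaResult.clamped()`), not an estimation one. The permutation test
permutes individual population labels, is one-tailed on Φ_ST (large
values mean more structure), includes the observed labelling in the null
(+1 convention, so p ∈ (0,1]), and draws from a named substream of the
master seed. Pooled SNPs are rejected by type: without individual
genotypes there is no within-population component.

## Mantel and MRM

Mantel r is the Pearson correlation over the N(N−1)/2 lower-triangle
entries; the null permutes rows and columns of one matrix jointly. For
N ≤ 7 sites (N! ≤ 5040) the full permutation group is enumerated and the
p-value is exact, with the identity permutation supplying the observed
statistic; above that, sampled permutations use the +1 convention. The
default alternative is one-sided "greater", matching the directional
hypotheses (more differentiation with more environmental or geographic
distance); two-sided is available.

MRM regresses the unfolded response triangle on unfolded predictor
triangles with an intercept (OLS). Significance permutes the **response
matrix only** — the standard scheme for regression on distance matrices;
permuting predictors is not offered. Coefficient p-values are two-sided
on magnitude (the sidedness convention is stated in reports since it is
not universal), the R² p-value one-sided. With a single predictor,
R² equals the squared Mantel r to 1e-12 (tested). Rank-deficient designs
fail with the offending predictor pair named.

## Synthetic riverscape generator

The generator's defaults mirror the emulated study design: 13 sites,
24 individuals per species per site, 260 epiloci, 15 microsatellites of
8 alleles (the study's two species had 13 and 17), 1,500 pooled SNPs
(study: 1,892 and 1,244), 14 environmental variables.

*Environment.* Three latent site gradients, made mutually orthogonal
(QR) so the designed axes are identifiable at 13 sites, load on variable
blocks with ecologically signed loadings: eutrophication (oxygen −,
conductivity/nitrite/nitrate/BOD +, oxygen saturation −),
upstream–downstream (flow/width/pH/temperature +), altitude/nutrient
(orthophosphate/slope/altitude/suspended matter +), plus N(0, 0.35²)
noise per variable, then an affine rescale to realistic units.
Riparian distances are leaf-to-leaf path lengths on a random bifurcating
river tree with Uniform(5, 50) km branches; they satisfy the tree-metric
properties by construction but are generated independently of the
gradients (real upstream–downstream structure is partly spatial; the
generator keeps space and environment separable so their effects can be
disentangled in tests).

*Genetics.* Per site, a neutral scalar factor z ~ N(0,1); the selection
proxy a = z + γ·g1 (γ = `gamma_env_gen`, g1 the eutrophication
gradient). SNP site frequencies follow a logit-scale F-model: deviation
scale σ = 2√(f/(1−f)) for intensity `f_gen`, split equally between the
shared site factor (a, via per-locus loadings) and per-site-locus noise.
Microsatellites use z only — neutral markers should carry no
environmental signal, matching the emulated study where only SNPs showed
an environment association. Pool frequencies are exact site frequencies
by default so SNP G″ST has a clean oracle; binomial read sampling
(`pool_read_depth`) is opt-in.

*Epigenetics.* Site condition probabilities are softmax-transformed
logits: baseline Dirichlet state profiles (8% of loci drawn
Condition-IV-dominant to exercise the locus filter), shifted by
σ_e·F·c_l with F = ρ·ã + √(1−ρ²)·z′ (ã the standardised genetic factor,
z′ independent, ρ = `rho_epi_gen`) plus β·g1·d_l (β = `beta_env`) on
per-locus contrasts. There is deliberately no additional per-site-locus
noise term: at ρ = 1, β = 0 the site probabilities are a deterministic
function of the genetic factors, which is the regime where a marginal
epigenetics~environment association is entirely spurious. Individuals
draw states independently from their site's probability vector.

The intensity-to-scale map σ = 2√(f/(1−f)) gives realised
differentiation of roughly the requested intensity at intermediate
frequencies; it is a calibration convenience, not an exact F_ST match.

*What the generator does not emulate:* linkage, microsatellite mutation
models, migration along the river network (no isolation-by-distance is
built in unless coupled through the gradients), tissue heterogeneity of
methylation, and scoring artefacts other than simple missingness.
Passing tests therefore demonstrate the statistical machinery and the
inferential logic, not field realism.

## Study sizes used in the test suite

Replicated studies are run at the design's site and individual counts
(13 × 24) with reduced locus counts — 24–60 epiloci, 2–5
microsatellites, 50–300 SNPs — and 199 permutations per test, sizes at
which every check is stable while the whole suite stays fast. The null
calibration study uses 200 replicates with all couplings at zero (the
degenerate f_gen = 0 is allowed for exactly this purpose) and binomial
read noise (depth 50) on pools so no matrix is degenerate; each test's
rejection rate is then exactly Binomial(200, 0.05) under correct
implementation, checked against the exact binomial 95% band. The
spurious-association study uses 100 replicates at f_gen = 0.15, γ = 1.5,
ρ = 1, β = 0 — an effect size giving SNP–environment associations of the
strength typical for this design (Mantel r around 0.5–0.8).

## Numerical conventions

- Permutation p-values: sampled runs use (1 + #extreme)/(n_perm + 1);
  exhaustive runs divide by N! with the identity included. p ∈ (0, 1].
- All randomised procedures draw from independent substreams named
  `(master seed, stream name)` via `SeedSequence`; toggling one analysis
  never perturbs another's p-values, and reruns are bit-identical.
- Distance matrices are symmetrised against float noise at 1e-9 on read;
  larger asymmetries are errors.
- G″ST matrices clamp numerical negatives (possible under the unbiased
  estimator) at zero for the matrix while the raw components keep sign.
- Degenerate cases carry explicit flags or warnings (all-zero distance
  AMOVA, fixed-pair G″ST) rather than NaN surprises.

## Known limitations

- The plugin G″ST bias under weak structure (see above) means absolute
  epigenetic-vs-genetic level comparisons on small samples should use
  the unbiased mode; pooled SNPs cannot be corrected at all because pool
  depth does not enter the calculation.
- AMOVA is two-level only (no region level, no within-individual
  heterozygosity level).
- MRM assumes a linear relation between unfolded distances; a monotone
  but curved relation can leave structure in residuals.
- With 13 sites, Mantel/MRM power is modest and single-run statistics
  are noisy; replicate-level conclusions (as in the test studies) are
  the reliable ones.
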