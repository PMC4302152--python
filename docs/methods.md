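# Methods

This note documents the statistical model behind `diffmet`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Data model and QC

A *feature table* holds raw LC-MS ion intensities (features × technical
replicates) with per-feature metadata (m/z, retention time,
chromatography column, signal-to-noise ratio) and per-sample annotations
(sex, genotype, developmental temperature, adult temperature, replicate
structure). The two chromatography columns (C18 reverse phase, AE anion
exchange) have different chemistries and are treated as separate datasets
throughout, as are the two sexes.

QC runs in a fixed order; both filters are idempotent and feature counts
never increase:

1. **SNR filter** — keep features with signal-to-noise ≥ `snr_min`
   (default 14, inclusive). SNR is treated as a given per-feature
   property supplied by the instrument pipeline, not recomputed.
2. **Log transform** — base 2 by default. The base only rescales the
   data; downstream correlations and F statistics are invariant to it.
3. **Missingness filter** — drop a feature if it is missing from more
   than `max_missing_frac` (default 5%) of the samples of *any* level of
   the grouping factor (default sex). Applied before replicate
   collapsing, so "samples" here are technical replicates.
4. **Imputation** — the residual missingness after filtering is small
   (fractions of a percent); missing cells are filled by an EM-style
   iterative local regression: initialise with feature means, then
   repeatedly regress each incomplete feature on its k = 5
   most-correlated other features (ridge-stabilised, λ = 1e-6, fitted on
   the feature's observed samples), re-predicting its missing cells
   until the largest change is below 1e-6 or 100 sweeps. Predictors are
   re-ranked on the current filled matrix each sweep, so information
   propagates between incomplete features; observed cells are never
   altered. A feature with no observed cells is an error. The scheme is
   deterministic. It recovers exactly-collinear structure to machine
   precision and beats mean imputation whenever features are correlated,
   which is the regime the network analysis assumes.
5. **Replicate collapsing** — technical replicates are averaged
   (arithmetic mean post-log, i.e. geometric mean on the raw scale) into
   one column per biological sample. Averaging after the log transform
   was chosen because all downstream analysis is on the log scale.

## Per-metabolite linear model

Each feature's collapsed log intensity is modelled by OLS as

    y = mu + L + A + G + L:A + L:G + A:G + eps

with developmental temperature L, adult temperature A and genotype G
categorical fixed effects. Per-term F tests use **Type II sums of
squares** (compare the model of all terms not containing the factor
against that model plus the term, scaled by the full model's residual
mean square). Type II is invariant to factor order and agrees with
Type I/III in a balanced design; the test implementation is vectorised
across features via shared QR projections and is verified against
statsmodels' `anova_lm(typ=2)` in the test suite. Interactions can also
be tested by the Gaussian likelihood-ratio statistic
2(llₓ − llᵣ) = n·log(RSSᵣ/RSSₓ) against χ² with the rank difference as
degrees of freedom; the χ² reference is asymptotic, and the suite
additionally checks the statistic against its exact finite-sample law
(a monotone transform of an F variate).

Multiplicity across features is controlled per term by
Benjamini–Hochberg at q = 0.01 — a deliberately conservative default for
untargeted data with thousands of features.

The *warm/cool* contrast restricts to flies kept at one temperature for
life (18→18 and 27→27), collapses L and A into a single two-level
temperature factor, and refits the same model with
factors = (temperature, genotype).

Degenerate inputs: a constant (or perfectly explained) response yields
F = 0, p = 1 for every term rather than 0/0; a rank-deficient design
after subsetting raises an error naming the aliased columns.

## Differential networks

The adjacency of the network under condition *t* is the signed Pearson
correlation matrix across that condition's samples (minimum 4 samples;
zero-variance features are an error naming the feature). Identifying the
adjacency with the raw signed correlation — rather than a soft-powered
|r|^β — is forced by the similarity matrix's limit S = r² when the two
conditions agree, which holds only for A = r.

With A and A′ the two adjacencies and β a positive integer (default 5):

    D = |(A − A')/2| ** (β/2)          (zero diagonal)
    S = (1 − D) * |A| * |A'|           (unit diagonal)

The exponent is β/2 applied to the half correlation difference, so at
β = 5 an extreme flip r: 1 → −1 gives D = 1 while a modest change
r: 0.8 → 0.2 gives D = 0.3^2.5 ≈ 0.049. Raising β never increases D
(|Δr/2| ≤ 1), which is how it buys stringency: small, noise-dominated
correlation differences are suppressed relative to large ones. Both
matrices live in [0, 1]; D and S agree with naive scalar double loops to
1e-12 and those identities are enforced in the acceptance tests.

**Module detection.** D is the adjacency of the change network, so
differential ("plastic") modules are found by average-linkage
agglomerative clustering on the dissimilarity **1 − D**; preserved
modules on **1 − S**. (Clustering D itself as a distance would scatter
plastic modules: their members are mutually *distant* in D.) An optional
flag replaces 1 − D by 1 − TOM(D), the topological-overlap dissimilarity
used by the WGCNA family; it is off by default because the plain
transform is already sufficient on planted benchmarks and keeps the
method easier to reason about. The dendrogram is cut statically at
`cut_fraction` × the maximum merge height, and clusters smaller than
`min_size` (default 10) are left unassigned ("grey"). The dynamic hybrid
tree cut used by some implementations is not reproduced; the exact
cutting procedure was an open design choice, and the permutation test is
the guard against spurious modules, not the cut itself.

`cut_fraction` defaults to **0.95**. The background of both dendrograms
merges in a narrow band just below the maximum height (around 0.99 of it
for 1 − D and 1 − S alike), while planted modules join far lower
(≈ 0.85–0.9 for a Δr = 0.8 plastic block, ≈ 0.4–0.6 for an r = 0.8
preserved block). A cut at 0.99 of the maximum lands inside the
background band and admits background lumps — on the standard planted
benchmark (two 20-feature modules over 200 background features, 30
samples per condition) it recovers the preserved module with Jaccard
only ≈ 0.56 — whereas any cut comfortably below the band separates
signal from background; at 0.95 both planted modules are recovered
exactly. Module labels are colour names assigned by decreasing size with
deterministic tie-breaking, so the partition is invariant to feature
order up to renaming.

Edge lists for visualisation (Cytoscape import) keep unordered pairs
with |r| ≥ 0.7 by default, signed.

## Permutation significance

**Differential (dispersion) test.** For module M,

    d(M) = sqrt( mean over pairs i<j in M of ((r_ij,1 − r_ij,2)/2)^2 )

and the analogue over cross pairs for each module pair. The null
shuffles the condition labels across samples, preserving group sizes;
both correlation matrices and every statistic are recomputed per
permutation (default 1000), and

    p = (1 + #{d_perm >= d_obs}) / (1 + n_perm).

The plus-one rule keeps p in (0, 1] — the smallest attainable p at 1000
permutations is 1/1001 ≈ 0.001 — and is conservative at finite
permutation counts. The statistic is symmetric in the two conditions, so
the permutation distribution is invariant to relabelling them.

**Preservation test.** Label shuffling cannot test preservation: mixing
the conditions makes the two shuffled "condition" networks similar for
*every* module, so the null would never reject. Instead the observed
mean within-module similarity s̄ = mean off-diagonal S is compared
against s̄ on random feature sets of the same size drawn from all
analysed features, with the same plus-one rule. Calibration of both
nulls (≈ 5% rejection at α = 0.05 for the dispersion test on
null data; uniform random-set p-values by KS test) is enforced in the
acceptance tests.

*Caveat.* The random-set null asks "does this module share more strong
structure across conditions than a random feature set?". A genuinely
plastic module that retains residual similarity (e.g. r 0.8 → 0 leaves
S ≈ 0.1 against a background of ≈ 0.02) can therefore reach preservation
significance with a much weaker statistic than a truly invariant module.
The two analyses should be read together: a module that is significant
in the *differential* test is changing, whatever its preservation p.

## Pathway over-representation

Pathways are plain identifier sets (GMT files; duplicate members
deduplicated, malformed lines reported with their line number). For a
universe of M reference ids, a pathway covering K of them and N hits
overlapping in k ids, the p-value is the exact hypergeometric upper tail
P(X ≥ k); zero-overlap pathways report p = 1, and BH adjustment runs
across the tested pathways with a conventional adjusted-p cutoff of
0.01. Pathway sizes are always counted after intersection with the
reference universe. This is deliberately plain ORA on pre-annotated
identifiers: m/z-based putative annotation and network-weighted
enrichment scoring are out of scope.

## Synthetic data

The generator emulates the study design end to end: genotypes × sexes ×
four temperature groups (18→18, 18→27, 27→18, 27→27) × biological
replicates, measured in technical duplicate; the default demo drops one
replicate from one genotype, giving 95 biological samples (190 technical
columns) as in designs where one line contributes a sample fewer.

Biological log2 intensities are `mu_f + x`, with per-feature baselines
mu_f ~ U(14, 22) and unit-variance deviations x. A planted module of
size m follows a single-latent-factor model per condition:

    x_f = lambda_t * z + sqrt(1 − lambda_t^2) * eps_f,   lambda_t = sqrt(r_t)

with z shared by the module's features within a sample, giving expected
pairwise correlation exactly λ² = r_t under the sample's condition.
A preserved module uses equal high targets (default 0.8/0.8), a plastic
module very different ones (default 0.8/0.0). Negative common targets
are rejected: a constant negative pairwise correlation is not positive
semi-definite beyond two features. Background features are independent
noise. Planted mean shifts are expressed in units of the unit biological
SD; technical replicates add independent N(0, 0.2²) noise; cells are
removed completely at random at rate 0.003 by default, matching the
order of residual missingness such pipelines report (a few tenths of a
percent); per-feature SNR is drawn from U(5, 60) so the SNR filter is
exercised, and ground-truth module membership is stored in the feature
metadata (`planted`) for recovery scoring.

What the simulator does **not** emulate: chromatography physics,
adducts/isotopes, retention-time drift, batch effects, heteroscedastic
or intensity-dependent noise, informative (non-MCAR) missingness, and
correlation structure beyond a single latent factor per module. Passing
tests therefore demonstrate that the statistical machinery is correct
and calibrated under its stated assumptions — not that real LC-MS data
meet those assumptions.

## Problem sizes and determinism

Default analysis scales were chosen so a complete run is interactive on
a laptop: the demo pipeline uses 300 features over 95 biological
samples with 1000 permutations per network; the validation suite uses
200 null datasets (40 features, 20+20 samples, 199 permutations) for
calibration, a 240-feature benchmark for planted recovery, and
1000-feature simulations with 24 samples per temperature group for
linear-model calibration and power. All randomness flows from a single
integer seed through deterministic child seeds; two runs with the same
seed produce byte-identical summaries, which the test suite asserts.

## Known limitations

- The static tree cut has no per-branch adaptivity; modules with very
  unequal tightness may be over- or under-split. The permutation tests,
  not the clustering, carry the inferential weight.
- The preservation statistic is relative to the random-set background
  (see caveat above).
- The dispersion permutation test reuses one label-shuffle null per
  dataset across modules and module pairs; p-values are exchangeable but
  not independent across modules, and no multiplicity correction is
  applied to module-level p-values by default.
- OLS assumes homoscedastic Gaussian errors on the log scale; no robust
  or mixed-model variants are provided.
- Imputation assumes approximately linear inter-feature relationships
  and low residual missingness; it warns above 5% missing cells.
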