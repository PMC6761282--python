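# Methods

## Study design assumed by the pipeline

Twelve samples in four age groups — SR40, SR50, SR60, SR70, three samples
each (one female, two males), with representative ages 40/50/60/70 years —
profiled twice: a miRNA count matrix and a gene count matrix over the same
samples.  The pipeline starts from raw integer counts; alignment,
quantification and QC are out of scope.  Two reciprocal contrasts, SR60 vs
SR40 and SR70 vs SR50, are tested per feature, so each feature carries two
effect estimates and two p-values that are then combined.  The rationale is
robustness at n = 3 per group: a feature must show the same direction of
change in two independent decade-apart comparisons before it is called
age-associated.

## Negative-binomial GLM (module `diffexpr`)

Counts are modelled as NB(μ, φ) with variance μ + φμ² (the edgeR
parameterisation of overdispersion) and log-link mean
log μ = Xβ + log N_s, where N_s is the raw library size (column total).  No
between-sample normalisation factor is applied beyond the library size; a
hook for plug-in factors exists in `log_cpm` and defaults to 1.0.

Fitting is batched Fisher scoring across features (a feature is one row; the
design is shared), with step-halving so the likelihood never decreases, a
convergence tolerance of 1e-8 on the relative log-likelihood change, and a
cap of 50 iterations.  Non-converged features are flagged and their p-values
set to NaN rather than reported silently.  Features with all-zero counts in
the contrast samples are dropped and counted in the log.

The common dispersion is the maximiser of the Cox–Reid adjusted profile
likelihood, Σ_f [ℓ_f(β̂_f, φ) − ½ log det(XᵀW_fX)], over a 41-point grid of
log10 φ ∈ [−4, 1] refined by golden-section search to 1e-3 in log10 units.
The CR adjustment corrects the downward bias of plain profile ML when every
feature carries its own mean parameters — material here, with 2 mean
parameters per feature and 6 observations.  On a seeded null simulation the
estimate recovers the generating φ (0.098 for true 0.1); on the committed
test fixture the estimate agrees with the reference edgeR implementation to
five decimals (0.10472), and per-feature logFC/LR agree to six decimals at
equal dispersion.  Common dispersion only: no trended or tagwise shrinkage —
with three samples per group a per-feature dispersion is not estimable, and
a single φ keeps the core verifiable.

The test is LR = 2(ℓ_full − ℓ_null) clipped at zero against χ²(1)
(two-sided; the direction is carried by the sign of logFC).  The reported
logFC comes from a refit with a prior count of 0.5 added to every count —
shrinking low-abundance fold changes away from ±∞ — while LR and p always
come from the raw-count fits.  Abundance is reported as
log2((count + 0.5)/(libsize + 1) × 1e6), per contrast and averaged over all
samples.

Calibration, measured by the test-suite on null NB data (φ = 0.1, 5,000
features, 3 + 3 samples): type-I error 0.055 at the 0.05 level,
Kolmogorov–Smirnov uniformity p = 0.33.  The χ²(1) reference is slightly
liberal at n = 3 per group; this is inherent to the LRT at this sample size
and is inherited by any downstream error-rate statement.

## Meta-analysis and selection (module `meta`)

Fisher's statistic −2(ln p₁ + ln p₂) is referred to χ²(4).  Underflowed
zero p-values are floored at 1e-300 with a logged warning.  BH adjustment is
step-up over the complete vector of combined p-values (delegated to
statsmodels; the identical function also serves the pathway ORA so the two
stages cannot disagree).  The gene path is fixed as: Fisher over all tested
genes → BH over that full vector → FDR cut → direction-consistency filter;
the miRNA path requires nominal p < 0.05 in both contrasts plus consistency.
The direction string is the pair of logFC signs; zero logFC is treated as
"+" with a warning (it cannot pass any threshold anyway).  Discordant
features passing every other filter go to a separate report.

## Correlation and trends (module `association`)

Correlations are computed on logCPM (prior 0.5), not raw counts, across the
12 samples; the exact p uses t = r√(n−2)/√(1−r²) with n−2 df, two-sided.
No multiplicity adjustment is applied to the ~10⁵ pairwise correlations —
the valid-pair rule filters at nominal p < 0.05, which is a known limitation
of the design (the published analysis does the same); the package documents
rather than "fixes" this.  Age trends are OLS of logCPM on age in years with
t-based 95% CIs on the slope.

## Valid pairs, classification, enrichment (modules `integration`, `enrichment_network`)

Condition (iii) — direction consistency — is operationalised as the sign
identity sign(r) = sign(logFC_miRNA)·sign(logFC_gene).  Exact r = 0 cannot
pass condition (ii) and is rejected with a warning if it arises.  *Direct*
requires both database membership and r < 0; predicted pairs with r > 0 are
indirect and flagged `predicted_positive`.  The enrichment universe defaults
to the number of genes tested by mRNA-seq; the per-miRNA direct scope is
predicted targets with significant negative correlation, the indirect scope
significantly correlated non-predicted genes.  The hypergeometric upper tail
agrees with exhaustive enumeration for every (N ≤ 25, K, n, k).  Pathway ORA
uses the union of the supplied gene sets intersected with tested genes as
its default universe (configurable to all tested genes), upper tail only.
The exported network is bipartite by construction; SIF lines are
`mirna <interaction> gene`, GraphML carries node kind/direction and edge
sign/interaction attributes.

## Synthetic data (module `synthetic_data`)

The generator emulates the assumed study: per-feature baseline CPM drawn
log-normal (median 50 CPM, σ_ln = 1.2 — a realistic bulk abundance spread
with a few very high and many low features), library sizes log-uniform in
[0.8, 1.2]×10⁶, NB noise with φ = 0.1.  Planted age-associated features
change linearly in log2 with age-group index at planted_logfc/2 per decade,
so each reciprocal contrast sees the full planted_logfc (default 2) and the
feature also shows a linear age trend.  Repression couplings multiply a
target's mean by 2^(−coupling·(latent miRNA log2 CPM − its mean)), default
coupling 0.8; the coupling acts on the regulator's noiseless latent
abundance so the ground truth is well defined regardless of noise.  The
target database contains every coupled pair plus 10× uniformly drawn decoy
pairs.  Structure (baselines, planting, library sizes) and count noise are
drawn from separate child streams of the single config seed, so fresh noise
realisations around a fixed truth are available for replicate-based checks.

Couplings attach only to regulators and targets with baseline at or above
`coupling_min_cpm` (default: the population median).  A repression coupling
planted on a ~zero-count feature is undetectable *by construction* — the
signature is never expressed, so its non-recovery would measure the
abundance lottery, not pipeline correctness — whereas planted age effects
remain uniform over abundance so differential-expression power is still
genuinely exercised.  Measured end-to-end at the suite's scale, planted
direct-pair recovery is 0.83–1.0 across structure seeds with this floor.

What the generator does **not** emulate: batch effects, sample-specific
dispersion, composition bias (hence no TMM), sequence-based targeting, and
correlated co-regulation between features.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the assumed
model, not performance on real tissue data.

## Problem sizes and seeds in the test-suite

The recovery suite and the acceptance script simulate 300 miRNAs × 3,000
genes with 20 planted AA-miRNAs, 80 AA-genes and 30 couplings — the same
statistical conditions (φ, effect size, coupling, group sizes) at a reduced
feature count, chosen so the whole suite completes in seconds; the
`analysis/` drivers run the full 1,482 × 23,346 scale.  Test seeds are fixed
constants; the acceptance script seeds everything from `--seed`.

## Numerical choices

- IRLS initialisation from least-squares projection of log((y+0.5)/N_s)
  onto the design; linear predictors clipped at ±500 before exponentiation.
- φ below 1e-12 switches the likelihood to its Poisson limit.
- Fisher df is 2k with k the number of contrasts (4 here), not configurable.
- BH ties and ordering: step-up with cummin from the largest p, capped at 1;
  ORA results sort by (p, set_id) so ties break deterministically.
- TSV output at 10 significant digits round-trips losslessly for all
  reported quantities.

## Known limitations

- χ²(1) reference at n = 3 per group is mildly liberal (measured ~0.055).
- Nominal correlation filtering (no FDR on pairs) inflates the indirect-pair
  count; direct pairs are additionally gated by database membership.
- The genome build of miRNA vs gene quantification is not reconciled;
  feature ids are opaque strings, with an optional alias table for
  display-name mapping (unmapped genes are dropped from name-dependent
  outputs and counted).
- Enrichment p-values depend on the chosen universe; the defaults are
  documented above and configurable.
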