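# Methods

## The three normalization viewpoints

For counts `y_gs` of gene g in sample s, all downstream models use a
per-sample denominator `D_s`:

* per-library-size: `D_s = N_s f_s`, where `N_s` is the raw library size and
  `f_s` the TMM scaling factor — a compositional viewpoint (abundance
  relative to the mRNA pool);
* per-total-RNA: `D_s = 1e6`, a constant — valid because every library was
  prepared from the same mass of total RNA, so depth variation carries the
  mRNA-per-unit-RNA signal;
* per-sample-size: `D_s = mg_s * 1e6`, tissue mass — an absolute viewpoint
  per unit tissue.

CPM is `y_gs / D_s * 1e6`. The `1e6` constants are cosmetic: every
within-gene statistic (t, ICC, DE p-values) is provably invariant to a
common rescaling of the denominators, which the test suite asserts
numerically.

### TMM

The scaling factor follows the original trimmed-mean-of-M-values algorithm:
against a reference sample (the one whose upper-quartile count proportion is
closest to the mean upper-quartile), gene-wise `M = log2` ratio of library
proportions and `A = ` average `log2` abundance are computed over genes with
count ≥ 1 in both samples; the top and bottom 30% of M and 5% of A are
trimmed; the factor is `2**(weighted mean M)` with inverse binomial-variance
weights, and factors are rescaled to geometric mean 1. Degenerate cases
(`max |M| < 1e-6`, or nothing surviving the trim) yield a factor of exactly 1,
the latter with a warning. The implementation reproduces edgeR's
`calcNormFactors(method="TMM")` to ~1e-12 on a frozen reference case.

## Stable-gene screen

Genes with count ≥ 30 in every sample ("robust expression") are fitted
per mode, gene by gene, with

    log CPM_gs = x_s' b + u_p(s) + e_s,   u ~ N(0, s2_b), e ~ N(0, s2_e)

where `x_s` contains intercept, week-2/week-12 dummies (week 0 baseline),
a volume dummy (moderate vs low leg) and time×volume interactions. All five
non-intercept coefficients represent study conditions; a gene is discarded
when `max |t| >= 1.5`. Survivors are ranked by ICC = s2_b/(s2_b+s2_e)
(descending, ties broken by gene identifier) and the top 10 become the
mode's reference genes. Whether interactions belong in the screen is
genuinely open; they are included by default (the screen should be
sensitive to any systematic condition effect) and can be switched off in
the config. Natural log is the default transform — the affine-invariance
of t and ICC makes the base consequence-free, which is also asserted in the
tests.

### REML implementation

The single-random-intercept model admits a one-dimensional profile: given
the variance ratio `lam = s2_b/s2_e`, GLS estimates, the residual variance
and the REML criterion are closed-form through the Woodbury identity on the
block covariance (`a'Wb = a'b - sum_p c_p (sum a)_p (sum b)_p` with
`c_p = lam/(1+lam n_p)`). The criterion is minimized on the ICC scale
h = lam/(1+lam) by a coarse grid (81 points) plus bounded Brent refinement
(xatol 1e-12); the boundary h = 0 is always compared explicitly and flagged
when selected. Boundary fits remain valid ranking candidates (maximally
un-clustered, ICC 0). Fixed-effect SEs use `s2_e (X'WX)^-1`; t-values carry
no small-sample df correction — they feed a screening threshold, not
inference. The fit agrees with a dense grid-search REML oracle to 1e-4 in
the variance ratio and with statsmodels MixedLM on random instances.

## Sample references and cross-mode ratios

Each mode's ten reference genes are scaled `x / max(x)` per gene across
samples and averaged per sample, giving the sample reference in (0, 1].

The profiles are taken on the common count scale (equivalently per-total-RNA
CPM — max-scaling removes the constant) for every mode, not on mode-specific
CPM. Two reasons, both structural: (i) the reference is used as a log-offset
on *raw counts* in the DE stage, so it must carry the mode's denominator
signal — and it does, through the gene selection: genes stable per
library-size have raw profiles that track the pool-plus-depth, genes stable
per mg have flat raw profiles; mode-specific CPM references would be flat
for every mode by construction and all three DE analyses would collapse
onto the same answer. (ii) Cross-mode ratios of references are only
meaningful on a common scale; on mode-specific scales every ratio is
identically flat over time.

Ratios `log(r_num/r_den)` are fitted with cell-means time coding plus a
participant random intercept; the package reports exponentiated per-time
means and change-from-baseline contrasts (`week2_vs_week0`), both with Wald
95% CIs on the log scale (the CI method is a design choice; only "95% CI"
is prescribed by the workflow). The library-over-tissue contrast at week 2
estimates the global amplification directly: its population value equals
the total-RNA rise per mg.

## Negative-binomial GLMM

For each gene in the DE universe (count ≥ 1 in all samples, the union of
the three reference-gene sets excluded — the universe is fixed before
testing and shared by all modes so that intersections compare identical
genes):

    log mu_s = x_s' b + u_p(s) + log r_s,    y_s ~ NB(mu_s, phi)

with variance `mu + phi mu^2` and `x_s` = intercept + time dummies (legs
pooled as biological replicates; a volume term is available behind a config
flag). The participant integral is approximated by adaptive Gauss–Hermite
quadrature centred at each group's posterior mode (inner 1-D Newton), 5
nodes by default; 1 node is the Laplace approximation, and refining 5 → 15
nodes moves coefficients by < 1e-3 on simulated fits. b, log sigma_u and
log phi are maximized jointly by L-BFGS-B over a numba-compiled marginal
log-likelihood (finite-difference gradients); starting values come from a
Poisson IRLS fit plus moment estimates, with two further deterministic
restarts on non-convergence. SEs are from the inverse observed information
(central finite differences) at the optimum, falling back to the
fixed-effect block if the full information is not invertible. Tests are
Wald z with two-sided normal tails — a standard GLMM choice, slightly
liberal at 25 participants (measured type-I error ~0.06 at nominal 0.05);
likelihood-ratio tests would be more conservative but triple the fit cost.
Benjamini–Hochberg runs per time contrast across genes (week-2 and week-12
families separately, matching the per-contrast reporting; a pooled family
is a config switch away). All-zero genes are flagged degenerate; any gene
whose fit fails in one mode is labelled `ns` in *all* modes so that no
"unique" call can be an artifact of differential convergence.

The offset contract — adding c to every offset shifts only the intercept,
by exactly −c — is exact at the optimum and asserted to 1e-6.

## The synthetic-data generator

The generator emulates the emulated study's structure: 25 participants ×
2 legs (low/moderate training volume, treated as biological replicates) ×
3 time points, 2000 genes, fixed 1000 ng RNA input. Per-mg abundance is

    T_gs = exp(alpha_g + u_gp + delta_gt),   mRNA pool M_s = sum_g T_gs,
    mu_gs = L_s T_gs / M_s,                  y_gs ~ NB(mu_gs, phi_g).

* `alpha_g ~ N(3, 1.5^2)`; `phi_g ~ lognormal(log 0.05, 0.5)` (dispersions
  0.01–0.3, typical bulk RNA-seq); gene-wise participant-intercept sd
  uniform on (0.05, 0.35), but (0.4, 0.6) for designated stable genes —
  designated reference genes are, by definition, participant-consistent,
  which is what makes the ICC ranking able to find them.
* `delta_gt` (per-mg log fold change, 0 at baseline) carries the global
  amplification `A_t` (1, 1.27, 1.17): designated `tissue_stable` genes
  have delta = 0; designated `library_stable` genes have delta = log A_t
  (constant pool share); `de` genes add a persistent N(0, 0.5^2) per-gene
  effect; background genes track log A_t with per-gene, per-time wobble
  sd 0.3 — real transcriptomes do not amplify perfectly uniformly, and
  without the wobble every background gene would be exactly stable and no
  screen could isolate the designated classes.
* RNA yield per mg `Y_s` is 350 ng/mg × A_t × lognormal noise (sd 0.1);
  tissue mass is lognormal(log 3 mg, 0.25), independent of time; sequencing
  depth `L_s` is lognormal(log 1.5e6, 0.15) × A_t. Depth tracking the
  amplification mirrors the observed rise in sequenced library size that
  accompanies tissue growth, and it is the channel that makes the three
  viewpoints informationally distinct: with fixed RNA input, counts carry
  only pool proportions times depth, so a depth trend is the only way the
  count data can see the global change. A consequence worth stating
  plainly: under this generator the per-total-RNA and per-sample-size
  screens both target the per-mg-stable class (the per-sample-size mode
  simply adds tissue-mass noise), which matches the empirical pattern in
  this kind of study — those two modes share reference genes and DE calls,
  while the per-library-size mode stands apart, with the highest ICCs.
* Truth tables record delta (per-tissue truth), delta − log(pool ratio)
  (per-library truth, pool ratio from the population abundance profile) and
  delta − log A_t (per-total-RNA truth), plus realized M_s, Y_s, L_s and an
  analytic `expected_counts` oracle satisfying `sum_g mu_gs = L_s` exactly.

Problem sizes were chosen so the whole pipeline (≈ 4400 REML screens plus
≈ 5900 NB-GLMM fits) runs in about two minutes: 2000 genes at depth 1.5e6 is
a proportional scale-down of ~12000 transcripts at tens of millions of
reads, keeping per-gene counts in a realistic range.

### What the generator does not emulate

No read-level structure (FASTQ, alignment, multimapping), no
isoform/length effects, no rRNA compartment (total RNA enters only through
the global factor), no time trend in tissue mass, no correlation between
depth and a sample's realized pool, no batch effects or library-prep
chemistry artifacts. Passing tests therefore demonstrate that the
*statistical machinery* behaves as specified under the stated generative
model — not that real data meet that model's assumptions.

## Numerical and degenerate-input choices

* REML: boundary s2_b = 0 allowed and flagged; rank-deficient designs raise
  an error naming aliased columns; identically-zero responses give a
  zero-variance fit with degenerate (width-0) CIs rather than an error.
* NB-GLMM: bounds log sigma_u in [log 1e-4, log 10], log phi in
  [log 1e-8, log 10]; all-zero genes flagged, never fitted.
* BH: step-up with monotonicity enforced from the largest p down, capped at
  1, exact against a brute-force implementation.
* Ties in ICC ranking broken lexicographically by gene identifier; fewer
  than k screen survivors proceed with a prominent warning.
* Robust filtering guarantees positive CPM, so log-CPM needs no
  pseudocount; a zero value under log with pseudocount 0 is an error
  directing the user to the filter.

## Known limitations

* Wald (not LRT) inference; slightly liberal at this design size.
* No empirical-Bayes dispersion shrinkage or precision weights — each gene
  stands alone, as in the emulated workflow.
* The per-total-RNA mode follows the constant-denominator definition
  literally; an optional depth rescaling is available but off by default,
  since whether the original analysis corrected for depth cannot be
  determined from its description.
* The reference-ratio estimate is computed from ten genes and inherits
  their sampling noise; on default-sized simulations the recovered
  amplification is typically within a few percentage points of the truth.
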