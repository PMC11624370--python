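# Methods

`mefeval` implements, at desk scale and on synthetic data with known truth,
the statistical pipeline behind a routine genomic evaluation for methane
efficiency (MEF) in dairy cattle: milk mid-infrared (MIR) prediction of
daily CH4, multi-trait variance-component estimation, (single-step) genomic
BLUP, and the published relative-breeding-value index. This note records
the models, the generator that stands in for real data, the numerical
choices, and what the tests do and do not demonstrate.

## The evaluation model

All four traits (CH4_MIR in g/d; milk, fat and protein yield in kg/d) are
analysed jointly with the test-day animal model

y = Xb + Z1·htd + Z2·a + Z3·p + e,

where `b` holds age-at-calving class (2-month classes), DIM class (5-day
classes inside the 120-185 d analysis window) and year-season of calving;
`htd` is the random herd-test-day contemporary group, `a` the additive
genetic effect, `p` the permanent environment of the cow and `e` the
residual. The random vectors are zero-mean normal with covariances
HTD⊗I, G⊗A (or G⊗H in the single-step case), P⊗I and R⊗I, each trait
matrix 4×4. Every record carries all four traits, so the mixed-model
equations take a Kronecker form with level-major equation ordering.

Heritability is defined with the full denominator,
h² = G_tt / (G_tt + HTD_tt + P_tt + R_tt); the contemporary group is part
of phenotypic variance. A flag on `CovarianceComponents.heritability`
excludes HTD for users who prefer the narrower definition.

## Synthetic data

Because no evaluation data of this kind is public, every stage is exercised
on simulated populations (module `mefeval.simulate`):

* **Pedigrees.** Either a generic generational random-mating design, or a
  nested full-sib/half-sib design (sires × dams × daughters with founder
  parents and non-parent recorded cows) used for variance-component
  recovery.
* **Genotypes.** Founder allele counts binomial(2, p) with p uniform in the
  configured MAF range; descendants by gene dropping (each known parent
  transmits one sampled allele; an unknown parent side is drawn from the
  founder frequency).
* **True effects.** Founder breeding values N(0, G); non-founders as half
  the known-parent average plus Mendelian sampling with variance d·G
  (d = 0.5/0.75/1 for 2/1/0 known parents; an optional flag applies the
  inbreeding correction 0.5·(1 − (F_s+F_d)/2)). HTD and PE effects are
  i.i.d. multivariate normal.
* **Phenotypes.** Records follow the model above with fixed-effect truth
  zero beyond the trait means; each herd has `records_per_cow` test days
  and cows are recorded on every test day of their herd, with days in milk
  placed inside the analysis window.
* **Default (co)variance truth.** Per trait, phenotypic variance is split
  as h²·σ²p genetic, 15% HTD, 15% PE, remainder residual, with phenotypic
  SDs (81.2, 5.0, 0.2, 0.2) and means (490.4, 33.3, 1.3, 1.1) typical of
  first-lactation Holstein test-day data. Genetic correlations follow the
  published estimates for these traits. The three non-genetic components
  share one correlation matrix, solved so the phenotypic correlation matrix
  is reproduced exactly given the genetic covariances; setting the
  non-genetic covariances to zero instead would force a residual MY-PY
  correlation above 1, so the shared-correlation rule is the simplest
  feasible completion. All four matrices are verified PSD at construction.
* **Spectra.** A smooth multi-band loading times a partially saturating
  response f(CH4) = (1−w)·x + w·tanh(1.5x) on standardized CH4, plus a
  polynomial baseline and i.i.d. noise. The default noise SD (1.15 per
  point) was chosen once by grid search so that a ridge-regression oracle
  reaches a holdout correlation near 0.7 with CH4, emulating the accuracy
  regime of MIR CH4 prediction; `calibrate_spectra_noise` reruns that
  search.

The generator does **not** emulate linkage/LD, QTL architecture, selection,
lactation-curve shapes, seasonal calving patterns or laboratory drift
beyond what the spectral-subset tests inject. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated model, not performance on real milk-recording data.

## MIR phenotyping

Region selection keeps FOSS pins 260-402, 442-472 and 701-767 (1-based,
closed), i.e. 241 points. Within a laboratory, principal components of the
scaled spectra explaining more than 1% of variance are monitored over time;
a two-window running-mean shift (window 30 spectra, 3 pooled-SD threshold,
both configurable) marks a changepoint and splits the series into
homogeneous subsets. Each subset is standardized to the reference by a
per-pin affine map matching mean and SD (zero-variance pins fall back to an
offset-only map); the fitted maps are returned for audit. Outliers are
flagged by Mahalanobis distance in the retained-component score space
against the chi-squared quantile at P < 0.001 with df equal to the number
of retained components. Savitzky-Golay smoothing uses a cubic polynomial
and width 11; edge points are fitted on the available shrunken window
rather than padded data, so no values are fabricated beyond the spectrum.

Weekly CH4 phenotypes are ISO-calendar-week means of daily g/d values
(≥ 2 daily records), restricted to first lactation and DIM 5-305, with a
single-pass |3.5| SD edit applied to the weekly means over the whole
dataset (a switch applies it to daily values instead, since either reading
is defensible). A week is matched to the nearest same-animal spectrum
within 11 days of the week midpoint (median measurement date); ties go to
the earlier date.

The CH4 predictor is a Bayesian-regularized network: 2 tanh hidden neurons,
linear output, spectra as the sole input (z-scored; target centred/scaled).
Training minimizes βE_D + αE_W with Levenberg-Marquardt inner steps and
MacKay's Gauss-Newton evidence update of (α, β) each of the 100 epochs;
weight initialization is N(0, 0.1²) under the given seed, so training is
deterministic. With two neurons the network spans near-linear and
saturating responses, which is the point of using it on the partially
nonlinear spectra-CH4 link.

## REML

Two exact engines estimate (HTD, G, P, R); both standardize traits
internally (all matrices pre- and post-multiplied by the inverse phenotypic
SDs) so the four traits, whose variances span five orders of magnitude, are
numerically comparable.

* **Full-MME EM** (`reml_em_full`): every animal and PE level has an
  equation; each iteration solves the dense MME, takes the blocks of the
  inverse coefficient matrix it needs, and applies the standard EM updates.
  The restricted likelihood is evaluated every iteration and asserted
  non-decreasing. Intended for small data; it is the in-package oracle.
* **Absorbed engine with AI acceleration** (`AbsorbedREML`): for
  repeatability data on non-parent cows with founder parents (the nested
  design), only fixed, HTD and parent-animal equations are retained. Each
  cow's Mendelian-sampling-plus-PE effect is absorbed into a per-cow
  residual covariance V = J_k⊗Σc + I_k⊗R with Σc = 0.5G + P — the
  classical reduced animal model combined with the bijective free
  reparameterization (HTD, G, Σc, R) ↔ (HTD, G, P, R), so its optimum is
  the animal-model optimum whenever the implied P is PSD. Iterations are
  EM steps (first three, and as fallback) plus average-information Newton
  steps on the 40 free covariance parameters, guarded by step halving,
  projection back into the PD cone, and a monotonicity check. Scores come
  from the EM sufficient statistics; the AI matrix is built from the
  working variates V̇θP y with one multi-right-hand-side solve on the
  retained system. Standard errors are the inverse AI matrix at
  convergence, mapped through the linear transform to (HTD, G, P, R).

Convergence is declared when the maximum relative parameter change falls
below the tolerance (default 1e-5) or the likelihood is flat to 1e-8
(relative) for three consecutive iterations — small datasets leave weakly
identified directions along which parameters drift without likelihood
change. Because Σc is the free parameter, the implied P̂ = Σc − 0.5G can
have slightly negative eigenvalues at small n; it is reported as estimated
(the likelihood is the unconstrained REML optimum) and heritabilities are
computed from the implied sums. The two engines agree to 1e-12 in the
restricted likelihood at common parameters and to numerical precision at
interior optima (tested).

`reml_estimate` dispatches automatically: the absorbed engine when the
design qualifies, the full engine otherwise. `reml_by_herd_subsets`
reproduces the production practice of estimating on random herd subsets and
comparing results.

**Recovery design.** Variance-component recovery runs on 1,500 recorded
cows with 2 records each in 75 herds, structured as 100 unrelated sires ×
5 dams × 3 daughters (dams unrelated founders, full-sib triplets nested in
half-sib families). At a fixed number of cows this allocation keeps the
genetic (co)variances well identified through both the sire and dam
contrasts; over 30 validation seeds the mean estimates deviated from truth
by at most ~0.015 in heritability and ~0.02 in genetic correlation, with
per-replicate SDs around 0.03-0.05 and 0.08-0.13 respectively. One
replicate takes on the order of 15 s on a single core.

## Relationship matrices and single-step evaluation

Inbreeding coefficients use ancestor tracing of the A diagonal
(Meuwissen-Luo style); the dense A uses the tabular method (for tests and
A22 blocks), and A⁻¹ is assembled directly from Henderson's rules with
inbreeding. The genomic matrix is VanRaden method 1, G = ZZ′/(2Σp(1−p)),
with observed allele frequencies by default, linear tuning of the mean
diagonal/off-diagonal to A22, and blending G* = (1−w)G + wA22 with
w = 0.05. The single-step inverse is
H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹] with no extra scaling (τ = ω = 1).
Unknown-parent groups and metafounders are not implemented (single genetic
base).

The MME are solved by sparse LU for systems up to a few thousand equations
(needed anyway for exact PEV extraction) and by Jacobi-preconditioned
conjugate gradients above that (a 72,000-equation system solves in about a
second). Reliabilities are exact PEV-based, rel = 1 − PEV/((1+F)σ²a),
clipped to [0, 1]; effective-daughter-contribution approximations are
deliberately not used at desk scale. GEBV reliability blends the
direct-genomic (genotyped-block PEV of the single-step system) and
animal-model reliabilities 80:20.

## The MEF index

The genetic regression of CH4 on (MY, FY, PY), b = G_pp⁻¹ g_p, is computed
from the genetic covariance matrix of the evaluation; raw MEF is
EBV_CH4 − b′EBV_prod, and the published index is its negative (higher =
less CH4), standardized so base bulls (born 2008-2017 with an official
evaluation, window configurable) have mean 100 and SD 5. The sign is
reversed after all computations; reversal order is immaterial
mathematically. Index reliability uses the selection-index approximation
cov(EBV_i, EBV_j) ≈ √(rel_i·rel_j)·G_ij, which is exact at the reliability
extremes and collapses to the CH4 reliability when b = 0. Official status
requires ≥ 20 daughters, ≥ 5 herds and ≥ 70% reliability (all inclusive).

In validation, the independence property |corr(raw MEF, production EBV)| is
checked on a 10,000-animal high-reliability simulation with b computed from
the population's realized genetic covariance — the analogue of a production
system whose G is fitted to the same data; with b from the theoretical G
the check additionally absorbs the finite-pedigree sampling error of G
itself (a ±0.03-0.04 effect at this scale).

Reporting follows the published conventions: RBV classes low (< 95),
medium ([95, 105], boundaries medium — the printed class description is
followed where the inequality notation is self-contradictory), high
(> 105); class SEs are SD/√n; the daughter-average regression converts the
slope per RBV point into an expected g/d reduction per 5-point (1 SD) step.

## Known limitations

* The absorbed REML engine requires the nested design (uniform record
  counts, founder parents, non-parent cows); anything else routes to the
  full engine, which is dense and limited to small problems.
* The full cross-laboratory standardization algorithm of the production
  system is reduced to per-subset affine alignment with a running-mean
  changepoint rule.
* No SNP-space DGV machinery: direct genomic reliabilities come from the
  genotyped-block PEV, which carries the same information at desk scale.
* P̂ may sit outside the PSD cone at small n (see above); production-scale
  runs with the default design did not exhibit this.
* The generator's independence assumptions (no LD, no selection) make the
  recovery targets cleaner than any real population would be.
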