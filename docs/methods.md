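# Methods

This note documents the statistical models, the synthetic-trial generator,
the numerical choices, and the known limitations of `clonalspec`.

## Univariate spatial mixed model

The model for one trait on a clonal trial is

    y = 1μ + X_r β_r + X_c β_c + Z c + e

with second-order orthogonal polynomial bases in the row index and in the
column index (built by QR orthogonalization of the centered powers; columns
are orthonormal and orthogonal to the constant), a clone effect
c ~ N(0, σ²_c I), and residuals e ~ N(0, R) with R either σ² I or the
separable autoregressive field σ² [AR1(ρ_col) ⊗ AR1(ρ_row)]. Grid
coordinates are 1-based integers and the AR1 lag is the absolute index
difference — standard row/column field-trial practice, with no metric
distances. Missing positions are handled by taking the observed-tree
submatrix of the full Kronecker covariance; missing responses are dropped
listwise per trait while retaining the layout for lag computation.

Estimation is REML in the Patterson–Thompson form, including the log|X'X|
term so the value equals the Gaussian log-density of any orthonormal
error-contrast projection and is invariant to the fixed-effect basis (this
is also what the brute-force oracle in the tests computes). The fixed
effects and the residual scale σ² are profiled analytically, leaving a
bounded search over (γ = σ²_c/σ², ρ_row, ρ_col): a multi-start Powell
search over the grid γ ∈ {0.1, 1, 3}, ρ ∈ {0, ±0.5}, ranked by profiled
likelihood with the best two starts polished to convergence
(ftol 1e-9). Bounds are γ ≥ 0 (the boundary is allowed) and |ρ| ≤ 0.99 to
keep the covariance well conditioned. The optimizer trace records the
running best likelihood, which is monotone by construction.

The asymptotic variance–covariance of the variance parameters is the
inverse negative Hessian of the (unprofiled) restricted log-likelihood,
numerically differenced with central steps of 1e-4 × parameter scale;
variance parameters sitting at zero are floored slightly above the boundary
before differencing, and non-positive curvature directions are clipped, so
boundary fits yield conservative rather than undefined standard errors.
Software that uses the average-information matrix instead is equivalent at
convergence.

Heritability is H² = σ²_c/(σ²_c + σ²) with the delta-method SE from the
gradient (σ², −σ²_c)/(σ²_c + σ²)². The clone variance is tested by a
likelihood-ratio test against the no-clone model with the ½χ²₀ + ½χ²₁
boundary mixture; autocorrelation parameters (interior nulls) use the plain
χ² reference. Approximate F-tests for fixed terms are Wald statistics on
the GLS coefficient covariance with containment-style denominator degrees
of freedom n − rank(X) — a deliberate simplification (Kenward–Roger is out
of scope) that is labeled in the output.

## Bivariate stacked model

Two traits are stacked into one response with a trait factor; the fixed
part has trait means and trait-nested row/column polynomials, and the
random structure is

    tc ~ N(0, G_c ⊗ I_c),  u ~ N(0, σ²_u I_trees),  e ~ N(0, blockdiag(R₁, R₂))

with G_c unstructured (2 × 2) and per-trait AR1 ⊗ AR1 (or iid) residual
blocks that are re-estimated inside the bivariate fit. Cross-trait
dependence enters only through G_c (clone level) and the shared tree effect
u (within-tree level); residual blocks are trait-diagonal. A single σ²_u
shared across traits is the minimal structure that correlates the two
records of one tree.

Numerics: responses are standardized internally (the clonal covariance is
back-transformed afterwards), G_c is parameterized by its Cholesky factor
so it stays positive semi-definite, and the search is bounded L-BFGS-B with
finite-difference gradients, warm-started from the two univariate fits and
from the correlation of clone means. The Cholesky map has a zero-gradient
saddle at G_c = 0, so collapsed or boundary solutions trigger a rescue
pass: G_c and σ²_u are re-optimized with the residual blocks frozen at
their univariate estimates from strongly correlated starts of both signs,
then all parameters are released. The residual variances carry a floor of
0.01 on the standardized scale, which keeps the covariance matrix away from
singularity when the two responses are (nearly) identical. The reported
restricted log-likelihood is re-evaluated on the original response scale so
fits are comparable across parameterizations.

r_g = G_c[1,2]/√(G_c[1,1] G_c[2,2]); its SE applies the delta method to the
(G11, G12, G22) block of the jointly inverted numerical information matrix.
|r_g| > 0.999 is reported as ±0.999 with flag "B" and no SE — the boundary
convention — and a clonal variance within 1e-5 (standardized) of zero makes
the correlation undefined, reported as an error rather than a number.
Significance uses a 1-df LRT against the model with G_c[1,2] = 0 (an
interior null, plain χ²).

## Scans and comparisons

Seasonal comparisons are paired t-tests per wavelength on trees matched by
id across sampling dates (unmatched trees dropped, matched ids canonically
sorted so the scan is permutation invariant); zero-variance differences are
flagged degenerate with p = 1. Ecotype comparisons use Fisher's LSD —
pairwise t-tests on the pooled one-way error variance, unadjusted, with a
Welch option; p-values are two-sided by default with a one-sided option.
Pearson scans report r, SE = √((1 − r²)/(n − 2)), and the two-sided p from
t = r√((n − 2)/(1 − r²)); they run on per-tree values (the unit of analysis
of the mixed models), with clone-median aggregation available upstream.
Wavelength-wise p-values are reported raw — contiguous runs of p < α form
the significant regions, inclusive of endpoints — because raw-threshold
regions are the reporting convention this pipeline mirrors; a
Benjamini–Hochberg option exists but is off by default. Heritability and
genetic-correlation scans wrap the mixed models column-by-column and record
per-column failures (constant columns, degenerate fits) in the output
instead of aborting.

## Synthetic-trial generator

The generator is the ground-truth instrument for everything above. It
emulates: clones replicated as ramets on a grid (randomized or contiguous
clonal-row planting, with empty positions allowed); clone genetic values
drawn MVN(0, G); per-trait spatial surfaces equal to a second-order
polynomial trend (coefficients in trait units applied to indices normalized
to [−1, 1]; the default amplitude is 0.3 × the phenotypic SD) plus an
AR1 ⊗ AR1 field sampled exactly via the matrix-normal identity
E = L_row N L_col'; and trait assembly as mean + optional clone-level
ecotype shift + genetic value + surface.

Spectra are built from a fixed baseline curve — low visible reflectance
with a green bump at 550 nm, a logistic red-edge rise at ~715 nm to a NIR
plateau near 0.45, and a smooth SWIR decay — minus Gaussian absorption
features tied linearly to traits: total chlorophyll deepens the 680-nm band
(and half as strongly the 550-nm band), a latent unit-variance water
variable deepens the 970/1,200/1,450/1,930-nm bands, and a latent structure
variable raises the NIR plateau. Reflectance is clipped to [0, 1] after
adding iid Gaussian noise (default SD 0.005).

Default conditions: a 10 × 10 grid with 30 clones × 3 ramets and
ρ_row = ρ_col = 0.5 — the reference design used throughout the recovery
studies — and a trait registry whose means, spreads, and heritabilities
(0.29–0.46) are typical of mature clonal Norway-spruce material: DBH
33 cm, height 20.6 m, chlorophyll a ≈ 3.1 mg/g. The genetic correlation
matrix has pigments mutually at 0.95, pigments–crown length at 0.65,
growth traits at 0.4–0.9, and water tied to crown length (0.6) and
pigments (0.4), projected to the nearest positive semi-definite
correlation matrix once at construction. Ecotype effects default to
clone-level shifts matching the kind of differences seen among
low/medium/high-elevation ecotypes (high-elevation trees smaller; medium
slightly lower in pigments).

Two generator properties deserve emphasis when interpreting outputs:

* **Ecotype shifts dilute genetic correlations.** The mixed models do not
  include ecotype (the analysis treats ecotype by post-hoc comparison), so
  ecotype mean shifts appear as clone-level variance. For crown length the
  default shift variance (~6 m²) exceeds the within-ecotype genetic
  variance (~2.1 m²), so the fitted pigment–crown-length r_g is strongly
  attenuated relative to the generative correlation matrix. This is a
  faithful rendering of the design being emulated, not an estimator defect
  (recovery tests without ecotype effects hit the generative values).
* **Absorption is linear, not saturating.** Index–pigment correlation
  signs can differ from field experience (e.g. DWSI4 correlates positively
  with chlorophyll here) because real 680-nm absorption saturates while the
  generator's is linear by design — linearity is what makes the
  link-coefficient recovery test exact.

What passing tests show, and do not show: parameter recovery and
calibration hold under Gaussian traits, exactly separable AR1 noise, and
linear spectral links. Real needle spectra have saturating absorption,
instrument noise structure, needle-age effects, and non-Gaussian trait
distributions; none of these are emulated.

## Monte-Carlo problem sizes

Recovery studies use 200 replicates of the reference design (both
univariate and bivariate), LRT calibration uses 1,000 null replicates on a
6 × 6 / 12-clone iid design, and likelihood-oracle equivalence uses 20+
random instances of ≤ 50 trees at tolerance 1e-6 — sizes chosen so the
Monte-Carlo standard errors are well inside the assertion bands while the
whole suite stays a coffee-break run. Wavelength scans in the analysis
scripts run on thinned grids (50–100-nm steps); the per-column model is
identical at any grid density.

## Known limitations

* Denominator degrees of freedom for fixed-effect F-tests are the
  containment simplification, not Kenward–Roger.
* Delta-method SEs near variance boundaries are conservative
  approximations; the boundary flag, not the SE, is the reliable signal
  there.
* The bivariate optimizer re-estimates residual blocks per column in
  scans; freezing them (supported) trades exactness for speed.
* The index registry covers the seven indices of the study dialect, not a
  full spectral-index catalogue; continuum removal and derivative spectra
  are out of scope.
* Pigment equations assume clear 80%-acetone extracts; no path-length or
  turbidity corrections.
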