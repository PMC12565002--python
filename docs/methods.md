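# Methods

This note documents the models, numerical choices and limitations behind
`albisoil`. Everything stated here is computed by the package's tests or by
`scripts/acceptance.py`; nothing is quoted from external tables.

## Experimental design model

The unit of analysis is a plot assigned to one of four treatments in a 2×2
factorial: control (CK), AMF inoculation (AM), *Trichoderma* inoculation
(TL), and both (AT), with four replicate plots per treatment by default
(16 samples). The control is always the first treatment label and anchors
every percent-change contrast, `100·(treated − control)/control`.

## Synthetic-data generator

The generator emulates the statistical structure the downstream analysis
assumes, not the field process itself.

**Soil indicators.** A replicate value is
`baseline × multiplier(treatment, indicator) × noise`, with `noise` drawn
lognormal with **unit mean** and coefficient of variation `noise_cv`
(σ² = ln(1 + CV²), location −σ²/2). Unit mean — rather than unit median —
was chosen so treatment means are unbiased for `baseline × multiplier` and
the Monte-Carlo convergence checks close; at CV ≤ 0.1 the two conventions
differ by < 0.5% in the mean and not at all in exact zero-noise recovery,
which is the generator's defining property: at `noise_cv = 0` every
configured multiplier is recovered exactly by a treatment-mean percent
change.

**Packaged effect profile.** Control baselines use a published albic-soil
site's measured chemistry (pH 5.94; SOM 30.08, TN 1.28, TP 0.56,
TK 14.62 g·kg⁻¹; AP 15.36, AK 133.51, AN 164.73 mg·kg⁻¹). Nitrate
(20 mg·kg⁻¹) and ammonium (10 mg·kg⁻¹) baselines are free parameters set to
field-plausible round values; the four enzyme activities default to 1.0
activity unit because only *relative* changes are known — any positive
baseline gives identical percent changes, correlations and memberships
(everything downstream is scale-invariant). Multipliers transcribe printed
percent changes: TN +7.5/21.2/19.2% and TP +3.1/15.6/10.9% (AM/TL/AT),
pH +3.8% and cellulase +24.9% and lignin peroxidase +36.7% (AT),
β-glucosidase +28.3/48.5/77.6%, NH₄⁺-N +10.8/2.2/14.0%. Indicators without
a printed change keep multiplier 1 — a deliberately conservative choice
that understates treatment separation relative to a real trial.

**Community tables.** Effects are specified on the relative-abundance
scale: designated taxa (*Mortierella*, with +58.29/99.35/77.86% shifts
from a 10.2% control share; *Sphingomonas*, with its AT share fixed at
1.7619× the AM share and 3.4617× the TL share) are pinned to per-treatment
targets, the remaining mass is spread over background taxa drawn once per
call from a lognormal(0, 1) abundance profile, noise multiplies every
entry, and rows are renormalized to sum to one. No sequencing-depth
(count) model is included; abundances are compositional proportions, with
Chao1 served by a pseudo-count conversion at a nominal depth (20 000) in
the pipeline.

**What the generator does not emulate:** spatial autocorrelation between
plots, indicator-specific error variances, correlated measurement error
across indicators, compositional count noise, and rare-taxon detection
limits. Passing tests therefore demonstrate correctness of the *methods*
under the stated noise model, not field-level robustness.

## Soil quality index

Given a Total Data Set (TDS) of indicators (default: pH, TP, TN, TK, AP,
AK and the four enzyme activities):

1. **PCA** eigendecomposes the Pearson correlation matrix. Loadings are
   `eigenvector × √eigenvalue` (indicator–component correlations), the
   convention under which the |0.5| grouping threshold and the Norm formula
   are standard. Signs are canonicalized so each component's
   largest-|loading| indicator loads positively; ties break by column
   order. Components with eigenvalue ≥ 1 are retained; if none reaches 1
   (possible only through roundoff, since the eigenvalues average 1), PC1
   is retained with a warning rather than failing.
2. **Grouping**: an indicator joins the retained component where
   |loading| ≥ 0.5; multi-assignments and indicators below 0.5 everywhere
   go to their max-|loading| component.
3. **Norm values** `N_i = √(Σ_j u_ij² e_j)` over retained components. The
   square-root form is used; it is the standard composite of loading and
   eigenvalue magnitudes in the MDS literature.
4. **10% rule**: within each group, keep `N ≥ 0.9 × group max`
   (multiplicative reading of "no more than 10% below the maximum").
5. **Correlation pruning**: within each group, survivors are scanned in
   descending Norm (column order on ties) and dropped if significantly
   correlated (two-sided Pearson t-test, n−2 df, default α = 0.01) with an
   already-kept member. Every drop is written to an audit log with the
   triggering rule.
6. **Scoring**: memberships are linear min–max over the observed data,
   direction-aware (all defaults ascending: every default indicator is a
   fertility or activity measure), clipped for out-of-range inputs.
   Weights are communalities over the retained components renormalized
   over the final set — the dominant convention where the weighting is not
   otherwise specified. `SQI = Σ W_i F(X_i) ∈ [0, 1]`.

Properties verified by tests: the engine agrees to 1e-9 with a literal
scalar-by-scalar reference implementation on 200 random 4-indicator
tables; SQI is invariant to positive rescaling of any indicator column
(correlation PCA + min–max membership), and monotone in any ascending MDS
indicator for a fixed selection.

The pipeline computes the SQI on the ten designated assessment indicators;
zero-variance columns (which a correlation PCA cannot accept, and which
arise in zero-noise simulations for no-effect indicators) are excluded and
listed in the report.

## Treatment statistics

Balanced designs only — the target trial is 4×4, and balance keeps the 2×2
factorial sums of squares orthogonal (SS_cells = SS_A + SS_B + SS_AB
exactly, verified numerically). One-way ANOVA reports F = MS_between /
MS_within; all-identical data yield an explicit "undefined" status, and
zero within-variance with unequal means reports F = +∞, p = 0. Duncan's
multiple range test uses protection levels α_p = 1 − (1−α)^(p−1) with
studentized-range quantiles from `scipy.stats.studentized_range` (a vetted
special-function routine), step-down protection for enclosed ranges, and an
insert-absorb compact letter display with letters assigned in
descending-mean order; with two groups the Duncan decision coincides with
the α-level pooled t-test, which the tests check.

## Community statistics

All implemented in-package; `scikit-bio` and `scipy.spatial` serve only as
independent cross-checks in the test suite.

* **Chao1** (bias-corrected): `S_obs + F1(F1−1)/(2(F2+1))`; integer counts
  required unless a rounding flag is passed. **Shannon**: `−Σ p ln p` in
  nats.
* **Bray–Curtis**: `Σ|x−y| / Σ(x+y)` on relative abundances.
* **PCoA**: Gower double-centering `B = −½ J D² J`, eigendecomposition,
  coordinates `v√e` for eigenvalues above a relative tolerance of 1e-10.
  Negative eigenvalues are excluded from the coordinates and from the
  percent-explained denominator, and their total magnitude is reported as
  a diagnostic; no Lingoes/Cailliez correction is applied.
* **PERMANOVA**: pseudo-F from the distance-based partition
  (SS_total = Σ d²/n; within-group analogue per group), label permutations,
  p = (1 + exceedances)/(1 + n_perm) so p ≥ 1/(n_perm+1). Fewer than 99
  permutations are refused unless strict mode is off. An all-equidistant
  matrix gets an explicit "degenerate" status. On univariate Euclidean
  distances the pseudo-F equals the one-way ANOVA F to 1e-9 (tested).
* **Mantel**: Pearson r of the strict lower triangles; one-tailed
  (r ≥ observed) p by simultaneous row/column permutation of the second
  matrix. Default pairing in the pipeline: Bray–Curtis community distance
  vs Euclidean distance of z-scored soil indicators.
* **RDA**: optional Hellinger transform (√ of row proportions — the
  standard variance-stabilizing choice for species data, and the default),
  column-centering of Y and X, least-squares fit, PCA of the fitted
  values; each axis's percent explained is its eigenvalue over the total
  variance of transformed Y. A rank-deficient explanatory matrix raises an
  error naming the collinear columns (QR with pivoting).
* **envfit**: R² of one variable regressed (with intercept) on the first
  two axis scores, permutation p.

## Statistical calibration

Under null simulations (4 groups × 4 replicates), one-way ANOVA and
PERMANOVA type-I error at α = 0.05 is verified to lie in [0.035, 0.065]
over 2000 simulations, and Mantel/envfit permutation p-values are verified
uniform (Kolmogorov–Smirnov p > 0.01 over 500 replicates at 99
permutations). These problem sizes keep the default suite under a minute
for the calibration block while leaving the Monte-Carlo error well inside
the asserted bands.

## Reproducibility

Every random draw flows from an explicit `numpy.random.default_rng` seed;
the pipeline derives per-stage seeds from the top-level seed by fixed
offsets (soil +0, community +1, PERMANOVA +2, Mantel +3, envfit +4…), so a
stage re-run standalone with its derived seed reproduces the pipeline's
numbers, and identical configs give byte-identical reports.

## Known limitations

* The MDS correlation-pruning rule makes the retained indicator set — and
  hence the SQI's sensitivity to any single treatment contrast — dependent
  on sampling noise at n = 16; with replicate CV 0.08 the weak AM-vs-CK
  contrast (carried almost entirely by the +28.3% β-glucosidase effect,
  which pruning often removes in favor of a correlated higher-Norm
  indicator) is recovered in only ≈ 78% of simulations. The strong AT
  contrast is recovered essentially always.
* Duncan letters and the two-way ANOVA accept balanced designs only.
* RDA axis percentages depend on the (configurable) transform; no
  permutation test of the overall RDA model is provided.
* No count-based (rarefaction/sequencing-depth) diversity machinery beyond
  the pseudo-count Chao1 conversion.
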