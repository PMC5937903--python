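# Methods

## Statistical model

Each (protein, carotenoid) pair is modeled as a linear mixed model with a
single random intercept per multiplexed experiment (plex):

    N_rk = b0 + B_r + b1 · P_rk + e_rk,
    B_r ~ N(0, σ_B²),  e_rk ~ N(0, σ_e²),  independent,

with N the log2 plasma concentration (log2 μmol/L), P the log2 relative
protein abundance (dimensionless; 0 = at the plex median), r the plex and
k the sample. The random intercept absorbs measurement shifts shared by
the seven study samples of one plex. Assumptions: Gaussian plex effects
and residuals, a common slope across plexes, abundance measured without
error, and ignorable missingness given complete-case analysis (each
protein is fit on the samples where both it and the analyte are
observed).

### Estimation

The REML log-likelihood is profiled to one parameter, the variance ratio
λ = σ_B²/σ_e². With V* = I + λZZ′ (Z the plex indicator matrix), the GLS
coefficients, the REML residual variance σ̂_e² = r′V*⁻¹r/(n−2) and

    ℓ(λ) = −½[(n−2)(log 2π + 1) + (n−2)·log σ̂_e²(λ) + log|V*| + log|X′V*⁻¹X|]

are available in closed form at fixed λ. Because V*⁻¹ decomposes into
per-plex rank-one corrections, one fit needs only per-plex counts and
sums: each likelihood evaluation is O(#plexes). λ is maximized on a
57-point log-spaced grid over [10⁻⁸, 10⁶] followed by golden-section
refinement of the bracketing interval (interval tolerance 10⁻⁹ on the
log scale); λ = 0 is evaluated explicitly and accepted as a boundary
estimate, in which case the fit reduces exactly to pooled OLS. The
profiled likelihood agrees with statsmodels MixedLM (REML) to ~10⁻⁸ in
both log-likelihood and slope on test instances, and with a dense-matrix
brute-force grid oracle to <10⁻⁶ in log-likelihood (verified in the test
suite over 50+ seeded instances).

Degenerate inputs: constant predictor, <2 plexes, or fewer observations
than the floor (default 10) raise typed errors that the screen converts
into logged skips. An exactly linear response (zero residual) returns the
OLS line with both variances at their lower boundary.

### Inference and derived statistics

- **Wald test.** p = 2·(1 − Φ(|b1/se(b1)|)), with se(b1) from the GLS
  information at λ̂ (λ treated as known). With ~500 observations and ~72
  plexes the normal reference is adequate; no Satterthwaite correction is
  applied. A zero standard error with a nonzero slope is flagged and
  reported as p = 0 with a warning.
- **BLUPs.** B̂_r = λ̂/(1 + n_r·λ̂) · Σ_k (residual of the fixed part),
  the standard shrinkage predictor; they sum to ~0 in balanced designs
  and shrink to 0 as λ̂ → 0.
- **r and R².** The fitted values ŷ = b0 + b1·P + B̂_r are correlated
  (Pearson) with the observed response; since this correlation is
  non-negative by construction, the reported r carries the slope's sign,
  and R² = r² identically.
- **Percent change.** b1 is reported as (2^b1 − 1)·100, the percent
  change in concentration per 2-fold (100%) increase in relative
  abundance; strictly increasing in b1 and bounded below by −100%.

## Preprocessing

- **Median referencing.** Each protein's log2 intensities are referenced
  to the within-plex median (midpoint convention for even counts —
  outside the package's control, upstream normalization is taken as
  given). The operation is idempotent; the pooled QC channel is excluded
  from the median by default (config switch `include_qc_in_median`).
- **Detection filter.** Proteins detected in strictly more than 10% of
  analytic samples are screened (51 of 500 passes, 50 does not). The
  filter is global, not per-analyte.
- **Response.** Concentrations are log2-transformed; samples flagged
  below the detection limit are excluded from that analyte (never
  imputed) and listed with a reason. A non-positive unflagged
  concentration is a data-integrity error.

## FDR control

q-values follow the step-up form q_(i) = π̂0 · min_{j≥i} m·p_(j)/j,
clipped to [0,1], computed per analyte over all tested proteins (not
pooled across analytes). π̂0 is estimated by the smoother approach: the
tail ratio π0(t) = #{p>t}/(m(1−t)) over t ∈ {0, 0.05, …, 0.90} is
smoothed with a cubic least-squares polynomial (a df-3 smoother) and
evaluated at the largest grid point. When m < 100 or the smoothed value
leaves (0, 1], π̂0 falls back to 1, making the procedure exactly
Benjamini–Hochberg (verified element-wise against a brute-force
min-over-tail scan). Ranking by q never contradicts ranking by p.

## Correlation matrices

- Analyte × analyte: Pearson correlations of log2 concentration over
  pairwise-complete detectable samples, with per-pair n and a two-sided p
  from the Fisher-z normal approximation; pairs with <3 shared samples
  are flagged missing.
- Protein × protein (per analyte): Pearson correlations of the
  median-referenced abundance vectors over shared non-missing samples,
  restricted to hits at q < 0.05, ordered positive correlates first
  (ascending q) then negative.

## Synthetic-data generator

The generator emulates the study design so the pipeline is testable with
known truth:

- **Design:** 72 plexes × 7 study samples + 1 pooled QC each; an optional
  subsample (default 500 of 504) drops random analytic slots while
  keeping ≥1 study sample per plex, mirroring the study's use of 500 of
  the available slots without guessing which were unused.
- **Detection:** per-plex detected-protein counts are rounded
  Normal(589, 65) truncated to [1, catalogue]; which proteins a plex
  detects is drawn with heavy-tailed per-protein prevalence weights
  (lognormal, SD 2 on the log scale, via Gumbel top-k sampling), giving a
  ubiquitous core plus a rare tail — with the default catalogue of 4705
  this yields ~1300 proteins past the >10% filter, the same order as a
  real depleted-plasma screen. Missingness is plex-level by construction.
- **Abundance:** detected values are Normal(0, 1) on the log2 scale
  (abundance_sd = 1, a typical spread for relative reporter-ion ratios),
  then median-centered within plex over study samples. The true abundance
  distribution is not identifiable from published summaries; log-normal
  is the conventional assumption.
- **Carotenoids:** generated from the analysis model itself with
  configurable planted slopes (defaults +0.5, +0.3, −0.5, −0.3 per
  analyte, assigned to the most widely detected proteins, disjoint across
  analytes), σ_B = 0.4, σ_e = 0.5. Per-analyte intercepts b0 are the log2
  of typical plasma medians (β-carotene 0.10, lutein/zeaxanthin 0.34,
  β-cryptoxanthin 0.06, α-carotene 0.01, lycopene 0.02 μmol/L).
  Detection limits (0.0164, 0.020, 0.005, 0.0028, 0.0244 μmol/L) were
  set analytically so the implied lognormal marginals — whose SD
  ≈ √(Σb1²·Var P + σ_B² + σ_e²) ≈ 1.04 — censor at roughly realistic
  rates: <1% for β-carotene, ~0 for the xanthophylls, ~4% for
  α-carotene, ~⅔ of samples for lycopene. Below-limit values are
  retained with a flag so the exclusion policy lives in one place.

What the generator does **not** emulate: reporter-ion-level noise,
isotope-impurity interference, peptide-to-protein roll-up, correlated
protein co-abundance (proteins are independent given the plex), skewed
or heteroscedastic residuals, and any real biological covariance between
carotenoids (each analyte's planted proteins are disjoint). Passing
tests therefore demonstrate the pipeline's statistical correctness under
the stated model, not robustness to these real-data features.

## Problem sizes and numerical choices

The validation suite uses: 50 seeded small instances (10 plexes × 7) for
oracle equivalence; 500 simulated fits and 2000 null fits at the study
scale (n ≈ 500, 72 plexes) for recovery, coverage and type-I error; and
100 replicate screens for sign fidelity and ranking — sizes chosen to
put Monte-Carlo error well inside the tested bands while keeping a full
run to a few minutes on one CPU. Ties in p-values are handled by stable
sorts; all simulation randomness flows from a single seeded generator
per run, recorded in every output header and the run manifest.

## Known limitations

- Inference treats λ̂ as known; for very few plexes the Wald test can be
  anticonservative (a t reference with estimated df is a noted, unbuilt
  alternative).
- Multi-protein (multivariable) models and imputation of missing
  abundances are out of scope; the screen is strictly marginal, so
  co-planted effects inflate each other's residual variance.
- The π0 smoother is a polynomial, not a spline; for highly non-uniform
  p-value distributions the two can differ slightly (both conservative
  directions are clipped to (0, 1]).
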