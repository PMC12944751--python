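# Methods

This note documents the models implemented in `vernstab`, the assumptions
they make, the defaults and why, and what the synthetic data do and do not
emulate.

## Vernalization intensity

Hourly temperatures are reconstructed from daily extremes with the sine
model T(h) = Tm + Ta·sin(π/12·(h − hx + 6)), h = 1..24. We interpret Tm as
the midpoint (tmin+tmax)/2 and Ta as half the daily range: only then does
the curve attain tmax at h = hx and tmin twelve hours earlier, which is the
defining property of the interpolation. The hour of the daily maximum hx is
not observable from daily extremes; the default 15:00 is the typical
mid-afternoon maximum and is configurable.

Each hourly temperature x in the 0–13 °C window contributes the weight
w(x) = −1.256 + (1.260 + 0.131x)·0.9357^x. The exponent reading of the last
factor gives a decaying exponential and hence a unimodal weight (maximum
≈ 0.118 near 5–6 °C falling to zero at the window edges), which is the only
reading consistent with a weighting curve; the product reading would make
w linear in x. The weight is clamped at zero (it goes slightly negative
just below 13 °C) and is identically zero outside the window — the window
is applied as a support restriction on the weight, before summation.

Days with Tmax > 23 °C are devernalizing: they contribute zero weighted
hours and are flagged, but they do not roll back previously accumulated
intensity. Accumulation runs from sowing to June 30 inclusive, the end of
the bolting-scoring season. Cumulative intensity is therefore non-decreasing
in time, and raising any day's Tmax can never increase it.

## Biphasic bolting model

Bolting percentage is modelled as y = max(0, b·(x − VT)): zero below the
genotype's vernalization threshold VT, linear above it. The sub-threshold
segment is fixed at zero rather than a free intercept because bolting below
the vernalization requirement is definitionally absent. Fitting is by grid
search on VT at 0.1 vernalizing-hour resolution over the observed intensity
range, with the slope for each candidate VT obtained in closed form as the
least-squares line through the breakpoint (clamped at b ≥ 0); SSE ties are
broken toward the largest VT (the most conservative threshold). When every
observation is zero the flat fit (VT at the largest observed intensity,
slope 0) is returned with `converged=False`. Fits pool plot-level
observations across the bolting-scored environments — with few such
environments, plot-level fitting maximizes the degrees of freedom — and
sites that never bolt are excluded via a configurable site filter, since
they carry no information about the breakpoint.

The model has no upper clamp at 100%: it is only identified while expected
bolting stays below the ceiling, so studies (real or simulated) should
deliver intensities in the informative range around the thresholds.

## Combined ANOVA and assumption checks

The model is Y_ijk = μ + E_i + B_k(E_i) + G_j + GE_ij + e_ijk on a balanced
g×e×b randomized complete block MET. Sums of squares are closed-form;
unbalanced tables are rejected with the missing cells named, not imputed,
because every df and expected mean square used downstream assumes balance.
Environments are tested against the replication-within-environment mean
square (blocks nested in environments are the environment-stratum error in
an RCBD MET); genotype and interaction are tested against the plot
residual. Normality is checked by Shapiro–Wilk on plot residuals and error
homogeneity by Levene's test (mean-centered) across environments. LSD mean
separation uses LSD = t(1−α/2, df_e)·√(2·MSE/r) with letters assigned from
the largest mean; candidate letter groups nested in an earlier group are
dropped, which makes the display exactly equivalent to all pairwise
comparisons.

## REML variance components and BLUP

For a balanced design the restricted likelihood of the mixed model
(G, GE random; E and B(E) fixed) factors into independent chi-square
strata, one per ANOVA line, with stratum eigenvalue equal to that line's
expected mean square:

    λ_G  = σ²res + b·σ²GE + e·b·σ²G      (df g−1)
    λ_GE = σ²res + b·σ²GE                (df (g−1)(e−1))
    λ_e  = σ²res                         (df e(b−1)(g−1))

REML therefore reduces to maximizing −½ Σ_s [df_s·log λ_s + SS_s/λ_s] over
the non-negative components, done by L-BFGS-B from the method-of-moments
start plus two deterministic scaled restarts. This is the exact REML
optimum for balanced data (the only kind accepted upstream), runs in
milliseconds, and yields honest restricted log-likelihoods for the
likelihood-ratio tests of G and GE (χ²₁; an optional boundary correction
halves the p-value). A fully-random variant (E and B(E) random too, five
strata) supplies the environment component for the variance-proportion
report, computed over (E, G, GE) and normalized to 100%.

Derived summaries are on the genotype-mean basis: δP² = σ²G + σ²GE/e +
σ²res/(eb), hmg² = σ²G/δP², accuracy = √hmg², R²GE = σ²GE/(σ²G+σ²GE+σ²res),
and the genotypic correlation across environments r_GE = σ²G/(σ²G+σ²GE).

BLUPs on balanced data are closed-form: the genotype BLUP is the centered
genotype mean shrunken by hmg², and the BLUP of the double-centered
interaction is the cell-mean interaction residual shrunken by
b·σ²GE/(b·σ²GE + σ²res). The latter is the matrix the WAASB stage
decomposes; it is defined on the double-centered interaction subspace, so
every entry is no larger in magnitude than the corresponding fixed-effect
interaction residual, and it vanishes as σ²GE → 0.

## AMMI, WAASB, WAASBY

AMMI double-centers the g×e cell-mean table and decomposes it by SVD. The
k-th component explains EP_k = 100·λ_k²/Σλ² percent of the interaction and
is tested with Gollob's approximate F: df_k = g + e − 1 − 2k, SS_k reported
on the plot-level scale (r·λ_k²) so component mean squares are directly
comparable with the ANOVA residual. IPC scores carry the singular values
(u·λ, v·λ) with a deterministic sign convention (largest-|score| genotype
positive per axis).

WAASB_i = Σ_k |IPCA_ik|·EP_k / Σ_k EP_k over all P = min(g−1, e−1)
components of the BLUP interaction matrix — using all components rather
than only the Gollob-significant ones, since the index's purpose is to
integrate the whole interaction variance (a significant-only variant is a
one-line filter on the inputs). WAASBY rescales genotype means to 0–100
(best = 100) and WAASB to 0–100 (most stable = 100) and blends them with
weights θY/θS (default 50/50). A degenerate range (all values equal)
rescales to 100 with a flag. Biplot quadrants classify genotypes and
environments by (mean vs grand mean) × (WAASB vs WAASB mean); points
exactly on a boundary go to the higher-yield / lower-WAASB side.

The stability stages run only for traits whose GE interaction is
significant in the combined ANOVA (α = 0.05 by default), mirroring standard
MET practice; skipped traits are logged.

## Factor analysis and MTSI

The genotype×trait input matrix uses, per trait, the WAASBY score when the
trait's GEI is significant and the goal-oriented 0–100 rescaled genotype
mean otherwise, so every column is oriented "higher is better". Factors of
the trait correlation matrix with eigenvalue > 1 are retained (at least
one), the loading matrix is varimax-rotated with a deterministic sign
convention, communalities are the rotation-invariant row sums of squared
loadings, and genotype scores use the regression method B = R⁻¹Λ. The ideal
genotype holds the best observed value of every trait given its goal and is
projected through the same regression weights — projection rather than
per-factor score extrema, so the ideal lives in the same score space as the
genotypes. MTSI_i is the Euclidean distance of genotype i from the ideal
over the retained factors; ranking is ascending and round(pressure·g)
genotypes are selected (pressure default 0.25; exact MTSI ties, which have
measure zero, fall back to the stable sort by genotype identifier).
Selection differentials are SD% = 100·(selected mean − grand mean)/grand
mean on the original trait scale and SG% = SD%·h² with h² the mean-basis
hmg² (for bolting, estimated from the bolting-scored environments only).
Per-factor contributions to MTSI² are (γ_if − γ*_f)²/MTSI_i²; a genotype
exactly at the ideal gets uniform shares with a flag.

## Synthetic data

The generator reproduces the statistical features the pipeline consumes,
not any particular meteorology or trial:

* **Weather** — daily midpoints follow an annual sinusoid (default mean
  18 °C, amplitude 12 °C, coldest day mid-January) plus Gaussian noise
  (sd 2 °C), with a fixed diurnal range of 10 °C, 270 days from October 1.
  This delivers a winter with thousands of hours in the 0–13 °C window and
  a spring with devernalizing days above 23 °C. Site/year climate shifts in
  the study bundle are chosen so the bolting-scored environments deliver
  ≈85–167 vernalizing hours: bracketing the simulated thresholds
  (107–134 h, the plausible range for a diverse hybrid panel) with at least
  two intensity levels above the highest threshold, which is what makes the
  breakpoint identifiable, while staying below the 100% bolting ceiling.
* **Trials** — balanced g×e×b phenotypes (defaults 12×6×4) with effect
  vectors drawn iid Gaussian then centered and rescaled so the df-adjusted
  empirical variance equals the configured σ² exactly. This variance
  control makes expected mean squares hold per draw, so recovery studies
  measure estimator behaviour rather than generator sampling noise. The GE
  interaction is a rank-r bilinear product of Gaussian factors (default
  r = 2) scaled so its total sum of squares is g·e·σ²GE; by orthogonal
  invariance every ANOVA stratum then receives the same expected share an
  iid interaction would, which keeps all REML components unbiased. An
  exactly double-centered variant (`center_gei=True`) is available for
  studying sum-to-zero interactions; note that with it the genotype-mean
  stratum no longer contains an interaction share, so σ²G estimated under
  the standard model is low by σ²GE/e by construction.
* **Bolting** — expected percentage clamp(b·(x−VT), 0, 100) realized as a
  binomial draw on n_plants = 100 per plot (plant counts per plot at
  scoring are an assumption; bolting is scored by counting plants, so the
  noise is binomial, with the Gaussian alternative available through the
  trial generator for regression tests).

What the synthetic data do **not** emulate: real station meteorology
(autocorrelated weather, heat waves), unbalanced or missing plots, spatial
field trends, non-Gaussian trait errors, or genetic correlation between
traits (trait tables are generated independently). Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those departures.

## Numerical choices and problem sizes

Grid search for VT uses 0.1 h resolution with the right edge always
included; refinement can only decrease SSE. REML optimizes variances
directly (bounds [0, ∞)) with a large finite penalty for non-positive
stratum eigenvalues so numerical gradients stay defined. The acceptance
script uses 100 replicates for threshold recovery, 500 null replicates for
F-test calibration and 200 replicates for REML recovery — sizes at which
the Monte-Carlo standard errors are several times smaller than the effects
being checked — and completes in well under a minute.

## Known limitations

* The accumulation model is purely thermal: no photoperiod term, no soil
  temperature, no rollback devernalization.
* The biphasic fit reports no standard errors for VT or the slope; the
  recovery simulations quantify typical error instead.
* All MET machinery requires balance; missing plots must be handled before
  entry.
* LRT p-values at the variance boundary are conservative without the
  optional ½-point-mass correction.
* The factor-analysis stage assumes a non-singular trait correlation
  matrix; perfectly collinear traits must be dropped first.
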