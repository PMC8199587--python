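# Methods

This note documents the models and numerical choices behind `nmrfp`: what the
synthetic cohort generator simulates and why, how each analysis stage is
defined, and what the tests do and do not establish about real data.

## 1. Synthetic cohort generator

### Study design emulated

Three patient groups with default sizes 65 (relapse-free early CRC, eCRC),
29 (relapsed eCRC) and 75 (metastatic CRC, mCRC).  Each subject carries true
concentrations for 32 named serum signals, three simulated spectra (NOESY 1D,
CPMG, diffusion-edited), clinical covariates, and survival endpoints.

### Concentrations and effect-size calibration

Concentrations are log-normal (biological positivity; multiplicative
variation).  The log-scale SD equals `concentration_cv` (default 0.25, a
typical biological CV for serum metabolites).  Group differences are imposed
as location shifts on the log scale, calibrated from the target signed
Cliff's delta by the closed form

    shift = √2 · σ · Φ⁻¹((δ + 1) / 2),

which is exact for two equal-variance normals; because Cliff's delta is
invariant under monotone transforms, the calibration transfers exactly to the
log-normal concentrations.  Default deltas: glutamine +0.330, histidine
+0.280, formate −0.212, the remaining 29 between −0.163 and +0.168; a
positive delta means lower levels in metastatic serum.  A relapsed eCRC
subject draws from the metastatic-like distribution with probability
`relapsed_metastatic_fraction` (default 0.95) and otherwise from the
relapse-free distribution.  The 0.95 default is fixed by the observed
contingency structure of such cohorts: with a classifier operating near
71 % sensitivity / 70 % specificity, a latent fraction near 0.95 reproduces
both the ~69 % projection rate of relapsed patients and the high/low risk
group composition (≈20+20 high, ≈9+45 low); a latent fraction equal to the
projection rate itself would predict only ~58 % projected metastatic.

### Spectra

Each signal is a sum of area-normalized Lorentzian peaks at standard serum
chemical shifts (fixture data in `data/signatures.yaml`); peak areas are
proportional to concentration × relative height, so window integrals are
linear in concentration.  Pulse-sequence selectivity is modelled by
weight-class attenuation: NOESY keeps both classes at 1.0; CPMG attenuates
macromolecules ×0.1; diffusion editing attenuates small molecules ×0.1.

Beyond the 32 quantifiable signals the generator adds an *unresolved
background* of 250 fixed small peaks (positions, widths, base areas and
weight classes are reproducible constants; per-sample abundances are
log-normal with the same CV).  This background serves two documented
purposes.  First, realism of the variance structure: real binned serum
spectra have biological variance in every bin, and without the background the
eigenvalue spectrum of the binned matrix is so sparse that the 99.9 %
variance rule truncates the informative low-variance bins.  Second, the
background carries a diffuse disease component (per-signal deltas drawn once
from N(0, `background_effect_sd`), applied to metastatic-like samples): a
serum fingerprint discriminates better than the sum of its quantified
metabolites, because unassigned and overlapping signals also co-vary with
disease.  The single scale `background_effect_sd` (default 0.15) was
calibrated once so that the default cohort's NOESY LOOCV accuracy sits at
the ~70 % operating point such studies report; it was not tuned per test.
Background peaks avoid the 32 quantification windows (margin 0.03 ppm) —
the panel signals are precisely those whose regions are resolvable — and
follow a realistic density (85 % in the aliphatic/carbohydrate region
0.6–4.4 ppm, sparse downfield).

Nuisances: residual water (broad Lorentzian at 4.70 ppm, amplitude ~2 —
metabolite-scale, as appropriate for presaturation); a sporadic ethanol
triplet/quartet (1.17/3.65 ppm) in a random 20 % of samples; a rigid ppm
miscalibration N(0, 0.01 ppm) per acquisition; a multiplicative dilution
factor LogNormal(0, 0.1) per sample (shared across its three spectra); and
additive Gaussian noise (SD 0.5 intensity units) per point.  The glucose
anomeric doublet (5.2369/5.2431 ppm, J ≈ 3.8 Hz at 600 MHz) merges into a
single apex at 5.240 ppm, which the calibration step targets.

The generator does **not** simulate: time-domain effects (phase/baseline
error, line-shape distortions), J-coupling fine structure, chemical-shift
dependence on pH/ion content (peak positions are fixed), inter-metabolite
physiological correlations within a group, or batch effects.  Passing tests
therefore demonstrate correctness of the pipeline's statistics under a
faithful but idealized spectral model, not robustness to all real-world
artifacts.

### Survival model

Relapse is exponential with hazard `baseline_hazard ·
exp(log_hr_high_risk · latent + log_hr_stage_iii · [stage III])`; other-cause
death and post-relapse cancer death are independent exponentials;
administrative censoring closes follow-up at 60 months.  Defaults:
baseline 0.003/month (≈17 % 5-year relapse in the low-risk stratum),
log-HR ln 3.6 for the latent score, ln 3.0 for stage III, other-cause death
0.003/month, post-relapse death 0.03/month (≈23-month median post-relapse
survival).  Endpoints: RFI (relapse, censored at death/end of follow-up),
DFS (relapse or death), CSS (cancer death, defined only after an observed
relapse), OS (any death).  Because group membership is part of the design
(relapsed subjects must relapse), survival records are redrawn until
consistent with the assigned group; this conditions the event-time
distribution slightly but preserves the hazard structure the recovery tests
estimate on unconditioned draws.

Clinical covariates (stage, grade, nodal status, localization, adjuvant
chemotherapy) are drawn from distributions conditional on the latent score,
so that stage is a genuine confounder of the metabolomic risk label — the
situation the stepwise Cox demo must untangle.

## 2. Analysis pipeline

**Binning.** Bins are half-open `[lo, hi)` ascending (last bin closed);
integration is exact trapezoidal on the piecewise-linear spectrum, so values
are grid-resolution robust and linear in intensity.  The exclusion windows
(water 4.50–5.15; ethanol 1.10–1.25 and 3.60–3.70; edge trims 0.20–0.30 and
9.00–10.00 ppm) live in `data/binning.yaml`, not in code, and remove exactly
40 of 196 bins.  Bins merely touching a window boundary are kept (overlap
test uses a 1e-9 ppm tolerance so float jitter in bin edges cannot flip a
bin).

**Calibration** shifts the axis so the maximum in 5.24 ± 0.1 ppm lands on
5.24.  Window-argmax is adequate at the fixture linewidths (the merged
doublet apex is unimodal); a fitting-based calibrator would be needed for
resolved doublets.  A flat or empty window leaves the spectrum unshifted
with a warning.

**PQN.** Reference = element-wise median over all training rows after
area-normalization (`median_all`); the fitted reference is reused for
projection, preventing leakage.  Outputs stay on the unit-total-area basis:
a data-dependent rescale would break the exact scale-invariance
(`pqn(c·x) = pqn(x)`) and idempotence of the transform.  The report records
both the median-quotient factor and the overall per-row divisor.

**PCA–CA–kNN.** Covariance PCA (bins share units; no autoscaling) retains
the smallest leading set of components reaching 99.9 % cumulative variance.
Canonical analysis for two classes reduces to the Fisher discriminant
`a ∝ W⁻¹(μ₁ − μ₀)` (the rank-one between-class scatter makes the leading
eigenvector of `W⁻¹B` proportional to it); the axis is scaled to unit pooled
within-class variance and oriented with the metastatic mean positive.  A
singular within-class scatter raises with advice to lower the variance
threshold.  kNN uses k = 9 (odd — no vote ties for two classes), Euclidean
distance on the canonical score, distance ties broken by the smaller
training index.  LOOCV refits the entire chain per fold; this is the only
leakage-free reading and is verified by a test that corrupts the held-out
row and checks the fold model is bit-identical.  For permutation nulls the
label-independent per-fold PCA scores are cached and only CA/kNN are refit —
numerically identical to the naive loop.

**Univariate screen.** Wilcoxon rank-sum uses the normal approximation with
mid-ranks, tie-corrected variance and continuity correction (adequate at
group sizes 65/75; degenerate all-tied input returns p = 1).  BH adjustment
is the standard step-up with monotonicity enforcement.  Cliff's delta is
computed by sorted rank counting (O((n+m) log m)).  Median-threshold
accuracy uses the pooled median; with positive delta (lower in mCRC) values
at or below the threshold are called metastatic — ties side with the
metastatic call, affecting at most one sample for odd pooled n.  Window
integration attenuates effect sizes relative to the true concentrations
(tail overlap from neighbouring signals; e.g. glutamine ~0.27 observed vs
0.33 true), so the significance-pattern tests are run on true
concentrations, where the calibration is exact; the spectral path is tested
for proportionality (r² against known concentrations) instead.  At
n = 65/75 with 32-test BH correction, a delta of 0.33 yields an adjusted
p that straddles 0.05 (P(adj p < 0.05) ≈ 0.6 per cohort) — per-cohort
significance of even the strongest metabolite is not guaranteed, which is
worth remembering when interpreting single-cohort univariate tables.

**Survival.** Kaplan–Meier, log-rank, reverse-KM and Cox estimation are
delegated to `lifelines`; the module fixes conventions: Greenwood variance
computed from the event table; reverse-KM returns ∞ when the flipped curve
never crosses 0.5; Cox fits use Efron tie handling (lifelines' method) on
complete cases with the complete-case n always reported; Wald CIs
`exp(β ± 1.96 SE)`.  Stepwise selection is bidirectional — forward entry by
smallest Wald p < 0.05, backward pruning of any retained covariate with
p ≥ 0.05 after each entry — deterministic with ties broken by candidate
order.  Contrasts follow clinical convention: stage III vs I–II, grade 3 vs
1–2, right-sided vs left/rectum, no adjuvant vs adjuvant.

## 3. Problem sizes used by tests and the acceptance script

Chosen to keep the full suite within a normal CI budget while leaving
comfortable statistical margins: effect-size calibration at n = 2000/group
(all 32 signals within ±0.05) and n = 1000/group for the glutamine recovery
(±0.08; sampling SE ≈ 0.026); Cox hazard-ratio recovery as the mean over
8 replicates of n = 500/arm (single-replicate SE ≈ 0.13 would make a
point check at ±0.15 a coin flip; the mean has SE ≈ 0.05); permutation null
with 200 label permutations of the 140-sample cohort; FDR control over 100
all-null cohorts; the end-to-end demo over 20 seeds using the NOESY
spectra (the headline model).

## 4. Known limitations

- Canonical scores are one-dimensional for two classes; score "plots" are a
  strip, not a plane.  A residual-PC axis is used purely for display.
- The window-argmax calibrator fails on spectra whose glucose region is
  overwhelmed by another signal; no doublet-shape verification is done.
- lifelines provides Efron tie handling only; no Breslow cross-check.
- Stepwise selection inherits the usual caveats (no multiplicity control;
  with three null candidates the chance of a spurious entry at p = 0.05 is
  ~14 %); the tests therefore exercise the empty-model path at a stricter
  threshold.
- The generator's latent disease structure is a single binary factor;
  real metabolomic heterogeneity is continuous and multi-factorial.
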