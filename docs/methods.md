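# Methods

## Signal model and partial-volume correction

The control image of a background-suppressed pCASL acquisition is modeled
as a pure tissue mixture, `control(v) = Σ_t p_t(v)·m_t`, over t ∈ {GM, WM,
CSF}, where p_t are posterior tissue probabilities on the ASL grid and m_t
are tissue magnetizations in scanner units. The control − label difference
carries perfusion signal from GM and WM only; CSF is not perfused, so the
difference regression uses two regressors.

PVEc solves these mixtures by windowed ordinary least squares at every
brain voxel. Choices, and why:

- **Kernel 7 × 7 × 1 voxels.** In-plane only: with a 2-D readout each slice
  has its own effective post-labeling delay, and an in-plane kernel keeps
  every regression sample at a single PLD, so the estimated dm_t is a pure
  kinetic amplitude rather than a mixture of decay states.
- **No intercept.** The mixture model has none; a free intercept would
  absorb tissue signal and bias m_t downward.
- **Brain mask at 30% total tissue.** Voxels with p_GM + p_WM + p_CSF <
  0.30 are excluded from both the regression windows and the outputs.
- **Edge handling.** Windows are truncated at the volume boundary and
  restricted to masked voxels; no padding or reflection.
- **Rank deficiency.** A window of (nearly) pure tissue cannot identify the
  other coefficients. The solver returns the minimum-norm least-squares
  solution (pseudo-inverse of the window Gram matrix, relative cutoff
  1e-12) and flags the voxel invalid when the Gram condition number
  exceeds 1e6 or the window holds fewer than p + 1 masked voxels.
  Invalid voxels are excluded from ROI averages, so pure-tissue
  neighborhoods cannot poison regional means.
- **Mean-then-regress.** The 60 control frames and 60 pair differences are
  averaged before regression. For OLS with a fixed design this equals the
  average of per-pair regressions; averaging first is faster and
  deterministic in memory order.
- **Negative coefficients are retained** by default (clipping is an
  option). Retention keeps downstream ROI means unbiased under noise.

## Kinetic quantification

CBF is obtained from the tissue-specific ratio dm_t/m_t with the
single-compartment model

    CBF = 6000·λ·(ΔM/M0)·exp(PLD/T1b) / (2·α·T1b·(1 − exp(−LD/T1b)))

(times in seconds; output in ml·100 g⁻¹·min⁻¹; the factor 6000 converts
ml·g⁻¹·s⁻¹). Defaults, configurable in `AcqParams`:

| parameter | default | unit | rationale |
|---|---|---|---|
| LD | 1950 | ms | long labeling to cover prolonged arterial transit in carotid disease |
| PLD₀ | 1200 | ms | first-slice post-labeling delay |
| slice_dt | 70 | ms | per-slice delay increment of the 2-D EPI readout |
| α | 0.70 | – | labeling efficiency with background-suppression losses folded in |
| T1b | 1650 | ms | arterial blood T1 at 3 T (consensus value) |
| λ | 0.9 | ml/g | blood–brain water partition coefficient (consensus value) |

Each voxel uses the PLD of its own slice, `PLD(s) = (s − 1)·slice_dt +
PLD₀` with 1-based slice numbering on the third axis (slice 10 → 1830 ms).
Background-suppression pulses are not modeled kinetically; their signal
cost is treated as folded into α. Voxels with invalid PVEc or |m_t| below
1e-6 of the masked median |m_t| are undefined (NaN), never infinite. No
outlier rejection is applied across pairs.

ROI summaries are unweighted means of GM CBF over ROI voxels that are
PVEc-valid, quantifiable, and have p_GM ≥ 0.30 (mirroring the brain-mask
threshold; PVEc output is already tissue-pure, so probability weighting is
unnecessary and offered only as an option). Occluded/unoccluded labels are
assigned from the subject's side of occlusion, never from anatomy.

## The phantom

The digital phantom emulates what the pipeline needs and nothing more:

- two mirrored hemisphere "blocks" (CSF rim, 2-voxel GM ribbon, WM core,
  central CSF ventricle) separated by an interhemispheric fissure wide
  enough that no masked 7 × 7 window bridges hemispheres;
- smooth probability maps: in-plane Gaussian smoothing (SD 0.8 voxel) of
  the label geometry plus a seeded smooth ±5% perturbation, normalized so
  the tissue sum never exceeds 1. Mid-ribbon and core regions are nearly
  pure tissue (exercising the rank-deficiency path at zero smoothness),
  boundary regions are well-conditioned mixtures;
- constant truth flows f_GM = 60, f_WM = 20 ml·100 g⁻¹·min⁻¹ (textbook
  values) with a multiplicative GM deficit (default 0.9) on the occluded
  side, and magnetizations m_GM:m_WM:m_CSF = 100:70:120 arbitrary units
  (plausible proton-density ordering);
- 60 control/label pairs with i.i.d. Gaussian noise per voxel per frame
  (default SD 5, i.e. 5% of the GM control signal — a typical EPI temporal
  SNR of ~20), difference signal generated per slice through the same
  kinetic forward model the quantifier inverts;
- mirrored M1 (anterior GM ribbon) and V1 (posterior GM ribbon) masks on
  slice 10, so left/right voxel counts are equal by construction.

Because the forward model and the quantifier are exact inverses, a
noiseless run must recover the truth flows voxelwise to machine precision
wherever the regression is valid — the pipeline's strongest structural
check. What the phantom does **not** emulate: motion, distortion, vascular
artifacts, arterial-transit-time heterogeneity, multi-delay readouts, or
realistic cortical folding. Passing phantom tests therefore validates the
algorithmic chain, not robustness to real-world MR artifacts.

At the default noise level the per-voxel dm_GM estimates are individually
noisy (median relative error ≈ 0.33 in high-GM voxels — the per-pair
difference SNR is below 1), but the estimator is unbiased: the ROI-mean GM
CBF averaged over repeated noise realizations is within ~1–2% of truth
(estimated over 150–400 realizations; single realizations scatter ±~30%).

## The synthetic cohort

`CohortSimConfig` encodes the effect structure the statistics must
recover: M1 cortical thickness depends linearly on same-side M1 GM CBF
(default 0.003 mm per ml·100 g⁻¹·min⁻¹) and age (−0.0042 mm/yr) with
residual SD 0.095 mm, giving population correlations of 0.50 (CBF) and
−0.35 (age); V1 thickness depends on neither. Regional CBF has a shared
subject-level component (SD 15) plus a region component (SD 13), an
occluded-side deficit (M1: 9.7, V1: 6.4 ml·100 g⁻¹·min⁻¹) and
within-subject side noise chosen so the paired asymmetry tests have the
strength typical of this design (M1 strongly significant, V1 marginal).
Hemispheral CBF is the average of the regional values plus noise (SD 12),
keeping its univariate association with thickness just below the
screening threshold on average. Covariate margins at n = 28 are fixed
(21 hypertensive, 6 diabetic, 14 complete occlusions, 14 left-sided,
15/6/7 collateral categories) and permuted per seed. Mean thickness
levels: M1 2.07/2.15 mm, V1 1.78/1.80 mm (occluded/unoccluded).

## Cohort statistics

- Paired t-tests (occluded vs unoccluded) with Bonferroni control over the
  two regions: two-sided significance at p < 0.025. Zero-variance
  differences with zero mean return t = 0, p = 1 (a well-defined "no
  difference", not an error).
- Univariate Pearson screening at p ≤ 0.05 (inclusive), then OLS on
  z-scored variables; standardized betas with classical t p-values.
  Designs with condition number > 1e8 raise an error naming the collinear
  columns.
- GEE: identity link, Gaussian family, exchangeable working correlation
  over two-row subject clusters, robust sandwich SEs. Exchangeable is the
  natural minimal structure for paired hemispheres; independence is
  available and reduces to OLS point estimates on singleton clusters.
  Unknown collateral status is kept as a third category rather than
  dropped, preserving the full cohort in the GEE.
- All analyses are complete-case; subjects flagged for missing ASL data
  are excluded from every CBF-involving fit.
- Ties in the asymmetry-direction count go against the expected direction
  (conservative).

## Problem sizes

Tests and the acceptance script use a 32 × 32 × 12 phantom (≈ 6,200 brain
voxels), 60 pairs, 150–300 noise realizations for bias estimates, and
150–200 independent n = 28 cohorts for pattern-frequency estimates; the
full suite runs in well under a minute of compute for the imaging parts
and a few tens of seconds for the repeated-cohort statistics.

## Known limitations

- With 28 clusters, sandwich-variance GEE p-values are anti-conservative
  (per-test type-I rate ≈ 8–12% at nominal 5%). Consequently the joint
  qualitative pattern (both M1 effects significant, both V1 effects null,
  paired asymmetry significant) is recovered in only ≈ 65% of synthetic
  cohorts at these effect sizes: the two V1 null checks alone cap the
  attainable frequency below 95%, and the M1 age effect (population
  r = −0.35) has ≈ 85–90% power in the GEE at n = 28. This is a property
  of the design, not of the implementation; no small-sample covariance
  correction is applied.
- Single-delay ASL cannot separate flow from arterial transit time; all
  quantified CBF is a combined flow-plus-transit effect, and the phantom
  inherits that identification limit by construction.
- The Gram-matrix condition threshold (1e6) is a heuristic boundary
  between "usable" and "unstable" windows; values near the threshold can
  flip validity under tiny probability perturbations.
- The .sav cohort dialect requires the optional pyreadstat backend and a
  user-supplied column mapping; only the CSV path is exercised by tests.
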