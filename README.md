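# perfcortex

Partial-volume-corrected pCASL perfusion quantification and hemispheric
cortical-thickness statistics for unilateral carotid occlusive disease.

## The problem

In patients with high-grade unilateral internal-carotid stenosis or
occlusion but no stroke, the cortex tends to be thinner on the side of the
occlusion, and reduced resting gray-matter (GM) perfusion is a candidate
mechanism. Testing that association requires (i) quantitative regional GM
cerebral blood flow (CBF) from single-delay pseudocontinuous arterial spin
labeling (pCASL) despite the coarse ASL voxel (here 3.5 × 3.5 × 8 mm³)
mixing GM, white matter (WM) and CSF, and (ii) cohort statistics that
respect the paired two-hemisphere structure of the data.

`perfcortex` implements that analysis as a reusable, fully testable
pipeline. A built-in digital ASL phantom and synthetic-cohort generator
provide inputs with known ground truth, so every stage — including the
statistics — can be validated without any patient data.

## The model

**Partial-volume correction (PVEc).** Each voxel's signal is modeled as a
mixture weighted by tissue posterior probabilities. Within a 7 × 7 × 1
window centered on each brain voxel (total tissue probability ≥ 30%), the
mean control image is regressed on (p_GM, p_WM, p_CSF), giving tissue
magnetizations m_GM, m_WM, m_CSF, and the mean control − label difference
image on (p_GM, p_WM) — CSF carries no perfusion signal — giving the
perfusion-weighted components dm_GM, dm_WM. No intercept is used; windows
with rank-deficient designs are flagged invalid.

**Kinetic quantification.** Tissue-specific CBF follows the standard
single-compartment pCASL model,

    CBF = 6000 · λ · (ΔM/M0) · exp(PLD/T1b) / (2 α T1b (1 − exp(−LD/T1b)))

in ml·100 g⁻¹·min⁻¹, with labeling duration LD = 1950 ms, labeling
efficiency α = 0.70, λ = 0.9 ml/g, T1b = 1650 ms, and a per-slice
post-labeling delay PLD(slice) = (slice − 1)·70 ms + 1200 ms for the 2-D
readout (slice 10 → 1830 ms).

**Statistics.** GM CBF is averaged over motor-cortex (M1, carotid
territory) and visual-cortex (V1, posterior circulation) ROIs per
hemisphere. Paired t-tests compare occluded vs unoccluded sides
(Bonferroni over the two regions, two-sided p < 0.025); univariate Pearson
correlations screen candidate predictors of cortical thickness (p ≤ 0.05)
for a standardized multiple regression; and a generalized estimating
equation (identity link, exchangeable working correlation, robust SEs)
models thickness with both hemispheres per subject.

## Worked example

```python
from perfcortex import (AcqParams, CohortSimConfig, pvec_correct, quantify_volume,
                        roi_mean_cbf, simulate_cohort, simulate_phantom, stats_report)

acq = AcqParams(noise_sd=0.0)               # noiseless phantom
ph = simulate_phantom(acq=acq, seed=0)      # 32x32x12 grid, GM deficit ×0.9 on the left
res = pvec_correct(ph.control4d, ph.label4d, ph.probmaps)
cbf = quantify_volume(res, acq)
occ, unocc = ph.atlas.by_side("M1", ph.side_occluded)
print(roi_mean_cbf(cbf, occ, ph.probmaps).mean_cbf,
      roi_mean_cbf(cbf, unocc, ph.probmaps).mean_cbf)

rep = stats_report(simulate_cohort(CohortSimConfig(seed=0)))
```

This prints ROI means `54.0` and `60.0` ml·100 g⁻¹·min⁻¹: the pipeline
recovers the phantom's ground-truth GM flow (60, with the 0.9 occluded-side
deficit) exactly in the noiseless case. The cohort report on the default
synthetic 28-subject cohort gives

```
M1 CBF occluded vs unoccluded: 104.2 vs 114.2, t(27) = -7.99, p = 1.4e-08
CBF asymmetry in expected direction: 26/28 (93%)
GEE (M1 thickness): p(rCBF) = 1.2e-05, p(age) = 0.0023
GEE (V1 thickness): p(rCBF) = 0.91, p(age) = 0.63
```

i.e. flow is lower on the occluded side, and regional CBF and age predict
M1 — but not V1 — cortical thickness, the effect structure the generator
encodes.

The same pipeline is available from the shell and composes through JSON
manifests:

```bash
perfcortex simulate --seed 1 --out sim/
perfcortex pvec     --manifest sim/manifest.json --out pv/
perfcortex quantify --manifest pv/manifest.json  --out q/
perfcortex roi      --manifest q/manifest.json   --out roi/
perfcortex stats    --cohort sim/cohort.csv      --out report.json
```

## Layout

- `perfcortex.io` / `perfcortex.grids` — NIfTI volumes, cohort tables, manifests
- `perfcortex.phantom` — digital ASL phantom and synthetic cohorts
- `perfcortex.pvec` — brain mask and local-regression partial-volume correction
- `perfcortex.quantify` — kinetic model and per-slice PLD adjustment
- `perfcortex.roi` — ROI means, paired tests, asymmetry counts
- `perfcortex.stats` — correlations, standardized OLS, GEE, full report
- `perfcortex.cli` — `perfcortex` command-line front end

See `docs/methods.md` for modeling assumptions, parameter choices and
known limitations.
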