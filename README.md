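# v2qstripes

Quantitative-MRI comparison of cytochrome-oxidase stripe types in human
secondary visual cortex (V2), built as a tested, fully synthetic-data-capable
analysis package.

## The scientific problem

V2 is tiled by repeating **pale–thin–pale–thick** stripe cycles (≈8 mm cycle
in humans — roughly double the macaque dimensions). Thin stripes are
color-selective and thick stripes disparity-selective, so both can be mapped
with high-resolution fMRI; pale stripes cannot be mapped functionally and are
inferred under a tripartite-architecture assumption. The question: do
functionally defined thin/thick stripes carry different myelination than the
pale-containing surround? Myelin is probed with the longitudinal relaxation
rate **R1** (and R2\*, PD) from a dual-flip-angle multi-echo FLASH protocol.

The core statistic, per hemisphere and ROI threshold *z*:

1. Residualize: `r = R1 − mean_V2(R1)`, then regress out local curvature
   (`r ~ β0 + β1·curv`, OLS over V2) and keep the residuals.
2. ROIs: `thin = {z_color ≥ z} \ {z_disp ≥ z}`, `thick` symmetrically;
   vertices supra-threshold in both contrasts are discarded.
3. Statistic: `d_thin = mean_w(r | thin) − mean_w(r | V2 \ {z_disp ≥ z})`
   (area-weighted), `d_thick` symmetrically; pooled as the unweighted mean
   over hemispheres.
4. Inference: ROIs are rebuilt on **variogram-matched surrogate maps**
   (spatial-autocorrelation-preserving permutations) `n` times; with `k`
   null values at least as extreme as the observed statistic, the p-value is
   inflated by three binomial standard deviations,
   `p = min(1, (k + 3σ)/n)`, `σ = √(n p̂ (1−p̂))`, `p̂ = max(k,1)/n`.

Supporting computations: the exact FLASH steady-state signal
`S = A sinα (1−E1)/(1−cosα·E1) e^(−TE·R2*)` with `E1 = e^(−TR·R1)`; the
shared-decay log-linear R2\* fit across both contrasts (ESTATICS); the
rational short-TR dual-flip-angle R1/A estimate with B1+ flip-angle
correction; PD calibration to 69 pu over white matter and MTVF = 100 − PD;
the equi-volume depth fraction
`x = (−A_w + √((1−ν)A_w² + ν A_p²)) / (A_p − A_w)`; and phase-encoded
retinotopy (percent signal change, discrete-cosine high-pass at
1/(3·period), first-quarter-cycle discard, opposite-direction complex
combination to cancel the hemodynamic delay, foveal exclusion of the inner
third of the phase cycle).

Everything runs on a synthetic cohort: flat V2 patches with ground-truth
stripe labels, spatially autocorrelated activation z-maps, and qMRI maps
whose stripe offsets are calibrated so the ideal-label statistics equal
−0.005 s⁻¹ (thin) and −0.014 s⁻¹ (thick) at a V2 baseline R1 of 0.58 s⁻¹
and an 11.3% coefficient of variation.

## Worked example

```python
from v2qstripes.cohort import CohortConfig, paper_effect_mode, generate_cohort
from v2qstripes.stripestats import prepare_hemisphere_maps, permutation_test

cfg = paper_effect_mode(CohortConfig(patch_width_mm=24, patch_height_mm=12,
                                     spacing_mm=0.8, seed=1))
cohort = generate_cohort(cfg)              # 4 subjects x 2 hemispheres
hemis = prepare_hemisphere_maps(cohort)    # residualized R1 + ROI inputs
res = permutation_test(hemis, threshold=2.0, n=300, seed=1)
print(res["thick"].observed, res["thick"].p_corrected)
```

Running the equivalent driver `python analysis/04_stripe_inference.py
--seed 1 --n-perm 300` prints (excerpt):

```
 threshold   d_thin  d_thick  p_thin  p_thick stars_thin stars_thick
       2.0 -0.00332 -0.01213 0.12275  0.00998                     **
```

i.e. at the z = 2.0 ROI threshold the pooled thick-stripe R1 sits
0.012 s⁻¹ below the pale-containing surround (significant against the
spatial null, `**`: p < 0.01), and the thin-stripe contrast is negative but
not significant at this desk-scale cohort — the thin effect (−0.005 s⁻¹
ground truth) is genuinely harder to detect than the thick one
(−0.014 s⁻¹). Negative contrasts mean the functionally defined stripes are
*less* myelinated than the surround, i.e. pale stripes are the most
myelinated compartment.

The numbered drivers under `analysis/` cover the whole pipeline:
cohort simulation + GIFTI export (01), FLASH forward simulation and
relaxometry refit with the documented approximation-error grid (02),
retinotopy phase recovery and foveal masking (03), the threshold sweep with
permutation inference and figure (04), and between-session reliability with
the spatial null (05). Each writes its tables under `results/`.

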