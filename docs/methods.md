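# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations of `v2qstripes`. It documents what the code computes and
why the open design decisions were resolved the way they were; every number
quoted as a result here is produced by the test suite or the analysis
drivers, not asserted from memory.

## Synthetic cortical patches

The analysis operates on flattened V2, so the generator produces flat 2D
patches directly: a regular triangulated grid (default 32 × 16 mm at 0.4 mm
vertex spacing, 3321 vertices) with barycentric vertex areas and Euclidean
inter-vertex distances standing in for geodesics on the flattened sheet.
The per-vertex "curvature" map is a synthetic confound field — a Gaussian
random field (GRF) with standard deviation 0.15 mm⁻¹ and 3 mm correlation
length, the order of magnitude of cortical mean curvature — linearly coupled
into the qMRI maps (default 0.05 s⁻¹ per mm⁻¹) so that the curvature
regression in the analysis has something real to remove.

GRFs are synthesized by convolving white noise with a Gaussian kernel of
standard deviation ℓ/2 (periodic boundary), which puts the 1/e point of the
autocorrelation at lag ℓ; the field is normalised analytically by the kernel
ℓ2 norm, so the marginal variance is exact rather than per-realization
rescaled. The activation-noise correlation length defaults to 2 mm.

## Stripe geometry and effect calibration

Stripe labels tile pale–thin–pale–thick along one axis with an 8.0 mm cycle,
2.0 mm thin and 2.6 mm thick widths (macaque dimensions doubled); the two
pale bands of a cycle share one width, and band intervals are half-open so
boundary vertices are labelled deterministically. Each hemisphere draws a
random cycle phase so grid discretization averages out across a cohort.

With area fractions a₀ (pale), a₁ (thin), a₂ (thick), mean-centred maps and
ideal-label ROIs, the stripe-versus-rest statistic is linear in the R1
offsets with the cross-term cancelling:

    d_thin  = δ_thin  · [(1 − a₁) − a₁a₂/(a₀ + a₁)]
    d_thick = δ_thick · [(1 − a₂) − a₂a₁/(a₀ + a₂)]

`paper_effect_mode` inverts these to find the offsets δ that make the
ideal-label statistics equal the reference contrasts (−0.005 and
−0.014 s⁻¹); given a concrete label map it uses that map's area-weighted
empirical fractions, so the noiseless round trip is exact to float
precision (verified against a brute-force weighted-mean oracle).

### Activation effect size

The study conditions fix the stripe contrast magnitudes, the R1 baseline
(0.58 s⁻¹) and the R1 noise level (11.3% CV), but not the activation
z-score effect size; it is a free parameter of the emulation. We set the
in-stripe mean to z = 5 (unit-SD GRF noise). The choice is driven by an
error-propagation argument: the recovery experiments threshold at z = 1.96,
and at an in-stripe mean of ~3 the ROIs would be only ~85% sensitive, with
enough thick-stripe leakage into the comparison set to attenuate the
recovered thin contrast by roughly a third — a regime in which the
calibrated contrasts could not meaningfully be recovered. At z = 5 the ROIs
are >99% sensitive and the residual attenuation is dominated by the
irreducible 2.5% false-positive rate of the threshold itself. Session-
averaged differential contrasts at ultra-high field plausibly reach such
peak z-scores. The residual, measured attenuation of the full pipeline is
~6% (ratio 0.94 with R1 noise disabled), so the expected recovered
magnitudes are ≈0.0047 and ≈0.0132 s⁻¹; the acceptance tests assert the
noise-free estimand is within 10% of the calibrated contrast and that noisy
recovery is unbiased about that estimand within Monte-Carlo error.

### Noise calibration

R1 noise is i.i.d. Gaussian with SD = 11.3% of the baseline. The realized
V2 coefficient of variation also carries the stripe offsets and the
curvature coupling, landing near 11.6–11.7% with a mean slightly below
baseline — the generator calibrates the dominant noise term, not the total
CV. R2* (baseline 28 s⁻¹) has a null stripe effect by default, matching the
negative R2* finding; PD (baseline 83 pu, 5% CV) likewise. Both are
configurable for power studies.

## Relaxometry

The forward model is the exact spoiled-FLASH steady state. Fitting follows
the standard multi-parameter-mapping chain:

- **ESTATICS**: one ordinary-least-squares fit per location on log-signals
  with a shared R2* slope and per-contrast TE = 0 intercepts; weights are
  uniform (the plain-OLS reading of the method; weighted variants are out
  of scope). Noiseless data are fit exactly. Locations with non-positive
  signals are flagged invalid and propagated as NaN rather than raised,
  with the invalid count reported.
- **Dual flip angle**: the rational short-TR approximation with angles in
  radians and true angle = B1⁺ efficiency × nominal. Against an exact
  two-point Ernst inversion (implemented only as a test oracle, by
  bisection on the signal ratio), the approximation error at the default
  protocol (TR 25 ms, FA 5°/24°) is 2.15% at R1 = 0.30 s⁻¹ falling
  monotonically to 1.23% at 1.20 s⁻¹ — about 1.7% at the V2 baseline. The
  error grid is written by `analysis/02_fit_relaxometry.py` and frozen in
  the unit tests. The half-angle-tangent variant would be two orders of
  magnitude more accurate but is not what this chain specifies, so it is
  deliberately not used.
- **PD**: the amplitude map is scaled so its white-matter mean equals 69 pu;
  the result is invariant to global amplitude scaling. MTVF = 100 − PD.
  Receive-bias correction is out of scope: synthetic amplitudes are
  generated bias-free, which means the PD path exercises calibration
  arithmetic, not bias-field removal.

B1⁺ maps are taken as already off-resonance-corrected.

## Depth sampling and curvature

The equi-volume depth fraction assumes the cross-sectional area of a
cortical column varies linearly between the white-side and pial-side
one-ring barycentric areas; the closed-form root is used, with the
equi-distant fallback x = ν when the areas agree within a relative ε of
1e−9. Volume conservation holds against numerical integration to 1e−10,
and the fraction is monotone in ν and in the area ratio. The level-set
formulation of the equi-volume model is out of scope at desk scale.

Mesh curvature is the cotangent-Laplacian discrete mean curvature with the
sign taken against the outward vertex normal (sphere of radius R → +1/R
within 0.1% away from poles on a UV test mesh; flat meshes are exactly
zero). Which curvature measure the regression should use was an open
choice; discrete mean curvature is the standard differential-geometric one.

Volume-to-surface sampling uses nearest-neighbour by default (trilinear
optionally), NIfTI RAS world coordinates, 0-based voxel indexing, and
half-open voxel ownership with ties rounding toward the lower index;
out-of-volume vertices are flagged, not raised.

## Surrogate maps and permutation inference

Surrogates preserve spatial autocorrelation by variogram matching: permute
the source map; smooth with an exponentially decaying kernel over the k = 30
nearest neighbours at candidate scales {0.5, 1, 2, 4, 8} mm; regress the
empirical variogram of the source onto the smoothed map's variogram (slope
β clipped at 0, intercept c clipped at 0 before noise injection); output
√β·(smoothed − mean) + √c·white noise + source mean, keeping the scale with
the lowest variogram SSE; finally (by default) replace values by the source
map's order statistics, so thresholding the surrogate sees exactly the
source value distribution. Variograms use 25 equal-width bins up to the
lower quartile of pairwise distances (long-range bins are noisy); empty
bins are excluded from fits. Constant maps pass through unchanged. The
published settings of this class of generator are not recorded anywhere
authoritative, so these defaults are declared choices, validated by
properties: on smooth sources the surrogates beat naive shuffles' variogram
SSE in ≥95% of draws, and on white-noise sources they are statistically
indistinguishable from plain permutation.

The permutation test rebuilds both contrasts' ROIs from surrogates in every
iteration, pools over hemispheres, counts exceedances inclusively (≥, the
conservative reading), and applies the 3σ binomial correction with
p̂ = 1/n substituted at k = 0 so p never reaches zero. Sidedness is
one-sided in the direction of the observed statistic for stripe contrasts
and two-sided for reliability. Iterations in which every hemisphere's ROI
is degenerate are redrawn (counted and reported). Type-I error of the full
pipeline, measured over 500 single-hemisphere null cohorts at 200
permutations and α = 0.05, stays below 0.07 — conservative, as the 3σ
inflation intends; that calibration runs at threshold z = 1.0 on a
16 × 8 mm / 0.8 mm patch (231 vertices) so null ROIs are essentially never
empty and the experiment stays desk-scale.

One spec'd-looking invariant deliberately does not hold: the
overlap-discarded thin/thick ROI sizes are **not** monotone in the
threshold (at low thresholds the discarded overlap is huge), so the sweep
table reports both the ROI sizes and the raw supra-threshold counts, and
only the latter are monotone.

## Retinotopy

Preprocessing converts to percent signal change, removes drifts by
projecting out a discrete-cosine basis below 1/(3 × period) Hz, and drops
the first quarter cycle. The DCT projection (the standard fMRI high-pass)
was chosen over an FIR filter because the runs are short (~132 samples) and
an FIR with an adequate transition band below a 1/192 Hz cutoff would be
longer than the data; on a pure stimulus-frequency sinusoid the projection
gain is 1 within 2%.

Two conventions matter and are easy to get wrong:

- **Conjugate-then-average**: the reverse run's Fourier coefficient is
  conjugated before complex averaging with the forward run. Without
  conjugation the hemodynamic delay does not cancel.
- **Stimulus-locked phase reference**: discarding the first quarter cycle
  shifts the time origin by period/4, adding π/2 to every run's phase;
  `fourier_coefficient` therefore accepts the start-time offset and
  re-references phases to the stimulus clock. Without this the combination
  degenerates at zero delay (the combined amplitude is cos(2πfδ − π/2)).
  With it, delay cancellation is exact to float precision for delays in
  [0, period/4), the quarter-period endpoint being inherently
  amplitude-degenerate.

The foveal mask excludes vertices whose eccentricity phase lies within the
inner third (configurable) of the full cycle from the foveal phase origin
(default 0, configurable).

## Pipeline and reproducibility

All randomness flows from one root seed, split hierarchically
(cohort → subject → hemisphere → stream) via named spawn keys, so adding
subjects never changes existing ones and identical configs are
bit-identical. Run configs serialize to YAML and round-trip losslessly;
every run writes the resolved config, a SHA-based config digest, and a log
with stage timings beside its outputs. Cohorts export as GIFTI (or CSV)
per-vertex maps and surfaces; FLASH stacks as 4D NIfTI.

Desk scales used by the shipped experiments: recovery runs 20–24 cohorts of
4 × 2 hemispheres at the 0.4 mm default geometry; the sweep driver uses a
24 × 12 mm / 0.8 mm cohort with 1000 permutations; the type-I calibration
uses 500 × 200 as above.

## What the synthetic cohort does and does not emulate

It reproduces the statistical structure the inference relies on — periodic
stripe geometry with realistic widths, spatially autocorrelated activation
noise, curvature-coupled qMRI values, calibrated effect and noise
magnitudes, forward-consistent FLASH signals, traveling-wave time series.
It does not emulate: folded 3D cortex (patches are born flat; depth
machinery is exercised on separate synthetic meshes), BOLD hemodynamics
beyond a fixed delay, draining-vein displacement, receive-field bias in PD,
registration/segmentation error, or between-subject variability in stripe
geometry beyond the random cycle phase. Passing tests therefore validate
the estimators and their calibration under the stated model, not robustness
to those real-data nuisances.

## Known limitations

- The dual-flip-angle approximation error slightly exceeds 2% at the low
  end of the cortical R1 range (2.15% at 0.30 s⁻¹); see the error grid.
- Thresholded-ROI selection attenuates recovered stripe contrasts by ~6%
  under the default conditions; the calibration targets the ideal-label
  statistic, not the thresholded estimate.
- The 3σ-corrected permutation p is deliberately conservative; at n = 200
  the effective one-sided rejection level at nominal α = 0.05 is ~2%.
- Reliability uses rank correlation against rank-matched surrogates of one
  session only, mirroring the asymmetric null construction.
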