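# Methods

## The model

`pet4d` studies how much a direct ("4D") parametric reconstruction gains over
the conventional indirect route when dynamic PET data become count-starved.
Both routes estimate the one-tissue-compartment (1TC) model

    C_T(t) = K1 · exp(−k2 t) ⊗ C_p(t),      V_T = K1 / k2,

where `C_p(t)` is the metabolite-corrected arterial plasma input function
(Bq ml⁻¹), `K1` (ml min⁻¹ cm⁻³) the plasma-to-tissue influx rate, `k2`
(min⁻¹) the efflux rate, and `V_T` (ml cm⁻³) the volume of distribution.
Estimation uses the basis-function method: `exp(−k2 t) ⊗ C_p` is precomputed
on a geometric grid of `k2` values (default 500 bases, 0.005–1.0 min⁻¹),
frame-averaged to the acquisition schedule, and each fit reduces to a
weighted linear regression through the origin for `K1` plus a discrete
search over the grid, with ties broken to the smallest `k2` and negative
closed-form `K1` clamped to zero before the SSE comparison. A voxel whose
selected `k2` sits at the grid minimum is flagged (`hit_lower_bound`): these
flags feed the boundary diagnostic described below.

The convolution is evaluated analytically — the exponential kernel against a
piecewise-linear `C_p` — on a uniform fine grid (default 0.01 min), so no
quadrature bias enters the 30-s early frames; the fine grid is only used for
the trapezoidal frame integration.

### Acquisition model

Scans follow a 21-frame, 60-min schedule (6×30 s, 3×1 min, 2×2 min,
10×5 min). The first two frames are excluded from every kinetic fit (tracer
delivery / blood-volume transients) but still carry counts. Fit weights are
pluggable: `uniform`, `duration-decay` (w ∝ Δt·e^(−λt_mid), λ for C-11,
T½ = 20.36 min — a frame-count proxy used as the default, since the exact
noise-equivalent-counts formula of clinical software is not public), and
`inv-var` (1/SD², used by the bias simulation).

## Synthetic phantom

A 2-D brain-like phantom (default 64×64, 2-mm voxels) with five regions:
a cortical ring, interior white matter, two striatal blobs and a small
substantia-nigra-like blob. Template kinetics are typical SV2A-tracer
values (cortex K1 = 0.30 ml min⁻¹ cm⁻³, V_T = 15 ml cm⁻³; WM V_T = 5;
striatum V_T = 18; nigra V_T = 6.41 ml cm⁻³, a parkinsonian group-mean
value, so the power analysis can mirror a patient-vs-control contrast).
Between-subject biology is modelled by independent unit-mean lognormal
factors on each region's K1 and V_T (default CV 0.15, a typical
between-subject spread for kinetic parameters); k2 = K1/V_T follows.

Counts: per frame, the expected sinogram is the PSF-blurred forward
projection (sparse voxel-driven parallel-beam projector, 120 angles ×
95 radial bins; Gaussian PSF, FWHM 2.5 mm, applied in image space) of the
frame-averaged activity times Δt·e^(−λ t_mid), globally scaled so the scan's
expected total prompts equal the calibration (default 3×10⁷), then Poisson
sampled per bin. Truth maps are decay-corrected activity, as in standard
PET quantification; decay enters expected counts only. No attenuation,
scatter, randoms or dead time are simulated, and the reconstructions use
the identical projector and PSF (matched-model regime).

Low-count replicates emulate list-mode gating at the count level: each bin
count is multinomially split into 20 equal-probability gates; replicates
are disjoint unions of gates — every 5th gate (20%, 5 replicates), every
10th (10%, 10 replicates), or one gate each (5%, the first 10 of the 20
gates; which 10 is immaterial by exchangeability). Because thinning a
Poisson variable yields independent Poissons, the replicates are exact
independent low-count realizations, and the 20% and 10% sets sum
bin-for-bin to the parent scan.

## Reconstruction arms

**Indirect (IR)** — each frame is reconstructed independently with OSEM
(30 angle-interleaved subsets, up to 4 iterations, every iteration
retained, uniform positive initialisation inside the circular FOV, no
post-smoothing), then the 1TC basis fit is applied voxel-wise.

**Direct (DR)** — the parametric image is the state of the EM loop
(nested-EM / optimisation-transfer structure). Each subset pass:
(a) the current state implies a dynamic image x_j,i = K1_j·B_i(k2_j);
(b) each frame receives the standard OSEM multiplicative update restricted
to the subset, giving an intermediate dynamic image; (c) every voxel's
intermediate TAC is re-projected onto the 1TC manifold by the weighted
basis fit. The fit weights are the per-frame subset sensitivity times the
frame scale; the voxel-wise sensitivity factor is common to all frames and
cancels in the closed-form regression, so the implementation passes
per-frame scale weights — algebraically identical. The first two frames
keep their model-implied expected counts but are excluded from the nested
fit, mirroring the IR fit mask. Subset count and iteration semantics match
OSEM exactly so "iteration 2" is comparable across arms. Initialisation:
uniform K1 in the FOV, k2 at the geometric mean of the grid. In the
one-subset limit the scheme is monotone in the Poisson likelihood (verified
in the tests to 1e-8 relative); at every iteration each voxel's implied
dynamic image is exactly K1·B(k2) for some grid k2.

The original direct method operates on list-mode events; this
implementation bins to the 21-frame schedule — a desk-scale simplification
that preserves the statistical structure for framed Poisson data.

## Figures of merit

For an ensemble θ_jrs (voxel j, replicate r, subject s):

- within-subject: m_js = mean_r θ, σ_js = SD_r θ (ddof 1), then
  m_j = mean_s m_js and σ_j = √(mean_s σ_js²) — root-mean-variance, never
  the SD of SDs;
- between-subject: the same with r and s interchanged. The two means
  coincide (linearity), which the tests assert exactly.

Voxel-wise ROI metrics average m_j/σ_j over ROI voxels; ROI-level metrics
average θ over the ROI first and then apply the same machinery. %CV is
100·σ/ref with a *fixed* reference — the IR full-count iteration-2 ROI
value — so method/level/iteration comparisons share a denominator. The
boundary diagnostic reports the percent of ROI voxels flagged at the k2
grid minimum, compared between the default grid (k2_min 0.005) and an
extended grid (0.001).

## Noise-induced-bias simulation

Per ROI, a noiseless 1TC TAC is built from the reference (IR full-count
iteration-2) parameters; 10,000 Gaussian realizations are drawn with
per-frame SDs measured from the pipeline's own reconstructed replicates
(voxel SD across replicates per frame, ROI-averaged, per count level and
iteration); each realization is refitted with 1/SD² weights; negative TAC
values are kept (reconstructed-image noise can be negative). Full-count
SDs, for which no replicates exist, use the ideal-Poisson extrapolation
(SD₂₀%/√5 + SD₁₀%/√10)/2. Reported: mean estimates and %bias versus the
reference, plus the median across gray-matter ROIs. Exact bias magnitudes
depend on the data's noise levels and are not reproduction targets; the
orderings (bias grows with lower counts and more iterations; V_T bias ≥ K1
bias) are.

## Power analysis

Per-group sample size for a two-sided pooled-variance two-sample t-test at
80% power, α = 0.05, by exact noncentral-t power iterated over n (the
`power.t.test` convention). With the published group means and SDs of the
patient-vs-control V_T contrast (8.72 vs 6.21, SD 1.60; 8.72 vs 6.41,
SD 1.79; and the 10%-count SDs 3.08 / 5.17 ml cm⁻³) the procedure returns
8, 11, 25 and 80 subjects per group. The experiment runner repeats the
design with its own synthetic between-subject SDs (nigra ROI).

## Problem sizes and numerical choices

- The shared acceptance study runs at 32×32 / 60 angles / 3 subjects /
  5 replicates per low-count level / 200 bases, with calibration scaled by
  the voxel-count ratio (7.5×10⁶) so per-voxel count statistics match the
  default 64×64 / 3×10⁷ configuration — scaling the grid down at fixed
  total prompts would quietly change the noise regime under study. The
  SD-scaling check and the acceptance script's replicate target run at the
  full 64×64 / 120-angle scale.
- The boundary diagnostic is evaluated at the 5% count level: at desk
  scale, per-voxel noise deep enough to push fitted k2 onto the grid
  boundary only appears at the lowest level (at 10% counts fewer than 1%
  of voxels hit the boundary, a degenerate diagnostic).
- EM guards: zero-sensitivity voxels are excluded by mask, expected-count
  ratios use an epsilon floor, images stay nonnegative by construction.
- All randomness flows through named integer seeds (one experiment seed
  spawns per-stage children via `SeedSequence`); identical seeds give
  byte-identical output tables.

## What the synthetic study does and does not show

The phantom reproduces the *procedures* and the statistical structure of a
replicate down-sampling study, not the scanner: it is 2-D, matched-model
(simulator and reconstructions share projector and PSF), free of
attenuation/scatter/randoms and their correction noise, and its per-voxel
counts at 3×10⁷ calibration are far more benign than list-mode HRRT voxels.
In this regime the direct method's advantages appear clearly — lower
within- and between-subject variability at 10% and 5% counts, near-ideal
√-count SD scaling (5%/20% K1 SD ratio ≈ 1.85–1.9 vs the indirect arm's
≥ 2.1), smaller k2-boundary sensitivity and smaller noise-induced bias —
but more compressed than on real data. In particular the reported
*four-fold count advantage* (direct at 5% matching indirect at 20%) is not
reached here: with indirect %CV in the 12–25% range its nonlinear noise
amplification is mild, whereas the original data sit at far deeper
per-voxel noise where indirect fitting degrades catastrophically. Passing
tests therefore certify the estimators, the metrics and the qualitative
orderings — not the quantitative superiority margins on clinical data.

Other known limitations: 2-D geometry only; no motion; no arterial-input
measurement noise; the Gaussian bias simulation deliberately ignores the
skewed noise distributions of real reconstructed images; ROI delineation is
the phantom's own label map (no registration/resampling step).
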