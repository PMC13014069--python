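# pet4d — direct vs indirect 4D parametric PET reconstruction

`pet4d` is a simulation and analysis package for a question that matters to
anyone running low-dose or short dynamic PET protocols: **how much precision
does direct ("4D") parametric reconstruction buy over the conventional
indirect route when counts get scarce?**

The conventional *indirect* route (IR) reconstructs every time frame
independently with OSEM and then fits a kinetic model voxel by voxel. The
*direct* route (DR) estimates the kinetic parameters inside the Poisson EM
loop, constraining the dynamic image to the kinetic model at every update
and thereby modelling the count statistics where they actually live — in
projection space.

Both arms target the one-tissue-compartment (1TC) model

```
C_T(t) = K1 · exp(−k2 t) ⊗ C_p(t),        V_T = K1 / k2
```

with `C_p(t)` the arterial plasma input function, `K1` (ml min⁻¹ cm⁻³) the
influx rate, `k2` (min⁻¹) the efflux rate and `V_T` (ml cm⁻³) the volume of
distribution — for SV2A tracers, a synaptic-density marker. Fitting uses
the basis-function method (500 bases, `k2` geometric in 0.005–1.0 min⁻¹),
and DR re-projects each EM intermediate image onto the 1TC manifold with
the identical fit kernel (nested EM), so the two arms differ only in where
the noise model sits.

The package provides, as first-class tested code:

- **kinetics** — analytic exponential⊗piecewise-linear convolution, frame
  averaging, basis sets, weighted basis fits for TACs and whole images
  (`OneTissueBasisModel(...).fit()` → results object with `summary()`);
- **synthetic phantom** — multi-subject 2-D brain phantom with lognormal
  between-subject variation, Feng-type input function, Poisson sinogram
  frames under the 21-frame / 60-min schedule, and gated count
  downsampling into disjoint 20% / 10% / 5% replicate sets;
- **reconstruction** — frame-wise OSEM (`IndirectReconstruction`) and
  nested-EM direct parametric reconstruction (`DirectReconstruction`),
  matched subsets/iterations/PSF;
- **variability metrics** — within-/between-subject voxel and ROI %CV with
  the fixed full-count reference denominator, k2-boundary diagnostics,
  per-iteration change;
- **bias simulation** — 10,000-realization Gaussian TAC refits at
  replicate-derived noise levels (noise-induced bias tables);
- **power analysis** — exact noncentral-t two-sample sample sizes;
- **experiment runner + CLI** — `pet4d run-all` executes the whole study
  (simulate → downsample → IR + DR → metrics → bias → boundary → power)
  deterministically from one seed.

## Worked example

```python
import numpy as np
import pet4d

cp = pet4d.make_input_function()                  # Feng-type plasma input
schedule = pet4d.FrameSchedule.default()          # 6x30s, 3x1, 2x2, 10x5 min
basis = pet4d.make_basis_set(cp, schedule)        # 500 bases, 0.005-1.0 /min

rng = np.random.default_rng(0)
tac = pet4d.simulate_tac(0.30, 0.02, cp, schedule)        # K1, k2 truth
noisy = tac + rng.normal(0, 0.03 * tac.max(), tac.shape)

res = pet4d.OneTissueBasisModel(noisy, basis).fit()
print(res.summary())
```

```
One-tissue-compartment basis-function fit
=============================================
K1 (ml/min/cm3)                0.292034
k2 (1/min)                    0.0194632
VT (ml/cm3)                     15.0044
hit lower k2 bound                False
weighted SSE                1.26754e+06
n bases                             500
k2 range (1/min)             [0.005, 1]
```

At 3% frame noise the fit recovers the truth (K1 = 0.30, k2 = 0.02,
V_T = 15) to within ~3%; `hit lower k2 bound` flags the pathological fits
that drive the boundary diagnostic on noisy maps.

The power module answers the study's clinical question — how many subjects
does a patient-vs-control V_T difference need per group:

```python
n, power = pet4d.two_sample_t_sample_size(pet4d.PowerSpec(8.72, 6.21, 1.60))
# n per group = 8 (achieved power 0.8306)
```

With the direct method's tighter between-subject SD (1.60 ml cm⁻³) 8
subjects per group suffice; the indirect arm's SD of 1.79 needs 11, and at
10% counts the gap widens to 25 (DR) versus 80 (IR).

A full synthetic replicate study from the shell:

```bash
pet4d run-all --out results/study --seed 1
```

writes tidy CSVs (`variability.csv`, `bias.csv`, `boundary.csv`,
`power.csv`), NIfTI truth/parametric maps and a checksummed manifest.

## Layout

```
src/pet4d/        kinetics, phantom, projector, recon, metrics, bias,
                  power, experiment, io, cli
tests/            unit + property tests, acceptance suite
scripts/          acceptance.py
docs/methods.md   model, assumptions, parameter choices, limitations
```
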