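# specdot

Multi-wavelength continuous-wave diffuse optical tomography (DOT) in Python:
structured-light surface profilometry, voxel-based tetrahedral meshing, a
diffusion-approximation FEM forward model, pre-reconstruction calibration,
and spectrally constrained Levenberg-Marquardt reconstruction of chromophore
concentrations — together with deterministic phantom generators so the whole
pipeline runs and is tested without any hardware.

## The problem

Near-infrared light crossing centimetres of tissue is scattered far more than
it is absorbed, so transmission images are diffuse blurs.  DOT recovers the
interior absorption distribution from many source-detector amplitude
measurements by inverting a light-transport model.  Measuring at several
wavelengths and solving directly for chromophore concentrations — oxy- and
deoxy-haemoglobin, water, or a phantom dye — constrains the otherwise
ill-posed inversion with the known extinction spectra.  The intended
application is imaging total haemoglobin around hand joints (an early marker
of rheumatoid arthritis); the package reproduces the computational chain of
such a system on solid and liquid tissue phantoms.

The model stack, in the field's standard notation:

* **Forward model** (CW diffusion approximation, linear tetrahedral FEM):
  `[-∇·κ(r)∇ + C₀ μₐ(r)] φ(r) = q₀(r)`, with `κ = 1/(3(μₐ + μₛ'))`, a Robin
  boundary condition with index-mismatch factor A, collimated sources modelled
  as isotropic point sources at depth `1/μₛ'`, and camera-pixel blocks as
  virtual detectors read out on the surface.
* **Spectral model**: `μₐ(λ) = Σᵢ εᵢ(λ) Cᵢ` and the Mie power law
  `μₛ'(λ) = a (λ/1000 nm)⁻ᵇ`.
* **Inversion**: Levenberg-Marquardt on log-amplitudes,
  `∂μ = (JᵀJ + R·I)⁻¹ Jᵀ ∂φ`, with the spectral Jacobian assembled from
  adjoint per-wavelength absorption sensitivities chained through `εᵢ(λ)`,
  updated on a coarse pixel basis, R annealed from 100, and a 2%
  projection-error stopping rule.
* **Surface capture**: N-step phase-shifting fringe projection at frequencies
  1/4/20/70 waves per image, temporal phase unwrapping, and a rational
  11-coefficient phase-to-height calibration fitted by linear least squares.

`docs/methods.md` documents every model choice, default and limitation.

## Worked example

`examples/03_reconstruction.py` simulates five-wavelength transmission data
on a 50 × 30 × 20 mm block phantom containing two absorbing rods
(normalized dye concentration 1.068 vs background 1), then reconstructs the
concentration map on a homogeneous mesh:

```
$ python examples/03_reconstruction.py
iterations          : 10 (projection error 1.2 -> 0.000768)
anomaly support     : peak 1.0379, mean 1.0153  (truth 1.068)
background          : mean 1.0010  (truth 1.000)
The rods appear as a raised-concentration feature; at this single-view
geometry the two rods merge along depth (see the geometry study).
```

The projection error (squared log-amplitude misfit) falls by three orders of
magnitude; the anomaly is recovered as a concentration contrast close to its
true value, while the background stays at 1.  The other examples cover
surface profilometry (`01`, exact to <1e-12 mm on noiseless fringes), forward
simulation (`02`), the calibration chain (`04`, per-source gains and per-link
biases cancel exactly), and the source-detector geometry study (`05`, only a
three-orthogonal-view geometry separates the two rods along depth).

A thin CLI wraps the same pipeline for shell use:

```bash
specdot run --config experiment.yaml --seed 1 --out results/
specdot reconstruct --exclude-wavelength 930 ...
```

## Layout

```
src/specdot/
  profilometry.py   fringe synthesis, N-step phase, unwrapping, height model
  meshing.py        voxel volumes, Kuhn tetrahedralization, camera, optodes
  spectra.py        extinction tables, Mie law, spectral parameter fits
  fem.py            diffusion FEM assembly, sources/detectors, simulation
  recon.py          adjoint Jacobians, pixel basis, LM reconstruction
  calibrate.py      characterization normalization, bulk fit, model offsets
  phantoms.py       block/petri phantom generators, synthetic fringe scenes
  io.py             plain-text mesh/measurement/calibration formats, VTK
  pipeline.py, cli.py   experiment runner and its click interface
```
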