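# Methods

This note documents the models implemented in `specdot`, the choices made
where the design was genuinely open, and what the synthetic studies do and do
not demonstrate about real measurements.

## Surface profilometry

Fringe projection renders sinusoidal patterns `I_i = A + B cos(phi_total -
delta_i)` at several spatial frequencies (default 1, 4, 20, 70 waves per
image), each with N phase shifts.  The wrapped phase of one frequency is the
four-quadrant arctangent of the sine/cosine-weighted image sums — the
standard N-step estimator, exact (to round-off) when the shifts cover the
circle uniformly.  The default shift set is therefore `2 pi k / 5`.  A
`SYSTEM_PHASE_SHIFTS` set (`pi/3 .. 5 pi/3`, spanning only 5/6 of the circle)
is provided for fidelity to the physical system; using it triggers a
documented bias warning because the estimator is no longer orthogonal to the
DC offset.  Phase maps are unwrapped temporally up the frequency ladder:
`Phi_high = phi_high + 2 pi round((r Phi_low - phi_high)/(2 pi))` with `r`
the frequency ratio and round-half-away-from-zero tie-breaking; the 1
wave/image rung is unambiguous by construction because the synthesized
carrier is centred in `(-pi, pi]`.  Pixels whose fringe-order residual
exceeds a quarter period are flagged as suspect rather than silently
accepted.

Height follows the rational calibration model

    Zp = [1 + C1 P + (C2 + C3 P) I + (C4 + C5 P) J]
         / [D0 + D1 P + (D2 + D3 P) I + (D4 + D5 P) J]

fitted by linear least squares after multiplying through by the denominator,
with the numerator constant pinned at 1 to remove the scale ambiguity.  A
rank check (11 independent columns, at least two distinct plane heights)
guards against degenerate calibrations.  Because the numerator constant is
1, zero phase cannot map to zero height at every pixel; the reference plane
therefore carries a per-pixel phase offset (`HeightCalibration.
reference_phase`), which the measurement chain adds to the object-minus-
reference phase difference before evaluating the model.  Scene synthesis
inverts the model pixelwise (it is linear in phase), so the noiseless chain
is exact end to end; the tests require < 1e-6 mm.  The only smoothing is an
optional k x k mean filter (default off in the library, 3 x 3 where the
sinusoidal artefacts of real data would matter).

Scene-induced phase is defined at the highest projected frequency and scales
proportionally to frequency down the ladder, as a height-induced lateral
fringe displacement does physically.

## Meshing

Height maps are thresholded into a binary voxel volume (voxel occupied iff
the local height exceeds the threshold and `k * voxel < height`), and every
occupied voxel is split into the six Kuhn tetrahedra around its min-to-max
body diagonal.  With a uniform diagonal orientation the decomposition is
face-conformal across neighbouring voxels — shared-face diagonals agree — so
no parity alternation is needed; a face-incidence audit (every interior face
shared by exactly two tetrahedra) is part of the test suite.  The mesh
volume equals occupied-voxel volume exactly, which the tests assert to
1e-13 relative.

Virtual detectors are blocks of camera pixels; their physical positions come
from a pinhole model (`pitch = standoff / focal length`).  Source and
detector grids are projected onto the mesh surface by a 2-D point-in-triangle
search over the boundary faces of the requested side.  By default two of the
sixteen sources are switched off — the two corner sources farthest from the
detector-grid centroid, a deterministic proxy for the low-signal corners; an
explicit active mask overrides this.

## Forward model

Continuous-wave light transport uses the diffusion approximation
`[-div(kappa grad) + C0 mua] phi = q0` with `kappa = 1/(3(mua + musp'))`,
discretized with linear tetrahedral elements.  Choices:

* **Stiffness** uses the element mean of nodal kappa.
* **Absorption and Robin boundary terms are mass-lumped** (diagonal).  On
  the Kuhn mesh the stiffness has non-positive off-diagonals, so lumping
  makes the assembled system an M-matrix and the discrete fluence of a
  positive source strictly positive.  The consistent (full) mass matrix was
  measured to undershoot to small negative fluence near slab corners
  (~0.3% of peak), which breaks the positivity the measurement model relies
  on; lumping removes this at the same asymptotic order of accuracy.
* **Boundary condition**: Robin (type III) with the internal-reflection
  parameter computed from the critical angle of a relative refractive index
  (default 1.33; 1.54 is appropriate for epoxy phantoms).
* **Sources**: an isotropic point source placed `1/musp'` beneath the
  illumination point along the inward normal, distributed barycentrically to
  the containing tetrahedron — the standard CW model of a collimated fibre.
* **Detectors** read out fluence by barycentric interpolation on the nearest
  boundary face.
* `C0` defaults to 1: with amplitude-only data it rescales amplitudes
  without changing log-amplitude contrasts.

One sparse LU factorization per wavelength is shared by all source and
adjoint solves.  Validation oracles: `log(r phi)` versus distance from an
interior point source matches the analytic infinite-medium slope
`-sqrt(3 mua (mua + musp'))` within 2% (the test uses a 50 mm cube so the
5-15 mm fitting shell keeps clearance from the absorbing boundary, where the
infinite-medium solution does not apply); source-detector reciprocity holds
to 0.1%; amplitudes decrease monotonically with separation.

Known limitation: very far from a source (> ~30 mm in a weakly absorbing
medium) the discrete fluence approaches the round-off floor of the
factorization; detector placements in the package's geometries stay well
inside the trustworthy range.

## Spectral model

Absorption is linear in chromophore concentrations, `mua(lambda) = sum_i
eps_i(lambda) C_i`; scattering follows the Mie power law `musp' = a
(lambda/1000 nm)^(-b)`.  The 1000 nm normalization keeps `a` in musp' units;
the power law's wavelength unit is otherwise arbitrary.  Concentration fits
use non-negative least squares; `(a, b)` come from a log-log linear fit.
Wavelengths are looked up exactly — no interpolation — so accidental
off-grid queries fail loudly.

Two chromophore tables ship with the package.  The *phantom* table has a
single dye whose extinction equals the characterized background absorption
of the solid block phantom (0.0187/0.0179/0.0181/0.0162/0.0149 mm^-1 at
690/730/750/850/930 nm), so the background has normalized concentration 1 by
construction and the rod anomaly, characterized only at 730 nm
(0.02 mm^-1), has normalized concentration 1.068.  The *tissue* table
(HbO2, Hb in mm^-1/mM; water in mm^-1 per volume fraction) is a packaged CSV
compiled from the standard literature compilations of haemoglobin molar
extinction and water absorption; it is user-replaceable and intended for
HbT-style reconstructions, where dropping water and the noisy 930 nm band is
a supported configuration.

## Reconstruction

The inverse problem is solved by Levenberg-Marquardt iteration on natural-log
amplitudes (CW transmission spans decades; the log stabilizes the residual).
Per iteration: forward solves at all included wavelengths; residual `log Y -
log F`; adjoint absorption Jacobian `J[link, node] = -V_node phi_source
psi_detector / amplitude` (the nodal quadrature exactly consistent with the
lumped absorption operator, verified against finite differences to < 1e-3 —
in practice ~1e-6); chain rule through the extinction spectra to stack the
spectral Jacobian over wavelengths and chromophore blocks; projection onto a
coarse regular pixel basis; regularized update `(J^T J + R max diag(J^T J)
I)^-1 J^T dphi`, solved through the primal or dual normal system, whichever
is smaller (they are algebraically identical); positivity clamp at 1e-6 of
the initial values.  R starts at 100, shrinks by 10^0.25 per accepted step
and grows tenfold on rejections; iteration stops when the projection error
changes by less than 2% (or at the iteration cap, or when steps stop
helping, which sets a non-convergence flag).  The Jacobian is taken at fixed
kappa: the kappa(mua) coupling contributes ~0.1% for the phantom contrasts
and is the standard CW absorption-only approximation.  Scattering recovery
is disabled in the CW driver (amplitude-only data cannot separate it from
absorption); the scattering-amplitude/power Jacobian blocks are available
through `spectral_jacobian` for frequency-resolved extensions.

The pixel basis interpolates trilinearly from grid nodes to mesh nodes
(matrix B); the reverse map is the volume-weighted least-squares inverse, so
constants and linear ramps round-trip exactly and a single-cell constant
basis returns the volume-weighted mesh mean.

**Anomaly readout.** The recovered concentration over the true rod support
is summarized by both its peak and its regional mean; the peak is the
headline number (partial-volume averaging at 2 mm resolution biases the
regional mean low by construction).  In the scaled-down study the noiseless
single-view reconstruction gives peak ~1.05 and mean ~1.03 against the 1.068
truth — the same neighbourhood as the full-scale study's 1.044.

## Calibration

Raw amplitudes are divided by per-source strengths and the per-wavelength
spectral response (delimited-text characterization tables).  Bulk optical
properties are fitted to a homogeneous reference measurement by minimizing
the squared log-amplitude misfit; because CW amplitude data cannot uniquely
separate mua from musp', the default fixes musp' to a configured prior and
fits mua with a bounded scalar search (a two-parameter Nelder-Mead search in
log space is available).  The per-link model offset `log Y_hom - log F_hom`
is subtracted from heterogeneous data, so any per-link multiplicative bias
common to both datasets cancels exactly — the chain is linear in
log-amplitude, which the tests verify to 1e-9.

## Synthetic studies: what they emulate and what they do not

The phantom generators reproduce the study conditions: a 50 x 30 x 20 mm
block (outer dimensions are not part of the manufacturer characterization;
these defaults match the joint-like geometry and the 20-30 mm height range
of the profilometry scenes) with two 5 mm rods stacked 10 mm apart along the
depth axis; petri-dish phantoms 84 mm across and 14 mm deep with 3 mm rods
at 7 mm depth at separations 15/11/4 mm, plus rotated and compound variants;
milk-like background optics with normalized concentration 1 and a
configurable rod contrast (default 2, consistent with the strong attenuation
reported for plastic rods).  Boundary data are noiseless by default, with
optional seeded multiplicative Gaussian amplitude noise.

Scaled-down problem sizes are used throughout: 2 mm mesh resolution
(~4.6k nodes) and a 2 mm pixel basis for the headline block study, 2.5-3 mm
for the qualitative geometry and dish studies.  These sizes preserve the
physics being tested (depth vs lateral resolvability, contrast recovery)
while keeping each study in the tens of seconds to a few minutes.

Passing these studies shows the algorithmic chain is self-consistent and
reproduces the simulation-level findings: quantitative contrast recovery in
the anomaly region, failure of the single transmission view to separate
depth-stacked rods, success of the three-orthogonal-view geometry, and a
lateral resolution limit between 4 and 11 mm for the dish geometry.  They do
not validate against physical data: real measurements add camera noise,
stray light, fibre-coupling drift, surface-coupling errors and model
mismatch (the full-scale physical experiment recovered peak values several
times the truth even after offset calibration), none of which the generators
emulate.

## Numerical details

* Tetrahedra are oriented positive at construction; degenerate elements
  raise at assembly with the element index.
* Wrapped phase is returned in `(-pi, pi]`; the branch point at -pi is
  folded to +pi.
* The homogeneous fit clips non-positive trial amplitudes (possible for
  strongly absorbing trials on coarse meshes) to a large finite penalty
  rather than propagating NaNs.
* `lm_update` raises with advice to use R > 0 if the normal equations are
  numerically singular at R = 0.
* All randomness flows through explicit seeds (`numpy.random.default_rng`);
  noiseless runs are bit-reproducible, a property the tests assert.
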