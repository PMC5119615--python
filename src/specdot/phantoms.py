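"""Deterministic phantom generators and synthetic experiments.

Three families of synthetic objects exercise the pipeline without hardware:

* a solid rectangular block phantom with two absorbing rods stacked along the
  depth (z) axis — the main simulation target;
* petri-dish "milk" phantoms: an 84 mm diameter, 14 mm deep dish with thin
  absorbing rods at 7 mm depth in several arrangements, used to probe lateral
  resolution;
* synthetic fringe-projection scenes rendered through a height calibration,
  so the profilometry chain can be validated end to end.

The block's outer dimensions are not part of the manufacturer specification;
the defaults (50 x 30 x 20 mm with 5 mm rods 10 mm apart in depth) are sized
to the metacarpophalangeal-joint geometry the phantom mimics and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spectra
from .fem import simulate_measurements
from .meshing import (OptodeGridSpec, OptodeSet, TetMesh, box_volume,
                      build_optode_set, grid_on_face, volume_to_mesh,
                      VoxelVolume)
from .profilometry import (HeightCalibration, HeightMap,
                           generate_fringe_patterns, phase_from_height)
from .spectra import SpectralParams, fit_spectral_params, phantom_dye_table

__all__ = [
    "Cylinder",
    "PhantomSpec",
    "block_phantom_spec",
    "petri_phantom_spec",
    "build_block_phantom",
    "build_petri_phantom",
    "Phantom",
    "single_view_optodes",
    "petri_optodes",
    "three_view_optodes",
    "default_height_calibration",
    "synthesize_profilometry_scene",
    "MILK_MUA_BACKGROUND",
    "MILK_MUSP_BACKGROUND",
]


class PhantomSpecError(ValueError):
    """Inclusions do not fit inside the outer geometry."""


@dataclass
class Cylinder:
    """Axis-aligned cylindrical inclusion (mm)."""

    center: np.ndarray
    axis: np.ndarray
    radius: float
    length: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("cylinder radius and length must be > 0")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - self.center
        t = p @ self.axis
        radial = p - t[:, None] * self.axis
        return (np.abs(t) <= self.length / 2 + 1e-12) & \
            (np.linalg.norm(radial, axis=1) <= self.radius + 1e-12)

    @property
    def volume(self) -> float:
        return np.pi * self.radius**2 * self.length


@dataclass
class PhantomSpec:
    """Outer geometry + inclusions + per-region spectral parameters."""

    kind: str  # 'block' or 'dish'
    extent: tuple = (50.0, 30.0, 20.0)  # block: x, y, z mm
    diameter: float = 84.0  # dish only
    depth: float = 14.0  # dish only
    inclusions: list = field(default_factory=list)
    region_params: dict = field(default_factory=dict)
    resolution: float = 2.0

    def validate(self) -> None:
        """Every inclusion must lie strictly inside the outer geometry.

        Endpoints are checked inside the solid; the radius must clear the
        boundary in the directions perpendicular to the cylinder axis.
        """
        for cyl in self.inclusions:
            perp = 1.0 - np.abs(cyl.axis)  # ~1 for perpendicular directions
            ends = [cyl.center + s * cyl.axis * cyl.length / 2 for s in (-1, 1)]
            for p in ends:
                if self.kind == "block":
                    lo = np.array([-self.extent[0] / 2, -self.extent[1] / 2, 0.0])
                    hi = np.array([self.extent[0] / 2, self.extent[1] / 2,
                                   self.extent[2]])
                    if np.any(p - cyl.radius * perp < lo - 1e-9) or \
                       np.any(p + cyl.radius * perp > hi + 1e-9):
                        raise PhantomSpecError(
                            f"inclusion at {cyl.center} extends outside the block")
                else:
                    if np.linalg.norm(p[:2]) + cyl.radius * max(perp[0], perp[1]) \
                       > self.diameter / 2 + 1e-9 or \
                       p[2] - cyl.radius < -1e-9 or p[2] + cyl.radius > self.depth + 1e-9:
                        raise PhantomSpecError(
                            f"inclusion at {cyl.center} extends outside the dish")


@dataclass
class Phantom:
    """A labelled mesh together with its spectral description."""

    mesh: TetMesh
    spec: PhantomSpec
    table: spectra.ExtinctionTable
    region_params: dict
    musp_by_wavelength: dict | None = None

    def anomaly_node_mask(self) -> np.ndarray:
        """Mesh nodes strictly inside any inclusion (the true anomaly support)."""
        mask = np.zeros(self.mesh.n_nodes, dtype=bool)
        for cyl in self.spec.inclusions:
            mask |= cyl.contains(self.mesh.nodes)
        return mask

    def anomaly_points_mask(self, points: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(np.atleast_2d(points)), dtype=bool)
        for cyl in self.spec.inclusions:
            mask |= cyl.contains(points)
        return mask


# ---------------------------------------------------------------------------
# block phantom
# ---------------------------------------------------------------------------

def _fitted_background_params() -> SpectralParams:
    """Dye concentration and Mie (a, b) fitted to the block background."""
    return fit_spectral_params(spectra.BLOCK_PHANTOM_MUA_BACKGROUND,
                               spectra.BLOCK_PHANTOM_MUSP_BACKGROUND,
                               phantom_dye_table())


def block_phantom_spec(extent=(50.0, 30.0, 20.0), rod_diameter: float = 5.0,
                       rod_separation: float = 10.0, rod_length: float | None = None,
                       resolution: float = 2.0,
                       anomaly_concentration: float | None = None) -> PhantomSpec:
    """Two-rod block phantom: rods run along y at the block centre, stacked
    10 mm apart along the depth (z) axis."""
    if anomaly_concentration is None:
        anomaly_concentration = spectra.BLOCK_PHANTOM_ANOMALY_CONCENTRATION
    length = extent[1] if rod_length is None else rod_length
    zc = extent[2] / 2
    rods = [
        Cylinder(center=(0.0, 0.0, zc - rod_separation / 2), axis=(0, 1, 0),
                 radius=rod_diameter / 2, length=length),
        Cylinder(center=(0.0, 0.0, zc + rod_separation / 2), axis=(0, 1, 0),
                 radius=rod_diameter / 2, length=length),
    ]
    bg = _fitted_background_params()
    anomaly = SpectralParams(concentrations={"dye": anomaly_concentration},
                             a=bg.a, b=bg.b)
    spec = PhantomSpec(kind="block", extent=tuple(extent), inclusions=rods,
                       region_params={0: bg, 1: anomaly}, resolution=resolution)
    spec.validate()
    return spec


def _label_regions(mesh: TetMesh, inclusions) -> None:
    centroids = mesh.element_centroids()
    labels = np.zeros(mesh.n_elements, dtype=np.int64)
    for cyl in inclusions:
        labels[cyl.contains(centroids)] = 1
    mesh.regions = labels


def build_block_phantom(spec: PhantomSpec | None = None,
                        resolution: float | None = None,
                        table1_anomaly_scattering: bool = False) -> Phantom:
    """Mesh the block phantom and label rod elements as anomaly.

    By default scattering is shared between background and anomaly (the
    anomaly differs in absorption only); ``table1_anomaly_scattering`` instead
    honours the manufacturer's 1.8 mm^-1 anomaly value at 730 nm by giving
    the anomaly its own Mie fit through that point (same power b).
    """
    spec = spec or block_phantom_spec()
    res = resolution or spec.resolution
    vol = box_volume(spec.extent, res,
                     origin=(-spec.extent[0] / 2, -spec.extent[1] / 2, 0.0))
    mesh = volume_to_mesh(vol)
    _label_regions(mesh, spec.inclusions)
    params = dict(spec.region_params)
    if table1_anomaly_scattering:
        bg = params[0]
        a_anom = spectra.BLOCK_PHANTOM_ANOMALY_MUSP_730 / (730.0 / 1000.0) ** (-bg.b)
        params[1] = SpectralParams(concentrations=dict(params[1].concentrations),
                                   a=a_anom, b=bg.b)
    mesh.provenance.update({"phantom": "block", "resolution": res})
    return Phantom(mesh=mesh, spec=spec, table=phantom_dye_table(),
                   region_params=params)


def homogeneous_like(phantom: Phantom) -> Phantom:
    """The same mesh with every element labelled background (recon mesh)."""
    mesh = TetMesh(phantom.mesh.nodes.copy(), phantom.mesh.elements.copy(),
                   regions=np.zeros(phantom.mesh.n_elements, dtype=np.int64),
                   provenance=dict(phantom.mesh.provenance, homogeneous=True))
    return Phantom(mesh=mesh, spec=phantom.spec, table=phantom.table,
                   region_params={0: phantom.region_params[0]},
                   musp_by_wavelength=phantom.musp_by_wavelength)


# ---------------------------------------------------------------------------
# petri-dish (liquid) phantoms
# ---------------------------------------------------------------------------

#: Literature-typical semi-skimmed milk optical properties (mm^-1); the
#: background normalized concentration is 1 by construction, as for the block.
MILK_MUA_BACKGROUND = {690.0: 0.004, 730.0: 0.005, 750.0: 0.006,
                       850.0: 0.009, 930.0: 0.025}
MILK_MUSP_BACKGROUND = {690.0: 1.30, 730.0: 1.25, 750.0: 1.22,
                        850.0: 1.10, 930.0: 1.00}


def milk_dye_table() -> spectra.ExtinctionTable:
    lams = np.array(sorted(MILK_MUA_BACKGROUND))
    eps = np.array([[MILK_MUA_BACKGROUND[l]] for l in lams])
    return spectra.ExtinctionTable(lams, ("dye",), eps)


def petri_phantom_spec(separation: float = 11.0, rotated: bool = False,
                       compound: bool = False, rod_diameter: float = 3.0,
                       rod_length: float = 60.0, rod_depth: float = 7.0,
                       rod_concentration: float = 2.0,
                       diameter: float = 84.0, depth: float = 14.0,
                       resolution: float = 3.0) -> PhantomSpec:
    """Petri-dish rod phantom: two parallel rods at 7 mm depth separated
    laterally; ``rotated`` swaps the rod axis, ``compound`` suspends an extra
    crossing rod above the pair."""
    if separation + rod_diameter >= diameter:
        raise PhantomSpecError(
            f"separation {separation} mm does not fit a {diameter} mm dish")
    axis = (1, 0, 0) if rotated else (0, 1, 0)
    lateral = np.array([0, 1, 0]) if rotated else np.array([1, 0, 0])
    rods = [
        Cylinder(center=tuple(-separation / 2 * lateral + [0, 0, rod_depth]),
                 axis=axis, radius=rod_diameter / 2, length=rod_length),
        Cylinder(center=tuple(+separation / 2 * lateral + [0, 0, rod_depth]),
                 axis=axis, radius=rod_diameter / 2, length=rod_length),
    ]
    if compound:
        cross_axis = tuple(lateral)
        rods.append(Cylinder(center=(0.0, 0.0, rod_depth + 3.5), axis=cross_axis,
                             radius=rod_diameter / 2, length=rod_length))
    bg = fit_spectral_params(MILK_MUA_BACKGROUND, MILK_MUSP_BACKGROUND,
                             milk_dye_table())
    rod = SpectralParams(concentrations={"dye": rod_concentration}, a=bg.a, b=bg.b)
    spec = PhantomSpec(kind="dish", diameter=diameter, depth=depth,
                       inclusions=rods, region_params={0: bg, 1: rod},
                       resolution=resolution)
    spec.validate()
    return spec


def build_petri_phantom(separation: float = 11.0, rotated: bool = False,
                        compound: bool = False, resolution: float | None = None,
                        spec: PhantomSpec | None = None, **kwargs) -> Phantom:
    """Voxelize and mesh a petri-dish phantom variant."""
    spec = spec or petri_phantom_spec(separation=separation, rotated=rotated,
                                      compound=compound,
                                      resolution=resolution or 3.0, **kwargs)
    res = resolution or spec.resolution
    r = spec.diameter / 2
    n_xy = int(np.ceil(spec.diameter / res))
    n_z = max(int(round(spec.depth / res)), 1)
    c = (np.arange(n_xy) + 0.5) * res - r
    X, Y = np.meshgrid(c, c, indexing="ij")
    disk = X**2 + Y**2 <= r**2
    occ = np.repeat(disk[:, :, None], n_z, axis=2)
    vol = VoxelVolume(occ, res, origin=np.array([-r, -r, 0.0]))
    mesh = volume_to_mesh(vol)
    _label_regions(mesh, spec.inclusions)
    mesh.provenance.update({"phantom": "dish", "resolution": res})
    return Phantom(mesh=mesh, spec=spec, table=milk_dye_table(),
                   region_params=dict(spec.region_params))


# ---------------------------------------------------------------------------
# optode layouts
# ---------------------------------------------------------------------------

def single_view_optodes(mesh: TetMesh, n_sources=(4, 4), source_spacing=5.0,
                        n_detectors=(6, 6), detector_spacing=2.5,
                        n_omitted_sources=2) -> OptodeSet:
    """The system layout: source grid on the resting face (z=0), virtual
    detector grid on the imaged top face; two low-signal corner sources off."""
    spec = OptodeGridSpec(n_sources=n_sources, source_spacing=source_spacing,
                          n_detectors=n_detectors, detector_spacing=detector_spacing,
                          n_omitted_sources=n_omitted_sources)
    return build_optode_set(spec, mesh)


def petri_optodes(mesh: TetMesh, n_detectors=(7, 7)) -> OptodeSet:
    """Liquid-phantom layout: 49 virtual detectors at 2.5 mm over the dish
    centre, same source grid as the block experiments."""
    return single_view_optodes(mesh, n_detectors=n_detectors)


def three_view_optodes(mesh: TetMesh, sources_three_views: bool = False,
                       n_sources=(4, 4), source_spacing=5.0,
                       n_detectors=(6, 6), detector_spacing=2.5) -> OptodeSet:
    """Extended geometries: detectors on three orthogonal faces (+z, +x, +y),
    optionally sources on the three opposite faces (-z, -x, -y)."""
    det_faces = [("z", +1), ("x", +1), ("y", +1)]
    src_faces = [("z", -1), ("x", -1), ("y", -1)] if sources_three_views \
        else [("z", -1)]
    detectors = np.vstack([
        grid_on_face(mesh, n_detectors, detector_spacing, f, name="detector")
        for f in det_faces])
    sources = np.vstack([
        grid_on_face(mesh, n_sources, source_spacing, f, name="source")
        for f in src_faces])
    return OptodeSet(sources, detectors)


# ---------------------------------------------------------------------------
# synthetic measurement convenience
# ---------------------------------------------------------------------------

def simulate_phantom_data(phantom: Phantom, optodes: OptodeSet,
                          wavelengths=None, noise_fraction: float = 0.0,
                          seed: int | None = None, n_rel: float = 1.33):
    wavelengths = tuple(wavelengths) if wavelengths is not None \
        else tuple(sorted(spectra.SYSTEM_WAVELENGTHS))
    return simulate_measurements(phantom.mesh, phantom.region_params, optodes,
                                 wavelengths, phantom.table,
                                 noise_fraction=noise_fraction, seed=seed,
                                 musp_by_wavelength=phantom.musp_by_wavelength,
                                 n_rel=n_rel)


# ---------------------------------------------------------------------------
# synthetic profilometry scenes
# ---------------------------------------------------------------------------

def default_height_calibration() -> HeightCalibration:
    """A well-conditioned synthetic calibration: height roughly linear in
    phase with mild pixel dependence, invertible for heights 0-60 mm on
    images up to ~512 px."""
    C = np.array([0.8, 1e-4, 2e-6, -8e-5, 1e-6])
    D = np.array([0.04, 1e-4, 2e-7, 1e-9, -1e-7, 1e-9])
    return HeightCalibration(C=C, D=D)


def synthesize_profilometry_scene(heights: np.ndarray | HeightMap,
                                  calib: HeightCalibration | None = None,
                                  frequencies=(1.0, 4.0, 20.0, 70.0),
                                  n_shifts: int = 5, offset: float = 120.0,
                                  modulation: float = 100.0,
                                  noise_sigma: float = 0.0,
                                  seed: int | None = None):
    """Render object + reference fringe stacks for a ground-truth height map.

    The scene phase is the exact inverse of the rational calibration model,
    so the noiseless profilometry chain must reproduce ``heights`` to
    round-off.  Returns (object patterns, reference patterns, truth map,
    calibration).
    """
    calib = calib or default_height_calibration()
    hm = heights if isinstance(heights, HeightMap) else HeightMap(np.asarray(heights, float))
    # scene-induced phase relative to the zero-height reference plane
    theta = phase_from_height(hm.values, calib) \
        - calib.reference_phase(hm.values.shape)
    rng = np.random.default_rng(seed)
    from .profilometry import uniform_phase_shifts
    shifts = uniform_phase_shifts(n_shifts)
    h, w = hm.values.shape
    obj = generate_fringe_patterns(w, h, frequencies, shifts, offset, modulation,
                                   scene_phase=theta, rng=rng,
                                   noise_sigma=noise_sigma)
    ref = generate_fringe_patterns(w, h, frequencies, shifts, offset, modulation,
                                   scene_phase=None, rng=rng,
                                   noise_sigma=noise_sigma)
    return obj, ref, hm, calib
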