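"""Continuous-wave diffusion FEM forward model.

Solves the diffusion approximation to the radiative transfer equation,

    [-div(kappa grad) + C0 mua] phi = q0,

with a Robin (type III) boundary condition phi + 2 A kappa dphi/dn = 0 on a
linear tetrahedral mesh, where A accounts for the refractive-index mismatch
at the surface.  Measurements are CW amplitudes: the fluence interpolated at
each detector's surface projection, one sparse solve per active source with
the factorization shared across sources and adjoint (detector) solves.

Since only CW amplitudes are used, the speed of light C0 is folded into the
absorption term and defaults to 1: it rescales absolute amplitude but not
log-amplitude contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .meshing import TetMesh, OptodeSet
from .spectra import (ExtinctionTable, OpticalProps, SpectralParams,
                      mua_from_concentrations, musp_from_mie)

__all__ = [
    "FemSystem",
    "FluenceField",
    "MeasurementSet",
    "boundary_reflection_factor",
    "assemble_system",
    "nodal_volumes",
    "point_source_vector",
    "surface_source_vector",
    "detector_matrix",
    "solve_forward",
    "nodal_concentrations",
    "nodal_props",
    "simulate_measurements",
]


def boundary_reflection_factor(n_rel: float) -> float:
    """Internal-reflection parameter A of the Robin boundary term.

    Uses the critical-angle form for a relative refractive index ``n_rel``
    between medium and surroundings; A = 1 for a matched boundary.
    """
    if n_rel == 1.0:
        return 1.0
    r0 = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
    cos_c = abs(np.cos(np.arcsin(1.0 / n_rel)))
    return (2.0 / (1.0 - r0) - 1.0 + cos_c**3) / (1.0 - cos_c**2)


@dataclass
class FemSystem:
    """Assembled sparse symmetric system for one wavelength."""

    matrix: sp.csc_matrix
    mesh: TetMesh
    c0: float = 1.0
    boundary_A: float = 1.0
    _factor: object = field(default=None, repr=False)

    def factorize(self):
        if self._factor is None:
            self._factor = splu(self.matrix)
        return self._factor

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve for one RHS vector or a stack of columns (N, k)."""
        return self.factorize().solve(np.asarray(rhs))


@dataclass
class FluenceField:
    """Nodal photon fluence per active source (arbitrary source units)."""

    values: np.ndarray  # (n_nodes, n_active_sources)
    source_indices: np.ndarray  # original source ids, length n_active_sources
    wavelength: float = float("nan")


def _element_geometry(mesh: TetMesh):
    """Volumes (E,) and shape-function gradients (E, 4, 3), cached on mesh."""
    if "fem_geom" in mesh._cache:
        return mesh._cache["fem_geom"]
    x = mesh.nodes[mesh.elements]  # (E, 4, 3)
    T = x[:, 1:] - x[:, :1]  # (E, 3, 3) edge matrix rows
    vol = np.linalg.det(T) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise ValueError(f"degenerate or inverted element {bad} (volume {vol[bad]:g})")
    Tinv = np.linalg.inv(T)  # (E, 3, 3); columns are gradients of N1..N3
    grads = np.empty((len(vol), 4, 3))
    grads[:, 1:, :] = np.transpose(Tinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    mesh._cache["fem_geom"] = (vol, grads)
    return vol, grads


def nodal_volumes(mesh: TetMesh) -> np.ndarray:
    """Lumped nodal volume shares: a quarter of each adjacent element."""
    if "nodal_vol" not in mesh._cache:
        vol, _ = _element_geometry(mesh)
        w = np.zeros(mesh.n_nodes)
        for k in range(4):
            np.add.at(w, mesh.elements[:, k], vol / 4.0)
        mesh._cache["nodal_vol"] = w
    return mesh._cache["nodal_vol"]


def assemble_system(mesh: TetMesh, props: OpticalProps, c0: float = 1.0,
                    n_rel: float = 1.33, robin: bool = True) -> FemSystem:
    """Galerkin assembly of diffusion + absorption + Robin boundary terms.

    ``props`` holds nodal mua/musp/kappa (scalars are broadcast).  The
    diffusion stiffness uses the element mean of nodal kappa; the absorption
    and Robin terms are mass-lumped (diagonal).  On the structured Kuhn mesh
    the stiffness has non-positive off-diagonals, so lumping makes the full
    system an M-matrix and the discrete fluence of a positive source strictly
    positive — the monotonicity the measurement model relies on.
    """
    n = mesh.n_nodes
    mua = np.broadcast_to(props.mua, (n,)) if props.mua.size != n else props.mua
    kappa = np.broadcast_to(props.kappa, (n,)) if props.kappa.size != n else props.kappa
    if props.mua.size not in (1, n):
        raise ValueError(f"props defined on {props.mua.size} nodes, mesh has {n}")
    vol, grads = _element_geometry(mesh)
    elems = mesh.elements
    kap_e = kappa[elems].mean(axis=1)  # (E,)
    K = np.einsum("e,eid,ejd->eij", kap_e * vol, grads, grads)
    rows = np.repeat(elems, 4, axis=1).ravel()
    cols = np.tile(elems, (1, 4)).ravel()
    A = sp.coo_matrix((K.ravel(), (rows, cols)), shape=(n, n)).tocsc()
    diag = c0 * mua * nodal_volumes(mesh)
    bA = boundary_reflection_factor(n_rel)
    if robin:
        f = mesh.boundary_faces()
        p = mesh.nodes[f]
        area = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
        w = area / (3.0 * 2.0 * bA)
        for k in range(3):
            np.add.at(diag, f[:, k], w)
    A = A + sp.diags(diag, format="csc")
    return FemSystem(A.tocsc(), mesh, c0=c0, boundary_A=bA)


# ---------------------------------------------------------------------------
# sources and detectors
# ---------------------------------------------------------------------------

def point_source_vector(mesh: TetMesh, position) -> np.ndarray:
    """Unit isotropic point source distributed barycentrically."""
    e, w = mesh.locate(position)
    q = np.zeros(mesh.n_nodes)
    q[mesh.elements[e]] = w
    return q


def _inward_normal_at(mesh: TetMesh, position) -> np.ndarray:
    faces = mesh.boundary_faces()
    centers = mesh.nodes[faces].mean(axis=1)
    idx = int(np.argmin(np.linalg.norm(centers - position, axis=1)))
    return -mesh.boundary_face_normals()[idx]


def surface_source_vector(mesh: TetMesh, position, musp_local: float) -> np.ndarray:
    """Collimated-source model: point source 1/musp' beneath the surface."""
    inward = _inward_normal_at(mesh, position)
    depth = 1.0 / float(musp_local)
    return point_source_vector(mesh, np.asarray(position, float) + depth * inward)


def detector_matrix(mesh: TetMesh, optodes: OptodeSet) -> sp.csr_matrix:
    """Sparse (n_nodes, n_detectors) barycentric readout on boundary faces."""
    faces = mesh.boundary_faces()
    p = mesh.nodes[faces]
    centers = p.mean(axis=1)
    rows, cols, vals = [], [], []
    for d, pos in enumerate(optodes.detectors):
        idx = int(np.argmin(np.linalg.norm(centers - pos, axis=1)))
        a, b, c = p[idx]
        # project the detector point onto the face plane, then barycentric
        nvec = np.cross(b - a, c - a)
        nvec /= np.linalg.norm(nvec)
        q = pos - np.dot(pos - a, nvec) * nvec
        T = np.column_stack([b - a, c - a])
        lam, *_ = np.linalg.lstsq(T, q - a, rcond=None)
        w = np.clip(np.array([1.0 - lam.sum(), lam[0], lam[1]]), 0.0, None)
        w /= w.sum()
        rows.extend(faces[idx])
        cols.extend([d] * 3)
        vals.extend(w)
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(mesh.n_nodes, len(optodes.detectors)))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSet:
    """Per-(source, detector, wavelength) CW amplitudes.

    ``table`` columns: source, detector, wavelength, amplitude; canonical row
    order is wavelength-major then link-table order.  ``role`` tags whether
    the set is modelled (F) or measured (Y).
    """

    table: pd.DataFrame
    role: str = "simulated"

    def __post_init__(self):
        required = {"source", "detector", "wavelength", "amplitude"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"measurement table must have columns {sorted(required)}")
        if np.any(self.table["amplitude"].to_numpy() <= 0):
            raise ValueError("amplitudes must be strictly positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.unique(self.table["wavelength"].to_numpy())

    def amplitudes(self, lam: float | None = None) -> np.ndarray:
        t = self.table
        if lam is not None:
            t = t[np.isclose(t["wavelength"], lam)]
        return t["amplitude"].to_numpy()

    def log_amplitude(self, lam: float | None = None) -> np.ndarray:
        return np.log(self.amplitudes(lam))

    def with_amplitudes(self, amps: np.ndarray, role: str | None = None) -> "MeasurementSet":
        t = self.table.copy()
        t["amplitude"] = amps
        return MeasurementSet(t, role=role or self.role)

    def select_wavelengths(self, lams) -> "MeasurementSet":
        keep = np.zeros(len(self.table), dtype=bool)
        for l in np.atleast_1d(lams):
            keep |= np.isclose(self.table["wavelength"], l)
        return MeasurementSet(self.table[keep].reset_index(drop=True), role=self.role)

    def same_links(self, other: "MeasurementSet") -> bool:
        cols = ["source", "detector", "wavelength"]
        return len(self.table) == len(other.table) and \
            bool((self.table[cols].to_numpy() == other.table[cols].to_numpy()).all())


def _measurement_frame(optodes: OptodeSet, wavelengths, amps_by_lam) -> pd.DataFrame:
    rows = []
    for lam in wavelengths:
        amps = amps_by_lam[lam]
        for (s, d), a in zip(optodes.links, amps):
            rows.append((int(s), int(d), float(lam), float(a)))
    return pd.DataFrame(rows, columns=["source", "detector", "wavelength", "amplitude"])


def solve_forward(system: FemSystem, optodes: OptodeSet,
                  musp_for_sources: float | np.ndarray = 1.0,
                  wavelength: float = float("nan")):
    """Fluence for every active source and amplitudes for every link."""
    mesh = system.mesh
    act = np.nonzero(optodes.source_active)[0]
    rhs = np.column_stack([
        surface_source_vector(mesh, optodes.sources[s],
                              np.atleast_1d(musp_for_sources)[0]) for s in act])
    phi = system.solve(rhs)
    if phi.ndim == 1:
        phi = phi[:, None]
    D = detector_matrix(mesh, optodes)
    amp_sd = phi.T @ D  # (n_active, n_detectors)
    col = {int(s): i for i, s in enumerate(act)}
    amps = np.array([amp_sd[col[int(s)], int(d)] for s, d in optodes.links])
    return FluenceField(phi, act, wavelength), amps


def nodal_concentrations(mesh: TetMesh, region_values: dict) -> np.ndarray:
    """Volume-weighted nodal field from per-region element values."""
    vol = mesh.element_volumes()
    val = np.array([region_values[int(r)] for r in mesh.regions])
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for k in range(4):
        np.add.at(num, mesh.elements[:, k], vol * val)
        np.add.at(den, mesh.elements[:, k], vol)
    return num / den


def nodal_props(mesh: TetMesh, region_params: dict, table: ExtinctionTable,
                lam: float, musp_by_wavelength: dict | None = None) -> OpticalProps:
    """Nodal optical properties at one wavelength from per-region spectra."""
    chroms = table.chromophores
    conc = {}
    for name in chroms:
        conc[name] = nodal_concentrations(
            mesh, {r: p.concentrations[name] for r, p in region_params.items()})
    params = SpectralParams(concentrations=conc, a=1.0, b=1.0)
    mua = mua_from_concentrations(table, params, lam)
    if musp_by_wavelength is not None:
        musp = np.full(mesh.n_nodes, musp_by_wavelength[lam])
    else:
        musp = nodal_concentrations(
            mesh, {r: musp_from_mie(p.a, p.b, lam) for r, p in region_params.items()})
    return OpticalProps(mua=mua, musp=musp)


def simulate_measurements(mesh: TetMesh, region_params: dict,
                          optodes: OptodeSet, wavelengths,
                          table: ExtinctionTable,
                          noise_fraction: float = 0.0,
                          seed: int | None = None,
                          musp_by_wavelength: dict | None = None,
                          c0: float = 1.0, n_rel: float = 1.33,
                          role: str = "simulated") -> MeasurementSet:
    """Forward-model CW amplitudes on a labelled mesh at several wavelengths.

    Optional multiplicative Gaussian amplitude noise (fraction of each
    amplitude); deterministic under a fixed seed.
    """
    if noise_fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    rng = np.random.default_rng(seed)
    amps_by_lam = {}
    for lam in wavelengths:
        props = nodal_props(mesh, region_params, table, lam, musp_by_wavelength)
        system = assemble_system(mesh, props, c0=c0, n_rel=n_rel)
        _, amps = solve_forward(system, optodes,
                                musp_for_sources=float(np.mean(props.musp)),
                                wavelength=lam)
        if np.any(amps <= 0):
            raise RuntimeError("non-positive simulated amplitude")
        if noise_fraction > 0:
            amps = amps * (1.0 + noise_fraction * rng.standard_normal(len(amps)))
            amps = np.clip(amps, 1e-300, None)
        amps_by_lam[lam] = amps
    return MeasurementSet(_measurement_frame(optodes, wavelengths, amps_by_lam),
                          role=role)
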