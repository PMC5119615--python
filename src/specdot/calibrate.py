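"""Pre-reconstruction data conditioning.

Raw camera amplitudes carry per-source coupling efficiencies and the
spectral response of the camera/filter chain.  Calibration proceeds in three
steps, all linear in log-amplitude:

1. divide each link's amplitude by its source strength and wavelength
   response (the system characterization);
2. fit homogeneous bulk optical properties to a reference (homogeneous)
   dataset.  CW amplitude-only data cannot separate mua from musp', so by
   default musp' is fixed to a prior and only mua is fitted; a bounded
   two-parameter search is available;
3. compute a per-link model offset, log Y_homog - log F_homog, which is
   subtracted from the heterogeneous data before reconstruction so that
   unmodelled per-link gains cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .fem import (MeasurementSet, OpticalProps, assemble_system, solve_forward)
from .meshing import OptodeSet, TetMesh

__all__ = [
    "SystemCharacterization",
    "CalibrationResult",
    "normalize_raw",
    "homogeneous_fit",
    "compute_data_offset",
    "apply_data_offset",
    "calibrate_dataset",
]


@dataclass
class SystemCharacterization:
    """Per-source relative strengths and per-wavelength spectral response."""

    source_strength: dict  # source id -> factor (> 0)
    spectral_response: dict  # wavelength nm -> factor (> 0)

    def __post_init__(self):
        if any(v <= 0 for v in self.source_strength.values()) or \
           any(v <= 0 for v in self.spectral_response.values()):
            raise ValueError("characterization factors must be > 0")

    def factor(self, source: int, lam: float) -> float:
        try:
            s = self.source_strength[int(source)]
        except KeyError:
            raise KeyError(f"no source-strength factor for source {source}") from None
        resp = None
        for k, v in self.spectral_response.items():
            if np.isclose(k, lam):
                resp = v
                break
        if resp is None:
            raise KeyError(f"no spectral-response factor for wavelength {lam} nm")
        return s * resp

    def to_csv(self, source_path, response_path) -> None:
        pd.DataFrame({"source_id": list(self.source_strength),
                      "strength": list(self.source_strength.values())}
                     ).to_csv(source_path, index=False)
        pd.DataFrame({"wavelength_nm": list(self.spectral_response),
                      "response": list(self.spectral_response.values())}
                     ).to_csv(response_path, index=False)

    @classmethod
    def from_csv(cls, source_path, response_path) -> "SystemCharacterization":
        s = pd.read_csv(source_path)
        r = pd.read_csv(response_path)
        return cls(dict(zip(s["source_id"].astype(int), s["strength"])),
                   dict(zip(r["wavelength_nm"].astype(float), r["response"])))


def normalize_raw(raw: MeasurementSet, char: SystemCharacterization) -> MeasurementSet:
    """Divide every amplitude by source strength x spectral response."""
    t = raw.table
    factors = np.array([char.factor(s, l) for s, l in
                        zip(t["source"], t["wavelength"])])
    return raw.with_amplitudes(t["amplitude"].to_numpy() / factors,
                               role="normalized")


@dataclass
class CalibrationResult:
    """Bulk properties per wavelength plus per-link model offsets."""

    bulk_mua: dict
    bulk_musp: dict
    offsets: pd.DataFrame  # source, detector, wavelength, offset (log-amplitude)
    reference: str = ""


def _homog_log_forward(mesh: TetMesh, optodes: OptodeSet, mua: float,
                       musp: float, n_rel: float, c0: float) -> np.ndarray:
    props = OpticalProps(mua=np.full(mesh.n_nodes, mua),
                         musp=np.full(mesh.n_nodes, musp))
    system = assemble_system(mesh, props, c0=c0, n_rel=n_rel)
    _, amps = solve_forward(system, optodes, musp_for_sources=musp)
    # strongly absorbing trials can undershoot to non-positive amplitudes on
    # coarse meshes; clip so the search sees a large but finite penalty
    return np.log(np.clip(amps, 1e-300, None))


def homogeneous_fit(data: MeasurementSet, mesh: TetMesh, optodes: OptodeSet,
                    lam: float, musp_prior: float = 1.0,
                    fit_musp: bool = False,
                    mua_bounds=(1e-4, 0.1), musp_bounds=(0.2, 3.0),
                    n_rel: float = 1.33, c0: float = 1.0,
                    xatol: float = 1e-6):
    """Estimate global (mua, musp') from homogeneous-phantom data at ``lam``.

    Minimizes the squared log-amplitude misfit between the data and a
    homogeneous forward model.  With ``fit_musp=False`` (the default) musp'
    stays at ``musp_prior`` and a bounded scalar search fits mua only,
    acknowledging the CW absorption/scattering degeneracy.
    """
    logY = data.log_amplitude(lam)
    if len(logY) != optodes.n_links:
        raise ValueError("data links do not match the optode set")
    if len(np.unique(np.round(
            np.linalg.norm(optodes.sources[optodes.links[:, 0]]
                           - optodes.detectors[optodes.links[:, 1]], axis=1), 6))) < 2:
        raise ValueError("need at least 2 distinct source-detector separations")

    if not fit_musp:
        def obj(mua):
            r = logY - _homog_log_forward(mesh, optodes, mua, musp_prior, n_rel, c0)
            return float(r @ r)
        res = minimize_scalar(obj, bounds=mua_bounds, method="bounded",
                              options={"xatol": xatol})
        if not res.success:
            raise RuntimeError(f"homogeneous fit did not converge: {res.message}")
        return float(res.x), float(musp_prior)

    def obj2(x):
        mua, musp = np.exp(x)
        r = logY - _homog_log_forward(mesh, optodes, mua, musp, n_rel, c0)
        return float(r @ r)
    x0 = np.log([np.sqrt(mua_bounds[0] * mua_bounds[1]), musp_prior])
    res = minimize(obj2, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200})
    mua, musp = np.exp(res.x)
    mua = float(np.clip(mua, *mua_bounds))
    musp = float(np.clip(musp, *musp_bounds))
    return mua, musp


def compute_data_offset(measured: MeasurementSet,
                        modeled: MeasurementSet) -> pd.DataFrame:
    """Per-link, per-wavelength log-amplitude offsets log Y - log F."""
    if not measured.same_links(modeled):
        raise ValueError("measured and modeled link tables differ")
    out = measured.table[["source", "detector", "wavelength"]].copy()
    out["offset"] = np.log(measured.table["amplitude"].to_numpy()) \
        - np.log(modeled.table["amplitude"].to_numpy())
    return out


def apply_data_offset(data: MeasurementSet, offsets: pd.DataFrame) -> MeasurementSet:
    """Subtract offsets in log-amplitude: amplitude / exp(offset)."""
    cols = ["source", "detector", "wavelength"]
    if len(data.table) != len(offsets) or \
       not (data.table[cols].to_numpy() == offsets[cols].to_numpy()).all():
        raise ValueError("offset link table does not match the data")
    amps = data.table["amplitude"].to_numpy() / np.exp(offsets["offset"].to_numpy())
    return data.with_amplitudes(amps, role="calibrated")


def calibrate_dataset(raw_heterogeneous: MeasurementSet,
                      raw_homogeneous: MeasurementSet,
                      char: SystemCharacterization,
                      mesh: TetMesh, optodes: OptodeSet,
                      musp_prior_by_wavelength: dict,
                      n_rel: float = 1.33, c0: float = 1.0):
    """Full chain: normalize both sets, fit bulk properties on the
    homogeneous set, compute model offsets, and correct the heterogeneous
    set.  Returns (calibrated MeasurementSet, CalibrationResult)."""
    het = normalize_raw(raw_heterogeneous, char)
    hom = normalize_raw(raw_homogeneous, char)
    bulk_mua, bulk_musp, model_rows = {}, {}, []
    for lam in hom.wavelengths:
        lam = float(lam)
        mua, musp = homogeneous_fit(hom, mesh, optodes, lam,
                                    musp_prior=musp_prior_by_wavelength[lam],
                                    n_rel=n_rel, c0=c0)
        bulk_mua[lam], bulk_musp[lam] = mua, musp
        logF = _homog_log_forward(mesh, optodes, mua, musp, n_rel, c0)
        sub = hom.table[np.isclose(hom.table["wavelength"], lam)].copy()
        sub["amplitude"] = np.exp(logF)
        model_rows.append(sub)
    modeled = MeasurementSet(pd.concat(model_rows).reset_index(drop=True),
                             role="modeled")
    hom_sorted = MeasurementSet(
        pd.concat([hom.table[np.isclose(hom.table["wavelength"], l)]
                   for l in hom.wavelengths]).reset_index(drop=True), role=hom.role)
    offsets = compute_data_offset(hom_sorted, modeled)
    het_sorted = MeasurementSet(
        pd.concat([het.table[np.isclose(het.table["wavelength"], l)]
                   for l in hom.wavelengths]).reset_index(drop=True), role=het.role)
    calibrated = apply_data_offset(het_sorted, offsets)
    result = CalibrationResult(bulk_mua=bulk_mua, bulk_musp=bulk_musp,
                               offsets=offsets, reference=raw_homogeneous.role)
    return calibrated, result
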