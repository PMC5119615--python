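"""Chromophore spectra and per-wavelength optical properties.

Continuous-wave DOT measures light attenuation at a handful of near-infrared
wavelengths.  The absorption coefficient at each wavelength is modelled as a
linear combination of chromophore concentrations,

    mua(lambda) = sum_i  eps_i(lambda) * C_i ,

and the reduced scattering coefficient by the empirical Mie power law

    musp(lambda) = a * (lambda / lambda_ref)**(-b) ,

with the diffusion coefficient kappa = 1 / (3 * (mua + musp)).  This module
maps between the spectral parameters (C_i, a, b) and per-wavelength optical
properties (mua, musp, kappa), in both directions.

Two chromophore sets are used in practice: a *tissue* set (oxy-/deoxy-
haemoglobin in mM, water as a volume fraction) and a *phantom* set with a
single dye whose extinction spectrum is the background absorption of the
characterized solid phantom, so that the background has normalized
concentration 1 by construction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SYSTEM_WAVELENGTHS",
    "LAMBDA_REF",
    "BLOCK_PHANTOM_MUA_BACKGROUND",
    "BLOCK_PHANTOM_MUSP_BACKGROUND",
    "BLOCK_PHANTOM_ANOMALY_MUA_730",
    "BLOCK_PHANTOM_ANOMALY_MUSP_730",
    "BLOCK_PHANTOM_ANOMALY_CONCENTRATION",
    "ExtinctionTable",
    "SpectralParams",
    "OpticalProps",
    "phantom_dye_table",
    "tissue_table",
    "mua_from_concentrations",
    "musp_from_mie",
    "diffusion_coefficient",
    "fit_spectral_params",
]

#: The five interference-filter bands of the imaging system (nm).
SYSTEM_WAVELENGTHS = (690.0, 730.0, 750.0, 850.0, 930.0)

#: Wavelength normalization of the Mie power law, so that ``a`` carries
#: musp units (mm^-1) and equals musp at 1000 nm.
LAMBDA_REF = 1000.0

# Manufacturer-characterized optical properties of the solid block phantom
# (INO-style epoxy phantom), mm^-1.
BLOCK_PHANTOM_MUA_BACKGROUND = {
    690.0: 0.0187,
    730.0: 0.0179,
    750.0: 0.0181,
    850.0: 0.0162,
    930.0: 0.0149,
}
BLOCK_PHANTOM_MUSP_BACKGROUND = {
    690.0: 1.1608,
    730.0: 1.0662,
    750.0: 1.0648,
    850.0: 0.9825,
    930.0: 0.9515,
}
#: Anomaly (rod) absorption is only characterized at 730 nm.
BLOCK_PHANTOM_ANOMALY_MUA_730 = 0.02
BLOCK_PHANTOM_ANOMALY_MUSP_730 = 1.8
#: Normalized dye concentration of the rods relative to the background.
BLOCK_PHANTOM_ANOMALY_CONCENTRATION = 1.068


class WavelengthLookupError(KeyError):
    """Requested wavelength is not tabulated (no interpolation by default)."""


class IllConditionedFitError(ValueError):
    """Spectral fit design matrix is rank deficient."""


@dataclass
class ExtinctionTable:
    """Per-chromophore extinction coefficients on an explicit wavelength grid.

    Parameters
    ----------
    wavelengths:
        Strictly increasing wavelengths in nm.
    chromophores:
        Chromophore names, one per column of ``extinction``.
    extinction:
        Array of shape ``(n_wavelengths, n_chromophores)``.  Units are
        mm^-1 per concentration unit (mm^-1/mM for haemoglobins, mm^-1 per
        volume fraction for water, mm^-1 per normalized unit for phantom dye).
    """

    wavelengths: np.ndarray
    chromophores: tuple
    extinction: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.extinction = np.atleast_2d(np.asarray(self.extinction, dtype=float))
        self.chromophores = tuple(self.chromophores)
        if self.extinction.shape != (len(self.wavelengths), len(self.chromophores)):
            raise ValueError(
                f"extinction shape {self.extinction.shape} does not match "
                f"{len(self.wavelengths)} wavelengths x {len(self.chromophores)} chromophores"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.extinction < 0):
            raise ValueError("extinction coefficients must be non-negative")

    def _index(self, lam: float) -> int:
        idx = np.nonzero(np.isclose(self.wavelengths, lam, rtol=0, atol=1e-9))[0]
        if len(idx) == 0:
            raise WavelengthLookupError(
                f"wavelength {lam} nm not in table {list(self.wavelengths)}"
            )
        return int(idx[0])

    def epsilon(self, lam: float) -> np.ndarray:
        """Extinction row for one wavelength, shape (n_chromophores,)."""
        return self.extinction[self._index(lam)]

    def epsilon_of(self, name: str, lam: float) -> float:
        if name not in self.chromophores:
            raise KeyError(f"chromophore {name!r} not in table {self.chromophores}")
        return float(self.extinction[self._index(lam), self.chromophores.index(name)])

    def subset(self, wavelengths: Sequence[float] | None = None,
               chromophores: Sequence[str] | None = None) -> "ExtinctionTable":
        """Restrict the table, e.g. dropping water and/or the 930 nm band."""
        lams = self.wavelengths if wavelengths is None else np.asarray(wavelengths, float)
        rows = [self._index(l) for l in lams]
        names = self.chromophores if chromophores is None else tuple(chromophores)
        cols = [self.chromophores.index(n) for n in names]
        return ExtinctionTable(self.wavelengths[rows], names,
                               self.extinction[np.ix_(rows, cols)])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.extinction, columns=list(self.chromophores))
        df.insert(0, "wavelength_nm", self.wavelengths)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise ValueError(f"{path}: missing 'wavelength_nm' column")
        names = tuple(c for c in df.columns if c != "wavelength_nm")
        return cls(df["wavelength_nm"].to_numpy(), names, df[list(names)].to_numpy())


def phantom_dye_table() -> ExtinctionTable:
    """Single-dye extinction table for the solid block phantom.

    The dye extinction at each wavelength equals the background absorption
    coefficient, so the homogeneous background has normalized concentration 1.
    """
    lams = np.array(sorted(BLOCK_PHANTOM_MUA_BACKGROUND))
    eps = np.array([[BLOCK_PHANTOM_MUA_BACKGROUND[l]] for l in lams])
    return ExtinctionTable(lams, ("dye",), eps)


def tissue_table() -> ExtinctionTable:
    """HbO2 / Hb / water extinction table at the five system wavelengths.

    Shipped as packaged CSV compiled from standard literature compilations of
    haemoglobin molar extinction and water absorption spectra; replaceable by
    any user table with the same column layout (see ``ExtinctionTable.from_csv``).
    """
    ref = importlib.resources.files("specdot.data").joinpath("extinction_tissue.csv")
    with importlib.resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path)


@dataclass
class SpectralParams:
    """Chromophore concentrations plus Mie scattering amplitude/power.

    ``concentrations`` maps chromophore name to a scalar (per region) or to a
    nodal array.  ``a`` and ``b`` are the scattering amplitude (mm^-1 at
    ``LAMBDA_REF``) and power.
    """

    concentrations: dict = field(default_factory=dict)
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self):
        for name, c in self.concentrations.items():
            if np.any(np.asarray(c) < 0):
                raise ValueError(f"concentration of {name!r} must be >= 0")
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be > 0")

    @property
    def hbt(self) -> float:
        """Total haemoglobin concentration HbO2 + Hb (tissue mode)."""
        return self.concentrations["HbO2"] + self.concentrations["Hb"]


def mua_from_concentrations(table: ExtinctionTable, params: SpectralParams,
                            lam: float):
    """Absorption coefficient mua(lambda) = sum_i eps_i(lambda) C_i (mm^-1)."""
    eps = table.epsilon(lam)
    out = 0.0
    for name, e in zip(table.chromophores, eps):
        out = out + e * np.asarray(params.concentrations[name])
    return out


def musp_from_mie(a: float, b: float, lam: float, lam_ref: float = LAMBDA_REF):
    """Reduced scattering musp = a * (lambda/lambda_ref)**(-b) (mm^-1)."""
    if np.any(np.asarray(a) <= 0):
        raise ValueError("scattering amplitude a must be > 0")
    return a * (lam / lam_ref) ** (-b)


def diffusion_coefficient(mua, musp):
    """Diffusion coefficient kappa = 1/(3 (mua + musp)) in mm."""
    total = np.asarray(mua, dtype=float) + np.asarray(musp, dtype=float)
    if np.any(total <= 0):
        raise ValueError("mua + musp must be > 0")
    return 1.0 / (3.0 * total)


def fit_spectral_params(mua_by_wavelength: Mapping[float, float],
                        musp_by_wavelength: Mapping[float, float],
                        table: ExtinctionTable) -> SpectralParams:
    """Fit (C_i, a, b) to per-wavelength optical properties.

    Concentrations come from non-negative linear least squares on the
    chromophore model; (a, b) from ordinary least squares on
    ln musp = ln a - b ln(lambda/lambda_ref).
    """
    lams = sorted(mua_by_wavelength)
    if len(lams) == 0:
        raise ValueError("need at least one wavelength")
    if len(lams) < len(table.chromophores):
        raise ValueError(
            f"{len(lams)} wavelengths cannot constrain {len(table.chromophores)} chromophores"
        )
    E = np.array([table.epsilon(l) for l in lams])
    if np.linalg.matrix_rank(E) < len(table.chromophores):
        raise IllConditionedFitError(
            "extinction spectra are collinear at the given wavelengths"
        )
    y = np.array([mua_by_wavelength[l] for l in lams], dtype=float)
    conc, _ = nnls(E, y)

    lams_s = sorted(musp_by_wavelength)
    x = np.log(np.array(lams_s) / LAMBDA_REF)
    z = np.log([musp_by_wavelength[l] for l in lams_s])
    if len(lams_s) == 1:
        ln_a, slope = z[0], -1.0  # single point: pin b = 1
    else:
        A = np.column_stack([np.ones_like(x), -x])
        (ln_a, bpow), *_ = np.linalg.lstsq(A, z, rcond=None)
        slope = bpow
    return SpectralParams(
        concentrations={n: float(c) for n, c in zip(table.chromophores, conc)},
        a=float(np.exp(ln_a)),
        b=float(slope),
    )


@dataclass
class OpticalProps:
    """Per-node (or per-region) optical properties at one wavelength.

    ``kappa`` is derived from mua and musp at construction, but is stored as
    an independent field: the absorption Jacobian of the reconstruction is
    defined at fixed kappa, and perturbing ``mua`` alone leaves ``kappa``
    untouched until :meth:`refresh_kappa` is called.
    """

    mua: np.ndarray
    musp: np.ndarray
    kappa: np.ndarray = None

    def __post_init__(self):
        self.mua = np.atleast_1d(np.asarray(self.mua, dtype=float)).copy()
        self.musp = np.atleast_1d(np.asarray(self.musp, dtype=float)).copy()
        if self.musp.shape != self.mua.shape:
            self.musp = np.broadcast_to(self.musp, self.mua.shape).copy()
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise ValueError("mua and musp must be strictly positive")
        if self.kappa is None:
            self.kappa = diffusion_coefficient(self.mua, self.musp)
        else:
            self.kappa = np.broadcast_to(
                np.atleast_1d(np.asarray(self.kappa, dtype=float)), self.mua.shape
            ).copy()

    def refresh_kappa(self) -> None:
        self.kappa = diffusion_coefficient(self.mua, self.musp)

    @property
    def n(self) -> int:
        return len(self.mua)
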