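"""Phase-shifting fringe-projection profilometry.

Surface shape is measured by projecting sinusoidal fringe patterns at several
spatial frequencies, each shifted N times in phase.  The wrapped phase at one
frequency is the four-quadrant arctangent

    phi = atan2( sum_i sin(delta_i) I_i ,  sum_i cos(delta_i) I_i ),

exact for uniform shifts delta_k = 2 pi k / N.  Wrapped maps are unwrapped
temporally up the frequency ladder (the 1 wave/image map is unambiguous), and
the unwrapped phase difference between object and reference plane is mapped
to height through the rational calibration model

    Zp = [1 + C1 P + (C2 + C3 P) I + (C4 + C5 P) J]
         / [D0 + D1 P + (D2 + D3 P) I + (D4 + D5 P) J],

whose 11 coefficients are fitted by linear least squares from planes of known
height.  Pixel coordinates I (row) and J (column) are 0-based, origin
top-left; heights are mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "SYSTEM_PHASE_SHIFTS",
    "uniform_phase_shifts",
    "FringePatternSet",
    "PhaseMap",
    "HeightCalibration",
    "HeightMap",
    "generate_fringe_patterns",
    "wrapped_phase",
    "unwrap_temporal",
    "fit_height_calibration",
    "height_from_phase",
    "phase_from_height",
    "measure_height",
    "wrap_phase",
]

#: The five shifts used by the physical system: pi/3 .. 5 pi/3.  They span
#: only 5/6 of the circle, which biases the N-step estimator for images with
#: a DC offset; the uniform default below is exact.
SYSTEM_PHASE_SHIFTS = tuple(np.pi * k / 3 for k in range(1, 6))


def uniform_phase_shifts(n: int = 5) -> tuple:
    """N uniform shifts 2 pi k / N, the exact N-step set."""
    return tuple(2 * np.pi * k / n for k in range(n))


class NonUniformShiftsError(ValueError):
    """Phase shifts do not uniformly cover the circle (strict mode)."""


class DegenerateCalibrationError(ValueError):
    """Height-calibration design matrix is rank deficient."""


def wrap_phase(x):
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x, dtype=float), 2 * np.pi)


@dataclass
class FringePatternSet:
    """Stacks of phase-shifted fringe images, one sub-stack per frequency.

    ``images`` has shape (n_frequencies, n_shifts, H, W); ``frequencies`` are
    waves per image (strictly increasing), ``phase_shifts`` the shared shift
    set delta_i in radians.  ``offset`` and ``modulation`` record the A and B
    used at synthesis time.
    """

    images: np.ndarray
    frequencies: tuple
    phase_shifts: tuple
    offset: float = float("nan")
    modulation: float = float("nan")

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.frequencies = tuple(float(f) for f in self.frequencies)
        self.phase_shifts = tuple(float(d) for d in self.phase_shifts)
        if self.images.ndim != 4:
            raise ValueError("images must have shape (n_freq, n_shift, H, W)")
        if self.images.shape[0] != len(self.frequencies) or \
           self.images.shape[1] != len(self.phase_shifts):
            raise ValueError("image stack does not match frequency/shift lists")
        if len(self.phase_shifts) < 3:
            raise ValueError("at least 3 phase shifts are required")
        if any(f2 <= f1 for f1, f2 in zip(self.frequencies, self.frequencies[1:])):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def n_shifts(self) -> int:
        return len(self.phase_shifts)

    def stack(self, frequency: float) -> np.ndarray:
        for i, f in enumerate(self.frequencies):
            if np.isclose(f, frequency):
                return self.images[i]
        raise KeyError(f"frequency {frequency} not in set {self.frequencies}")


@dataclass
class PhaseMap:
    """2-D phase raster; ``kind`` is 'wrapped' or 'unwrapped'."""

    values: np.ndarray
    kind: str
    frequency: float
    suspect: np.ndarray = None  # pixels where unwrapping looked unreliable

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("wrapped", "unwrapped"):
            raise ValueError("kind must be 'wrapped' or 'unwrapped'")


@dataclass
class HeightCalibration:
    """Coefficients C1..C5, D0..D5 of the rational height model."""

    C: np.ndarray  # (5,) C1..C5
    D: np.ndarray  # (6,) D0..D5

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float).ravel()
        self.D = np.asarray(self.D, dtype=float).ravel()
        if self.C.shape != (5,) or self.D.shape != (6,):
            raise ValueError("calibration needs exactly C1..C5 and D0..D5")

    def numerator(self, phase, I, J):
        C1, C2, C3, C4, C5 = self.C
        return 1.0 + C1 * phase + (C2 + C3 * phase) * I + (C4 + C5 * phase) * J

    def denominator(self, phase, I, J):
        D0, D1, D2, D3, D4, D5 = self.D
        return D0 + D1 * phase + (D2 + D3 * phase) * I + (D4 + D5 * phase) * J

    def reference_phase(self, shape) -> np.ndarray:
        """Model phase of the zero-height reference plane.

        The rational model's numerator constant is fixed at 1, so phase 0
        cannot map to height 0 at every pixel; the reference plane instead
        carries this per-pixel phase offset, which the measurement chain adds
        to the object-minus-reference phase difference before evaluating the
        model.
        """
        return phase_from_height(np.zeros(shape), self)


@dataclass
class HeightMap:
    """Surface height raster (mm) with pixel pitch and validity mask."""

    values: np.ndarray
    pitch: float = 1.0
    mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be > 0")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)


# ---------------------------------------------------------------------------
# synthesis and phase extraction
# ---------------------------------------------------------------------------

def _carrier(frequency: float, width: int, height: int) -> np.ndarray:
    """Projector carrier phase, centred so the 1 wave/image map stays in
    (-pi, pi] and is unambiguous."""
    u = np.arange(width)
    ramp = 2 * np.pi * frequency * (u + 0.5 - width / 2) / width
    return np.broadcast_to(ramp, (height, width)).copy()


def generate_fringe_patterns(width: int, height: int, frequencies,
                             phase_shifts=None, offset: float = 120.0,
                             modulation: float = 100.0,
                             scene_phase: np.ndarray | None = None,
                             rng: np.random.Generator | None = None,
                             noise_sigma: float = 0.0) -> FringePatternSet:
    """Render phase-shifted sinusoidal fringe stacks.

    Each image is I_i = A + B cos(carrier_f + theta_f - delta_i).  The
    optional ``scene_phase`` is the object-induced phase *at the highest
    frequency*; it scales proportionally to frequency down the ladder, as a
    height-induced lateral fringe displacement does.
    """
    if phase_shifts is None:
        phase_shifts = uniform_phase_shifts(5)
    phase_shifts = tuple(float(d) for d in phase_shifts)
    if len(phase_shifts) < 3:
        raise ValueError("at least 3 phase shifts are required")
    if modulation > offset:
        raise ValueError("modulation must not exceed offset (negative intensities)")
    frequencies = tuple(float(f) for f in frequencies)
    f_max = max(frequencies) if frequencies else 1.0
    theta = np.zeros((height, width)) if scene_phase is None \
        else np.asarray(scene_phase, dtype=float)
    images = np.empty((len(frequencies), len(phase_shifts), height, width))
    for i, f in enumerate(frequencies):
        total = _carrier(f, width, height) + theta * (f / f_max if f_max else 0.0)
        for j, d in enumerate(phase_shifts):
            images[i, j] = offset + modulation * np.cos(total - d)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng()
        images = images + noise_sigma * rng.standard_normal(images.shape)
    return FringePatternSet(images, frequencies, phase_shifts,
                            offset=offset, modulation=modulation)


def _shifts_are_uniform(shifts: np.ndarray) -> bool:
    z1 = np.exp(1j * shifts).sum()
    z2 = np.exp(2j * shifts).sum()
    return abs(z1) < 1e-8 and abs(z2) < 1e-8


def wrapped_phase(patterns: FringePatternSet, frequency: float,
                  strict: bool = False) -> PhaseMap:
    """Per-pixel N-step wrapped phase of one frequency sub-stack."""
    stack = patterns.stack(frequency)
    shifts = np.asarray(patterns.phase_shifts)
    if not _shifts_are_uniform(shifts):
        msg = ("phase shifts do not uniformly cover 2 pi; the N-step "
               "estimator is biased for images with a DC offset")
        if strict:
            raise NonUniformShiftsError(msg)
        warnings.warn(msg, stacklevel=2)
    num = np.tensordot(np.sin(shifts), stack, axes=(0, 0))
    den = np.tensordot(np.cos(shifts), stack, axes=(0, 0))
    values = np.arctan2(num, den)
    # move the branch point so values lie in (-pi, pi]
    values = np.where(values <= -np.pi, np.pi, values)
    return PhaseMap(values, "wrapped", frequency)


def unwrap_temporal(phase_maps, frequencies=None,
                    flag_threshold: float = 0.25) -> PhaseMap:
    """Unwrap a low-to-high ladder of wrapped maps pairwise.

    Phi_high = phi_high + 2 pi round((r Phi_low - phi_high) / 2 pi) with
    r = f_high / f_low; rounding is half away from zero.  The lowest rung is
    taken as already unwrapped.  Pixels whose fringe-order residual exceeds
    ``flag_threshold`` (fraction of a period) are flagged as suspect.
    """
    maps = list(phase_maps)
    if not maps:
        raise ValueError("need at least one phase map")
    freqs = [m.frequency for m in maps] if frequencies is None else list(frequencies)
    if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
        raise ValueError("phase maps must be ordered low to high frequency")
    phi = maps[0].values.copy()
    suspect = np.zeros(phi.shape, dtype=bool)
    for m, f_lo, f_hi in zip(maps[1:], freqs[:-1], freqs[1:]):
        r = f_hi / f_lo
        x = (r * phi - m.values) / (2 * np.pi)
        order = np.sign(x) * np.floor(np.abs(x) + 0.5)  # half away from zero
        suspect |= np.abs(x - order) > flag_threshold
        phi = m.values + 2 * np.pi * order
    return PhaseMap(phi, "unwrapped", freqs[-1], suspect=suspect)


# ---------------------------------------------------------------------------
# height calibration
# ---------------------------------------------------------------------------

def _pixel_grids(shape):
    I, J = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return I.astype(float), J.astype(float)


def fit_height_calibration(plane_data, max_equations: int = 50_000,
                           rng_seed: int = 0) -> HeightCalibration:
    """Fit C1..C5, D0..D5 from (unwrapped phase map, known height) planes.

    Multiplying the rational model through by its denominator gives one
    linear equation per pixel with the numerator constant fixed at 1:

        -(C terms) + Zp * (D terms) = 1.

    Requires at least 11 independent equations from >= 2 distinct heights.
    """
    rows, rhs = [], []
    heights = set()
    n_eq = sum(m.values.size for m, _ in plane_data)
    if n_eq < 11:
        raise ValueError(f"{n_eq} equations cannot determine 11 coefficients")
    stride = max(int(np.sqrt(n_eq / max_equations)), 1)
    for pmap, z in plane_data:
        heights.add(float(z))
        P = pmap.values[::stride, ::stride]
        I, J = _pixel_grids(pmap.values.shape)
        I, J = I[::stride, ::stride], J[::stride, ::stride]
        P, I, J = P.ravel(), I.ravel(), J.ravel()
        z = float(z)
        block = np.column_stack([
            -P, -I, -P * I, -J, -P * J,                       # C1..C5
            z * np.ones_like(P), z * P, z * I, z * P * I,     # D0..D3
            z * J, z * P * J,                                  # D4, D5
        ])
        rows.append(block)
        rhs.append(np.ones(len(P)))
    if len(heights) < 2:
        raise DegenerateCalibrationError(
            "all calibration planes share one height; the design is rank deficient")
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 11:
        raise DegenerateCalibrationError(
            f"calibration design rank {rank} < 11; add planes or texture")
    return HeightCalibration(C=coef[:5], D=coef[5:])


def height_from_phase(phase: PhaseMap, calib: HeightCalibration,
                      smoothing: int | None = None, pitch: float = 1.0,
                      den_tol: float = 1e-9) -> HeightMap:
    """Evaluate the rational height model; optional k x k mean filter.

    Pixels whose denominator magnitude falls below ``den_tol`` are masked
    invalid.  ``smoothing`` is the mean-filter kernel size (e.g. 3); None
    disables filtering and makes the chain exactly deterministic.
    """
    I, J = _pixel_grids(phase.values.shape)
    num = calib.numerator(phase.values, I, J)
    den = calib.denominator(phase.values, I, J)
    mask = np.abs(den) > den_tol
    z = np.where(mask, num / np.where(mask, den, 1.0), np.nan)
    if smoothing is not None:
        if smoothing < 1 or smoothing % 2 == 0:
            raise ValueError("smoothing kernel must be a positive odd size")
        z = uniform_filter(np.where(mask, z, 0.0), size=smoothing, mode="nearest")
    return HeightMap(z, pitch=pitch, mask=mask)


def phase_from_height(heights: np.ndarray, calib: HeightCalibration,
                      tol: float = 1e-12) -> np.ndarray:
    """Invert the rational model pixelwise: the unwrapped phase that yields
    the given heights.  The model is linear in phase, so

        Phi = [1 + C2 I + C4 J - Zp (D0 + D2 I + D4 J)]
              / [Zp (D1 + D3 I + D5 J) - (C1 + C3 I + C5 J)].
    """
    Z = np.asarray(heights, dtype=float)
    I, J = _pixel_grids(Z.shape)
    C1, C2, C3, C4, C5 = calib.C
    D0, D1, D2, D3, D4, D5 = calib.D
    num = 1.0 + C2 * I + C4 * J - Z * (D0 + D2 * I + D4 * J)
    den = Z * (D1 + D3 * I + D5 * J) - (C1 + C3 * I + C5 * J)
    if np.any(np.abs(den) < tol):
        raise ValueError("height outside the invertible calibration domain")
    return num / den


def measure_height(object_patterns: FringePatternSet,
                   reference_patterns: FringePatternSet,
                   calib: HeightCalibration,
                   smoothing: int | None = None,
                   pitch: float = 1.0, strict: bool = False) -> HeightMap:
    """Full profilometry chain: wrapped phase per frequency for object and
    reference, temporal unwrapping, phase difference, rational height model."""
    def unwrapped(patterns):
        maps = [wrapped_phase(patterns, f, strict=strict)
                for f in patterns.frequencies]
        return unwrap_temporal(maps)

    phi_obj = unwrapped(object_patterns)
    phi_ref = unwrapped(reference_patterns)
    delta = phi_obj.values - phi_ref.values \
        + calib.reference_phase(phi_obj.values.shape)
    phase = PhaseMap(delta, "unwrapped", phi_obj.frequency)
    return height_from_phase(phase, calib, smoothing=smoothing, pitch=pitch)
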