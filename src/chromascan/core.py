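"""Sigma maps and the Sigma -> D inversion.

A normalized spectral cube is reduced to a per-pixel spectral standard
deviation Sigma (the raw csPWS readout), and Sigma is inverted to the
chromatin packing scaling D through a monotone calibration curve built from
the package's own forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ChromatinParams, InstrumentParams, RIModel, SpectralCube
from .synthetic import sigma_forward

__all__ = [
    "SigmaMap",
    "CalibrationCurve",
    "DMap",
    "normalize_cube",
    "compute_sigma",
    "build_calibration",
    "estimate_d_map",
    "acf_log_slope",
]


@dataclass
class SigmaMap:
    """Per-pixel spectral standard deviation with a validity mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share dimensions")
        if np.any(self.values[self.mask] < 0):
            raise ValueError("Sigma must be non-negative where valid")


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone lookup from Sigma to packing scaling D.

    Knots are forward-model evaluations at a grid of D values; phi, Nf and
    the instrument fingerprint record the conditions the curve is valid for.
    """

    sigma_knots: np.ndarray
    d_knots: np.ndarray
    phi: float
    nf: float
    instrument_fingerprint: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_knots", np.asarray(self.sigma_knots, float))
        object.__setattr__(self, "d_knots", np.asarray(self.d_knots, float))
        if self.sigma_knots.shape != self.d_knots.shape or self.sigma_knots.ndim != 1:
            raise ValueError("knot vectors must be 1-D and equal length")
        if self.sigma_knots.size < 2:
            raise ValueError("calibration needs at least 2 knots to interpolate")
        if np.any(np.diff(self.sigma_knots) <= 0):
            raise ValueError("sigma_knots must be strictly increasing")
        if np.any(np.diff(self.d_knots) <= 0):
            raise ValueError("d_knots must be strictly increasing")
        if np.any(self.d_knots <= 2.0) or np.any(self.d_knots >= 3.0):
            raise ValueError("d_knots must lie in the open interval (2, 3)")

    def fingerprint(self) -> dict:
        return {
            "phi": self.phi,
            "nf": self.nf,
            "instrument": self.instrument_fingerprint,
            "d_range": [float(self.d_knots[0]), float(self.d_knots[-1])],
            "n_knots": int(self.d_knots.size),
        }


@dataclass
class DMap:
    """Per-pixel packing scaling estimates with clip flags at the calibration bounds."""

    values: np.ndarray
    mask: np.ndarray
    out_of_range_flags: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        self.out_of_range_flags = np.asarray(self.out_of_range_flags).astype(bool)
        if not (self.values.shape == self.mask.shape == self.out_of_range_flags.shape):
            raise ValueError("values, mask and flags must share dimensions")


def normalize_cube(raw: SpectralCube) -> SpectralCube:
    """Divide every pixel's spectrum by the blank-slide reference spectrum."""
    if raw.reference is None or np.any(raw.reference <= 0):
        raise ValueError("reference must be strictly positive at every wavelength")
    normalized = raw.intensities / raw.reference[None, None, :]
    return SpectralCube(
        intensities=normalized,
        wavelengths=raw.wavelengths.copy(),
        pixel_pitch=raw.pixel_pitch,
        reference=np.ones_like(raw.wavelengths),
    )


def compute_sigma(
    norm: SpectralCube,
    mask: np.ndarray,
    noise_floor: float = 0.0,
) -> SigmaMap:
    """Per-pixel sample standard deviation of the normalized spectrum.

    Uses the n-1 denominator after per-pixel mean removal (the interference
    baseline is not informative). ``noise_floor`` is an optional known
    spectral-noise SD subtracted in quadrature, the standard noise-floor
    calibration: ``Sigma = sqrt(max(s^2 - noise_floor^2, 0))``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != norm.intensities.shape[:2]:
        raise ValueError("mask must match the cube's spatial dimensions")
    if norm.n_wavelengths < 2:
        raise ValueError("need at least 2 wavelengths to form a standard deviation")
    if noise_floor < 0:
        raise ValueError("noise_floor must be non-negative")
    s = np.std(norm.intensities, axis=2, ddof=1)
    if noise_floor > 0:
        s = np.sqrt(np.clip(s**2 - noise_floor**2, 0.0, None))
    values = np.where(mask, s, 0.0)
    return SigmaMap(values=values, mask=mask)


def build_calibration(
    instrument: InstrumentParams,
    phi: float,
    nf: float,
    d_grid: np.ndarray,
    ri: RIModel | None = None,
) -> CalibrationCurve:
    """Evaluate the forward model along a D grid and store the monotone lookup.

    The domain radius at each D follows from the mass-fractal relation for a
    domain of ``nf`` base pairs, so both phi and Nf shape the curve. A
    non-monotone Sigma(D) is a hard failure: it would signal a broken
    forward model and is never silently reordered.
    """
    d_grid = np.asarray(d_grid, dtype=np.float64)
    if d_grid.ndim != 1 or d_grid.size < 2:
        raise ValueError("d_grid must contain at least 2 values to interpolate")
    if np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be strictly increasing")
    if np.any(d_grid <= 2.0) or np.any(d_grid >= 3.0):
        raise ValueError("d_grid must lie within the open interval (2, 3)")
    ri = ri if ri is not None else RIModel()
    sigmas = np.array(
        [
            sigma_forward(
                ChromatinParams.from_genomic_size(d=d, phi=phi, nf=nf),
                instrument,
                ri,
            )
            for d in d_grid
        ]
    )
    if np.any(np.diff(sigmas) <= 0):
        raise RuntimeError(
            "forward model produced a non-monotone Sigma(D); calibration aborted"
        )
    return CalibrationCurve(
        sigma_knots=sigmas,
        d_knots=d_grid,
        phi=phi,
        nf=nf,
        instrument_fingerprint=instrument.fingerprint(),
    )


def estimate_d_map(sigma: SigmaMap, cal: CalibrationCurve) -> DMap:
    """Invert Sigma to D by monotone piecewise-linear interpolation.

    Sigma outside the knot range is clipped to the boundary D and flagged
    rather than extrapolated (extrapolation would leave the physical (2, 3)
    interval).
    """
    values = np.interp(sigma.values, cal.sigma_knots, cal.d_knots)
    flags = sigma.mask & (
        (sigma.values < cal.sigma_knots[0]) | (sigma.values > cal.sigma_knots[-1])
    )
    values = np.where(sigma.mask, values, np.nan)
    return DMap(values=values, mask=sigma.mask, out_of_range_flags=flags)


def acf_log_slope(b_values: np.ndarray, r_grid: np.ndarray) -> float:
    """Packing scaling D from the log-log slope of an ACF: D = 3 + slope.

    Ordinary least squares of log(B) against log(r); the identity
    ``D - 3 = d log B / d log r`` holds exactly for a power-law ACF.
    """
    b = np.asarray(b_values, dtype=np.float64)
    r = np.asarray(r_grid, dtype=np.float64)
    if b.shape != r.shape or b.ndim != 1 or b.size < 2:
        raise ValueError("b_values and r_grid must be equal-length 1-D arrays, n >= 2")
    if np.any(b <= 0) or np.any(r <= 0):
        raise ValueError("ACF values and separations must be strictly positive")
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    slope = np.polyfit(np.log(r), np.log(b), 1)[0]
    return 3.0 + float(slope)
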