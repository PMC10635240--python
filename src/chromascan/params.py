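"""Physical parameter objects shared across the pipeline.

The measurement model: within a nucleus the refractive index is
``n(r) = n_media + alpha * rho(r)`` where ``rho`` is the local macromolecular
mass density. Chromatin inside a packing domain follows a mass-fractal
scaling ``N_f ~ r**D`` with packing scaling exponent ``D`` in (2, 3), which
fixes the log-log slope of the density autocorrelation ``B(r)`` at ``D - 3``.
The interferometric readout Sigma integrates the spectral density of ``B``
over the instrument's length-scale sensitivity window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChromatinParams",
    "InstrumentParams",
    "RIModel",
    "SpectralCube",
]

#: genomic content (base pairs) of one chain segment at the lower cutoff r_min;
#: the disordered nucleosome chain packs ~1 kbp into a ~10 nm unit.
BP_PER_CHAIN_UNIT = 1000.0


@dataclass(frozen=True)
class ChromatinParams:
    """Chromatin packing-domain parameters.

    Parameters
    ----------
    d : float
        Packing scaling exponent, open interval (2, 3).
    phi : float
        Chromatin volume concentration inside a domain, in (0, 1).
    nf : float
        Genomic size of a packing domain in base pairs (> 0).
    r_min : float
        Lower cutoff of the chain scaling regime, nm.
    r_domain : float
        Domain radius (upper cutoff of the power-law regime), nm.
    """

    d: float
    phi: float = 0.35
    nf: float = 200_000.0
    r_min: float = 10.0
    r_domain: float = 80.0

    def __post_init__(self) -> None:
        if not 2.0 < self.d < 3.0:
            raise ValueError(f"packing scaling D must lie in (2, 3), got {self.d}")
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must lie in (0, 1), got {self.phi}")
        if self.nf <= 0:
            raise ValueError("nf must be positive")
        if self.r_min <= 0 or self.r_domain <= 0:
            raise ValueError("length cutoffs must be positive")
        if self.r_min >= self.r_domain:
            raise ValueError("r_min must be smaller than r_domain")

    @classmethod
    def from_genomic_size(
        cls, d: float, phi: float = 0.35, nf: float = 200_000.0, r_min: float = 10.0
    ) -> "ChromatinParams":
        """Build parameters with the domain radius implied by the mass-fractal law.

        A domain holding ``nf`` base pairs with ``BP_PER_CHAIN_UNIT`` bp per
        r_min-sized chain unit satisfies ``nf = (r_domain/r_min)**d * 1 kbp``,
        i.e. ``r_domain = r_min * (nf / 1 kbp)**(1/d)``. For nf = 200 kbp and
        D ~ 2.6 this gives r_domain ~ 77 nm.
        """
        r_domain = r_min * (nf / BP_PER_CHAIN_UNIT) ** (1.0 / d)
        if r_domain <= r_min:
            raise ValueError("genomic size too small to form a domain above r_min")
        return cls(d=d, phi=phi, nf=nf, r_min=r_min, r_domain=r_domain)

    def with_d(self, d: float) -> "ChromatinParams":
        """Same parameters at a different D, keeping r_domain fixed."""
        return replace(self, d=d)

    def at_d(self, d: float) -> "ChromatinParams":
        """Same phi/Nf/r_min at a different D, with the domain radius
        re-derived from the mass-fractal relation (see from_genomic_size).

        This is the parameterization the Sigma->D calibration assumes, so
        forward simulation and inversion stay on the same curve."""
        return ChromatinParams.from_genomic_size(
            d=d, phi=self.phi, nf=self.nf, r_min=self.r_min
        )


@dataclass(frozen=True)
class InstrumentParams:
    """csPWS acquisition geometry and wavelength axis.

    Defaults follow a visible-band instrument: illumination NA 0.6,
    collection NA 0.8, 500-700 nm sampled every 2 nm (101 samples),
    458 nm transverse coherence length, ~3 um depth of field, and a
    length-scale sensitivity window of 23-334 nm.
    """

    na_illum: float = 0.6
    na_collect: float = 0.8
    lambda_min: float = 500.0
    lambda_max: float = 700.0
    lambda_step: float = 2.0
    coherence_side: float = 458.0
    depth_of_field: float = 3000.0
    sens_lo: float = 23.0
    sens_hi: float = 334.0

    def __post_init__(self) -> None:
        if self.lambda_min >= self.lambda_max:
            raise ValueError("lambda_min must be below lambda_max")
        for name in ("lambda_step", "coherence_side", "depth_of_field", "sens_lo", "sens_hi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sens_lo >= self.sens_hi:
            raise ValueError("sens_lo must be below sens_hi")

    @property
    def wavelengths(self) -> np.ndarray:
        """Wavelength axis in nm, inclusive of both endpoints."""
        n = int(round((self.lambda_max - self.lambda_min) / self.lambda_step)) + 1
        return self.lambda_min + self.lambda_step * np.arange(n)

    def fingerprint(self) -> str:
        return (
            f"NA{self.na_illum}/{self.na_collect};"
            f"{self.lambda_min}-{self.lambda_max}nm@{self.lambda_step};"
            f"coh{self.coherence_side};dof{self.depth_of_field};"
            f"win{self.sens_lo}-{self.sens_hi}"
        )


@dataclass(frozen=True)
class RIModel:
    """Refractive-index model ``n(r) = n_media + alpha * rho(r)``.

    ``alpha`` is the specific refractive increment (~0.18 mL/g for
    biological macromolecules); ``rho_scale`` sets the amplitude of
    macromolecular density fluctuations in the same density units.
    """

    n_media: float = 1.337
    alpha: float = 0.18
    rho_scale: float = 1.6

    def __post_init__(self) -> None:
        if self.n_media <= 1.0:
            raise ValueError("n_media must exceed 1 (aqueous background)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.rho_scale < 0:
            raise ValueError("rho_scale must be non-negative")


@dataclass
class SpectralCube:
    """Raw or normalized csPWS measurement: intensities I(row, col, lambda)."""

    intensities: np.ndarray
    wavelengths: np.ndarray
    pixel_pitch: float = 458.0
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D (row, col, wavelength) array")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.intensities.shape[2]:
            raise ValueError("wavelength axis length must match the cube's third axis")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.reference is None:
            self.reference = np.ones_like(self.wavelengths)
        else:
            self.reference = np.asarray(self.reference, dtype=np.float64)
            if self.reference.shape != self.wavelengths.shape:
                raise ValueError("reference must be one value per wavelength")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_wavelengths(self) -> int:
        return self.intensities.shape[2]
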