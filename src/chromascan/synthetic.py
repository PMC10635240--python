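"""Synthetic csPWS data: forward model, spectral cubes, and patient cohorts.

The generator produces every input the downstream pipeline consumes —
per-pixel interference spectra whose spectral standard deviation Sigma
encodes a configured packing scaling D, nucleus label masks, and patient
cohorts with group structure, an age effect on D, and demographics — so the
full analysis is testable with no external data.

Forward model
-------------
The density autocorrelation of a mass-fractal packing domain is a power law
``B(r) = A (r/r_min)**(D-3)`` between the chain cutoff r_min and the domain
radius, with an exponential tail beyond the domain; the amplitude
``A = phi (1 - phi)`` is the variance of a two-phase medium at chromatin
volume concentration phi. Sigma integrates ``B`` over the instrument's
length-scale sensitivity window [sens_lo, sens_hi] (a hard band-pass
surrogate for the coherence-volume smoothing S(r)) and is first order in the
refractive-index fluctuation amplitude ``alpha * rho_scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import truncnorm

from .params import ChromatinParams, InstrumentParams, RIModel, SpectralCube

__all__ = [
    "acf_model",
    "sigma_forward",
    "generate_cube",
    "CohortConfig",
    "generate_cohort",
    "disk_phantom",
    "GROUP_ORDER",
]

#: diagnostic groups in order of increasing expected packing scaling
GROUP_ORDER = ("Control", "DA", "NDA", "AA", "HNPCC", "CRC")


def acf_model(params: ChromatinParams, r_grid: np.ndarray) -> np.ndarray:
    """Mass-density autocorrelation B(r) of a packing domain.

    ``B(r) = A (r/r_min)**(D-3)`` for ``r_min <= r <= r_domain``; beyond the
    domain radius B decays exponentially with scale ``r_domain``. The log-log
    slope inside the power-law window is exactly ``D - 3``.
    """
    r = np.asarray(r_grid, dtype=np.float64)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("r_grid must be a non-empty 1-D array")
    if np.any(r <= 0):
        raise ValueError("r_grid must be strictly positive")
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    amp = params.phi * (1.0 - params.phi)
    exponent = params.d - 3.0
    core = amp * (r / params.r_min) ** exponent
    b_edge = amp * (params.r_domain / params.r_min) ** exponent
    tail = b_edge * np.exp(-(r - params.r_domain) / params.r_domain)
    return np.where(r <= params.r_domain, core, tail)


def sigma_forward(
    chromatin: ChromatinParams,
    instrument: InstrumentParams,
    ri: RIModel,
) -> float:
    """Expected spectral standard deviation Sigma for one coherence volume.

    Integrates the ACF over the band-pass sensitivity window and scales by
    the refractive-index fluctuation amplitude:

        Sigma = alpha * rho_scale * sqrt( mean_{[lo,hi]} B(r) )

    Sigma is strictly increasing in D at fixed phi and Nf: a flatter ACF
    (larger D) leaves more correlated mass at the length scales the
    instrument senses.
    """
    if ri.rho_scale == 0.0:
        return 0.0
    lo, hi = instrument.sens_lo, instrument.sens_hi

    def _b(r: float) -> float:
        return float(acf_model(chromatin, np.array([r]))[0])

    # split at the domain radius where the integrand has a kink
    if lo < chromatin.r_domain < hi:
        i1, _ = quad(_b, lo, chromatin.r_domain, limit=200)
        i2, _ = quad(_b, chromatin.r_domain, hi, limit=200)
        integral = i1 + i2
    else:
        integral, _ = quad(_b, lo, hi, limit=200)
    return ri.alpha * ri.rho_scale * math.sqrt(integral / (hi - lo))


def generate_cube(
    d_map_true: np.ndarray,
    mask: np.ndarray,
    chromatin: ChromatinParams,
    instrument: InstrumentParams,
    ri: RIModel,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_level: float = 1000.0,
) -> SpectralCube:
    """Synthesize a spectral cube whose per-pixel Sigma encodes ``d_map_true``.

    Each in-mask pixel carries an interference fringe on its normalized
    spectrum: a cosine in wavenumber with amplitude ``sqrt(2) * Sigma``
    (so its standard deviation over the wavelength axis is Sigma), optical
    path difference set by the axial coherence (``2 n_media depth_of_field``
    with a small per-pixel jitter) and a random per-pixel phase, plus
    additive Gaussian spectral noise of standard deviation ``noise_sd``
    drawn independently per (pixel, wavelength). The per-pixel sample SD
    converges to ``sigma_forward`` at that pixel's D as the wavelength axis
    covers more fringe periods. Out-of-mask pixels carry reference-only
    spectra. The raw cube is the normalized spectrum times the reference.
    """
    d_map_true = np.asarray(d_map_true, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if d_map_true.shape != mask.shape:
        raise ValueError("d_map_true and mask must share dimensions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    d_vals = d_map_true[mask]
    if d_vals.size and (np.any(d_vals <= 2.0) or np.any(d_vals >= 3.0)):
        raise ValueError("masked D values must lie in the open interval (2, 3)")

    wavelengths = instrument.wavelengths
    n_lam = wavelengths.size
    rng = np.random.default_rng(seed)
    reference = np.full(n_lam, reference_level, dtype=np.float64)

    norm = np.ones(d_map_true.shape + (n_lam,), dtype=np.float64)
    if d_vals.size:
        # one sigma per distinct D value keeps the forward integral cheap
        uniq, inv = np.unique(d_vals, return_inverse=True)
        sig_uniq = np.array(
            [sigma_forward(chromatin.at_d(d), instrument, ri) for d in uniq]
        )
        sigma_px = sig_uniq[inv]
        opd0 = 2.0 * ri.n_media * instrument.depth_of_field
        opd = opd0 * rng.uniform(0.95, 1.05, size=d_vals.size)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=d_vals.size)
        fringe = np.cos(2.0 * np.pi * opd[:, None] / wavelengths[None, :] + phase[:, None])
        fluct = np.sqrt(2.0) * sigma_px[:, None] * fringe
        if noise_sd > 0:
            fluct += rng.standard_normal((d_vals.size, n_lam)) * noise_sd
        norm[mask] = 1.0 + fluct
    intensities = np.clip(norm, 0.0, None) * reference
    return SpectralCube(
        intensities=intensities,
        wavelengths=wavelengths,
        pixel_pitch=instrument.coherence_side,
        reference=reference,
    )


def disk_phantom(
    shape: tuple[int, int],
    centers: list[tuple[int, int]],
    radius: int,
) -> np.ndarray:
    """Integer label mask with one disk nucleus per center (labels 1..K)."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, dtype=np.uint16)
    for k, (r0, c0) in enumerate(centers, start=1):
        disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
        mask[disk] = k
    return mask


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_DEFAULT_GROUP_SIZES = {
    "Control": 135,
    "DA": 13,
    "NDA": 15,
    "AA": 74,
    "HNPCC": 9,
    "CRC": 10,
}

# Group-mean packing scaling chosen so the control-AA standardized difference
# is ~0.8 at the default between-patient SD of 0.075, matching the magnitude
# of the case/control effect sizes the method is designed to resolve.
_DEFAULT_GROUP_D_MEAN = {
    "Control": 2.54,
    "DA": 2.56,
    "NDA": 2.58,
    "AA": 2.60,
    "HNPCC": 2.63,
    "CRC": 2.66,
}

# AA lesion-size mix: categories and counts within the 74-patient AA group
_DEFAULT_AA_SIZE_COUNTS = {"<1cm": 23, "1-1.5cm": 35, ">1.5cm": 16}


@dataclass
class CohortConfig:
    """Configuration of the synthetic patient cohort.

    Defaults reproduce the study conditions the analysis assumes: group
    sizes 135/13/15/74/9/10 (Control/DA/NDA/AA/HNPCC/CRC), group-mean D
    strictly increasing along that order, ages ~N(57, 8) for controls and
    ~N(62, 8) for cases truncated to [40, 90], a -0.008 per-year age effect
    on D, and near-balanced sex with slightly more smokers among cases and
    slightly more drinkers among controls.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_GROUP_SIZES))
    group_d_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GROUP_D_MEAN))
    group_d_sd: float = 0.075
    nucleus_d_sd: float = 0.04
    cells_per_patient: int = 40
    age_mean_control: float = 57.0
    age_mean_case: float = 62.0
    age_sd: float = 8.0
    age_coeff: float = -0.008
    sex_female_frac: dict[str, float] | float = 0.49
    smoker_frac: dict[str, float] | float = field(
        default_factory=lambda: {
            "Control": 0.18, "DA": 0.18, "NDA": 0.20, "AA": 0.20, "HNPCC": 0.20, "CRC": 0.26,
        }
    )
    drinker_frac: dict[str, float] | float = field(
        default_factory=lambda: {
            "Control": 0.55, "DA": 0.52, "NDA": 0.50, "AA": 0.50, "HNPCC": 0.50, "CRC": 0.48,
        }
    )
    aa_size_counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_AA_SIZE_COUNTS))
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUP_ORDER:
                raise ValueError(f"unknown diagnostic group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be non-negative")
        if self.group_d_sd < 0 or self.nucleus_d_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.cells_per_patient <= 0:
            raise ValueError("cells_per_patient must be positive")
        for frac in (self.sex_female_frac, self.smoker_frac, self.drinker_frac):
            vals = frac.values() if isinstance(frac, dict) else [frac]
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError("proportions must lie in [0, 1]")

    def frac(self, name: str, group: str) -> float:
        value = getattr(self, name)
        return value[group] if isinstance(value, dict) else float(value)


def _truncated_ages(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    a, b = (40.0 - mean) / sd, (90.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic patient cohort.

    Returns ``(patients, nuclei)``: a per-patient table with columns
    patient_id, group, age, sex, smoker, drinker, lesion_size (AA only),
    true_mean_d; and a per-nucleus table with patient_id, nucleus_id, true_d.

    Patient-mean D is drawn from the group's normal distribution, shifted by
    ``age_coeff * (age - group mean age)`` (group-centered so configured
    group means are preserved in expectation), and per-nucleus D is drawn
    around the patient mean. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    patients: list[dict] = []
    nuclei: list[dict] = []
    for group in GROUP_ORDER:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        is_case = group != "Control"
        age_mean = config.age_mean_case if is_case else config.age_mean_control
        ages = _truncated_ages(rng, age_mean, config.age_sd, n)
        mean_d = rng.normal(config.group_d_mean[group], config.group_d_sd, size=n)
        mean_d = mean_d + config.age_coeff * (ages - ages.mean())
        mean_d = np.clip(mean_d, 2.02, 2.98)
        female = rng.random(n) < config.frac("sex_female_frac", group)
        smoker = rng.random(n) < config.frac("smoker_frac", group)
        drinker = rng.random(n) < config.frac("drinker_frac", group)
        sizes = _lesion_sizes(config, group, n)
        for i in range(n):
            pid = f"{group}-{i:04d}"
            patients.append(
                {
                    "patient_id": pid,
                    "group": group,
                    "age": float(ages[i]),
                    "sex": "F" if female[i] else "M",
                    "smoker": bool(smoker[i]),
                    "drinker": bool(drinker[i]),
                    "lesion_size": sizes[i],
                    "true_mean_d": float(mean_d[i]),
                }
            )
            d_nuc = rng.normal(mean_d[i], config.nucleus_d_sd, size=config.cells_per_patient)
            d_nuc = np.clip(d_nuc, 2.02, 2.98)
            for j, d in enumerate(d_nuc):
                nuclei.append({"patient_id": pid, "nucleus_id": j + 1, "true_d": float(d)})
    patients_df = pd.DataFrame(patients)
    nuclei_df = pd.DataFrame(nuclei)
    return patients_df, nuclei_df


def _lesion_sizes(config: CohortConfig, group: str, n: int) -> list[str | None]:
    """Assign AA lesion-size categories at the configured counts (scaled to n)."""
    if group != "AA" or not config.aa_size_counts:
        return [None] * n
    cats = list(config.aa_size_counts)
    counts = np.array([config.aa_size_counts[c] for c in cats], dtype=float)
    total = counts.sum()
    alloc = np.floor(counts / total * n).astype(int)
    # distribute the remainder by largest fractional part
    frac = counts / total * n - alloc
    for idx in np.argsort(-frac)[: n - alloc.sum()]:
        alloc[idx] += 1
    out: list[str | None] = []
    for c, k in zip(cats, alloc):
        out.extend([c] * int(k))
    return out[:n]
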