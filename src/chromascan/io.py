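"""File I/O: spectral cubes (HDF5 canonical, TIFF interchange), masks, maps.

HDF5 layout: datasets ``/intensities`` (row, col, wavelength),
``/wavelengths`` (nm), ``/reference`` (per-wavelength), root attribute
``pixel_pitch`` (nm per pixel). TIFF cubes are one page per wavelength with
a JSON sidecar carrying the wavelength axis, reference and pixel pitch.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import DMap, SigmaMap
from .params import SpectralCube

__all__ = [
    "read_cube",
    "write_cube",
    "read_cube_tiff",
    "write_cube_tiff",
    "read_mask",
    "write_mask",
    "read_dmap",
    "write_dmap",
]

_CUBE_DATASETS = ("intensities", "wavelengths", "reference")


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=cube.intensities)
        f.create_dataset("wavelengths", data=cube.wavelengths)
        f.create_dataset("reference", data=cube.reference)
        f.attrs["pixel_pitch"] = cube.pixel_pitch


def read_cube(path: str | Path, expected_wavelengths: np.ndarray | None = None) -> SpectralCube:
    path = Path(path)
    with h5py.File(path, "r") as f:
        missing = [name for name in _CUBE_DATASETS if name not in f]
        if missing:
            raise ValueError(f"{path.name}: missing dataset(s) {missing}")
        cube = SpectralCube(
            intensities=f["intensities"][...],
            wavelengths=f["wavelengths"][...],
            reference=f["reference"][...],
            pixel_pitch=float(f.attrs.get("pixel_pitch", 458.0)),
        )
    if expected_wavelengths is not None and (
        cube.wavelengths.shape != np.shape(expected_wavelengths)
        or not np.allclose(cube.wavelengths, expected_wavelengths)
    ):
        raise ValueError(
            f"{path.name}: wavelength axis does not match the declared instrument"
        )
    return cube


def write_cube_tiff(cube: SpectralCube, path: str | Path) -> None:
    """One 32-bit float page per wavelength, plus a JSON metadata sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.intensities.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages)
    sidecar = {
        "wavelengths": cube.wavelengths.tolist(),
        "reference": cube.reference.tolist(),
        "pixel_pitch": cube.pixel_pitch,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_cube_tiff(path: str | Path) -> SpectralCube:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"{path.name}: missing metadata sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    return SpectralCube(
        intensities=np.moveaxis(pages, 0, 2).astype(np.float64),
        wavelengths=np.asarray(meta["wavelengths"]),
        reference=np.asarray(meta["reference"]),
        pixel_pitch=float(meta["pixel_pitch"]),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Integer-label mask as 16-bit TIFF (0 = background, k = nucleus k)."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels must fit in uint16")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_dmap(dmap: DMap, path: str | Path, calibration_fingerprint: dict | None = None) -> None:
    """32-bit float TIFF plus a JSON sidecar with flags summary and provenance."""
    path = Path(path)
    tifffile.imwrite(path, dmap.values.astype(np.float32))
    sidecar = {
        "mask": dmap.mask.astype(np.uint8).tolist(),
        "out_of_range_flags": dmap.out_of_range_flags.astype(np.uint8).tolist(),
        "n_valid": int(dmap.mask.sum()),
        "n_flagged": int(dmap.out_of_range_flags.sum()),
        "calibration": calibration_fingerprint or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_dmap(path: str | Path) -> DMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return DMap(
        values=tifffile.imread(path).astype(np.float64),
        mask=np.asarray(meta["mask"], dtype=bool),
        out_of_range_flags=np.asarray(meta["out_of_range_flags"], dtype=bool),
    )
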