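"""Image I/O at the [0, 1] float boundary.

PNG/TIFF images are read through imageio and rescaled from their integer
range; optional DICOM (pydicom) and MetaImage .mhd/.raw (SimpleITK) readers
extract 2-D slices from clinical files when those libraries are installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_image", "write_image", "read_dicom_slice", "read_mhd_slice"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        scale = 65535.0 if arr.max() > 255 else 255.0
        arr = arr / scale
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    import imageio.v3 as iio

    data = (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
    iio.imwrite(path, data)


def read_dicom_slice(path: str | Path) -> np.ndarray:
    """Read one DICOM file as a min-max scaled [0, 1] slice."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def read_mhd_slice(path: str | Path, index: int | None = None) -> np.ndarray:
    """Read a 2-D slice from a MetaImage volume, min-max scaled to [0, 1]."""
    import SimpleITK as sitk

    vol = sitk.GetArrayFromImage(sitk.ReadImage(str(path))).astype(float)
    if vol.ndim == 3:
        vol = vol[vol.shape[0] // 2 if index is None else index]
    lo, hi = vol.min(), vol.max()
    return (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
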