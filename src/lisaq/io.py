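"""Reading grayscale slices from standard formats and writing score reports.

Supported inputs: PNG and TIFF rasters (via imageio), NIfTI-1 volumes (via
nibabel, with slice selection) and single-frame DICOM (via pydicom).
Intensities are kept on their native scale — the Moran statistic is invariant
to positive affine rescaling, so no normalisation is applied, and images with
negative values are rejected rather than silently shifted (an explicit
``offset`` opts into a shift).

Reports serialise :class:`~lisaq.quality.QualityScores` bundles or sweep
tables to JSON or CSV and round-trip all numeric fields at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quality import QualityScores

__all__ = ["GrayImage", "read_image", "write_image", "write_report", "read_report"]

#: ITU-R BT.601 luminance weights for colour→gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D nonnegative intensity raster with provenance."""

    pixels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("GrayImage requires a nonempty 2-D raster")
        if not np.all(np.isfinite(p)):
            raise ValueError("GrayImage intensities must be finite")
        if p.min() < 0:
            raise ValueError(
                "negative intensities; pass offset= to read_image to shift the image explicitly"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # colour raster → luminance
        return arr[..., :3].astype(float) @ _LUMA
    return arr.astype(float)


def _select_slice(vol: np.ndarray, slice_index: int | None, axis: int | None, path: str) -> np.ndarray:
    if vol.ndim == 2:
        return vol
    if slice_index is None:
        raise ValueError(f"{path}: volume input ({vol.ndim}-D) requires slice_index")
    ax = vol.ndim - 1 if axis is None else axis
    if not (0 <= ax < vol.ndim):
        raise ValueError(f"{path}: axis {ax} out of range for {vol.ndim}-D volume")
    if not (0 <= slice_index < vol.shape[ax]):
        raise ValueError(
            f"{path}: slice {slice_index} out of range along axis {ax} (size {vol.shape[ax]})"
        )
    sl = np.take(vol, slice_index, axis=ax)
    if sl.ndim != 2:
        raise ValueError(f"{path}: selected slice is {sl.ndim}-D; choose slice_index/axis to reach 2-D")
    return sl


def read_image(path, slice_index: int | None = None, axis: int | None = None,
               offset: float = 0.0) -> GrayImage:
    """Read a 2-D grayscale slice from PNG, TIFF, NIfTI or DICOM.

    Parameters
    ----------
    path:
        Input file.  NIfTI volumes need ``slice_index`` (0-based) along
        ``axis`` (default: the last axis).
    offset:
        Added to all intensities before validation; use it to shift
        reconstructions that contain negative values.

    Intensities are returned on their native scale as float64.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(p)).dataobj)
        arr = _select_slice(vol, slice_index, axis, str(p))
    elif name.endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(str(p))
        arr = _select_slice(ds.pixel_array, slice_index, axis, str(p))
    elif name.endswith((".png", ".tif", ".tiff")):
        import imageio.v3 as iio

        arr = _to_gray(iio.imread(str(p)))
        arr = _select_slice(arr, slice_index, axis, str(p))
    else:
        raise ValueError(f"{p}: unsupported format (expected PNG, TIFF, NIfTI or DICOM)")
    pixels = np.asarray(arr, dtype=float) + offset
    src = str(p) if slice_index is None else f"{p}[{slice_index}]"
    return GrayImage(pixels=pixels, source=src)


def write_image(img, path) -> None:
    """Write an image to PNG or TIFF, choosing 8- or 16-bit by intensity range.

    Float TIFF is used when intensities exceed 16-bit range or are
    non-integral; PNG inputs are rounded to the narrowest unsigned type.
    """
    import imageio.v3 as iio

    pixels = np.asarray(getattr(img, "pixels", img), dtype=float)
    p = Path(path)
    suffix = p.suffix.lower()
    integral = np.allclose(pixels, np.round(pixels))
    if suffix == ".png" or (integral and pixels.max() <= 65535):
        if pixels.max() > 65535:
            raise ValueError(f"{p}: intensities exceed 16-bit range; write a float TIFF instead")
        arr = np.round(pixels).astype(np.uint8 if pixels.max() <= 255 else np.uint16)
    elif suffix in (".tif", ".tiff"):
        arr = pixels.astype(np.float32)
    else:
        raise ValueError(f"{p}: unsupported output format (use .png/.tif/.tiff)")
    iio.imwrite(str(p), arr)


def _scores_record(scores: QualityScores) -> dict:
    return scores.to_dict()


def write_report(scores, path, format: str = "json") -> None:
    """Write a score bundle or sweep table to JSON or CSV.

    ``scores`` may be a :class:`QualityScores`, a pandas DataFrame (sweep
    table), or a list of dicts/rows.
    """
    p = Path(path)
    if isinstance(scores, QualityScores):
        payload = _scores_record(scores)
        frame = pd.DataFrame([payload])
    elif isinstance(scores, pd.DataFrame):
        payload = scores.to_dict(orient="records")
        frame = scores
    else:
        payload = [s.to_dict() if hasattr(s, "to_dict") else dict(s) for s in scores]
        frame = pd.DataFrame(payload)
    if format == "json":
        p.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        frame.to_csv(p, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")


def read_report(path):
    """Read back a report written by :func:`write_report` (JSON or CSV)."""
    p = Path(path)
    if p.suffix.lower() == ".csv":
        return pd.read_csv(p)
    return json.loads(p.read_text())
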