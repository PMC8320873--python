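"""Foreground (region-of-interest) extraction by mean thresholding + morphology.

Three steps, in order:

1. Global threshold at the mean intensity of the image (ties kept: ``>=``,
   so a constant image is entirely foreground).
2. Morphological hole filling — background components not connected to the
   raster border (4-connectivity) are absorbed into the foreground.
3. Area threshold — 8-connected foreground components smaller than
   ``min_area_frac`` of the raster are discarded.

The mask is scale-equivariant: multiplying all intensities by a positive
constant leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["ForegroundMask", "EmptyForegroundError", "extract_foreground", "full_mask"]


class EmptyForegroundError(ValueError):
    """No foreground pixels survive extraction.

    Callers scoring images without a meaningful background (e.g. fixture
    patterns whose bright pixels are isolated) may substitute
    :func:`full_mask` instead.
    """


@dataclass(frozen=True)
class ForegroundMask:
    """Boolean region-of-interest raster and its pixel count ``n_foreground``."""

    mask: np.ndarray
    n_foreground: int

    def __post_init__(self) -> None:
        if self.n_foreground != int(np.count_nonzero(self.mask)):
            raise ValueError("n_foreground inconsistent with the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def full_mask(img) -> ForegroundMask:
    """A mask covering the whole raster (foreground extraction bypassed)."""
    pixels = np.asarray(getattr(img, "pixels", img))
    m = np.ones(pixels.shape, dtype=bool)
    return ForegroundMask(mask=m, n_foreground=int(m.size))


def extract_foreground(img, min_area_frac: float = 0.001) -> ForegroundMask:
    """Extract the foreground mask of a grayscale image.

    Parameters
    ----------
    img:
        2-D nonnegative intensity raster.
    min_area_frac:
        Connected components covering less than this fraction of the raster
        are removed (default 0.1%).

    Raises
    ------
    EmptyForegroundError
        If nothing survives the three steps.
    """
    x = np.asarray(getattr(img, "pixels", img), dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    if not (0 <= min_area_frac < 1):
        raise ValueError("min_area_frac must lie in [0, 1)")

    mask = x >= x.mean()
    # default structuring element = 4-connectivity for the background
    mask = ndi.binary_fill_holes(mask)
    min_area = min_area_frac * x.size
    if min_area > 1:
        # drop 8-connected components with area strictly below the threshold
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            areas = np.bincount(labels.ravel())
            small = areas < min_area
            small[0] = False
            mask = mask & ~small[labels]
    if not mask.any():
        raise EmptyForegroundError(
            "foreground extraction produced an empty mask; "
            "pass a precomputed mask or use full_mask() to score the whole raster"
        )
    return ForegroundMask(mask=mask, n_foreground=int(mask.sum()))
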