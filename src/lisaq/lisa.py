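"""Local and global Moran statistics on raster images, and pixel classification.

The local Moran statistic (the workhorse LISA — Local Indicator of Spatial
Autocorrelation) at pixel ``i`` is

    I_i = z_i * sum_j w_ij z_j,   z_i = (x_i - X̄) / S²,   z_j = x_j - X̄,

where the sum runs over the neighbours of ``i`` inside an ``r x c`` kernel
window (default 3x3, queen contiguity), ``w_ij = 1/(r*c - 1)`` is the
row-standardised binary weight, and ``X̄``, ``S²`` are the mean and
(population) variance of the intensities.  Positive ``I_i`` marks a pixel
whose intensity deviates from the mean in the same direction as its
neighbourhood (local clustering); negative ``I_i`` marks a local outlier
(dispersion).  The average of ``I_i`` over a region of interest is the global
Moran statistic (GMS), on an interpretive scale where +1 means maximal
clustering, 0 randomness and -1 maximal dispersion.

Two readings of the moments ``X̄`` and ``S²`` are supported via
``LisaConfig.stat_scope``:

``"image"`` (default)
    ``X̄`` and ``S²`` are computed over the whole image — the classic local
    Moran form.  Smooth regions then score positive, so the statistic
    degrades gradually as noise decorrelates neighbouring pixels.
``"window"``
    ``X̄`` is the local window mean and ``S²`` the spread of the 8 window
    neighbours about it.  Under this reading the neighbour deviations sum to
    exactly ``-(x_i - X̄)``, so ``I_i = -(x_i - X̄)² / Σ_j z_j² <= 0`` for every
    non-flat window: only exactly flat neighbourhoods count as clustered.
    Kept for comparison; see the methods note.

Flat-window convention: wherever the statistic is degenerate (all neighbour
values identical under the window scope, or a globally constant image under
the image scope), ``I_i`` is set to +1 when the centre equals the common
neighbour value (locally constant patch → clustered) and -1 otherwise
(outlier on a flat background).

Borders use replicate (nearest-edge) padding so every pixel has a full
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "LisaConfig",
    "LisaField",
    "ClassField",
    "QuadrantField",
    "local_moran_field",
    "global_moran",
    "classify_pixels",
    "quadrant_labels",
]

#: labels used by ClassField.labels
LABEL_OUTSIDE, LABEL_A, LABEL_B = 0, 1, 2

#: quadrant codes
QUAD_NONE, QUAD_HH, QUAD_LL, QUAD_HL, QUAD_LH = 0, 1, 2, 3, 4
QUAD_NAMES = {QUAD_NONE: "none", QUAD_HH: "HH", QUAD_LL: "LL", QUAD_HL: "HL", QUAD_LH: "LH"}


@dataclass(frozen=True)
class LisaConfig:
    """Tunable conventions of the local Moran computation.

    Attributes
    ----------
    kernel:
        Window size (odd), or an ``(rows, cols)`` pair of odd ints. Default 3.
    stat_scope:
        ``"image"`` (global X̄ and S², default) or ``"window"`` (local).
    mean_includes_center:
        Window scope only: whether the centre pixel enters the window mean X̄.
        With ``False`` the neighbour deviations sum to zero identically and
        every I_i vanishes, so ``True`` is the only non-degenerate choice;
        the switch exists to make that explicit.
    weight_scheme:
        Only ``"row_standardized_binary"`` is implemented: each in-window
        neighbour carries weight 1/(r*c - 1).
    flat_window_policy:
        ``"signed_unit"``: degenerate windows map to ±1 as described in the
        module docstring.
    gms_scope:
        Region the global Moran statistic averages over in the pipeline:
        ``"image"`` (default — the global statistic is defined across the
        whole raster) or ``"foreground"``.  Class counts are always
        foreground-restricted.
    min_area_frac:
        Foreground area threshold passed through to foreground extraction
        (fraction of the raster, default 0.001).
    """

    kernel: int | tuple[int, int] = 3
    stat_scope: str = "image"
    mean_includes_center: bool = True
    weight_scheme: str = "row_standardized_binary"
    flat_window_policy: str = "signed_unit"
    gms_scope: str = "image"
    min_area_frac: float = 0.001

    def __post_init__(self) -> None:
        r, c = self.kernel_shape
        if r < 3 or c < 3 or r % 2 == 0 or c % 2 == 0:
            raise ValueError("kernel dimensions must be odd integers >= 3")
        if self.stat_scope not in ("image", "window"):
            raise ValueError("stat_scope must be 'image' or 'window'")
        if self.weight_scheme != "row_standardized_binary":
            raise ValueError("only row_standardized_binary weights are implemented")
        if self.flat_window_policy != "signed_unit":
            raise ValueError("only the signed_unit flat-window policy is implemented")
        if self.gms_scope not in ("image", "foreground"):
            raise ValueError("gms_scope must be 'image' or 'foreground'")

    @property
    def kernel_shape(self) -> tuple[int, int]:
        k = self.kernel
        return (k, k) if isinstance(k, int) else (int(k[0]), int(k[1]))


@dataclass(frozen=True)
class LisaField:
    """Per-pixel local Moran statistics plus the terms they factor into.

    ``values[i] = center_dev[i] / scale[i] * lag[i]`` away from degenerate
    windows; ``center_dev`` is ``x_i - X̄`` and ``lag`` the row-standardised
    neighbour deviation sum ``Σ_j w_ij z_j``.  Both are kept so quadrant
    labelling reuses exactly the terms that produced ``values``.
    """

    values: np.ndarray
    kernel: tuple[int, int]
    weight_scheme: str
    center_dev: np.ndarray = field(repr=False, default=None)
    lag: np.ndarray = field(repr=False, default=None)
    config: LisaConfig = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ClassField:
    """Binary classification of the local Moran field over a foreground.

    Class A (``I_i <= 0``) holds random/dispersed pixels, class B
    (``I_i > 0``) clustered pixels; the two partition the foreground, so
    ``n_A + n_B`` equals the foreground pixel count.
    """

    labels: np.ndarray
    n_A: int
    n_B: int


@dataclass(frozen=True)
class QuadrantField:
    """Moran-scatterplot quadrant labels (HH/LL/HL/LH, 'none' on zero terms)."""

    labels: np.ndarray

    def names(self) -> np.ndarray:
        out = np.empty(self.labels.shape, dtype=object)
        for code, name in QUAD_NAMES.items():
            out[self.labels == code] = name
        return out


def _as_pixels(img) -> np.ndarray:
    pixels = getattr(img, "pixels", img)
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    return arr


def _neighbor_kernel(shape: tuple[int, int]) -> np.ndarray:
    k = np.ones(shape)
    k[shape[0] // 2, shape[1] // 2] = 0.0
    return k


def local_moran_field(img, kernel: int | tuple[int, int] | None = None,
                      config: LisaConfig | None = None) -> LisaField:
    """Compute the local Moran statistic at every pixel.

    Parameters
    ----------
    img:
        2-D nonnegative intensity raster (or an object with a ``pixels``
        attribute).
    kernel:
        Window size override; otherwise taken from ``config``.
    config:
        Conventions; defaults to ``LisaConfig()``.

    Returns
    -------
    LisaField
        The I_i raster plus the centre-deviation and lag terms.
    """
    cfg = config or LisaConfig()
    if kernel is not None:
        cfg = replace(cfg, kernel=kernel)
    x = _as_pixels(img)
    kshape = cfg.kernel_shape
    nw = kshape[0] * kshape[1] - 1
    nk = _neighbor_kernel(kshape)

    # exact degeneracy test: all in-window neighbours share one value
    nmin = ndi.minimum_filter(x, footprint=nk.astype(bool), mode="nearest")
    nmax = ndi.maximum_filter(x, footprint=nk.astype(bool), mode="nearest")
    flat = nmin == nmax

    neigh_sum = ndi.correlate(x, nk, mode="nearest")

    if cfg.stat_scope == "image":
        xbar = x.mean()
        s2 = np.mean((x - xbar) ** 2)
        d = x - xbar
        lag = (neigh_sum - nw * xbar) / nw
        if s2 == 0.0:  # constant image: every pixel a flat cluster
            values = np.ones_like(x)
            return LisaField(values, kshape, cfg.weight_scheme, d, lag, cfg)
        values = d / s2 * lag
        flat_mask = None  # formula is well defined everywhere
    else:
        win_sum = ndi.correlate(x, np.ones(kshape), mode="nearest")
        m = win_sum / (nw + 1) if cfg.mean_includes_center else neigh_sum / nw
        neigh_sumsq = ndi.correlate(x * x, nk, mode="nearest")
        # S² of the neighbours about X̄ (population divisor over the nw neighbours)
        s2 = (neigh_sumsq - 2.0 * m * neigh_sum + nw * m * m) / nw
        d = x - m
        lag = (neigh_sum - nw * m) / nw
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(flat, 0.0, d / np.where(flat, 1.0, s2) * lag)
        flat_mask = flat

    if flat_mask is not None and flat_mask.any():
        same = flat_mask & (x == nmin)
        values = np.where(same, 1.0, np.where(flat_mask, -1.0, values))

    if not np.all(np.isfinite(values)):
        raise FloatingPointError("non-finite local Moran values; degenerate window escaped the flat convention")
    return LisaField(values, kshape, cfg.weight_scheme, d, lag, cfg)


def global_moran(field: LisaField, mask) -> float:
    """Average of I_i over the foreground — the global Moran statistic (GMS).

    +1 ~ maximal clustering, 0 ~ randomness, -1 ~ maximal dispersion.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if m.shape != field.values.shape:
        raise ValueError("mask shape does not match the Moran field")
    if not m.any():
        raise ValueError("cannot average the Moran field over an empty mask")
    gms = float(field.values[m].mean())
    if field.config is None or field.config.stat_scope == "image":
        assert -3.0 <= gms <= 3.0, f"global Moran statistic {gms} outside sanity band"
    return gms


def classify_pixels(field: LisaField, mask) -> ClassField:
    """Split foreground pixels into dispersed (A: I_i <= 0) and clustered (B).

    Pixels outside the mask are left unlabelled and uncounted; the boundary
    case ``I_i == 0`` belongs to class A.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if m.shape != field.values.shape:
        raise ValueError("mask shape does not match the Moran field")
    labels = np.full(field.values.shape, LABEL_OUTSIDE, dtype=np.int8)
    a = m & (field.values <= 0.0)
    b = m & (field.values > 0.0)
    labels[a] = LABEL_A
    labels[b] = LABEL_B
    return ClassField(labels=labels, n_A=int(a.sum()), n_B=int(b.sum()))


def quadrant_labels(img, field: LisaField, mask) -> QuadrantField:
    """Moran-quadrant labels from the signs of the centre deviation and lag.

    HH: centre above the mean with a positive neighbour lag (bright cluster);
    LL: both negative (dark cluster); HL/LH: outliers.  Either term exactly
    zero → 'none'.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if m.shape != field.values.shape:
        raise ValueError("mask shape does not match the Moran field")
    d, lag = field.center_dev, field.lag
    labels = np.full(field.values.shape, QUAD_NONE, dtype=np.int8)
    labels[m & (d > 0) & (lag > 0)] = QUAD_HH
    labels[m & (d < 0) & (lag < 0)] = QUAD_LL
    labels[m & (d > 0) & (lag < 0)] = QUAD_HL
    labels[m & (d < 0) & (lag > 0)] = QUAD_LH
    return QuadrantField(labels=labels)
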