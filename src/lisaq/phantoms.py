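"""Synthetic grayscale phantoms with known spatial-autocorrelation structure.

Every phantom is deterministic for a given :class:`PhantomSpec`, and each kind
pins one analytic regime of the quality metric:

``uniform``
    A constant image — the perfectly clustered limit.  Every local Moran value
    is +1 under the flat-window convention and the pipeline scores 1.
``checkerboard``
    With ``cell=1``, the maximally dispersed limit: every pixel is a local
    outlier and the pipeline scores 0.
``stripes``
    Columns alternating with period ``cell`` — an anisotropic two-valued
    pattern useful for weight/kernel sanity checks.
``brain_like``
    A piecewise-constant nested-ellipse "head": 3–5 distinct tissue
    intensities on a zero background.  Noiseless interiors are flat, so the
    clean phantom sits near the clustered limit with dispersed pixels only
    along tissue boundaries; adding noise degrades it smoothly.

Coordinates are 0-based ``(row, col)``, row-major, with the pattern origin at
pixel ``(0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomSpec", "make_phantom", "brain_like_phantom"]

_KINDS = ("uniform", "checkerboard", "stripes", "brain_like")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Parameters
    ----------
    kind:
        One of ``uniform``, ``checkerboard``, ``stripes``, ``brain_like``.
    height, width:
        Image dimensions in pixels, each at least 8.
    low, high:
        The two intensity values of the pattern (arbitrary units,
        ``0 <= low < high``).  ``uniform`` uses only ``high``;
        ``brain_like`` draws tissue intensities from ``(low, high]``.
    cell:
        Pattern period in pixels for ``checkerboard`` and ``stripes``.
    seed:
        Randomness control for ``brain_like`` (ignored by the other kinds).
    """

    kind: str
    height: int = 64
    width: int = 64
    low: float = 0.0
    high: float = 255.0
    cell: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom dimensions must be at least 8x8")
        if not (self.high > self.low >= 0):
            raise ValueError("intensities must satisfy high > low >= 0")
        if self.cell < 1:
            raise ValueError("cell period must be a positive integer")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render ``spec`` to a 2-D float64 intensity image."""
    h, w = spec.height, spec.width
    if spec.kind == "uniform":
        return np.full((h, w), float(spec.high))
    if spec.kind == "checkerboard":
        r, c = np.ogrid[:h, :w]
        even = ((r // spec.cell) + (c // spec.cell)) % 2 == 0
        return np.where(even, float(spec.high), float(spec.low))
    if spec.kind == "stripes":
        c = np.arange(w)
        cols = np.where((c // spec.cell) % 2 == 0, float(spec.high), float(spec.low))
        return np.broadcast_to(cols, (h, w)).copy()
    return brain_like_phantom(h, w, seed=spec.seed, low=spec.low, high=spec.high)


def brain_like_phantom(
    height: int = 64,
    width: int = 64,
    seed: int = 0,
    low: float = 0.0,
    high: float = 255.0,
) -> np.ndarray:
    """Piecewise-constant nested-ellipse head phantom.

    Draws an outer "skull" ellipse filled with 3–5 nested elliptical tissue
    shells of distinct intensities, plus one small off-centre low-intensity
    "ventricle", all on a zero background.  Interiors are exactly flat so the
    noiseless phantom is almost entirely locally clustered.  The outer
    semi-axes are bounded so the background always covers roughly 35–65% of
    the raster.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width))
    rr, cc = np.mgrid[:height, :width].astype(float)

    cy = height / 2.0 + rng.uniform(-0.03, 0.03) * height
    cx = width / 2.0 + rng.uniform(-0.03, 0.03) * width
    a = rng.uniform(0.33, 0.42) * height  # outer semi-axes
    b = rng.uniform(0.35, 0.44) * width

    n_shells = int(rng.integers(3, 5))  # plus the ventricle: 4-5 tissue intensities
    span = high - low
    # distinct, well-separated intensities; brightest shell outermost
    levels = low + span * np.linspace(1.0, 0.45, n_shells)
    levels += rng.uniform(-0.02, 0.02, n_shells) * span
    scales = np.linspace(1.0, 0.4, n_shells)

    for lvl, s in zip(levels, scales):
        inside = ((rr - cy) / (s * a)) ** 2 + ((cc - cx) / (s * b)) ** 2 <= 1.0
        img[inside] = lvl

    # small dark off-centre structure inside the innermost shell
    vy = cy + rng.uniform(-0.08, 0.08) * height
    vx = cx + rng.uniform(-0.08, 0.08) * width
    va, vb = 0.10 * a, 0.12 * b
    vent = ((rr - vy) / va) ** 2 + ((cc - vx) / vb) ** 2 <= 1.0
    img[vent] = low + 0.35 * span
    return img
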