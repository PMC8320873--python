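"""Contrast, sharpness and total quality scores from Moran statistics.

The global Moran statistic I acts as a perceptual weight on the mix of
clustered (N_CB) and dispersed (N_CA) foreground pixels (N_If = N_CA + N_CB):

    Q1 = I·(1 − N_CA/N_If) + (1 − I)·(N_CB/N_If)     (contrast)
    Q2 =   (1 − N_CA/N_If) + (1 − I)·(N_CB/N_If)     (sharpness)
    QT = (Q1 + Q2) / 2                               (total)

Because the two classes partition the foreground, 1 − N_CA/N_If equals
N_CB/N_If, so Q1 reduces algebraically to the clustered fraction and
Q2 = (N_CB/N_If)·(2 − I); the implementation asserts the Q1 identity on every
call as a regression guard.  Raw Q2 can exceed 1 (clustered fraction near 1
with I well below 1); each score is clipped to the published [0, 1] range and
a flag records when clipping fired.  QT is the mean of the clipped scores, so
QT ∈ [0, 1] structurally.

Limit cases: a perfectly clustered image (I = 1, N_CA = 0) scores
Q1 = Q2 = QT = 1; a maximally dispersed one (N_CB = 0) scores 0.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .foreground import ForegroundMask, extract_foreground
from .lisa import ClassField, LisaConfig, classify_pixels, global_moran, local_moran_field

__all__ = ["QualityScores", "quality_scores", "evaluate_image"]


@dataclass(frozen=True)
class QualityScores:
    """Scores of one image: GMS, class counts, and unit-scale Q1/Q2/QT."""

    gms: float
    n_A: int
    n_B: int
    n_foreground: int
    q1: float
    q2: float
    qt: float
    q1_raw: float
    q2_raw: float
    q1_clipped: bool
    q2_clipped: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        # counts as plain ints for JSON
        for k in ("n_A", "n_B", "n_foreground"):
            d[k] = int(d[k])
        return d


def _clip_unit(value: float) -> tuple[float, bool]:
    clipped = float(min(1.0, max(0.0, value)))
    return clipped, clipped != value


def quality_scores(classes: ClassField, mask: ForegroundMask, gms: float) -> QualityScores:
    """Combine class counts and the global Moran statistic into Q1/Q2/QT.

    ``gms`` is passed explicitly rather than recomputed so callers can verify
    the decomposition of the global statistic into its local terms.
    """
    n_if = int(getattr(mask, "n_foreground", np.count_nonzero(mask)))
    if n_if == 0:
        raise ValueError("cannot score an empty foreground")
    if classes.n_A + classes.n_B != n_if:
        raise ValueError(
            f"class counts ({classes.n_A} + {classes.n_B}) do not partition "
            f"the foreground ({n_if} pixels)"
        )
    frac_a = classes.n_A / n_if
    frac_b = classes.n_B / n_if
    q1_raw = gms * (1.0 - frac_a) + (1.0 - gms) * frac_b
    q2_raw = (1.0 - frac_a) + (1.0 - gms) * frac_b
    # partition identity: Q1 must equal the clustered fraction exactly
    assert abs(q1_raw - frac_b) < 1e-9, "Q1 partition identity violated"
    q1, c1 = _clip_unit(q1_raw)
    q2, c2 = _clip_unit(q2_raw)
    return QualityScores(
        gms=float(gms),
        n_A=classes.n_A,
        n_B=classes.n_B,
        n_foreground=n_if,
        q1=q1,
        q2=q2,
        qt=(q1 + q2) / 2.0,
        q1_raw=float(q1_raw),
        q2_raw=float(q2_raw),
        q1_clipped=c1,
        q2_clipped=c2,
    )


def evaluate_image(img, mask: ForegroundMask | None = None,
                   config: LisaConfig | None = None) -> QualityScores:
    """Run the full four-step pipeline on a grayscale image.

    Steps: foreground extraction (skipped when ``mask`` is supplied), local
    Moran field, global Moran statistic (averaged across the whole raster by
    default — ``config.gms_scope`` — while class counts stay
    foreground-restricted), binary classification, quality scores.
    Deterministic for fixed input and config.
    """
    cfg = config or LisaConfig()
    if mask is None:
        mask = extract_foreground(img, min_area_frac=cfg.min_area_frac)
    field = local_moran_field(img, config=cfg)
    if cfg.gms_scope == "image":
        gms = global_moran(field, np.ones(field.values.shape, dtype=bool))
    else:
        gms = global_moran(field, mask)
    classes = classify_pixels(field, mask)
    return quality_scores(classes, mask, gms)
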