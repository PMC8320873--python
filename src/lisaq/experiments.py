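"""Desk-scale experiment harnesses: noise sweeps, denoising comparison,
and unit-scale normalisation of reference metrics.

A sweep degrades one clean image with Rician noise over a grid of levels τ
and seeds, scores every degraded image with the Moran pipeline, and
(optionally) computes full-reference SSIM/PSNR against the clean image,
normalised to the metric's [0, 1] scale so curves are directly comparable.
Averages over seeds at fixed τ stand in for averaging over the slices of a
volume.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from .lisa import LisaConfig
from .quality import evaluate_image
from .rician import add_rician_noise

__all__ = ["noise_sweep", "normalize_comparison_metric", "denoise_comparison", "bilateral_denoiser"]

_COMPARISON_METRICS = ("ssim", "psnr_db", "brisque")


def normalize_comparison_metric(name: str, value: float) -> float:
    """Map a reference metric onto the unit quality scale.

    * ``psnr_db``: decibel value divided by 100;
    * ``brisque``: (100 − value) / 100, so 0 is worst and 1 best;
    * ``ssim``: already unit-scale, returned unchanged.

    Values landing outside [0, 1] are passed through with a warning.
    """
    if name == "psnr_db":
        out = value / 100.0
    elif name == "brisque":
        out = (100.0 - value) / 100.0
    elif name == "ssim":
        out = value
    else:
        raise ValueError(f"unknown comparison metric {name!r}; choose from {_COMPARISON_METRICS}")
    if not np.isfinite(out) or not (0.0 <= out <= 1.0):
        warnings.warn(
            f"normalized {name} score {out!r} outside [0, 1]; passed through unchanged",
            stacklevel=2,
        )
    return float(out)


def _reference_scores(clean: np.ndarray, noisy: np.ndarray, metrics: Sequence[str]) -> dict:
    from skimage.metrics import peak_signal_noise_ratio, structural_similarity

    rng = float(clean.max() - clean.min()) or 1.0
    out = {}
    for m in metrics:
        if m == "ssim":
            native = structural_similarity(clean, noisy, data_range=rng)
        elif m == "psnr_db":
            if np.array_equal(clean, noisy):
                continue  # PSNR undefined at zero distortion
            native = peak_signal_noise_ratio(clean, noisy, data_range=rng)
        else:
            raise ValueError(f"cannot compute comparison metric {m!r} (only ssim/psnr_db)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[m] = normalize_comparison_metric(m, native)
    return out


def noise_sweep(img, taus: Sequence[float], seeds: Sequence[int] = (0,),
                config: LisaConfig | None = None,
                compare: Sequence[str] = ()) -> pd.DataFrame:
    """Score Rician-degraded copies of ``img`` over a τ × seed grid.

    Returns one row per (τ, seed), sorted by τ then seed, with columns
    ``tau, seed, gms, n_foreground, n_A, n_B, q1, q2, qt`` plus one column
    per requested comparison metric.  Deterministic for fixed seeds.
    """
    taus = list(taus)
    if not taus:
        raise ValueError("taus must be nonempty")
    clean = np.asarray(getattr(img, "pixels", img), dtype=float)
    rows = []
    for tau in sorted(taus):
        for seed in seeds:
            noisy = add_rician_noise(clean, tau, seed=seed)
            s = evaluate_image(noisy, config=config)
            row = {"tau": tau, "seed": seed, "gms": s.gms,
                   "n_foreground": s.n_foreground, "n_A": s.n_A, "n_B": s.n_B,
                   "q1": s.q1, "q2": s.q2, "qt": s.qt}
            row.update(_reference_scores(clean, noisy, compare))
            rows.append(row)
    return pd.DataFrame(rows)


def denoise_comparison(img, tau: float, denoiser: Callable[[np.ndarray], np.ndarray],
                       seeds: Sequence[int] = (0,),
                       config: LisaConfig | None = None) -> pd.DataFrame:
    """Score noisy vs denoised images across seeds.

    For each seed the clean image is degraded at level τ, scored, passed
    through ``denoiser`` (any image→image callable preserving shape) and
    scored again.  Returns per-seed rows with ``qt_pre``, ``qt_post`` and
    ``delta = qt_post − qt_pre``; positive deltas mean the denoiser improved
    the predicted quality.
    """
    clean = np.asarray(getattr(img, "pixels", img), dtype=float)
    rows = []
    for seed in seeds:
        noisy = add_rician_noise(clean, tau, seed=seed)
        denoised = np.asarray(denoiser(noisy), dtype=float)
        if denoised.shape != noisy.shape:
            raise ValueError(
                f"denoiser changed the image shape {noisy.shape} -> {denoised.shape}"
            )
        pre = evaluate_image(noisy, config=config)
        post = evaluate_image(denoised, config=config)
        rows.append({"tau": tau, "seed": seed,
                     "qt_pre": pre.qt, "qt_post": post.qt,
                     "delta": post.qt - pre.qt})
    return pd.DataFrame(rows)


def bilateral_denoiser(sigma_spatial: float = 2.0) -> Callable[[np.ndarray], np.ndarray]:
    """Edge-preserving bilateral smoother on the image's native scale.

    Convenience factory for :func:`denoise_comparison`; wraps the
    scikit-image bilateral filter with rescaling to and from [0, 1].
    """
    from skimage.restoration import denoise_bilateral

    def denoise(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        top = img.max()
        if top == 0:
            return img.copy()
        out = denoise_bilateral(img / top, sigma_spatial=sigma_spatial)
        return out * top

    return denoise
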