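"""Rician noise simulation for magnitude MR images.

Magnitude MRI noise is Rician: the acquired complex signal is the true image
``A`` plus independent Gaussian noise in the real and imaginary channels, and
the stored image is its modulus,

    real = A + G1,   imag_part = G2,   m = sqrt(real² + imag_part²),

with ``G1, G2 ~ N(0, σ)`` i.i.d.  The noise level is expressed as a
percentage τ of the maximum intensity ν of the clean image:

    σ = ν · τ / 100.

In dark regions (A ≈ 0) the output follows a Rayleigh distribution with mean
σ·sqrt(π/2); at high SNR it is approximately Gaussian around A + σ²/(2A).

Naming note: the usual symbol for the imaginary channel collides with the
local Moran statistic ``I_i`` used elsewhere in this package, so the
imaginary realization is called ``imag_part`` here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec", "noise_sigma", "add_rician_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise-level bookkeeping: τ (percent), ν (max clean intensity), σ = ν·τ/100."""

    tau: float
    nu: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("noise level tau must be nonnegative")
        if self.nu < 0:
            raise ValueError("maximum intensity nu must be nonnegative")

    @property
    def sigma(self) -> float:
        return noise_sigma(self.nu, self.tau)


def noise_sigma(nu: float, tau: float) -> float:
    """Gaussian standard deviation equivalent to Rician level τ% of intensity ν."""
    if nu < 0 or tau < 0:
        raise ValueError("nu and tau must be nonnegative")
    return nu * tau / 100.0


def add_rician_noise(clean, tau: float, seed: int = 0) -> np.ndarray:
    """Degrade a nonnegative image with Rician noise at level τ percent.

    Two independent Gaussian fields (split deterministically from ``seed``)
    form the real and imaginary channels; the returned image is the complex
    magnitude, hence nonnegative.  τ = 0 returns the input unchanged.
    """
    a = np.asarray(getattr(clean, "pixels", clean), dtype=float)
    if tau < 0:
        raise ValueError("noise level tau must be nonnegative")
    if a.size and a.min() < 0:
        raise ValueError("clean image must be nonnegative")
    sigma = noise_sigma(float(a.max()) if a.size else 0.0, tau)
    if sigma == 0.0:
        return a.copy()
    child_real, child_imag = np.random.SeedSequence(seed).spawn(2)
    g1 = np.random.default_rng(child_real).normal(0.0, sigma, a.shape)
    imag_part = np.random.default_rng(child_imag).normal(0.0, sigma, a.shape)
    return np.hypot(a + g1, imag_part)
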