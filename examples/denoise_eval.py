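"""Evaluate a denoiser blindly: QT before versus after bilateral smoothing.

Adds 8 percent Rician noise to a brain-like phantom (5 seeds), applies an
edge-preserving bilateral filter, and scores both images.  Positive deltas
mean the metric detects the quality gain from denoising — without ever
seeing the clean image.
"""

from lisaq import bilateral_denoiser, brain_like_phantom, denoise_comparison

phantom = brain_like_phantom(64, 64, seed=1)
table = denoise_comparison(phantom, tau=8.0, denoiser=bilateral_denoiser(),
                           seeds=[1, 2, 3, 4, 5])

print(table.round(4).to_string(index=False))
print(f"\nmean QT change after denoising: {table['delta'].mean():+.4f} "
      f"(improved in {(table['delta'] > 0).sum()} of {len(table)} seeds)")
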