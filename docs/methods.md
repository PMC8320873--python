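# Methods

## Model

The metric treats image quality as a function of spatial autocorrelation.
Pixel intensities in a clean MR slice are locally clustered — neighbouring
pixels belong to the same tissue and share similar values — while Rician
noise injects spatially independent variation that breaks clusters into
locally random or dispersed patterns.  The per-pixel measure of this is the
local Moran statistic

    I_i = z_i · Σ_j w_ij z_j,        z_i = (x_i − X̄)/S²,   z_j = x_j − X̄,

computed over a 3×3 window (queen contiguity) with row-standardised binary
weights w_ij = 1/8, where X̄ and S² are the mean and population variance of
the image.  I_i is positive where a pixel deviates from the mean in the
same direction as its neighbourhood average (clustering), negative at local
outliers, and its raster average — the global Moran statistic (GMS) I —
summarises the whole slice on an interpretive scale from +1 (maximal
clustering) through 0 (spatial randomness) to −1 (maximal dispersion).

Scoring proceeds in four steps.  (1) A foreground mask isolates the
anatomy: threshold at the image mean (ties kept), 4-connected hole filling,
and removal of 8-connected components smaller than `min_area_frac` (default
0.1%) of the raster.  (2) The I_i field is computed with replicate padding
so border pixels have complete windows.  (3) Foreground pixels are split
into dispersed (A: I_i ≤ 0, count N_CA) and clustered (B: I_i > 0, N_CB);
the boundary I_i = 0 is dispersed.  (4) With c = N_CB/N_If the clustered
fraction,

    Q1_raw = I·(1 − N_CA/N_If) + (1 − I)·c   ( = c exactly, see below)
    Q2_raw = (1 − N_CA/N_If) + (1 − I)·c     ( = c·(2 − I) )
    QT     = (Q1 + Q2)/2

where Q1, Q2 are the raw scores clipped to [0, 1].

## Conventions and their rationale

**Moments scope.**  Because the classes partition the foreground,
1 − N_CA/N_If ≡ N_CB/N_If, so Q1 reduces *identically* to the clustered
fraction c; the implementation asserts this on every call.  A second
algebraic fact drives the central design choice: if X̄ is taken as the
*local window* mean (the `stat_scope="window"` reading), the eight
neighbour deviations sum to exactly −(x_i − X̄), hence

    I_i = −(x_i − X̄)² / Σ_j z_j²  ≤ 0   for every non-flat window.

Under that reading only exactly-flat neighbourhoods can count as clustered,
so any continuous noise drives c to 0 and all scores to exactly 0 at every
noise level — a step function, not a quality scale.  The default is
therefore the classic form with image-global X̄ and S²
(`stat_scope="image"`), which degrades gradually as noise decorrelates
neighbours.  The window-local reading remains available behind the config
flag for comparison.

**Flat-window convention.**  Wherever the statistic degenerates (all eight
neighbour values identical under the window scope; a globally constant
image under the image scope), I_i := +1 when the centre equals the common
neighbour value (a locally constant patch is perfectly clustered) and −1
otherwise (an outlier on a flat background).  This choice is what makes the
ideal-slice limit (constant image → Q = 1) attainable exactly.

**GMS averaging region.**  The global statistic averages I_i across the
whole raster (`gms_scope="image"`, default), while the class counts are
restricted to the foreground.  Restricting the GMS average to the
foreground as well systematically inflates it above 1 on structured images
(foreground pixels carry the large standardised deviations), and since
Q2 = c·(2 − I), a falling inflated I *raises* Q2 — the total score then
responds non-monotonically to noise.  The foreground-restricted average is
available via config.

**Clipping.**  Q2_raw = c·(2 − I) exceeds 1 whenever the clustered fraction
is high but I < 1 (e.g. c = 1, I = 0 gives 2).  Scores are clipped
per-component to [0, 1], flags record when clipping fired, and QT is the
mean of the clipped components, making QT ∈ [0, 1] structural.

**Borders and ties.**  Replicate padding preserves the exact fixture values
of the uniform and checkerboard limit cases; ≥ at the foreground threshold
keeps constant images fully in the foreground.

## Rician noise simulator

Magnitude-MRI noise is simulated by its physical construction: two
independent Gaussian fields G1, G2 ~ N(0, σ) (split deterministically from
one seed via `SeedSequence.spawn`) form real channel A + G1 and imaginary
channel G2; the degraded image is the modulus.  The level is parameterised
as a percentage τ of the clean image's maximum intensity ν, σ = ν·τ/100, so
τ = 0 (or an all-zero image, where ν = 0) is exactly the identity.
Zero-signal regions follow a Rayleigh law with mean σ√(π/2); at high SNR
the output is approximately Gaussian around A + σ²/(2A).  Both facts are
used as distributional tests.

## Synthetic phantoms

The generator produces four families whose expected scores are known:
`uniform` (constant — the clustered limit, scores exactly 1),
`checkerboard` (cell 1 — every pixel an outlier, scores exactly 0; its
bright pixels are isolated, so it is scored under a full-image mask rather
than foreground extraction), `stripes` (anisotropic two-valued control),
and `brain_like`: 3–4 nested elliptical tissue shells plus a small
low-intensity "ventricle" (4–5 distinct tissue intensities) on a zero
background, piecewise constant, deterministic per seed, with the outer
semi-axes bounded so background covers roughly 35–65% of the raster.

What the phantom emulates: a bright-tissue anatomy on a dark background
with exactly flat interiors and sharp boundaries.  What it does not:
partial-volume blur, intra-tissue texture, intensity inhomogeneity, and
acquisition artefacts of real MRI.  Passing the sweep and denoising tests
therefore demonstrates the metric's response to Rician noise on clean
piecewise-constant structure, not calibrated agreement with human scores on
clinical data.  One known consequence: with only a few intensity levels,
pixels whose deviation from the global mean greatly exceeds the noise
amplitude never reclassify, so the mean-QT-versus-τ curve can plateau at
high τ for some phantom realizations, weakening (though rarely reversing)
the rank correlation.

## Experiment harnesses and problem sizes

Noise sweeps run τ = 0..15 in unit steps with 5 noise seeds on 64×64
phantoms — large enough that every foreground has ~2000 pixels and
Monte-Carlo summaries are stable, small enough that a full sweep (80
pipeline runs) takes about a second.  Averages over seeds at fixed τ stand
in for averaging over the slices of a volume.  Full-reference SSIM and PSNR
(scikit-image) can be computed alongside for comparison, mapped to the unit
scale (PSNR dB / 100; BRISQUE → (100 − value)/100, normalisation only —
BRISQUE itself is out of scope); values leaving [0, 1] pass through with a
warning.  PSNR is undefined at τ = 0 (zero distortion) and is omitted
there.  Denoiser evaluation pairs noisy/denoised scores per seed; the
bundled edge-preserving smoother wraps the scikit-image bilateral filter on
the image's native scale.

## Numerical notes

The vectorized field computation uses `scipy.ndimage.correlate` sums with
replicate padding and is tested to 1e−10 against an independent triple-loop
oracle.  Degenerate windows are detected exactly (neighbour min == max)
rather than by an S² tolerance, so the flat-window convention is immune to
floating-point cancellation.  I_i is invariant under positive affine
intensity maps (standardisation cancels scale and offset wherever the
statistic is defined), which is why readers never rescale intensities.
A sanity assertion bounds the default-convention GMS to [−3, 3]; the
mathematically attainable range under the image-scope conventions is about
[−8, +1] and realistic images stay well inside the band.

## Known limitations

- The score bounds of the local statistic for a given image class (the
  upper/lower limits the field literature calls k1, k2) have no closed form
  here and are not estimated.
- Spatially variant noise (multi-coil parallel imaging) is out of scope;
  the simulator is stationary.
- Volume handling is single-slice: users select slices from NIfTI/DICOM;
  no 3-D morphology or multi-slice aggregation beyond averaging sweeps.
- The metric is validated against analytic limits and trend properties on
  synthetic phantoms, not against subjective human scores.
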