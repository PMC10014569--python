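# Methods

`lpcos` implements an unsupervised-enhancement-plus-learning pipeline for
segmenting blood vessels in retinal fundus photographs, with particular
attention to *small* vessels (width under 65 µm), and an evaluation
protocol that measures small-vessel sensitivity separately from the usual
global scores. Everything is testable without external data through a
seeded synthetic fundus generator.

## Pipeline model

A fundus photograph is reduced to a scalar plane (green channel by
default — the highest-contrast plane for haemoglobin absorption), then:

1. **Local luminosity normalization.** Each pixel is divided by the mean
   of its n×n neighbourhood, N(x,y) = f(x,y) / mean_{n×n}(f). Any
   multiplicative illumination field that varies slowly relative to the
   window cancels exactly. `window_n` defaults to 31 px at a 565×584
   fundus scale (a few vessel diameters); it should be scaled with image
   resolution. The raw ratio is unbounded; for use as a network channel
   it is clipped at 4.0 and rescaled to [0, 1]. A `fov-aware` border
   policy averages over in-aperture neighbours only, avoiding the dark
   halo the camera aperture otherwise induces.

2. **Local phase congruency (LPC).** Vessels are low-contrast but
   phase-coherent across spatial frequency, so a contrast-invariant
   feature measure is computed from a bank of oriented log-Gabor
   quadrature filters (6 scales, minimum wavelength 3 px doubling per
   scale, 12 orientations). Per orientation θ the modified local energy
   E_θ = Σ_n A_n [cos(φ_n−φ̄) − |sin(φ_n−φ̄)|] is thresholded by a noise
   estimate T_θ and weighted by a sigmoidal frequency-spread term
   W_θ = σ(g·(s−c)) with c = 0.4, g = 10; the LPC value is
   Σ_θ W_θ(E_θ−T_θ)⁺ normalized by the total amplitude, and the LPC
   orientation is the argmax over θ of the per-orientation normalized
   energy (ties → smallest index). The noise threshold models the
   smallest-scale amplitude over a flat noise spectrum as Rayleigh,
   estimates its scale from the median (m = σ_g·√(ln 4)), propagates it
   to the other scales by the ratio of filter spectral norms, and sets
   T_θ = Σ_n µ_n + k·σ_total with k = 3 and the per-scale standard
   deviations combined in quadrature (a per-scale k is available behind
   `k_per_scale`).

3. **Orientation scores and left-invariant derivative (LID) filtering.**
   The image is lifted to position × orientation with cake wavelets: an
   angular B-spline (order 3) partition of the Fourier plane over 8
   orientation channels on [0, π), radially windowed by a raised-cosine
   low-pass reaching zero at Nyquist (inflection at 0.8·Nyquist). The
   one-sided transfers tile the pass-band exactly (partition of unity),
   so summing the real parts of the channels reconstructs the pass-band
   image. Per channel, a rotated anisotropic Gaussian blur (σ_η = σ_s
   across the local orientation, σ_ξ = 2σ_s along it), a Gaussian over
   the periodic orientation axis (σ_o = π/8), and the negated
   second derivative across the orientation (−µ⁻²∂²_η with µ = σ_o/σ_s)
   give a dimensionless, scale-normalized ridge response. Responses are
   summed over the spatial scales S and collapsed by a per-pixel maximum
   over orientations. Because each branch of a crossing lives in its own
   orientation channel, crossings keep full response (verified: ≥ 0.9×
   the straight-segment response on additive crossing fixtures — with
   *saturating* overlaps part of the crossing energy leaks across
   channels and the retention is lower; real fundus crossings are
   closer to additive in absorbance).

4. **Segmentation network.** A compact U-Net variant implemented
   directly in NumPy (forward and backward passes hand-written over
   BLAS-backed convolutions): every conv pair carries an identity
   shortcut (1×1 projection on channel change, added after the second
   activation), all down-sampling is stride-2 3×3 convolution (no
   pooling anywhere), decoder up-samples by 2×2 transposed convolution
   with encoder-skip concatenation, and a 1×1 convolution with
   per-pixel two-class softmax ends the network. Channel counts double
   per level from `base_filters`. Inputs are standardized per channel
   (z-scoring with statistics frozen from the first training batch set;
   stored in the checkpoint) — with only a handful of gradient steps in
   the small-scale test regime, learning speed depends strongly on
   input conditioning. Training: pixel-wise categorical cross entropy,
   plain SGD at learning rate 0.01, mini-batches of 32 patches of
   64×64, the patch set resampled every epoch and split positionally
   90/10 into train/validation with validation AUC logged per epoch.
   Patch centres are uniform over the frame including the aperture rim,
   so the network learns to reject the rim.

5. **Evaluation.** All counts are restricted to the field of view.
   Se, Sp, Acc from the pixel confusion matrix; ROC/AUC by threshold
   sweep (trapezoidal area). The small-vessel ground truth is
   gt AND NOT opening(gt, disk(d)) with d the 65 µm diameter converted
   to the nearest odd pixel count; Se_sv = TP_sv/(TP_sv+FN_sv) counts
   detections on those pixels only, and ROC_sv plots Se_sv against the
   *global* false-positive rate (negatives are all in-FOV non-vessel
   pixels). An alternative reading that also opens the prediction
   (crediting only predicted-thin structure) is available behind
   `open_prediction`; it is not the default because the headline
   small-vessel table pairs Se_sv with the global Sp.

## Synthetic data: what it emulates and what it does not

The generator grows seeded vessel trees as bounded-curvature random
walks inside a centred circular aperture (≥ 60% of the frame), renders
each branch with a Gaussian cross-profile (FWHM = nominal width, so
boundaries are blurred as in real small vessels), and composes the image
as background × smooth illumination ramp − contrast·profile + smoothed
texture + Gaussian noise, clipped to [0, 1]. Defaults: 256×256 frame,
3 trees, contrast 0.3, illumination amplitude 0.2, noise σ 0.02,
texture amplitude 0.015, nominal pixel size 8 µm (so the 65 µm opening
disk is 9 px). With ≥ 2 trees the first two trunks are routed through
the centre, guaranteeing a crossing.

Branch widths are deliberately **bimodal**: trunks draw from
10.4–13 px and distal twigs from 1.2–3 px (`small_width_max_px` = 3),
with a mild 15% along-branch taper. Real vessel trees also separate
arterioles/venules from capillary-scale side branches; the bimodal
choice additionally keeps the generative "small" label consistent with
the morphological definition — any width distribution with mass in the
4–9 px band would make the two definitions disagree by construction.
Twig pixels that fall inside a trunk's own footprint are labelled
trunk. Under these conditions the opening-based small-vessel ground
truth recovers 94–97% of generative small pixels and leaks < 1% of
trunk pixels.

Not emulated: optic disc, fovea, lesions, central vessel reflex,
photoreceptor mosaic, colour. Passing tests on these fixtures validate
the geometry/contrast/noise regime only; they say nothing about
pathology or camera-specific artifacts.

## Numerical choices

- All FFT stages edge-pad the image (LPC: by the largest wavelength;
  LID-OS: by ≈ 6σ_max) to suppress periodic wrap-around at the aperture
  rim, and crop afterwards.
- Log-Gabor radial profile σ/f₀ = 0.55 (≈ two-octave bandwidth,
  consistent with the ×2 scale multiplier); angular Gaussian
  σ = (π/12)/1.3. Self-conjugate Nyquist bins on even-sized grids are
  zeroed so the even/odd filter pair is an exact quadrature pair.
- The mean-phase normalization (the sin φ̄/cos φ̄ pair) divides exactly,
  with zero-amplitude pixels contributing zero energy; the small
  constant ε = 1e-4 appears where the model defines it — the spread
  weighting and the final value/orientation ratios. This keeps the
  identity-expanded implementation equal to an explicit-angle
  transcription to machine precision.
- LPC orientation at ideal ridge centres is a near-tie: phase
  congruency is ≈ 1 at *every* orientation that carries energy, so the
  per-orientation normalized argmax margin comes from the noise
  threshold alone. On noisy rotated-bar fixtures the correct label wins
  at roughly 75–85% of centreline pixels, with the remainder taken by
  the adjacent labels; the orientation channel should be read as a
  contextual cue (its stated purpose), not a per-pixel estimator.
- LPC is a feature detector, not a region-fill measure: vessels whose
  contrast falls to the level of the background texture field (0.015
  amplitude here, i.e. contrast ≈ 0.05) are indistinguishable from
  texture features at any noise-threshold setting; the LID-OS premise
  still holds there. Both enhancements cleanly rank vessels above
  background from contrast 0.1 upwards.
- The LID spatial scale set S should span the half-widths of the
  vessels actually present. Package default S = {1, 2, 3} px targets
  1–3 px half-widths (DRIVE-scale small vessels); the synthetic smoke
  protocol uses S = {1, 2, 3, 5, 8} because its trunks are ~11 px wide.
- Orientation period is π (undirected ridges); the imaginary (edge)
  part of the lift is retained in the stack but unused by the second
  derivative stage. Dark-on-bright polarity is the fundus default;
  `auto` infers it from the mean-median skew inside the aperture.
- Tie-breaks: Eq-level argmax ties resolve to the smallest orientation
  index; thresholding uses ≥.

## Problem sizes in the test suite

The self-contained training checks run a reduced instance of the full
protocol: 5 synthetic images, 500 patches per epoch (100 per image),
5 epochs, base_filters 8, depth 3 — about 80 SGD steps — with held-out
AUC read from the per-epoch validation log and from a sixth, unseen
image. The full-scale protocol (9 000 patches per epoch, base 32,
depth 4, ~70 epochs) is what the configuration defaults describe; it
needs real fundus data and hours of compute, and its headline scores
are not reproduced here.

## Known limitations

- The NumPy network trains on CPU only and is sized for small
  instances; no batch normalization, augmentation, momentum or
  learning-rate schedule (flags exist for momentum).
- Vessel boundary localization is soft by design (Gaussian profiles,
  enhancement widening); width measurements from these segmentations
  overestimate, as the enhancement-based approach tends to dilate small
  vessels.
- Patch stitching can reduce connectivity at tile seams; overlapped
  averaging (default overlap 16) mitigates but does not remove this.
- The morphological small-vessel definition counts *pixels*, not
  vessels; a missed faint twig and a missed rim of a medium vessel are
  weighted equally.
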