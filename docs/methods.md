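# Methods

## Model

The method treats sub-pixel edge localization in a blurred image as 1-D
regression. At a candidate site with edge-normal direction θ, an intensity
profile of length *L* pixels is sampled along θ (bilinear interpolation,
unit spacing). The regression target *t* ∈ [0, 1] is the position of the
true edge as a fraction of the profile: a profile spanning −*tL* …
(1−*t*)*L* around a verified edge point (negative = channel interior)
carries target *t*. A single-hidden-layer network

    y = w_O · σ(w_H x + b_H) + b_O,     σ = logistic

maps the min–max-normalized profile to the predicted fraction. The model
assumes that the blurred appearance of an edge, over a window long enough
to contain it, determines its position — a deliberately shallow hypothesis
that keeps training in the seconds-to-minutes range on one core.

Supervision comes from a sharp reference modality (SEM) registered to the
blurred one. At prediction time no reference exists; profiles are centered
(*t* = 0.5) on the skeleton of the blurred dark wall band, which on the
simulated chips — as on the real ones they emulate — sits systematically
10–15 px *inside* the true edge.

## Pipeline stages and key choices

**Calibration and registration.** The blurred image is resampled to the
reference pixel pitch by the scale ratio `C_cali = C_OM / C_SEM` with
nearest-neighbor lookup (each output pixel is a copy of a source pixel).
Rigid registration minimizes the *directed* sum over moving-centerline
points of the distance to the nearest reference-centerline point
(a symmetric variant is available); the search is an exhaustive coarse
grid (2 px translation, 1° rotation steps by default) followed by
Nelder–Mead refinement, with rotation about a caller-supplied pivot
(image center for full frames). Every evaluated transform is kept in a
trace, and the returned transform attains the traced minimum; ties break
toward the earliest evaluation, so results are deterministic. Channel
centerlines come from Otsu thresholding (inclusive, so exact two-level
images threshold correctly), skeletonization, and ordering of the longest
skeleton path by double breadth-first search. In the blurred modality the
lumen is identified as the bright connected component whose pixels lie
closest, on average, to dark pixels — the narrow corridor squeezed between
the wall bands — rather than the open background.

**Edge geometry.** Gradients use the classic 3×3 Sobel kernels applied as
cross-correlation; the vertical kernel's positive direction is *up* the
image, so θ = atan2(G_y, G_x) follows the mathematical convention and a
unit step along θ moves (cos θ, −sin θ) in (x, y). θ is the full-quadrant
arctangent so opposite-facing edges are distinguished; pixels with zero
gradient get NaN and are excluded. Reference edges are Canny edges
(Gaussian σ = 1; hysteresis at 0.1/0.3 of the maximum smoothed-gradient
magnitude — the detector is parameter-free in the pipeline but both
fractions are exposed). Inside a wide dark band the raw gradient vanishes,
so the band-normal orientation at skeleton points is taken from the
structure tensor of a σ = 2 smoothed copy (stable mod 180°); the outward
half-direction is then resolved by comparing mean intensity over the next
`sign_reach` samples along ±θ. Looking inward, a profile crosses the
bright lumen and reaches the *opposite* wall band, so the inward mean is
lower; the default reach (40 px) is sized to cross the lumen of the
default geometry and is configurable for other chips.

**Profile datasets.** Each reference edge point is sampled
`samples_per_point = 9` times with *t* drawn uniformly from [0.1, 0.9]
(seeded; an evenly spaced fixed grid is available since the sampling rule
admits both readings). The range excludes the extreme ends, where the
target is unlearnable from context. A point is dropped whole if any of its
segments leaves the image, so the row count is exactly retained points ×
9. Features are min–max normalized per row to [0, 1] — profiles from dark
band cores and bright plateaus otherwise differ by an order of magnitude
in range, and sigmoid inputs want a bounded scale; the per-row minimum and
range are stored so raw profiles are recoverable. Rows are split 70/25/5
by a seeded permutation (per-profile, not per-point — profiles from one
point may land in different splits; with 9 nearly-identical augmentations
per point this slightly flatters held-out metrics, which is acceptable
here because the synthetic acceptance margins are wide).

**Training.** Full-batch Levenberg–Marquardt with analytic Jacobian
(verified against central differences at 1e−5 relative tolerance).
Damping: μ starts at 1e−3, ×10 on a rejected step, ×0.1 on acceptance,
abort above 1e10 (in practice: converged). A step is accepted only if the
training MSE strictly decreases, so the recorded training curve is
strictly decreasing by construction. One epoch = one accepted step.
Stopping: validation MSE not below the best-so-far for 6 consecutive
epochs, or 1000 epochs; the returned parameters are the best-validation
snapshot, which can precede the stop epoch. Initialization is a seeded
Nguyen–Widrow-style scheme for inputs in [0, 1]. Hidden size defaults to
20; the parameter count is N_H·L + 2N_H + 1 (2041 at L = 100, N_H = 20),
so the default training sets (~2000–4000 rows in train) sit near the
parameterization scale and early stopping carries the regularization.

**Prediction and enhancement.** A predicted fraction *p* maps to pixel
index *p·L* along the profile and to image coordinates via the profile
origin and outward direction. Outputs are *not* clipped to [0, 1] by
default: prediction profiles are centered on the band skeleton, which sits
10–15 px inside the true edge, so for short windows the correct answer
lies at or beyond the window end and the linear output layer must be free
to extrapolate; clipping is available as an option (`clip=True`).
Enhancement rebuilds each profile piecewise-constant: `edge_width` pixels
(default 5 — purely presentational; 1 px would be nearly invisible)
centered at the rounded predicted index are set to the edge value (0),
indices left of the band take the profile's first element, indices right
of it the last element, preserving the interior/exterior contrast
side-wise. Bands falling outside the profile are clipped back into range.
Writeback is nearest-pixel along the sampling segment; overlapping
segments at corners resolve last-writer-wins, and pixels not on any
segment are untouched.

**Evaluation.** Prediction error is the directed Euclidean distance from
each predicted point to its nearest reference point (k-d tree; identical
to brute force, which the tests verify). Outliers follow the boxplot rule,
distance > Q3 + 1.5·IQR, applied per image. Correlations are Pearson's r
per split, NaN-flagged for degenerate inputs.

## The synthetic scene generator

The generator emulates the imaging regime of a PDMS micromixer chip: a
zigzag channel (turning angles 15–60°) whose sharp rendering is a
two-level raster (dark lumen 40, bright background 200, one-pixel
anti-aliased boundary so truth edges are sub-pixel meaningful), and whose
blurred rendering draws each wall as a 15-px dark band with its centerline
`edge_offset` px inside the true edge, convolved with a Gaussian PSF and
corrupted by additive Gaussian noise. Defaults — 320×320 px, channel width
68 px, band width 15 px, offset 12 px (drawn in [10, 15] for the
acceptance experiments), blur σ = 3 px, noise σ = 3 grey levels, scale
0.328 μm/px — reproduce the stated band-to-edge separation regime; blur
and noise levels are this package's own choices since the emulated setup
quantifies neither, picked so the band's edges are visibly soft (PSF
comparable to a few pixels) while Otsu/Canny still segment reliably.
Truth edges are sampled every 0.5 px of arc length along the exact offset
polygon. Rendering is a pure function of the spec, including the seed.

What the generator does *not* model: diffraction rings, shading or
illumination gradients, cross-modality registration error (the pair is
born aligned), SEM charging artifacts, wall roughness, or ground-truth
uncertainty in the reference edges. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline under the stated
geometry, not instrument-grade accuracy on real micrographs: the synthetic
error floor (~0.2–0.5 px) is several times lower than what real paired
data can achieve, because the dominant real error sources are absent.

## Problem sizes

The standard experiment suite uses four scenes (one per turning angle) of
320×320 px with ~670 reference edge points each, samples every second
edge point (`point_stride = 2`, ~2600 profile rows per scene), and trains
one network per scene — a deliberately desk-scale analog of a full
multi-megapixel acquisition, chosen so the complete acceptance run
(including the ten-length sweep) finishes in minutes on one core. The
row counts scale linearly with image size and stride; nothing in the
method depends on the reduced scale.

## Known limitations

- The learned mapping is setup-specific: a network trained on one
  chip/microscope pair does not transfer to another contrast mechanism or
  band polarity without retraining (bright-wall chips need the polarity
  flag of the outward-sign rule).
- Centered prediction windows bound the expressible displacement: with
  training targets in [0.1, 0.9], a window of length L covers band-to-edge
  offsets up to 0.4·L without extrapolation. With 10–15 px offsets the
  sweep error therefore only fully converges from L = 40; L = 20–30 relies
  on linear-output extrapolation and carries a few-pixel residual. Short
  windows (L = 10) fail outright — the band fills the window and carries
  no positional information.
- Registration is rigid (translation + rotation + uniform scale); lens
  distortion or non-rigid chip deformation is out of scope.
- Enhancement rewrites only profile segments through band-skeleton points;
  regions whose skeleton is missed (broken bands, extreme corners) retain
  their blurred appearance.
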