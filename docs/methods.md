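# Methods

This note documents the models, parameters, and numerical choices behind
`ms2quant`, and what the synthetic validation does and does not establish
about real data.

## Detection model

The MCP channel is max-projected over z per time point, smoothed with a
Gaussian filter (σ = 0.55 px, reflective boundaries), and thresholded at a
fraction `bth_fraction` (default 0.30) of maximum smoothed intensity.
Suprathreshold pixels are clustered with 4-connectivity; clusters smaller
than `min_pixels` (default 4) are not callable dots; clusters whose
geometric center falls outside every segmented nucleus are excluded; when
several clusters share a nucleus, the largest (ties: brightest peak, then
smallest centroid coordinates) survives, so a nucleus contributes at most
one dot per frame. Dot size is reported in 4-pixel units
(`pixel_count / 4`), a relative proxy for the number of nascent transcripts
at the site.

Choices that the recipe's verbal description leaves open, and how they were
fixed here:

- **Threshold scope.** "Fraction of maximum intensity" is frame-scoped by
  default (`max_scope="frame"`); a movie-wide scope is available by
  configuration. Every run logs the realized absolute threshold per frame.
- **Filter order.** The threshold is applied to the *smoothed* image, in
  the order the processing steps are described (smooth, then threshold);
  this is recorded in the run log.
- **Nucleus membership.** Tested at the dot's geometric center by default;
  a majority-pixel rule is available (`membership="majority"`).
- **No temporal linking.** Dots are detected independently per frame; all
  downstream statistics are per-frame or per-window. Initiation calls rely
  on stable nucleus identities (exact for static synthetic nuclei; a
  nearest-centroid matcher with a configurable gate, default 10 px, is
  provided for moving nuclei).
- **Early cycles.** Windows flagged `per_slice` (nc9/nc10 by default, when
  nuclei have not finished migrating to the periphery) are quantified on
  individual z-slices; the per-time-point count is the **maximum** over
  slices. A maximum (rather than a sum or mean) cannot double-count one
  dot seen in adjacent slices; the choice is isolated behind the flag.

Nuclear segmentation fills the ring-shaped Nup envelopes (Otsu threshold on
the smoothed channel, hole filling) so that a dot inside a nucleus tests as
inside, splits touching nuclei by watershed seeded from local maxima of the
distance transform (`split_min_distance` = 5 px), and discards regions whose
centroid lies outside the embryo boundary.

The embryo boundary is the contour of the largest above-background region
of the blurred (σ = 2) Nup channel after morphological closing and hole
filling, then smoothed along its arc (Gaussian, σ = 5 boundary points):
an embryo outline is smooth at embryo scale, whereas individual peripheral
nuclei scallop the raw contour. On synthetic ellipses this boundary is
within ~1.2 px (Hausdorff) of truth. The ventral/dorsal extremes defining
the EW axis should be supplied manually (they are snapped to the boundary),
as in the underlying imaging protocol; automatic extremes (extremal
boundary points along the configured DV image axis) are available but can
tilt the axis by a few pixels, costing up to ~3 EW units near the poles.

## Spatial model

EW is the relative coordinate along the ventral→dorsal axis: the projection
of a dot's center onto that axis, scaled to [0, 100] and clipped (clipping
is logged). Histograms use bins of 4 pixels along the DV axis, expressed in
EW units; each dot contributes to exactly one bin through its single-pixel
geometric center.

The density profile is a mixture of Gaussian kernels (one per dot position)
evaluated on a fixed EW grid (0–100, step 0.25). The bandwidth follows the
robust Silverman plug-in rule h = 0.9·min(sd, IQR/1.34)·n^(−1/5), with a
floor (default 2 EW) that also covers degenerate samples (n < 2 or zero
spread), where the rule itself is undefined. The rule assumes a near-normal
unimodal distribution; for the stripe-shaped profiles here it mildly
oversmooths, which the width tolerance below accounts for.

Width is the EW distance between the outermost positions where the density
reaches `th_fraction` (default 0.30) of the curve's own per-time-point
maximum. Crossings are refined by linear interpolation between the two
bracketing grid points — at the default grid step, snapping to the grid
would alias the crossing by up to 0.125 EW per side, which matters for the
closed-form check below. Multi-modal profiles use the outermost crossings
and are flagged. The ventral boundary walks ventrally from the curve peak
to the first sub-threshold crossing; for unimodal profiles it equals the
width call's left crossing, and a profile still above threshold at EW 0
returns 0 with a flag. Note the detection threshold (BTH, intensity
fraction) and the width threshold (TH, KDE fraction) are distinct
parameters that happen to share the default value 0.30.

For a single position, the kernel is explicit and the width has the closed
form 2h·sqrt(2·ln(1/TH)) ≈ 3.1036·h at TH = 0.3; the implementation matches
it to ~0.1%. For a dense uniform stripe on [a, b], the blurred edges move
each crossing outward by z·h where 1 − Φ(z) = TH (z ≈ 0.524 at TH = 0.3),
so a [20, 60] stripe reads ≈ 42.4 EW at n = 3000 — the 40 ± 4 EW acceptance
band is kernel blur, not error.

Replicates are aligned to the first profile by the EW shift (±15 EW search,
grid-step resolution, ties toward zero) maximizing the cross-correlation of
the densities, correcting for lateral mounting rotation; how such shifts
are chosen is otherwise unspecified in the protocol, so cross-correlation
is this package's decision.

## Group comparisons

Window-level per-embryo values are compared with a two-sample, two-tailed
Student's t test (equal variances) to match the small-scale replicate
analyses this pipeline mirrors; Welch's correction is available by flag.
SEM = sd/√n, undefined (NaN) below n = 2. No multiple-testing correction is
applied; output tables carry a footnote saying so. Missing windows are
reported as absent rather than zero so pooling embryos imaged over
different developmental spans does not bias cross-embryo means.

## Synthetic embryo generator

The generator emulates the structure the pipeline assumes, with exact
bookkeeping:

- 512×512 field; lateral-view ellipse (semi-axes 170 px along DV = image y,
  230 px along AP), ventral at the image bottom (EW 0);
- 90 ring-shaped nuclei (radius 5.5 px, ring 2 px) placed deterministically,
  evenly spaced along the periphery with ring outer edges on the ellipse;
  configurations whose nuclei would overlap are rejected;
- 8 windows (nc9 … nc14c) × 10 frames (~60 s/frame, ~10-min windows); the
  default activity trajectory rises from 4 nuclei at nc10 to 22 at nc13 and
  declines to 10 at nc14c, all within an EW [20, 60] stripe (onset at nc10
  mirrors the wild-type enhancer's behavior); per window, the active set is
  drawn from the nuclei inside the stripe (an error if too few exist);
- one dot per active nucleus per frame: an exactly-known integer pixel set
  (the `area` nearest pixels to a jittered sub-nuclear center, area uniform
  on 6–10 px so the size metric averages ≈ 2.0), rendered as a truncated
  Gaussian profile whose outermost set pixels hold ≈ 0.6 × peak (peak
  uniform on 0.85–1.0) — calibrated so the suprathreshold support after
  smoothing matches the true pixel set closely (detected areas within a few
  % of truth at window level);
- dots span 3 z-planes with attenuation (0.6, 1.0, 0.6) so the max
  projection preserves them and per-slice early-cycle detection sees them
  on every slice;
- uniform background (mean 0.10) plus Gaussian noise (sd 0.015), clipped to
  [0, 0.25].

Under these defaults the signal-to-background invariant holds: after
smoothing, every dot peak clears 0.3 × frame max and the background never
does, so per-frame detected counts equal ground truth exactly — recovery is
a fair, not a lucky, test. On frames with no dots at all, a fraction-of-max
threshold necessarily falls inside the background band; the resulting
single giant suprathreshold component has its centroid in the embryo
interior, outside every peripheral nucleus, and is discarded — zero-activity
frames therefore correctly yield zero dots.

`hard_mode` probes threshold sensitivity: background noise ×3 (clip
retained) and a 10% subpopulation of dim dots (peaks 0.30–0.45) whose
smoothed peaks can fall below 0.3 × frame max, deliberately violating the
invariant above. Losses (never false positives) result; per-window mean
counts stay within 10% of truth. Early experiments with globally dim dots
or unclipped noise made frame-scoped thresholding pathological on
low-signal frames (the threshold drops into the background band and
scattered noise clusters inside nuclei are called as dots) — an instructive
failure mode of fraction-of-max thresholding, but not a usable test
condition.

**What the generator does not emulate:** nuclear movement, division and
mitotic waves; photobleaching and shot-noise statistics; 3-D nuclear
geometry (nuclei sit on a single peripheral arc, as appropriate for
max-projected lateral views); inhomogeneous illumination; dot intensity
fluctuations within a window (bursting kinetics). Passing tests therefore
establish the correctness of the measurement chain on data satisfying the
pipeline's stated assumptions, not robustness to every real-microscope
artifact.

## Problem sizes

Unit tests run on a down-scaled embryo (192×256, 30 nuclei, 9 frames);
end-to-end acceptance checks use the full default conditions (512×512,
90 nuclei, 80 frames, seeded). Dense-stripe width checks use n = 3000
sampled positions; alignment checks n = 500. These sizes were chosen so the
statistics of interest (window means, KDE widths) are well determined.

## Known limitations

- Automatic EW extremes are sensitive to lateral wander of the extremal
  boundary point; supply manual extremes for quantitative EW work.
- The Silverman floor (2 EW) bounds the resolvable width from below
  (~6.2 EW at TH = 0.3); extremely narrow domains saturate there.
- Frame-scoped fraction-of-max thresholding is undefined-by-construction on
  signal-free frames; the giant-component behavior documented above makes
  it safe but depends on a non-zero background level.
- The nearest-centroid nucleus matcher is greedy and ungated across large
  displacements; it is adequate for slowly drifting nuclei, not for
  mitosis.
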