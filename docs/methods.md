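# Methods

This note documents the models, parameter choices and numerical decisions
behind `lamincycle`, and what the synthetic-data generator does and does not
emulate.

## Image containers and mask algebra

Images are per-cell, 2-D, multichannel (brightfield, lamin A, tubulin,
chromatin), aligned on one pixel lattice. Coordinates are 0-based,
row-major, origin at the upper-left corner; `centroid_x` is measured in
pixels from the left image edge. Masks are boolean grids on the same
lattice.

"Eroded/dilated by N pixels" uses a Euclidean disk of radius N as the
structuring element (radial, not square — a disk of radius 1 is the 5-pixel
cross). The peri-nuclear ring is `dilate(nucleus, 1) AND NOT
erode(nucleus, 2)`: a ~3-px band straddling the nuclear envelope where the
lamina sits. The nuclear morphology mask is a threshold at 0.3 of the
chromatin-channel maximum, hole-filled, keeping every connected component at
least 25 % the area of the largest (so two-lobed anaphase/telophase nuclei
survive) and at least 10 px.

Spot counting thresholds a channel at 60 % of its (restricted) maximum and
counts 8-connected components of at least 10 px; the minimum-area rule plays
the role of a noise-exclusion range mask, and 8-connectivity keeps diagonal
fragments of one nuclear lobe together. Neither the 0.3 morphology fraction,
the 10-px minimum area, nor the component-retention fraction have canonical
published values; all are configurable. The 60 % spot threshold is taken of
the per-image maximum (not a global percentile).

The focus measure is the RMS of the Sobel gradient magnitude over the cell
mask. Any monotone focus measure with the same ranking would serve; Sobel RMS
is simple and deterministic. Aspect ratio is minor/major axis of the
ellipse with the region's second central moments, pooled over all components
of the mask (a two-lobed nucleus is deliberately treated as one elongated
region); degenerate single-pixel regions return 1.0.

## Serial gating

Gates run in a fixed order; each cell gets exactly one label, and excluded
cells carry a reason (`not_single_cell`, `cropped`, `out_of_focus`,
`nuclear_intensity_extreme`, `ambiguous_morphology`). Comparisons at an exact
threshold pass (closed bounds).

Published gate boundaries for this kind of analysis are drawn interactively
on bivariate plots, so numeric defaults must come from the data. Range gates
(brightfield area, centroid-x, nuclear total intensity) resolve as quantile
anchors — [5 %, 95 %] for area and centroid-x, [2 %, 98 %] for nuclear
intensity — widened on both sides by 1.5 × IQR of the feature. The padding
matters: a raw quantile range by construction cuts the tails of *any*
population, including a clean one; the IQR fence keeps unimodal populations
intact while still cutting debris, doublets and cropped cells that sit far
outside the bulk. All ranges can be set explicitly in `GateConfig` instead.

The mitotic split on lamin A max-pixel over the peri-nuclear ring is a 1-D
two-class Otsu threshold computed exactly on the sample: every gap of the
sorted values is scanned for the split maximizing the between-class variance
w₁w₂(m₁−m₂)², and the threshold is the midpoint of the optimal gap. The exact
scan avoids histogram-binning artifacts, and the midpoint placement avoids
thresholds that graze a cluster edge. Population-dependent rules require at
least 10 cells and are resolved on the full input before any cell is
classified, so labels are invariant to input order.

The nuclear aspect-ratio cut between "high" (round) and "low" (elongated or
two-lobed) defaults to 0.6. Anaphase calls are flagged `low_confidence`:
the phase is short and sparsely sampled in real populations. Nuclear spots
are counted on the lamin A channel restricted to a 12-px dilation of the
nucleus intersected with the cell mask — wide enough to include spindle-
and pole-associated lamin structures in mitotic cells.

## Masked correlation

Pearson r uses the textbook product-moment formula over masked pixels only,
in double precision; background pixels never enter the sums. Spearman ρ is
the same statistic on mid-ranked intensities. A channel counts as constant
under the mask when its variance is below 1e-12 × (mean)²; if both channels
are constant the correlation is undefined and an error is raised. The sign
fractions in per-phase summaries count |r| < 1e-9 as zero — a practically
empty bin kept so the three fractions sum to 1.

The cell-area mask is the union of 10 %-of-maximum threshold masks on the
lamin and tubulin channels, hole-filled, largest connected component kept.
The two channels are complementary across the cycle (lamin nuclear in
interphase, tubulin cytoplasmic — and roughly reversed in mitosis), so their
union covers the whole cell in every phase.

## Lamina periphery/interior ratio

The nuclear mask is split into a rim band (`mask AND NOT erode(mask,
rim_width)`, default rim_width 2 px) and the eroded interior; the ratio is
the mean lamin A over the band divided by the mean over the interior — a
ratio of means, not a mean of pixel ratios, so dim pixels cannot dominate.
The band and interior are disjoint and partition the mask, and the ratio is
invariant to multiplicative rescaling of the channel. For two-lobed nuclei
the ratio is computed per connected component and averaged.

The erosion-band rim is an automated, reproducible stand-in for manual
periphery annotation; it is a geometric definition, not a segmentation of
the lamina itself. Nuclei smaller than the rim width are rejected rather
than silently measured.

## CP model and fitting

Model: I(t) = a·e^(−bt) + c·t + d after laser-on, a the bound amplitude,
b > 0 the bound-pool bleach rate (1/s), c ≤ 0 the slow linear bleaching of
the freely diffusing pool (a.u./s), d the free amplitude. Free fraction =
d/(a+d); after peak normalization a + d ≈ 1 (checked to 0.05).

Processing order: moving-average smoothing, t0 detection, truncation,
peak normalization, bounded nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective):

* The smoothing window (default 0.1 s) is converted to samples by rounding
  half-up with a minimum of 1, then forced odd: an odd centered window is
  zero-phase, so smoothing shifts neither the detected edge nor the fitted
  amplitudes by half a sample.
* t0 is the maximal first difference of the smoothed trace, refined to the
  maximal *raw* first difference within one window of that location —
  smoothing spreads the jump over the window and can bias the coarse
  estimate by a sample. A trace already starting at its peak yields t0 = 0
  with a warning; a trace whose largest difference carries less than 10 %
  of the dynamic range has no laser-on edge and is rejected.
* Samples within one smoothing window after t0 mix pre- and post-jump
  intensities and are dropped when the trace can afford it (≥ 10 samples
  remaining). The fit's time axis stays zeroed at t0, not at the first kept
  sample, so a and d extrapolate to the true laser-on instant.
* Bounds: a, d ∈ [0, 1.5]; b ∈ (0, 100]; c ∈ [−1, 0] — guaranteeing
  free fraction ∈ [0, 1]. Initialization exploits that the bound component
  has bleached out by the trace end: d₀ = mean of the last third,
  a₀ = 1 − d₀, b₀ = 1/s, c₀ = slope of the last third (clipped into
  bounds).
* `converged` requires optimizer success and mean squared residual ≤ 0.01
  (normalized units). b < 0.01/s flags the fit `ill_conditioned`: the
  exponential is then indistinguishable from the line over a ~60 s trace,
  the regime where binding–unbinding on the measurement timescale would
  require a dynamic model that is out of scope here.

Aggregation reports mean and *sample* standard deviation of the free
fraction over converged fits, in percent, plus (when traces are supplied)
the mean normalized curve with a per-timepoint SD band on a common time
grid spanning the shortest trace.

## Synthetic data generator

Images are piecewise-constant intensity compartments on a 128×128 canvas,
blurred with a Gaussian PSF (σ = 1.5 px) and degraded with additive Gaussian
noise of σ = 0.03·sqrt(intensity) — a Poisson surrogate that keeps the
generator dependency-light. Geometry is jittered per cell (position ±3 px,
size ±6 %, random orientation); everything is deterministic given
(preset, seed). Intensity units are arbitrary throughout, matching the
assay.

Per-phase presets encode the ground truth the pipeline must recover:
rim-enriched lamin with a nucleoplasmic pool in interphase (rim factor 3.0)
and telophase (3.4, two daughter nuclei), dispersed cytoplasmic lamin with a
depleted margin around condensed chromatin in prophase (0.7) and metaphase
(0.48), mild spindle enrichment in metaphase, and bright pole-proximal lamin
accumulations in anaphase. Lamin rim bands are painted with the same
disk-erosion geometry the analysis measures, so with blur and noise disabled
the measured periphery/interior ratio equals the preset rim factor up to
rasterization; with the default blur the measured ratios compress toward 1
(interphase ≈ 1.2 rather than 3) but never cross it — the directional claim
is what the generator guarantees, not the absolute value. Intensity levels
were chosen during generator construction so that its own invariants hold
robustly under the default noise: correlation sign patterns per phase, spot
counts (1/1/2 for prophase/metaphase/anaphase on lamin, 2 for telophase),
and the mitotic vs non-mitotic separation of the peri-nuclear lamin maximum.

CP traces are the forward model with a = 1 − f, d = f for a true free
fraction f, preceded by a 1 s detector baseline (level 0.03), sampled at
20 Hz for 60 s with noise σ = 0.02. The named presets G1 (f = 0.85) and
S (f = 0.75) define the two study conditions; the default bleach rate
(0.3/s) lets the bound pool decay within the first ~15 s, and the free
slope (−0.002 a.u./s) loses ~12 % over the recording.

What the generator does **not** emulate: optical aberrations and a realistic
PSF, detector offset/gain structure, cell-to-cell contact or clumping,
partial cropping and defocus (all synthetic cells pass gates 1–4),
chromatin texture, 3-D structure, and photophysics beyond the
exponential-plus-linear CP model. Passing tests therefore demonstrate that
the statistics and the gate logic are implemented correctly and recover
known ground truth under realistic noise — not that the pipeline is robust
to every artifact of real microscopy data.

## Problem sizes

Default validation runs use 10 cells per phase (50 images) for gating and
correlation trends, 20 cells per preset for the periphery-ratio direction
checks, and 65 traces per CP preset — enough for stable means at the
generator's noise levels while keeping the full suite fast.

## Known limitations

* Gate defaults are data-driven; on pathological populations (e.g. nearly
  all mitotic) the Otsu split is ill-posed and should be overridden with an
  explicit threshold.
* The anaphase/telophase distinction rests entirely on the mitotic lamin
  gate; cells mid anaphase–telophase transition are genuinely ambiguous.
* The periphery/interior ratio depends on the nuclear segmentation at the
  ±2 px level; with a strongly blurred rim the measured ratio is biased
  toward 1.
* The CP model assumes two non-exchanging pools on the measurement
  timescale; slow exchange shows up as an ill-conditioned fit, not as a
  third parameter.
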