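# Methods

## Scope and model

`synquant` quantifies synaptic connectivity and subcellular protein
localization from multichannel 2D confocal images. The measurement model
is mask-based: every channel is reduced to binary or labeled masks, and
every biological claim — "this bouton contacts this soma", "this
pre/post pair is a synapse", "this synapse comes from a labeled axon" —
is an inequality on a pixel-counted overlap area expressed in μm²:

- a presynaptic bouton (or postsynaptic cluster) is apposed to /
  contained in a soma or AIS when ≥ 0.04 μm² of the punctum mask lies on
  the structure mask;
- a presynaptic bouton and a postsynaptic cluster form a synapse when
  their masks share ≥ 0.03 μm²;
- a synapse is attributed to a labeled axonal process when the
  presynaptic punctum shares ≥ 0.025 μm² with the process mask.

All criteria are inclusive (≥) and are compared against exact
`pixel_count × pixel_size_um²`; thresholds are never rounded to whole
pixels. Because the physical pixel size is a required input and never
defaulted, the same grid analyzed at a different calibration scales all
areas by the square of the pixel size — absolute-area criteria are only
meaningful once μm/px is supplied.

Counts become densities by normalizing with the structure's extent: soma
perimeter (μm) or AIS length (μm), reported per μm with a per-10-μm
convenience scale. Which normalizer the density uses is written into
every output header, since "density" alone is ambiguous.

## Segmentation

Masks follow the ImageJ particle-analysis lineage: intensity thresholds
with ≥ semantics, 8-connected labeling, and particle filters.

- **IsoData threshold** — implemented as the continuous fixed point of
  `T ← (mean of pixels ≤ T + mean of pixels > T)/2`, iterated from the
  global mean. On any two-level image the class means are the levels, so
  the fixed point is their midpoint. Histogram-bin-quantized variants
  differ from this by up to one gray level; the suite cross-checks
  against one.
- **Somata** — connected components above a configurable threshold with
  a minimum-area gate (default 50 μm²). The gate, not the threshold, is
  what separates cell bodies from neuropil texture. Perimeter uses the
  weighted boundary-length estimator of `skimage.regionprops` (low bias
  on smooth shapes; ~3–5% on disks of radius ≥ 2 μm at 0.1 μm/px).
- **Neuropil** — high-threshold foreground minus all soma pixels.
- **AIS** — per-component skeletonization; length is the longest
  geodesic path through the 8-connected skeleton graph (edge weights 1
  and √2 px), found by the two-sweep farthest-point method, exact when
  the skeleton is a tree. Flat-capped elongated structures acquire short
  end spurs that bias length upward by roughly the structure half-width
  per end (≲ 5–10% for a 0.4-μm-wide, ≥ 8-μm AIS).
- **Puncta** — binarize at a per-experiment threshold, split touching
  blobs by watershed on the Euclidean distance transform with h-maxima
  markers (h = 1 px, configurable) so pixelation plateaus do not
  oversplit, then keep particles with area ≥ the marker-class minimum
  (0.06 μm² for GAD67/GAD65/CB1R boutons; 0.05 μm² for Syt2/VGlut1
  boutons and Gephyrin/PSD95 clusters) and circularity
  `4π·area/perimeter²` in the configured range (default [0, 1]).
  Circularity is clamped at 1: discrete perimeter estimators exceed the
  isoperimetric bound on few-pixel particles, and without the clamp the
  default range would discard exactly the diffraction-limited puncta the
  analysis targets. Border-touching puncta are kept by default
  (`exclude_border` flag available).

## Preprocessing

Conditioning applies, in order: background subtraction, Gaussian blur
(σ = 1 px), 3×3 mean smoothing, and a saturated percentile rescale to
the full bit range (0.3% of pixels saturated per tail). Background is
estimated by grayscale opening with a flat disk (default radius 50 px) —
the flat approximation of the rolling ball. The flat disk was chosen over
the curved ball deliberately: it commutes with intensity scaling, which
makes the whole pre-rescale chain linear in input intensity (a property
the suite tests), and removes constant plateaus exactly. Saturated
rescale was chosen over histogram equalization for the contrast step;
equalization remains available as `equalize_channel`.

Histogram matching (for transferring one experiment-wide threshold
across samples) is the exact inverted-CDF quantile transform: a pixel at
empirical CDF position q maps to the reference's q-quantile, so outputs
take only reference intensity values, the map is monotone, idempotent,
and the identity when an image is matched to itself. Matching operates
on whole frames, not per ROI, since normalization is a whole-image,
per-experiment operation.

## Localization scoring

Somatic expression of a tagged protein is the percentage of
reporter-masked somata whose overlap with the tag mask reaches a minimum
(default: one pixel's area; raise it to resist speckle). Neuropil
expression is the percentage of the neuropil mask covered by the tag
mask; the denominator is the neuropil mask by default, with a flag to
use the tag mask instead (both readings of "percent colocalization" are
defensible). ROI-based puncta densities count centroids inside half-open
rectangles — centroid membership partitions tiled ROIs without double
counting. A puncta set can be split into clusters apposed / not apposed
to the union of PV+ soma masks using the same ≥ 0.04 μm² contact
criterion; the two parts always partition the set.

## Hierarchical statistics

The unit of analysis for group comparisons is the animal: cell-level
values are averaged per animal, and only per-animal means enter tests.
Test selection is normality-gated at α = 0.05 (Shapiro–Wilk per group;
groups with fewer than 3 animals, or zero within-group variance, fail
the gate conservatively):

- 2 groups, all normal → two-tailed two-sample Student's t (equal
  variance; Welch behind a flag), else Mann–Whitney U;
- > 2 groups, all normal → one-way ANOVA with Tukey's range post hoc,
  else Kruskal–Wallis.

If every value in every group is identical the variance is degenerate;
the report then carries statistic 0, p = 1 and a `degenerate` flag
rather than NaNs. Cumulative-frequency (ECDF) summaries use cell-level
values — the per-animal bars and the per-cell ECDFs answer different
questions. Mean ± s.e.m. summaries use the sample standard deviation
(ddof = 1) over animals; s.e.m. is reported missing for n < 2. Two-way
ANOVA is accepted in configuration as a pass-through of the same
omnibus/post-hoc contract but is not exercised by any shipped analysis.

## Synthetic scenes

The generator emulates the measurement situations, not the optics: bright
soma disks (radius 2.8–4.5 μm) over a low-pass-filtered noise texture
standing in for neuropil; flat-capped AIS bars (8–15 μm × 0.4 μm);
circular puncta of radius 0.17–0.25 μm planted tangent to structure
borders with a controlled inside-fraction (default 0.6). After placing a
punctum the planted overlap is re-measured on the raster and the disk is
nudged inward in half-pixel steps until it clears the 0.04 μm² contact
criterion — rasterization at 2-px radii can undercut the continuous lens
geometry by a pixel or two, and the truth tables must satisfy the
criteria they claim. A near-miss mode instead offsets boutons 1–2 px off
the structure so every planted overlap fails the criterion. Post
partners are offset so the rasterized pre/post overlap meets a requested
fraction of the pre area. Channels are blurred with a Gaussian PSF
(σ = 0.08 μm), then corrupted by Poisson shot noise (2 photons per
intensity unit) plus Gaussian read noise (σ = 8 on the 8-bit scale),
giving peak-signal-to-noise ≈ 8 for a default punctum. Ground truth
(masks, perimeters, lengths, per-structure bouton counts, pair lists,
tag occupancy) is recorded before noise.

Randomness uses the counter-based Philox generator with per-entity
substreams keyed by `SeedSequence((seed, role, index))`, so scenes are
reproducible across platforms and adding one soma does not displace
another soma's boutons.

What the generator does **not** emulate: confocal PSF anisotropy and
axial structure, bleaching, autofluorescence gradients, densely packed
or overlapping somata, bouton clustering along real axon geometry, and
intensity heterogeneity within structures. Passing recovery tests
therefore demonstrates the correctness of the measurement chain on
scenes whose difficulty is controlled — not segmentation performance on
tissue.

## Cohort simulations

Cohorts lay out groups → animals → cells. Each animal carries a
multiplicative log-normal rate effect (sd 0.10) so animals, not cells,
are the unit of independent variation; each cell's bouton count is
Poisson with mean = base rate × group multiplier × animal effect,
capped at the soma perimeter's geometric placement capacity (the
truncated tail is ≪ 1% at default rates). Measurement runs the real
pipeline per cell: detect puncta at the generating threshold, call
contacts at ≥ 0.04 μm², divide by the measured soma perimeter.

Calibration and power studies use 5 animals × 15 cells per group on
112-px single-soma frames (soma radius 2.8–3.6 μm, 8–14 boutons per
soma) — small enough that a 100-replicate study runs in minutes while
preserving the full measurement chain. Under equal group means the
comparison rejects at α = 0.05 at close to the nominal rate; a 40%
bouton-rate reduction is detected in well over 80% of replicates.

## Numerical choices and degenerate inputs

- Contact assignment is exclusive: a punctum joins at most one
  structure (largest overlap, then lowest structure label).
- Synapse pairing is greedy one-to-one by descending overlap (ties:
  lower pre label, then lower post label); no punctum is counted twice.
- Process attribution uses the presynaptic punctum's overlap by
  default; `union` and `either` modes are available because "their
  area" admits more than one reading.
- Constant images are rejected by IsoData and by histogram matching
  (the mappings are undefined); empty soma lists and empty masks raise
  rather than return 0-division artifacts.
- 12-bit data travels in 16-bit containers; the reader infers 12-bit
  when the data range allows and the caller does not say otherwise.

## Known limitations

2D only — no z-stacks, no 3D apposition. No machine-learned
segmentation; thresholds are per-experiment constants supplied by the
user, as in the macro lineage this follows. The AIS length estimator
carries the end-spur bias noted above. Mixed pixel sizes within one
experiment are refused rather than resampled. No multiple-testing
correction beyond Tukey's post hoc.
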