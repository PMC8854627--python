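# Methods

## The measurement problem

Cortical actin forms a membrane-proximal mesh whose pores ("corrals")
confine membrane proteins. Two practical obstacles shape the design of this
package: (i) in SRRF/SIM images the filaments are resolvable but their
skeletons are noisy, so we measure the *gaps* the mesh encloses rather than
tracing filaments; (ii) in expansion-microscopy images the labelling is too
discontinuous to close pores at all, so density is read out statistically
from intensity fluctuations along random lines. Both workflows are
validated against a simulator whose ground truth is known exactly.

## Meshwork simulator (`netsim`)

**Network model.** `n_seed` filaments are chords with independent uniform
endpoints in a `W × H` µm field. Each seed carries `daughters_per_seed`
daughters: branch point uniform along the seed, direction rotated ±70° from
the seed's (sign equiprobable — Arp2/3 branches on either side; the
magnitude is the canonical Arp2/3 angle), length uniform in 25–100 % of the
seed's, truncated at the field boundary. The branch-point law and daughter
length are free choices (kept so daughter filaments are visibly subordinate
to seeds); the truncation keeps every endpoint inside the field so the
branch angle stays exact in the vector representation.

**Rendering.** Segments are drawn as 1-px digital lines on a raster of
`raster_pixel_nm` (default 1 nm) and dilated with a disk of diameter
`filament_width_px` (default 7, i.e. ≈ 7 nm — the diameter of an actin
filament). For speed the dilation is applied as per-line-point disk
offsets, which is provably (and unit-tested as) identical to morphological
dilation of the union. The raster is block-mean binned by `bin_factor`
(default 65 → 65 nm camera-scale pixels; intensity is conserved up to
zero-padding when the raster is not divisible).

**Microscope emulation.** In order: Gaussian PSF blur with
σ = 0.21·λ/NA ≈ 68.8 nm (λ = 488 nm, NA = 1.49 — the standard Gaussian
approximation of the Airy disk); Poisson resampling at `poisson_scale`
photons per intensity unit (default 50, a deliberately low-photon TIRF
regime); additive Gaussian read noise (default SD = 2 % of the image
maximum), clipped at zero; Gaussian smoothing of 1 binned px. Any stage
with a zero parameter is skipped; `SimulationParams.without_noise()`
retains only the PSF, the rendering mode appropriate for emulating
reconstructed (denoised) super-resolution data, and is what the
density-graded series uses.

**Ground truth.** The mask is the binned raster thresholded at zero (any
filament coverage marks a camera pixel), so mask and emulated image share
one grid and one segmentation can be applied to both. The vector network
is also kept, enabling exact chord-crossing counts.

**Determinism.** One `numpy` Generator seeded by `rng_seed` drives every
stochastic stage; identical parameters give bit-identical outputs. In the
density series all conditions share a seed and filaments are drawn in
interleaved (seed, daughter) order, so an *n*-seed network nests inside the
(*n*+k)-seed one — the series is genuinely graded in density rather than
five unrelated draws.

## Corral segmentation (`corralseg`)

Threshold (Otsu × `otsu_scale`, or manual) → binary filament mask → optional
binary erosion (default one iteration, 3 × 3 cross — the FIJI convention) →
watershed of the Euclidean distance transform of the pore space → region
statistics in physical units.

Numerical choices that matter:

* **Watershed seeding.** Seeds are the *connected local-maximum plateaus*
  of the EDT, merged when closer than ~3 px. Point-wise peak picking
  (e.g. `peak_local_max`) splits rectangular pores along their EDT ridge
  plateau; plateau seeding keeps a rectangle one region, which is what
  makes the grid-fixture oracle exact. Watershed separation lines are kept
  (label 0), so filament mask + corrals + lines exactly tile the ROI.
* **Erosion border handling.** Outside the ROI counts as filament
  (`border_value=1`); the conventional zero border etches a one-pixel pore
  ring around the frame that fuses every border corral into one region.
* **Sub-resolution filter.** Default minimum pore area `(2r)²/4` with
  `r = 150 nm` (≈ the SRRF-scale resolution; the PSF FWHM of the simulator
  is 162 nm). Pores smaller than the resolution cannot be trusted in any
  resolution-limited image.
* **Border pores** are measured but flagged, and excluded from ROI
  summaries by default: a pore cut by the crop has no defined area.
* **Erosion scale.** One 3 × 3 erosion removes one pixel of filament
  radius. On SRRF reconstructions (pixels typically 10–30 nm) this is a
  gentle halo correction; on the simulator's 65 nm camera pixels it removes
  65 nm — measured at ~4× the half-width bias that Otsu segmentation of
  the blurred filaments actually introduces, and enough to delete 1–2 px
  wide ground-truth filaments outright. The validation studies therefore
  segment both arms with `erosion_iterations=0`; the default of 1 stands
  for real reconstructions. This is the package's own scale-matching
  choice, applied uniformly to both arms of every study.

**Condition contrasts** are plain two-sample Student's *t*-tests on per-ROI
summaries (count, mean area, mean perimeter), with the pooled-variance SEM
of the difference reported alongside.

**Matching** detected to reference corrals is greedy by descending
intersection-over-union with pairs below `min_overlap` rejected. At
`min_overlap ≥ 0.5` greedy is provably optimal (two regions cannot both
exceed IoU 0.5 with the same partner), which the tests confirm against
exhaustive assignment.

## Line-density analysis (`linedensity`)

Chords run boundary-to-boundary (each endpoint: uniform side, uniform
position; redrawn when shorter than a quarter of the short ROI side, the
default minimum) so every profile spans the full ROI. Intensities are
sampled by bilinear interpolation at 1-px steps and min–max normalised per
line; a constant (blank) profile normalises to flat zero and contributes
zero peaks.

Peak semantics: *every* strict local maximum above `baseline_threshold`
(default 0.1, always recorded in outputs) is a peak — no prominence cutoff,
so shoulder peaks separated by shallow saddles are kept, which is the point
of the method for closely packed filaments. Plateaus count once, at their
midpoint. Prominence is the drop to the higher flanking saddle; width is
taken at half prominence with the saddle bounding merged peaks. Positions
are not sub-pixel refined (parity with simple maxima picking). The
implementation rides on `scipy.signal.find_peaks`/`peak_prominences`/
`peak_widths`, whose definitions coincide with these rules; the test suite
checks equivalence against an independent exhaustive scan on 1,000 random
profiles.

Distances are reported at the sample's physical scale; correction by a gel
expansion factor is opt-in (`compare_density(..., expansion_factor=4.1)`)
because expanded-sample lengths are conventionally reported uncorrected.

## Time-lapse tracking (`timecourse`)

Frames are segmented independently with shared parameters (no temporal
regularisation), then one corral chosen by a frame-0 point is linked
greedily: in each next frame the label with the largest pixel overlap with
the current region is taken, provided it covers ≥ `min_overlap` (default
0.3) of it; otherwise the track ends (no gap closing — the intended use is
short ~10-frame SRRF movies). When a pore splits, the larger-overlap child
is followed; ties break toward the larger intersection, then the smaller
label.

## Validation studies (`validation`) and problem sizes

* **Recovery** (30 meshworks, default conditions): identical segmentation
  on ground-truth masks and emulated images. Result (seed 0): truth
  0.453 ± 0.073 µm², processed 0.448 ± 0.077 µm² — processed at or below
  truth, within one SD, because PSF blur thickens filaments and obscures
  the smallest pores. Absolute values scale with the field geometry and
  filament count, which are simulation choices.
* **Density response** (5/10/15/20/25 seeds × 5 rng seeds, 100 chords per
  image): mean peak count strictly rises (≈ 2.5 → 8.9 per line) and mean
  inter-peak distance strictly falls (≈ 1.8 → 0.8 µm) with density.
* **Undercounting** (1,000 chords): ≈ 8 detected peaks per chord against
  ≈ 10–12 true filament crossings — the metric is relative, never an
  absolute count.
* **Disruption** (10 ROIs per condition): 10-seed "disrupted" meshes show
  a significantly larger mean pore area and smaller pore count than
  25-seed "controls" (both p ≪ 0.05), the direction expected of an
  actin-disrupting drug.
* **Monotonicity** (20 images): total pore area is non-decreasing in both
  threshold and erosion, 0 violations. Note the *mean* pore area is not
  monotone in erosion in general — merging and the size filter change the
  pore count — so the laws are stated on total area, which the
  shrinking-mask argument actually guarantees.

These sizes keep the full suite and the acceptance script to a few minutes
on one CPU while leaving the statistical conclusions stable across seeds.

## What the simulator does and does not capture

It captures the branched, quasi-random geometry of cortical mesh, the
camera pixel scale, PSF width, shot/read noise and smoothing — enough to
exercise every stage of both workflows against exact truth. It does not
model 3-D structure, filament curvature or bundling, temporal dynamics
(treadmilling, severing), sCMOS fixed-pattern noise, SRRF's
radial-fluctuation processing, or labelling discontinuity. Passing
validation therefore demonstrates correctness of the measurement pipeline
on meshes of known geometry, not robustness to every real-data artefact;
on real images the threshold scale, erosion count and minimum pore size
remain the user's scientific controls.

## Known limitations

* Watershed over-segments rough pores and merges pores connected through
  labelling gaps; the matching report (`match_corrals`) quantifies both on
  simulated data.
* Otsu assumes a bimodal intensity histogram; very sparse or very dense
  fields may need `otsu_scale` or a manual threshold.
* Peak counting saturates when filament spacing approaches the PSF width —
  the undercounting study measures exactly this.
* Tracking has no gap closing and follows a single corral.
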