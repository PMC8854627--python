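# cortexmesh

Quantification of super-resolved cortical actin meshworks.

The actin cortex immediately beneath the plasma membrane forms a dense mesh
whose pores — "corrals" in the picket-fence model of membrane organisation —
transiently confine membrane proteins. `cortexmesh` quantifies this mesh in
super-resolved fluorescence images (SRRF, SIM, expansion microscopy) with two
complementary workflows, plus the synthetic ground truth needed to validate
them. It is aimed at cell biologists and imaging scientists who want
reproducible, batch-friendly mesh statistics without hand-tracing filaments.

## What it computes

**Corral analysis** (`cortexmesh.corralseg`, `cortexmesh.timecourse`) — for
images where the mesh is continuous enough to enclose pores. The image is
thresholded (Otsu by default, `t = s · t_Otsu` with scale `s`), the filament
mask optionally eroded, and the complementary pore space partitioned by a
watershed of its Euclidean distance transform `D`, seeded at the connected
local-maximum plateaus of `D` (maxima closer than ~3 px merge into one
seed). Each region is reported as area `A = n_px · Δx²` (µm²), perimeter,
and centroid; pores below the resolution limit (default
`A_min = (2·r)²/4` with `r = 150 nm`) are discarded, and border-touching
pores are flagged. ROI summaries feed a two-sample Student's *t* contrast
for condition comparisons (e.g. cytochalasin D vs control), and the same
segmentation applied frame by frame tracks a chosen corral's area over time
by spatial-overlap linking.

**Filament-density analysis** (`cortexmesh.linedensity`) — for images (e.g.
expanded samples) whose labelling is too discontinuous for pore
segmentation. Random boundary-to-boundary chords are profiled by bilinear
interpolation, min–max normalised, and every strict local maximum above a
background threshold (default 0.1) is counted as a filament crossing —
deliberately with **no prominence cutoff**, so adjacent but distinct
filaments stay separate. Peak prominence is measured to the higher flanking
saddle and width at half prominence by linear interpolation. Pooled over
~100 chords, the mean peak count and mean inter-peak distance form a
relative density metric (it systematically *under*-counts true crossings
and is not an absolute filament number).

**Simulator** (`cortexmesh.netsim`) — branched meshworks as geometric truth:
seed filaments with uniform random endpoints, one daughter each branching at
±70° (Arp2/3-like), rasterised 7 px wide on a 1 nm grid, block-binned to the
65 nm camera pixel, Gaussian-PSF blurred (σ = 0.21·λ/NA ≈ 69 nm for 488
nm/1.49 NA), then Poisson shot noise, Gaussian read noise and smoothing.
Every simulated image comes paired with its ground-truth mask and vector
network, so the analyses above can be validated end to end
(`cortexmesh.validation`).

## Worked example

```python
from cortexmesh import (CorralParams, SimulationParams, match_corrals,
                        segment_corrals, simulate_pair, summarize_roi)

pair = simulate_pair(SimulationParams(rng_seed=42))        # 25 seeds + daughters
detected = segment_corrals(pair.emulated_image, pair.pixel_size_um,
                           CorralParams(erosion_iterations=0))
print(summarize_roi(detected))
```

Running `python examples/corral_segmentation.py` prints:

```
corrals detected : 84
mean area        : 0.431 +- 0.542 um^2
mean perimeter   : 2.31 um
matched to truth : 60 pores at IoU >= 0.5
area bias        : -0.0323 um^2 (detected minus true, matched pores)
```

84 pores are detected in the emulated 10 × 10 µm image; 60 of them match a
ground-truth pore at IoU ≥ 0.5, and matched pores are on average 0.03 µm²
smaller than truth — the expected signature of PSF blur thickening the
apparent filaments. The other examples cover density profiling
(`density_profiling.py`: a 25-seed mesh yields 8.8 peaks/line at 0.77 µm
spacing vs 2.4 peaks at 1.50 µm for a 5-seed mesh), live tracking
(`live_tracking.py`: a tracked pore doubles from 2.56 to 5.60 µm² when its
dividing wall is lost) and the validation studies at reduced size.

## Command line

```bash
cortexmesh simulate --seed-count 25 --reps 5 --seed 1 --out-dir sim/
cortexmesh corrals image.tif --pixel-size-um 0.065 --out-dir corrals/
cortexmesh density image.tif --pixel-size-um 0.032 --repeats 100 --seed 1
cortexmesh live stack.tif --seed-x 120 --seed-y 80 --pixel-size-um 0.065
cortexmesh fixtures grid_mesh --param k=3
```

Each run writes CSV/TIFF/PNG outputs plus a `provenance.json` recording the
exact parameters and seed.

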