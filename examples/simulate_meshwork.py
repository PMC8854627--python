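"""Simulate one branched actin meshwork and render the image pair.

Generates 25 seed filaments (one 70-degree daughter each) in a 10 x 10 um
field, rasterises them as 7 nm wide lines, bins to the 65 nm camera pixel
and applies PSF blur, Poisson/Gaussian noise and smoothing.
"""

import numpy as np

from cortexmesh import SimulationParams, simulate_pair

params = SimulationParams(rng_seed=42)
pair = simulate_pair(params)

print(f"segments simulated      : {len(pair.network)} "
      f"({len(pair.network.seeds)} seeds + {len(pair.network.daughters)} daughters)")
print(f"camera-pixel grid       : {pair.emulated_image.shape}, "
      f"{pair.pixel_size_um * 1000:.0f} nm/px")
print(f"filament coverage       : {pair.ground_truth_mask.mean():.1%} of the field")
print(f"emulated intensity range: {pair.emulated_image.min():.1f} .. "
      f"{pair.emulated_image.max():.1f} photons")

# The mask is the noise-free truth; the emulated image is what the
# microscope would record of the same network.
assert pair.ground_truth_mask.shape == pair.emulated_image.shape
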