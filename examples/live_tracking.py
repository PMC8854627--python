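"""Track one corral's area through a time-lapse stack.

Uses the decaying-mesh fixture (one wall segment lost per frame, emulating
progressive filament disruption); with real data, read a multi-frame TIFF
and segment with the default parameters.
"""

import numpy as np

from cortexmesh import CorralParams, analyze_stack, make_fixture, stack_summary, track_corral

stack, ann = make_fixture("decay_stack", frames=6)
params = CorralParams(threshold_method="manual", manual_threshold=0.5,
                      erosion_iterations=0, min_corral_area_um2=0.0)

per_frame = analyze_stack(stack, pixel_size_um=0.1, params=params)
print(stack_summary(per_frame)[["frame", "n_corrals", "mean_area_um2"]]
      .to_string(index=False))

seed = (ann["line_width"] + ann["cell_px"] // 2,) * 2  # inside the first pore
track = track_corral(per_frame, seed, min_overlap=0.3)
areas = track.area_series_um2()
print("\ntracked corral area (um^2):", np.round(areas, 2).tolist())
# The tracked pore doubles in area the moment its dividing wall is lost;
# the per-frame mean area climbs as the mesh decays.
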