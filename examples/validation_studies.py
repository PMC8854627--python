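"""Run the built-in validation studies at reduced size.

Full-size versions of these studies back the test suite and
scripts/acceptance.py; this script runs lighter variants for a quick look.
"""

from cortexmesh.validation import (
    density_monotonicity_study,
    disruption_study,
    recovery_study,
    underestimation_study,
)

rec = recovery_study(n_networks=10, seed=0)
print("ground-truth recovery (10 meshworks)")
print(f"  truth     : {rec['gt_mean_area_um2']:.3f} +- {rec['gt_sd_area_um2']:.3f} um^2")
print(f"  processed : {rec['processed_mean_area_um2']:.3f} +- "
      f"{rec['processed_sd_area_um2']:.3f} um^2")

dens = density_monotonicity_study(n_seeds=2, n_repeats=50, seed=0)
print("\ndensity response (5 -> 25 seed filaments)")
print("  mean peaks/line :", [round(float(x), 2) for x in dens["mean_peak_counts"]])
print("  mean spacing um :", [round(float(x), 2) for x in dens["mean_inter_peak_distances_um"]])

under = underestimation_study(n_chords=300, seed=1)
print("\nundercounting check (300 chords)")
print(f"  detected peaks/chord : {under['mean_detected_peaks']:.2f}")
print(f"  true crossings/chord : {under['mean_true_crossings']:.2f}")

dis = disruption_study(n_rois=5, seed=0)
print("\ndisruption contrast (25-seed control vs 10-seed disrupted, 5 ROIs)")
print(f"  mean corral area change : {dis['area_increase_um2']:+.3f} um^2 "
      f"(p = {dis['area_p']:.2e})")
print(f"  corral count change     : {dis['count_change']:+.1f} "
      f"(p = {dis['count_p']:.2e})")
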