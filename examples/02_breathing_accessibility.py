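"""Full two-track analysis of a breathing ensemble.

Generates a 25-frame ensemble whose aperture is open in exactly 64% of
the frames, runs the complete pipeline (per-frame pocket detection,
occupancy grid, min-rule reconciliation, channels, statistics) and
prints the five descriptors plus channel opening frequencies.
"""

from pocketens import analyze_replicates
from pocketens.synthetic import BreathingSchedule, CageSpec, make_breathing_ensemble

spec = CageSpec(cavity_radius=6.0, aperture_half_angle=40.0, seed=3)
schedule = BreathingSchedule(n_frames=25, open_fraction=0.64, seed=3)
ensemble, truth = make_breathing_ensemble(spec, schedule)

result = analyze_replicates([ensemble], enzyme="breathing-cage")
s = result.summary

print(f"frames analyzed:       {len(result.frames)}")
print(f"median volume:         {s.volume_mean_of_medians:7.1f} Å³ "
      f"(analytic cavity 904.8 Å³)")
print(f"volume range:          {s.range_mean:7.1f} Å³")
print(f"shape factor:          {s.shape_mean_of_medians:7.2f}")
print(f"hydrophobicity:        {s.hydrophobicity_mean_of_medians:7.2f}")
print(f"accessibility:         {result.accessibility_pct:7.1f} %  (scheduled 64%)")
for c in result.channels:
    print(f"channel {c.channel_id}: open at the {100 * c.opening_frequency:.0f}% isovalue"
          + ("  [solvent channel]" if c.is_solvent_channel else ""))
print("category symbols:      " + " ".join(result.categories))
# Accessibility counts frames whose pocket space connects to the frame's
# own solvent exterior — it recovers the scheduled open fraction exactly,
# while the per-channel frequency is quantized to the isovalue ladder.
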