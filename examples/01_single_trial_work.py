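"""Simulate one protocol trial and compute its mechanical work.

Generates a 30-s, 200-Hz trial (serve + 8 groundstrokes + sprint) for one
male player, runs the processing pipeline (6 Hz zero-lag filtering, event
detection, work bookkeeping) and prints the section works next to the
generator's ground truth.
"""
import numpy as np

from mechwork import (
    PipelineConfig,
    default_segment_lengths,
    load_segment_table,
    scale_segment_parameters,
)
from mechwork.pipeline import process_trial
from mechwork.simulate import PlayerParams, default_camera_rig, simulate_trial

scaled = scale_segment_parameters(77.2, default_segment_lengths(1.82), load_segment_table("male"))
player = PlayerParams(
    player_id="P01", sex="male", body_mass=77.2, height=1.82,
    baseline_velocity=6.0, slope=5e-4, cycle_work_estimate=240.0,
    scaled_segments=scaled,
)
rig = default_camera_rig()
trial, truth = simulate_trial(player, cycle_index=1, seed=42, cameras=rig)
result = process_trial(trial, scaled, PipelineConfig(), rig)

print(f"events (samples @200 Hz)  detected {result.boundaries}  truth "
      f"({truth.serve_start}, {truth.transition}, {truth.sprint_end})")
print(f"peak sprint velocity      {result.peak_velocity:6.3f} m/s   (truth {truth.peak_velocity:.3f})")
print()
print("per-cycle positive work (3 x groundstroke set + sprint), J/kg:")
for label, attr in (("external (CoM)", "w_ext_pos"), ("internal (limbs)", "w_int_pos"),
                    ("total", "w_tot_pos"), ("pelvis proxy", "w_pelvis_pos"),
                    ("bounding-box proxy", "w_bb_pos")):
    meas = getattr(result.cycle, attr)
    true = getattr(truth.cycle_work, attr)
    true_str = f"{true:7.1f}" if true is not None else "   n/a"
    print(f"  {label:<20} {meas:7.1f}   (truth {true_str})")
share = result.cycle.w_int_pos / result.cycle.w_tot_pos
print(f"\ninternal work share: {share:.2f} of total (about one third in this protocol);")
print("both proxies exceed the true external work - the proxies' extra")
print("high-frequency motion systematically inflates the summed energy increments.")
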