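"""Derive horizontal and true swim speeds from simulated telemetry.

Generates a week of correlated-random-walk fixes for three juvenile
white sharks, applies the HPE <= 5 m quality filter, the 300 s
interval filter and the 0.1 m/s speed floor, and summarises median
cruise speeds per animal and per diel period.
"""

from sharkspeed import kinematics, reference, synthetic, telemetry
from sharkspeed.telemetry import POSITION_COLUMNS

cfg = synthetic.TrackSimConfig(n_sharks=3, duration_days=7.0, seed=42)
sharks = synthetic.default_sharks(3, with_depth_every=2)
positions = synthetic.simulate_tracks(cfg, sharks)
print(f"simulated {len(positions)} fixes for {cfg.n_sharks} sharks")

filtered = telemetry.filter_hpe(positions[POSITION_COLUMNS], max_hpe=5.0)
print(f"HPE filter kept {len(filtered)} of {len(positions)} fixes "
      f"({telemetry.count_speed_slots(filtered)} candidate pairs)")

speeds = kinematics.compute_speeds(filtered, sharks)
speeds = kinematics.compute_ss_t(speeds)
speeds = kinematics.add_diel(speeds, *reference.ARRAY_CENTER)
print(f"{len(speeds)} speed estimates after interval and floor filters "
      f"({speeds.attrs['n_gap_removed']} gap-removed, "
      f"{speeds.attrs['n_floor_removed']} below 0.1 m/s)")

per_shark = kinematics.summarize_speeds(speeds, ["shark_id"])
print("\nper-shark median SS_H (m/s):")
print(per_shark.to_string(index=False))

diel = kinematics.summarize_speeds(speeds, ["diel"])
print("\nday vs night median SS_H (m/s):")
print(diel.to_string(index=False))
# Medians near the configured 0.6 m/s; the day median sits a few percent
# above the night median by construction (diel activity contrast).
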