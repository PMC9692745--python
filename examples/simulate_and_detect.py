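"""Simulate a single-pore recording and idealise it back into events.

A closed <-> open pore (0.41 nm, ~110 pS) gates on top of a 5 pS
membrane baseline; the latent path is rendered through the 1 kHz / 20 ms
recording chain with 2 pS noise, then the segmentation chain re-detects
the levels and scores the kinetics blind.
"""

import blmpore as bp

model = bp.build_two_state_model(
    r_open_nm=bp.pore_radius(110.0),  # 0.41 nm
    barrier_open_kT=16.0,             # open-state lifetime ~ seconds
    opening_rate_per_s=3.0 / 60,      # rare openings: 3 per minute here
    baseline_conductance_pS=5.0,
)
print(f"model: open dwell {model.mean_dwell_s('open'):.1f} s, "
      f"opening rate {model.escape_rates('closed')['open'] * 60:.1f} /min")

events = bp.simulate_events(model, duration_s=180.0, seed=7)
chain = bp.RecordingChain(noise_sd_pS=2.0)  # 1 kHz, tau = 20 ms, 16-bit ADC
trace = bp.render_trace(events, model, chain, seed=8)
print(f"rendered {trace.n_samples} samples ({trace.duration_s:.0f} s)")

segments, levels, _ = bp.segment_trace(trace)
print(f"\ndetected {len(segments)} events across {len(levels)} levels:")
for lv in levels.levels:
    print(f"  level {lv.level_id}: {lv.mean_pS:7.1f} +- {lv.sd_pS:.1f} pS, "
          f"occupied {lv.occupancy_s:6.1f} s")

open_level = levels.levels[-1]
g_pore = open_level.mean_pS - levels.baseline.mean_pS
print(f"\npore conductance {g_pore:.0f} pS -> radius "
      f"{bp.pore_radius(g_pore):.2f} nm (true 0.41 nm)")
print(f"opening frequency {bp.opening_frequency(segments, trace.duration_s):.2f} /min")
print(f"closed fraction after first opening: "
      f"{bp.closed_fraction(segments):.1f} % of the observation window")
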