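"""Event-reordered rebinning: 100-ms response resolution from 2-s volumes.

Radial zero-TE acquisition produces one timestamped ~1-ms spoke per
readout. By jittering the onsets of 20 repeated stimulation events
against the acquisition, the spokes' peristimulus phases tile the
sub-volume interval, so pooling them into 0.1-s bins yields a response
time course 20x finer than the nominal 2-s volume rate.
"""

import numpy as np

from ztefmri import make_group1_schedule
from ztefmri.fmri import SpokeStream, apply_rebin, plan_event_rebin

schedule = make_group1_schedule(n_events=20, train_hz=7.0, train_s=1.0,
                                cycle_s=48.0, jitter_grid_s=0.1, seed=3,
                                baseline_s=4.0)
spokes = SpokeStream.regular(schedule.total_duration_s)  # spoke TR 0.97 ms
plan = plan_event_rebin(spokes, schedule.onsets, rel_start=-3.0, rel_end=11.0,
                        bin_s=0.1)
counts = plan.bin_counts()
print(f"{spokes.n} spokes over {schedule.total_duration_s:.0f} s")
print(f"window [-3, 11) s at 0.1-s bins -> {plan.n_bins} peristimulus bins")
print(f"spokes pooled per bin: mean {counts.mean():.0f} "
      f"(min {counts.min()}, max {counts.max()})")
print(f"assigned {plan.n_assigned}, discarded {plan.n_discarded} "
      "(outside every event window)")

# plant a smooth known response on the spokes and recover it in the bins
response = lambda t_rel: np.exp(-0.5 * ((t_rel - 3.0) / 1.2) ** 2)
rel = np.full(spokes.n, 99.0)
for onset in schedule.onsets:
    sel = np.abs(spokes.spoke_times_s - onset - 4.0) < 7.0
    rel[sel] = spokes.spoke_times_s[sel] - onset
rng = np.random.default_rng(0)
values = response(rel) + rng.normal(0, 0.5, spokes.n)  # very noisy spokes
rebinned = apply_rebin(plan, values)
err = np.sqrt(np.mean((rebinned.values - response(rebinned.times)) ** 2))
print(f"\nplanted-response RMS error after rebinning: {err:.4f}")
print("(single-spoke noise sd was 0.5; pooling ~2000 spokes per bin")
print(" suppresses it by ~sqrt(2000) while keeping 0.1-s resolution)")
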