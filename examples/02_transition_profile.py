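"""Align event statistics to stable rest-to-run transitions in 1-s bins.

Transitions qualify only with >= 3 s of rest before and >= 6 s of running
after the onset of locomotion.  Events are pooled across transitions by
onset time relative to the transition; each bin is tested against the -1 s
bin (Kruskal-Wallis, Bonferroni-corrected).  The frequency trace should step
up at t = 0 while amplitude stays flat.
"""

import astromap as am
from astromap.events import transition_profile

cfg = am.GeneratorConfig(grid_shape=(64, 64), pixel_size=94 / 64, seed=2)
rng = cfg.rng()
mask = am.make_astrocyte_mask(cfg, rng)
field = am.make_hotspot_field(mask, cfg, rng)
trace = am.make_behavior_trace(
    3000.0, bout_params=am.BoutPlan(mean_rest_s=8, mean_run_s=10), config=cfg, rng=rng
)
labels = am.segment_run_rest(trace)
events = am.sample_events(field, labels, cfg, rng)

transitions = [t for t in am.extract_transitions(labels) if t.kind == "rest_to_run"]
print(f"{len(transitions)} stable rest-to-run transitions, {len(events)} events\n")

prof = transition_profile(events, transitions, window=(-3, 6), bin_width=1.0)
print(f"{'bin (s)':>10} {'freq (ev/s)':>12} {'amplitude':>10} {'p_adj(freq)':>12}")
for _, row in prof.table.iterrows():
    mark = " <- reference" if row.is_reference else ""
    p = "" if row.is_reference else f"{row.p_adj_frequency:12.3g}"
    print(f"[{row.bin_left:+3.0f},{row.bin_right:+3.0f}) {row.frequency:12.2f} "
          f"{row.mean_dff_max:10.2f} {p:>12}{mark}")
print("\nBins after t=0 should be significantly above the -1 s reference bin;")
print("bins before it should not (frequency steps ~4x at locomotion onset).")
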