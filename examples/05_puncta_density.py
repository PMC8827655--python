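"""Count fluorescent puncta in 3D stacks and compare group densities.

Synthesizes confocal-style stacks (67.5/1024 um pixels, 0.7-um sections)
with known puncta, detects them with the fixed 8-bit conversion + 3D
Gaussian + threshold + per-section size gate, and compares the densities of
a high-density and a low-density group with unpaired t-tests, reporting the
percent difference of the means.
"""

import numpy as np

import astromap as am
from astromap.puncta import StackGeometry, detect_puncta

GEOM = StackGeometry(shape=(8, 256, 256))
SETTINGS = dict(threshold=0.33, size_range=(0.06, 0.5), intensity_range=(0.0, 200.0))

groups = {}
for offset, (name, counts_per_stack) in enumerate(
    (("background", (10, 14, 12, 11, 13)), ("cell_bodies", (20, 24, 28, 22, 26)))
):
    densities = []
    for seed, n_puncta in enumerate(counts_per_stack):
        stack, truth = am.make_puncta_stack(
            n_puncta, size_range=(0.15, 0.5), geometry=GEOM, noise_sd=30.0,
            amplitude=150.0, rng=100 * offset + seed,
        )
        res = detect_puncta(stack, **SETTINGS)
        densities.append(res.density_per_um3)
    groups[name] = np.array(densities)
    vol = res.sampling_volume_um3
    print(f"{name:12s}: counts -> density mean {np.mean(densities):.2e} puncta/um^3 "
          f"(sampling volume {vol:.0f} um^3)")

report = am.compare_density_groups(groups)
row = report.iloc[0]
print(f"\n{row.comparison} vs {row.reference}: {row.percent_change:+.0f}% "
      f"(t = {row.t_statistic:.1f}, p = {row.p_value:.2g})")
print("A doubled true count should appear as roughly +100% density at p << 0.05.")
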