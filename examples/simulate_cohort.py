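"""Generate a synthetic segment-level cohort and inspect its structure.

Shows the generator's bookkeeping: archetype sizes, pathological
filtering, and how closely the simulated group moments track the
configured ones.
"""

import numpy as np

from mariabands import generate_cohort, preset_configs

config = preset_configs("maria_clusters", seed=1)
cohort, truth = generate_cohort(config)

print(f"cohort: {len(cohort)} segments "
      f"({int((cohort.frame['pathological'] == 1).sum())} pathological), "
      f"provenance {cohort.provenance!r}")

for gi, arch in enumerate(config.archetypes):
    members = cohort.frame[truth == gi]
    wall_mean, wall_sd = arch.wall_thickness
    print(f"  {arch.name:<8} n = {len(members):2d}  "
          f"wall thickness {members['wall_thickness'].mean():.2f} mm "
          f"(configured {wall_mean:.2f} +/- {wall_sd:.2f})  "
          f"ADC {members['adc'].mean():.2f} "
          f"(configured {arch.adc[0]:.2f})")

n_normal = int(np.sum(truth == -1))
print(f"  normal   n = {n_normal:d}  (filler segments, never analysed)")
print("\nSample means track the configured archetype means; the same")
print("seed always reproduces this cohort exactly.")
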