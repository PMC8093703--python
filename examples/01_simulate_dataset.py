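"""Generate one pseudo-dataset at the baseline scenario and inspect it.

20 sites, 10 citizen-science replicates per site, total abundance 2000
spread over ~80% occupied sites, detection 0.8, 10 expected false
positives per site per survey, and Poisson-error expert counts everywhere.
"""

import numpy as np

from intabund import ScenarioConfig, generate_dataset

config = ScenarioConfig(seed=42)
dataset = generate_dataset(config)

occupied = dataset.truth.z.sum()
print(f"occupied sites: {occupied}/{config.n_sites}")
print(f"true total abundance: {dataset.truth.total}")
print(f"citizen-science counts, site means: "
      f"{np.round(dataset.y.mean(axis=1), 1)}")
print(f"expert counts: {dataset.w.astype(int)}")

# Empty sites still record ~m counts per survey - pure false positives.
empty = dataset.truth.z == 0
print(f"mean CS count at unoccupied sites: {dataset.y[empty].mean():.1f} "
      f"(the misidentification rate m = {config.misidentification:g})")
print(f"mean CS count at occupied sites:  {dataset.y[~empty].mean():.1f} "
      f"(~ N_i * p + m)")
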