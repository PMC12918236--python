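"""Test DaN/GabaN spatial segregation with the grid permutation test.

Three synthetic sections with fully segregated angular sectors: each
section's observed 50-um-grid correlation should fall below its shuffled
null, and the cohort-level paired signed-rank test combines them.
"""

import numpy as np

from omlo import spatial, synth

results = []
for seed in range(3):
    spec = synth.SectionSpec(seed=seed, segregation_angle=np.pi)
    cells, _, _ = synth.gen_section(spec)
    dan = cells.loc[cells["type_label"] == "DaN", ["x_um", "y_um"]].to_numpy()
    gaba = cells.loc[cells["type_label"] == "GabaN", ["x_um", "y_um"]].to_numpy()
    res = spatial.grid_colocalization(dan, gaba, bin_um=50, n_perm=2000, seed=seed)
    results.append(res)
    print(f"section {seed}: observed r = {res.observed_r:+.3f}  "
          f"null median = {res.null_median:+.3f}  one-sided p = {res.p:.4f}")

test, table = spatial.cohort_colocalization(results)
print(f"cohort paired signed-rank p = {test.p:.4f} over {len(table)} sections")
# Observed r far below the null in every section = the two neuron types
# occupy disjoint territory; with only 3 sections the exact paired test
# bottoms out at p = 2/8 = 0.25, which is why cohorts need ~10 sections.
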