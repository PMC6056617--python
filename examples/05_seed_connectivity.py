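"""Seed-based functional connectivity with Fisher r-to-z and atlas labels.

Uses a planted remote pair: the seed (one half) is strongly correlated
with the other half in controls but decoupled in patients.  The seed's
mean series is correlated with every gray-matter voxel, z-transformed,
smoothed, and compared across groups with the same inference machinery
as the FCD maps; surviving clusters are annotated against a toy atlas.
"""

import numpy as np

from fcdpipe import (
    AtlasVolume,
    CohortSpec,
    SeedSpec,
    cohort_table,
    build_design_matrix,
    generate_cohort,
    group_fc_comparison,
    label_clusters_with_atlas,
    make_gm_mask,
    remote_pair_block,
    simulate_null_cluster_distribution,
    subject_seed_zmap,
    synthetic_gm_prob,
)
from fcdpipe.inference import adjacency_from_radius

GRID = (14, 14, 14)
spec = CohortSpec(
    n_per_group=10,
    grid_shape=GRID,
    n_volumes=120,
    seed=11,
    blocks=[remote_pair_block("pair", (3, 3, 3), (9, 9, 9), 3, coupling=0.81)],
    group_effects=[("pair", "patient", 0.2)],
)
records = generate_cohort(spec)
mask = make_gm_mask(synthetic_gm_prob(GRID))

seed_mask = np.zeros(GRID, bool)
seed_mask[3:6, 3:6, 3:6] = True
seed = SeedSpec(seed_mask, "pair half A")

zmaps = [subject_seed_zmap(r.bold, seed, mask, 6.0, r.subject_id) for r in records]
design = build_design_matrix(cohort_table(records))
adjacency = adjacency_from_radius((3, 3, 3), 5.0)
null = simulate_null_cluster_distribution(mask, 6.0, 0.01, 300, adjacency, seed=1)
table = group_fc_comparison(zmaps, design, mask, null)

atlas_labels = np.zeros(GRID, int)
atlas_labels[:, :7] = 1
atlas_labels[:, 7:] = 2
atlas = AtlasVolume(atlas_labels, {1: "anterior region", 2: "posterior region"})
table = label_clusters_with_atlas(table, atlas)

print(f"seed: {seed.label}, {int(seed_mask.sum())} voxels")
for c in table.clusters:
    direction = "decreased in patients" if c.sign > 0 else "increased in patients"
    print(
        f"cluster {c.index}: {c.size} voxels, peak t = {c.peak_t:.2f} at "
        f"{c.peak_mm} mm ({direction}); atlas: {c.atlas_labels}"
    )
print(
    "\nThe surviving decreased-connectivity cluster sits over the remote half"
    "\nat voxels (9-11)^3 - exactly where the patients' coupling was removed."
)
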