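"""Generate a synthetic resting-state cohort with planted connectivity.

Two groups of 6 subjects on a 12^3 grid of 3 mm voxels, 100 volumes at
TR = 2 s.  A contiguous 3^3 block is coupled at r = 0.9 in controls but
multiplied down to 0.09 in patients — a planted short-range connectivity
deficit the rest of the pipeline should find.
"""

import numpy as np

from fcdpipe import CohortSpec, cube_block, generate_cohort

spec = CohortSpec(
    n_per_group=6,
    grid_shape=(12, 12, 12),
    n_volumes=100,
    seed=7,
    blocks=[cube_block("deficit", (4, 4, 4), 3, coupling=0.9)],
    group_effects=[("deficit", "patient", 0.1)],
)
records = generate_cohort(spec)

block = spec.blocks[0]
for group in ("control", "patient"):
    rs = []
    for rec in records:
        if rec.group != group:
            continue
        series = rec.bold.data[tuple(block.member_voxels.T)]
        R = np.corrcoef(series)
        rs.append(R[np.triu_indices(len(series), 1)].mean())
    print(f"{group:8s}: mean within-block correlation {np.mean(rs):.3f}")

print(
    "\nControls sit near the planted coupling 0.9.  Patients' shared-signal"
    "\ncoupling is 0.9 x 0.1 = 0.09; the rest of their observed correlation is"
    "\nthe 6 mm smoothed noise shared by neighboring voxels.  Either way their"
    "\nblock falls below the r > 0.6 connection threshold, controls' stays above."
)
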