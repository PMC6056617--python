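"""Covariate-adjusted group comparison with Monte-Carlo extent correction.

Runs the full inference arm on a small synthetic cohort with a planted
patient short-range deficit: voxel-wise GLM (age, gender, TIV as
covariates), AlphaSim-style null simulation (voxel p = 0.01, 5 mm
connection radius, 6 mm FWHM), and cluster-extent thresholding.
"""

from fcdpipe import (
    CohortSpec,
    RunConfig,
    cube_block,
    generate_cohort,
    run_group_analysis,
    synthetic_gm_prob,
)

spec = CohortSpec(
    n_per_group=8,
    grid_shape=(12, 12, 12),
    n_volumes=100,
    seed=0,
    blocks=[
        cube_block("deficit", (2, 4, 4), 3, 0.9),
        cube_block("stable", (7, 4, 4), 3, 0.9),
    ],
    group_effects=[("deficit", "patient", 0.1)],
    drift_amplitude=0.3,
    physio_amplitude=0.2,
)
records = generate_cohort(spec)
config = RunConfig(out_dir="scratch/example_run", n_iterations=300, seed=5, n_discard=5)
result = run_group_analysis(config, records, synthetic_gm_prob(spec.grid_shape))

print(f"subjects kept after motion QC: {result.provenance['n_subjects_kept']}")
print(f"cluster extent threshold: {result.extent_threshold} voxels")
for kind, table in result.cluster_tables.items():
    print(f"\n{kind} clusters:")
    frame = table.to_frame()
    print(frame.to_string(index=False) if len(frame) else "  (none survive)")

print(
    "\n'pos' clusters are regions where controls exceed patients (HC > ALS in"
    "\nthe study's convention); the planted deficit block sits at voxels"
    "\n(2-4, 4-6, 4-6), so the pos cluster peaking there is the planted effect."
    "\nA neg cluster over the stable block can appear because each map is"
    "\nrescaled by its own mean: losing the deficit block raises the patients'"
    "\nrelative FCD elsewhere."
)
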