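"""Synthetic validation experiments for the full analysis chain.

These are the package's canonical planted-truth studies:

* :func:`planted_cohort_spec` defines the reference synthetic cohort — an
  ellipsoidal "gray matter" domain on a 24^3 grid of 3 mm voxels with a
  contiguous coupled cube whose coupling is reduced in patients (a
  short-range FCD deficit) and a remote coupled block pair that patients
  lose (a long-range / seed-connectivity deficit), plus drift, global,
  physiological and motion-linked nuisance components.
* :func:`run_planted_recovery` pushes one such cohort through motion QC,
  preprocessing, FCD mapping, the covariate-adjusted GLM and the
  Monte-Carlo extent correction, and reports whether the planted effects
  were recovered as surviving clusters overlapping the planted sites.
* :func:`familywise_error_rate` measures empirical type-I control of the
  inference machinery on null cohorts of smooth Gaussian maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VolumeMask
from .fcd import FCDConfig, FWHM_TO_SIGMA, compute_subject_fcd
from .inference import (
    NullClusterDistribution,
    adjacency_from_radius,
    build_design_matrix,
    cluster_extent_threshold,
    extract_clusters,
    fit_voxelwise_glm,
    simulate_null_cluster_distribution,
)
from .preprocess import make_gm_mask, preprocess_subject
from .seedfc import SeedSpec, group_fc_comparison, subject_seed_zmap
from .synthetic import CohortSpec, cohort_table, cube_block, generate_cohort, remote_pair_block, synthetic_gm_prob

__all__ = [
    "GRID",
    "planted_cohort_spec",
    "analysis_mask",
    "deficit_mask",
    "pair_seed_mask",
    "pair_target_mask",
    "reference_null",
    "run_planted_recovery",
    "familywise_error_rate",
]

GRID = (24, 24, 24)
_SEMIAXES = (8.0, 8.0, 8.0)  # ellipsoidal analysis domain, ~2200 voxels
_DEFICIT = (slice(6, 10), slice(8, 12), slice(8, 12))  # 4^3 contiguous cube
_PAIR_A = (slice(14, 17), slice(8, 11), slice(8, 11))  # 3^3 remote halves
_PAIR_B = (slice(8, 11), slice(14, 17), slice(14, 17))


def _slice_mask(sl) -> np.ndarray:
    m = np.zeros(GRID, dtype=bool)
    m[sl] = True
    return m


def deficit_mask() -> np.ndarray:
    """Voxels of the planted short-range deficit block."""
    return _slice_mask(_DEFICIT)


def pair_seed_mask() -> np.ndarray:
    """First half of the remote pair (used as the seed region)."""
    return _slice_mask(_PAIR_A)


def pair_target_mask() -> np.ndarray:
    """Second half of the remote pair (where decoupling should surface)."""
    return _slice_mask(_PAIR_B)


def planted_cohort_spec(
    seed: int,
    n_per_group: int = 20,
    n_volumes: int = 200,
    deficit_multiplier: float = 0.3,
) -> CohortSpec:
    """Reference planted-truth cohort on the 24^3 grid.

    Patients carry the ``deficit_multiplier`` on both the contiguous block
    (coupling 0.9) and the remote pair (coupling 0.81), i.e. their target
    correlations drop below the 0.6 connection threshold while the
    controls' stay above it.
    """
    corner = lambda sl: tuple(s.start for s in sl)  # noqa: E731
    return CohortSpec(
        n_per_group=n_per_group,
        grid_shape=GRID,
        n_volumes=n_volumes,
        seed=seed,
        blocks=[
            cube_block("deficit", corner(_DEFICIT), 4, 0.9),
            remote_pair_block("pair", corner(_PAIR_A), corner(_PAIR_B), 3, 0.81),
        ],
        group_effects=[
            ("deficit", "patient", deficit_multiplier),
            ("pair", "patient", deficit_multiplier),
        ],
        drift_amplitude=0.3,
        global_amplitude=0.2,
        physio_amplitude=0.2,
        motion_artifact_amplitude=0.1,
    )


def analysis_mask() -> VolumeMask:
    """Gray-matter mask of the reference domain (20% probability rule)."""
    return make_gm_mask(synthetic_gm_prob(GRID, _SEMIAXES))


def reference_null(
    n_iterations: int = 500, seed: int = 424242, voxel_p: float = 0.01
) -> NullClusterDistribution:
    """Null max-cluster-size distribution for the reference mask at the
    study parameters (6 mm FWHM, 5 mm connection radius); reusable across
    recovery seeds because it depends only on mask and parameters."""
    return simulate_null_cluster_distribution(
        analysis_mask(), 6.0, voxel_p, n_iterations,
        adjacency_from_radius((3.0, 3.0, 3.0), 5.0), seed=seed,
    )


@dataclass
class RecoveryResult:
    short_recovered: bool
    seedfc_recovered: bool
    short_peak_t: float
    n_short_clusters: int


def run_planted_recovery(
    seed: int,
    null: NullClusterDistribution,
    n_per_group: int = 20,
    n_volumes: int = 200,
    deficit_multiplier: float = 0.3,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
) -> RecoveryResult:
    """One full recovery replicate on the reference cohort.

    Returns whether a surviving HC > patient short-range-FCD cluster
    overlaps the planted deficit block, and whether the seed-based arm
    (seed = first half of the remote pair) recovers a surviving decreased-
    connectivity cluster overlapping the second half.
    """
    spec = planted_cohort_spec(seed, n_per_group, n_volumes, deficit_multiplier)
    records = generate_cohort(spec)
    mask = analysis_mask()
    cleaned = [
        preprocess_subject(r.bold, r.motion, 0, r.wm_series, r.csf_series)
        for r in records
    ]
    cfg = FCDConfig(dtype=np.float32)
    short = np.stack(
        [compute_subject_fcd(b, mask, cfg).short_fcd for b in cleaned]
    )
    design = build_design_matrix(cohort_table(records))
    adjacency = adjacency_from_radius(records[0].bold.voxel_size_mm, 5.0)
    k_min = cluster_extent_threshold(null, alpha)
    stat = fit_voxelwise_glm(short, design, mask)
    table = extract_clusters(stat, voxel_p, k_min, adjacency, mask)
    target = deficit_mask()
    short_hit = any(c.sign > 0 and (c.mask & target).any() for c in table.clusters)

    seed_spec = SeedSpec(pair_seed_mask(), "pair_half_a")
    zmaps = [
        subject_seed_zmap(b, seed_spec, mask, 6.0, r.subject_id)
        for r, b in zip(records, cleaned)
    ]
    fc_table = group_fc_comparison(zmaps, design, mask, null, voxel_p, alpha, adjacency)
    remote = pair_target_mask()
    fc_hit = any(c.sign > 0 and (c.mask & remote).any() for c in fc_table.clusters)

    return RecoveryResult(
        short_recovered=short_hit,
        seedfc_recovered=fc_hit,
        short_peak_t=float(stat.t_values[target].max()),
        n_short_clusters=len(table),
    )


def familywise_error_rate(
    n_replicates: int = 200,
    n_iterations: int = 500,
    seed: int = 0,
    shape: tuple[int, int, int] = (14, 14, 14),
    n_per_group: int = 20,
    fwhm_mm: float = 6.0,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
) -> float:
    """Fraction of null cohorts yielding >= 1 surviving cluster.

    Each replicate draws per-subject maps as Gaussian noise smoothed to the
    study smoothness, fits the covariate-adjusted group GLM and applies the
    Monte-Carlo extent threshold; with calibrated correction the fraction
    approximates ``alpha``.
    """
    mask = VolumeMask(np.ones(shape, bool))
    adjacency = adjacency_from_radius(mask.voxel_size_mm, 5.0)
    null = simulate_null_cluster_distribution(
        mask, fwhm_mm, voxel_p, n_iterations, adjacency, seed=seed + 1
    )
    k_min = cluster_extent_threshold(null, alpha)
    sigma = fwhm_mm * FWHM_TO_SIGMA / 3.0
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    hits = 0
    for _ in range(n_replicates):
        maps = ndimage.gaussian_filter(
            rng.standard_normal((n, *shape)), sigma=(0, sigma, sigma, sigma), mode="wrap"
        )
        table = pd.DataFrame(
            {
                "group": ["control"] * n_per_group + ["patient"] * n_per_group,
                "age": rng.normal(49, 10, n),
                "gender": ["M", "F"] * n_per_group,
                "tiv": rng.normal(1.6, 0.16, n),
            }
        )
        stat = fit_voxelwise_glm(maps, build_design_matrix(table), mask)
        hits += len(extract_clusters(stat, voxel_p, k_min, adjacency, mask)) > 0
    return hits / n_replicates
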