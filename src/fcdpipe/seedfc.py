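"""Seed-based functional connectivity follow-up.

Clusters with significant FCD alterations serve as seeds: the unweighted
mean time series over the seed voxels is correlated with every in-mask
voxel, the r map is Fisher r-to-z transformed, smoothed with the same 6 mm
kernel as the FCD maps, and compared across groups with the identical GLM +
cluster-extent machinery (one shared inference code path).  Cluster
locations can be annotated against any caller-supplied labeled atlas
volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BoldSeries, VolumeMask
from .fcd import AdjacencySpec, smooth_map
from .inference import (
    ClusterTable,
    DesignMatrix,
    NullClusterDistribution,
    cluster_extent_threshold,
    extract_clusters,
    fit_voxelwise_glm,
)

__all__ = [
    "SeedSpec",
    "ZMap",
    "AtlasVolume",
    "seed_timeseries",
    "seed_fc_map",
    "fisher_z",
    "subject_seed_zmap",
    "group_fc_comparison",
    "label_clusters_with_atlas",
]

R_CLIP = 1.0 - 1e-7  # |r|=1 clipped before arctanh so z stays finite


@dataclass
class SeedSpec:
    """A seed region: boolean mask plus a human-readable label."""

    cluster_mask: np.ndarray
    label: str = "seed"

    def __post_init__(self) -> None:
        self.cluster_mask = np.asarray(self.cluster_mask, dtype=bool)
        if not self.cluster_mask.any():
            raise ValueError("seed mask is empty")


@dataclass
class ZMap:
    z_values: np.ndarray
    seed_label: str = "seed"
    subject_id: str = ""


@dataclass
class AtlasVolume:
    """Integer label grid with an id -> region-name lookup."""

    labels: np.ndarray
    lookup: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"atlas ids without lookup entries: {sorted(missing)}")


def seed_timeseries(bold: BoldSeries, seed: SeedSpec) -> np.ndarray:
    """Unweighted mean across seed voxels at each time point."""
    if seed.cluster_mask.shape != bold.shape:
        raise ValueError("seed grid does not match BOLD grid")
    return bold.data[seed.cluster_mask].mean(axis=0)


def seed_fc_map(series: np.ndarray, bold: BoldSeries, mask: VolumeMask) -> np.ndarray:
    """Pearson r between the seed series and every in-mask voxel."""
    s = np.asarray(series, dtype=float)
    s = s - s.mean()
    ns = np.linalg.norm(s)
    if ns == 0:
        raise ValueError("seed series has zero variance")
    X = bold.data[mask.mask].astype(float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = np.inf  # zero-variance voxels get r = 0
    r = (X @ s) / (norms * ns)
    out = np.zeros(mask.shape)
    out[mask.mask] = np.clip(r, -1.0, 1.0)
    return out


def fisher_z(r_map: np.ndarray) -> np.ndarray:
    """Fisher r-to-z: z = arctanh(r), with |r| clipped at 1 - 1e-7."""
    r = np.asarray(r_map, dtype=float)
    if np.abs(r).max() > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def subject_seed_zmap(
    bold: BoldSeries,
    seed: SeedSpec,
    mask: VolumeMask,
    fwhm_mm: float = 6.0,
    subject_id: str = "",
) -> ZMap:
    """Seed mean series -> r map -> z map -> 6 mm smoothing (z, not r, is
    smoothed, in that order)."""
    z = fisher_z(seed_fc_map(seed_timeseries(bold, seed), bold, mask))
    if fwhm_mm > 0:
        z = smooth_map(z, fwhm_mm, bold.voxel_size_mm, mask)
    return ZMap(z, seed.label, subject_id)


def group_fc_comparison(
    zmaps: list[ZMap],
    design: DesignMatrix,
    mask: VolumeMask,
    null: NullClusterDistribution,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    adjacency: AdjacencySpec | None = None,
) -> ClusterTable:
    """Group comparison of (already smoothed) seed z maps.

    Delegates to the same GLM and cluster-extent threshold used for FCD so
    both arms share one inference code path; positive clusters are decreased
    connectivity in the patient group (HC > ALS), negative clusters
    increased.
    """
    adjacency = adjacency or AdjacencySpec.connectivity(18)
    maps = np.stack([z.z_values for z in zmaps])
    stat = fit_voxelwise_glm(maps, design, mask)
    k_min = cluster_extent_threshold(null, alpha)
    return extract_clusters(stat, voxel_p, k_min, adjacency, mask)


def label_clusters_with_atlas(table: ClusterTable, atlas: AtlasVolume) -> ClusterTable:
    """Annotate each cluster with the atlas regions it overlaps (voxel
    counts, sorted by overlap); unlabeled territory reports 'unassigned'."""
    for c in table.clusters:
        if c.mask.shape != atlas.labels.shape:
            raise ValueError("atlas grid does not match cluster grid")
        ids, counts = np.unique(atlas.labels[c.mask], return_counts=True)
        pairs = sorted(zip(ids, counts), key=lambda p: -p[1])
        c.atlas_labels = [
            (atlas.lookup.get(int(i), "unassigned") if i != 0 else "unassigned", int(n))
            for i, n in pairs
        ]
    return table


def edge_list(tables: dict[str, ClusterTable]) -> pd.DataFrame:
    """Connectogram-style edge list: seed label <-> target cluster regions,
    with the sign of the group difference (pos = decreased in patients)."""
    rows = []
    for seed_label, table in tables.items():
        for c in table.clusters:
            targets = c.atlas_labels or [("unassigned", c.size)]
            for name, nvox in targets:
                rows.append(
                    {
                        "seed": seed_label,
                        "target_region": name,
                        "overlap_voxels": nvox,
                        "direction": "decreased" if c.sign > 0 else "increased",
                        "peak_t": c.peak_t,
                    }
                )
    return pd.DataFrame(rows)
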