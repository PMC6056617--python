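"""Voxel-wise group comparison with Monte-Carlo cluster-extent correction.

The group model is an ordinary least-squares GLM per voxel: map value
regressed on a group indicator plus nuisance covariates (age, gender, TIV,
optionally mean frame-wise displacement).  The statistic of interest is the
t value of the group coefficient (control minus patient by default, so
positive t means HC > ALS).

Multiple comparisons are handled by cluster-extent thresholding calibrated
with a Monte-Carlo simulation in the AlphaSim tradition: unit Gaussian
noise fields smoothed to the assumed map smoothness (6 mm FWHM),
standardized within the analysis mask, thresholded two-sidedly at the
cluster-forming voxel p (0.01), and labeled with a cluster connection
radius (5 mm -> 18-neighbor adjacency at 3 mm voxels); the maximum cluster
size per iteration yields the null distribution whose upper alpha tail sets
the minimum surviving extent.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import VolumeMask
from .fcd import AdjacencySpec, FWHM_TO_SIGMA

__all__ = [
    "DesignMatrix",
    "StatMap",
    "NullClusterDistribution",
    "Cluster",
    "ClusterTable",
    "build_design_matrix",
    "fit_voxelwise_glm",
    "adjacency_from_radius",
    "simulate_null_cluster_distribution",
    "cluster_extent_threshold",
    "extract_clusters",
]


@dataclass
class DesignMatrix:
    """Subject-level design: group indicator first, covariates, intercept last."""

    matrix: np.ndarray
    columns: list[str]
    contrast: str = "HC-ALS"

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("one name per design column required")
        if "group" not in self.columns:
            raise ValueError("design must contain a 'group' column")
        g = self.matrix[:, self.columns.index("group")]
        if np.unique(g).size < 2:
            raise ValueError("group column must contain both levels")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def build_design_matrix(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "gender", "tiv"),
    group_col: str = "group",
    positive_group: str = "control",
) -> DesignMatrix:
    """Design from a covariate table.

    Group is coded 1 for ``positive_group`` and 0 otherwise, so the group
    t is positive where that group's maps are larger.  Gender is coded 0/1
    (M=0, F=1) and continuous covariates are mean-centered (this shifts
    only the intercept, not the group t).
    """
    cols, names = [], []
    g = (table[group_col].astype(str).to_numpy() == positive_group).astype(float)
    cols.append(g)
    names.append("group")
    for cov in covariates:
        v = table[cov]
        if cov == "gender":
            x = v.map({"M": 0.0, "F": 1.0}).to_numpy() if v.dtype == object else v.to_numpy(float)
        else:
            x = v.to_numpy(dtype=float)
        cols.append(x - x.mean())
        names.append(cov)
    cols.append(np.ones(len(table)))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names, contrast=f"{positive_group}-rest")


@dataclass
class StatMap:
    """Voxel-wise t statistics for the group contrast."""

    t_values: np.ndarray
    df: int
    contrast: str = "HC-ALS"
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def t_cutoff(self, voxel_p: float) -> float:
        """Two-sided |t| cutoff for the cluster-forming voxel p."""
        return float(stats.t.isf(voxel_p / 2.0, self.df))


def fit_voxelwise_glm(
    maps: np.ndarray,
    design: DesignMatrix,
    mask: VolumeMask,
    term: str = "group",
) -> StatMap:
    """OLS per voxel; t statistic for ``term`` with df = n - rank(design).

    ``maps`` is (n_subjects, x, y, z).  Voxels whose residual variance is
    exactly zero (e.g. identically zero maps across subjects) get t = 0.
    """
    X = design.matrix
    n, k = X.shape
    rank = design.rank
    if maps.shape[0] != n:
        raise ValueError("one map per design row required")
    if n <= rank:
        raise ValueError("not enough subjects for the design degrees of freedom")
    Y = maps[:, mask.mask].astype(float)  # (n, N)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - rank
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    j = design.columns.index(term)
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[j] / np.where(se > 0, se, 1.0), 0.0)
    out = np.zeros(mask.shape)
    out[mask.mask] = t
    return StatMap(out, df, design.contrast, mask.voxel_size_mm)


def adjacency_from_radius(voxel_size_mm, radius_mm: float) -> AdjacencySpec:
    """Cluster connection adjacency: all offsets within ``radius_mm``."""
    return AdjacencySpec.from_radius(voxel_size_mm, radius_mm)


def _label(binary: np.ndarray, adjacency: AdjacencySpec) -> tuple[np.ndarray, int]:
    structure = adjacency.structure()
    if structure is not None:
        return ndimage.label(binary, structure=structure)
    # generic offsets: iterative BFS labeling
    labels = np.zeros(binary.shape, dtype=np.int32)
    cur = 0
    for p in map(tuple, np.argwhere(binary)):
        if labels[p]:
            continue
        cur += 1
        frontier = [p]
        labels[p] = cur
        while frontier:
            nxt = []
            for q in frontier:
                for o in adjacency.offsets:
                    r = (q[0] + o[0], q[1] + o[1], q[2] + o[2])
                    if all(0 <= r[d] < binary.shape[d] for d in range(3)):
                        if binary[r] and not labels[r]:
                            labels[r] = cur
                            nxt.append(r)
            frontier = nxt
    return labels, cur


@dataclass
class NullClusterDistribution:
    """Maximum null cluster sizes from the Monte-Carlo smoothness simulation."""

    max_cluster_sizes: np.ndarray
    params: dict
    supra_counts: np.ndarray | None = None  # suprathreshold voxels per iteration

    def __post_init__(self) -> None:
        self.max_cluster_sizes = np.asarray(self.max_cluster_sizes, dtype=np.int64)
        if (self.max_cluster_sizes < 0).any():
            raise ValueError("cluster sizes must be non-negative")

    def suprathreshold_fraction(self, n_mask_voxels: int) -> float:
        """Mean fraction of in-mask voxels above the two-sided cutoff
        (should approximate voxel_p for unsmoothed fields)."""
        if self.supra_counts is None:
            raise ValueError("suprathreshold counts were not recorded")
        return float(self.supra_counts.mean() / n_mask_voxels)

    def to_json(self, path) -> None:
        """Cache the distribution (params include the mask hash and seed,
        so a cached file is only valid for the exact same analysis)."""
        import json
        from pathlib import Path

        payload = {
            "params": self.params,
            "max_cluster_sizes": self.max_cluster_sizes.tolist(),
            "supra_counts": None if self.supra_counts is None else self.supra_counts.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NullClusterDistribution":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        supra = d.get("supra_counts")
        return cls(
            np.asarray(d["max_cluster_sizes"]),
            d["params"],
            None if supra is None else np.asarray(supra),
        )


def simulate_null_cluster_distribution(
    mask: VolumeMask,
    fwhm_mm: float,
    voxel_p: float = 0.01,
    n_iterations: int = 5000,
    adjacency: AdjacencySpec | None = None,
    seed: int | None = None,
) -> NullClusterDistribution:
    """AlphaSim-style null: per iteration, a unit Gaussian field smoothed to
    ``fwhm_mm``, standardized within the mask, thresholded two-sidedly at the
    |z| quantile for ``voxel_p``, labeled per sign; the largest cluster size
    is recorded.  Deterministic given ``seed``."""
    if mask.n_voxels == 0:
        raise ValueError("empty analysis mask")
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must lie in (0, 1)")
    if seed is None:
        raise ValueError("an explicit seed is required for the null simulation")
    adjacency = adjacency or AdjacencySpec.connectivity(18)
    rng = np.random.default_rng(seed)
    z_cut = stats.norm.isf(voxel_p / 2.0)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(mask.voxel_size_mm, dtype=float)
    m = mask.mask
    maxes = np.empty(n_iterations, dtype=np.int64)
    supra_counts = np.empty(n_iterations, dtype=np.int64)
    for it in range(n_iterations):
        field_ = rng.standard_normal(mask.shape)
        if fwhm_mm > 0:
            # periodic boundaries keep the smoothed variance stationary, so
            # the single in-mask standardization is unbiased at every voxel
            # (reflect/zero padding would inflate edge variance and misalign
            # the null with the per-voxel-normalized t map)
            field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox, mode="wrap")
        vals = field_[m]
        field_ = (field_ - vals.mean()) / vals.std()
        best = 0
        n_supra = 0
        for sign in (1.0, -1.0):
            supra = (sign * field_ > z_cut) & m
            n_supra += int(supra.sum())
            if supra.any():
                labels, nlab = _label(supra, adjacency)
                if nlab:
                    best = max(best, int(np.bincount(labels.ravel())[1:].max()))
        maxes[it] = best
        supra_counts[it] = n_supra
    params = {
        "voxel_p": voxel_p,
        "n_iterations": n_iterations,
        "fwhm_mm": fwhm_mm,
        "adjacency": adjacency.derivation,
        "mask_hash": int(zlib.crc32(mask.mask.tobytes())),
        "seed": seed,
    }
    return NullClusterDistribution(maxes, params, supra_counts)


def cluster_extent_threshold(null: NullClusterDistribution, alpha: float = 0.05) -> int:
    """Smallest extent k whose empirical corrected p (fraction of null
    iterations with max cluster >= k) is <= alpha."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    sizes = null.max_cluster_sizes
    n = sizes.size
    if n * alpha < 1:
        warnings.warn(
            f"{n} iterations cannot resolve corrected p <= {alpha}; threshold is an upper bound"
        )
    for k in range(1, int(sizes.max()) + 2):
        if (sizes >= k).sum() / n <= alpha:
            return k
    return int(sizes.max()) + 1


@dataclass
class Cluster:
    index: int
    sign: int  # +1: positive contrast (e.g. HC > ALS), -1: negative
    size: int
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_t: float
    mask: np.ndarray
    atlas_labels: list[tuple[str, int]] | None = None


@dataclass
class ClusterTable:
    """Suprathreshold clusters surviving the extent threshold."""

    clusters: list[Cluster]
    voxel_p: float
    k_min: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            row = {
                "cluster_index": c.index,
                "sign": "pos" if c.sign > 0 else "neg",
                "size_voxels": c.size,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_i": c.peak_ijk[0],
                "peak_j": c.peak_ijk[1],
                "peak_k": c.peak_ijk[2],
                "peak_t": c.peak_t,
            }
            if c.atlas_labels is not None:
                row["atlas_labels"] = "; ".join(f"{n} ({v})" for n, v in c.atlas_labels)
            rows.append(row)
        return pd.DataFrame(rows)


def extract_clusters(
    stat: StatMap,
    voxel_p: float,
    k_min: int,
    adjacency: AdjacencySpec,
    mask: VolumeMask | None = None,
) -> ClusterTable:
    """Connected suprathreshold components per sign, dropping those below
    the extent threshold.  Peak = max |t| voxel; ties broken by lexicographic
    voxel index."""
    cut = stat.t_cutoff(voxel_p)
    t = stat.t_values
    domain = mask.mask if mask is not None else np.ones(t.shape, bool)
    clusters: list[Cluster] = []
    idx = 0
    for sign in (1, -1):
        supra = (sign * t > cut) & domain
        labels, nlab = _label(supra, adjacency)
        for lab in range(1, nlab + 1):
            member = labels == lab
            size = int(member.sum())
            if size < k_min:
                continue
            pts = np.argwhere(member)
            order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
            pts = pts[order]
            tv = np.abs(t[tuple(pts.T)])
            peak = pts[int(np.argmax(tv))]  # argmax takes the first (lexicographic) tie
            idx += 1
            clusters.append(
                Cluster(
                    index=idx,
                    sign=sign,
                    size=size,
                    peak_ijk=tuple(int(v) for v in peak),
                    peak_mm=tuple(float(p * v) for p, v in zip(peak, stat.voxel_size_mm)),
                    peak_t=float(t[tuple(peak)]),
                    mask=member,
                )
            )
    return ClusterTable(clusters, voxel_p, k_min)
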