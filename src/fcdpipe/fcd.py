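"""Functional connectivity density (FCD) mapping.

Global FCD (degree) at a voxel x0 is the number of other in-mask voxels
whose time series correlates with x0 above a threshold (Pearson r > 0.6 by
default).  Short-range (local) FCD is computed with a growing algorithm: the
spatially contiguous cluster grown from x0 by repeatedly adding in-mask
voxels that are (a) adjacent to the current cluster and (b) correlated with
x0 above threshold, until a fixed point; the count excludes the center, so
short <= global always.  Long-range FCD is the difference global - short:
the distal connections only.

Each map is rescaled by its own in-mask mean (FCD / mean(FCD)) and smoothed
with a 6 mm FWHM Gaussian kernel before group analysis.

The growing fixed point equals the connected component containing x0 of the
voxel set {x0} + {j : r(x0, j) > threshold} under the chosen spatial
adjacency, which is how it is computed here (component labeling restricted
to the set's bounding box).  Pairwise correlations are evaluated in row
chunks so the full N x N matrix is never materialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BoldSeries, VolumeMask

__all__ = [
    "AdjacencySpec",
    "FCDConfig",
    "FCDMaps",
    "global_fcd",
    "short_range_fcd",
    "long_range_fcd",
    "rescale_fcd",
    "smooth_map",
    "compute_subject_fcd",
    "correlation_neighbors",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AdjacencySpec:
    """Symmetric set of integer voxel offsets defining spatial adjacency."""

    offsets: tuple[tuple[int, int, int], ...]
    derivation: str = "custom"

    def __post_init__(self) -> None:
        offs = {tuple(int(v) for v in o) for o in self.offsets}
        if (0, 0, 0) in offs:
            raise ValueError("adjacency must exclude the zero offset")
        for o in offs:
            if tuple(-v for v in o) not in offs:
                raise ValueError(f"adjacency not symmetric: missing -{o}")
        object.__setattr__(self, "offsets", tuple(sorted(offs)))

    @classmethod
    def connectivity(cls, n: int) -> "AdjacencySpec":
        """Standard 6 / 18 / 26 neighborhoods of the 3x3x3 cube."""
        if n not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        order = {6: 1, 18: 2, 26: 3}[n]
        offs = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if 0 < abs(i) + abs(j) + abs(k) <= order
        ]
        return cls(tuple(offs), derivation=f"connectivity-{n}")

    @classmethod
    def from_radius(cls, voxel_size_mm, radius_mm: float) -> "AdjacencySpec":
        """All nonzero offsets within ``radius_mm`` Euclidean distance."""
        vs = np.asarray(voxel_size_mm, dtype=float)
        if radius_mm < vs.max():
            raise ValueError(
                f"radius {radius_mm} mm smaller than the largest voxel "
                f"dimension {vs.max()} mm: no neighbors possible"
            )
        reach = np.floor(radius_mm / vs).astype(int)
        offs = []
        for i in range(-reach[0], reach[0] + 1):
            for j in range(-reach[1], reach[1] + 1):
                for k in range(-reach[2], reach[2] + 1):
                    if (i, j, k) == (0, 0, 0):
                        continue
                    if np.linalg.norm((i * vs[0], j * vs[1], k * vs[2])) <= radius_mm:
                        offs.append((i, j, k))
        return cls(tuple(offs), derivation=f"radius_mm:{radius_mm}")

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)

    def structure(self) -> np.ndarray | None:
        """3x3x3 labeling structure, or None if offsets exceed the cube."""
        arr = np.array(self.offsets)
        if np.abs(arr).max() > 1:
            return None
        s = np.zeros((3, 3, 3), dtype=bool)
        s[1, 1, 1] = True
        s[arr[:, 0] + 1, arr[:, 1] + 1, arr[:, 2] + 1] = True
        return s


@dataclass
class FCDConfig:
    """Parameters of the per-subject FCD computation."""

    r_threshold: float = 0.6
    adjacency: AdjacencySpec = field(default_factory=lambda: AdjacencySpec.connectivity(26))
    fwhm_mm: float = 6.0
    rescale: bool = True
    smooth: bool = True
    include_self: bool = False
    shared_rescale_mean: bool = False  # rescale all 3 maps by the global map's mean
    zero_variance: str = "error"  # or "zero": zero-variance voxels get degree 0
    empty_map_policy: str = "zeros"  # all-zero count map: leave as zeros, or "error"
    remask_after_smoothing: bool = True
    chunk_size: int = 2048  # rows per correlation block; the N x N matrix is never held
    dtype: type = np.float64


@dataclass
class FCDMaps:
    """Per-subject global / short-range / long-range FCD volumes.

    ``global_fcd``/``short_fcd``/``long_fcd`` hold the maps after the
    configured rescaling and smoothing; the raw integer count maps are kept
    in ``raw_global``/``raw_short``/``raw_long`` (these always satisfy
    short <= global and long = global - short in-mask).
    """

    global_fcd: np.ndarray
    short_fcd: np.ndarray
    long_fcd: np.ndarray
    raw_global: np.ndarray
    raw_short: np.ndarray
    raw_long: np.ndarray
    rescaled: bool
    r_threshold: float
    adjacency: AdjacencySpec

    def named(self) -> dict[str, np.ndarray]:
        return {"gfcd": self.global_fcd, "sfcd": self.short_fcd, "lfcd": self.long_fcd}

    def save(self, outdir, subject_id: str, voxel_size_mm) -> None:
        """Write the three maps as NIfTI (suffixes _gfcd/_sfcd/_lfcd) plus a
        JSON sidecar recording threshold, adjacency and processing flags."""
        import json
        from pathlib import Path

        from .core import save_volume

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for suffix, vol in self.named().items():
            save_volume(vol, voxel_size_mm, out / f"{subject_id}_{suffix}.nii.gz")
        sidecar = {
            "r_threshold": self.r_threshold,
            "adjacency": self.adjacency.derivation,
            "rescaled": self.rescaled,
            "maps": [f"{subject_id}_{s}.nii.gz" for s in self.named()],
        }
        (out / f"{subject_id}_fcd.json").write_text(json.dumps(sidecar, indent=2))


def _standardized_series(bold: BoldSeries, mask: VolumeMask, zero_variance: str, dtype):
    """In-mask series, demeaned and scaled to unit norm (rows: voxels)."""
    if mask.shape != bold.shape:
        raise ValueError("mask grid does not match BOLD grid")
    X = bold.data[mask.mask].astype(dtype, copy=True)  # (N, T)
    X -= X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", X, X))
    dead = norms == 0
    if dead.any():
        if zero_variance == "error":
            raise ValueError(
                f"{int(dead.sum())} in-mask voxel(s) have zero variance; "
                "set zero_variance='zero' to assign them degree 0"
            )
        warnings.warn(f"{int(dead.sum())} zero-variance voxels assigned degree 0")
        norms[dead] = 1.0
        X[dead] = 0.0
    X /= norms[:, None]
    return X


def correlation_neighbors(
    bold: BoldSeries,
    mask: VolumeMask,
    r_threshold: float = 0.6,
    chunk_size: int = 2048,
    zero_variance: str = "error",
    dtype=np.float64,
) -> list[np.ndarray]:
    """Per in-mask voxel, indices (into the in-mask ordering) of the other
    voxels correlated with it strictly above ``r_threshold``.

    Correlations are computed in chunks of ``chunk_size`` rows; only the
    thresholded (sparse) neighbor lists are retained.
    """
    X = _standardized_series(bold, mask, zero_variance, dtype)
    n = X.shape[0]
    neighbors: list[np.ndarray] = []
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        R = X[start:stop] @ X.T  # (chunk, N)
        hits = R > r_threshold
        hits[np.arange(start, stop) - start, np.arange(start, stop)] = False
        rows, cols = np.nonzero(hits)
        bounds = np.searchsorted(rows, np.arange(stop - start + 1))
        neighbors.extend(
            cols[bounds[i] : bounds[i + 1]] for i in range(stop - start)
        )
    return neighbors


def _component_size(points: np.ndarray, center_pos: int, adjacency: AdjacencySpec) -> int:
    """Size of the adjacency-connected component of ``points`` (an (m,3)
    integer array) that contains ``points[center_pos]``."""
    structure = adjacency.structure()
    lo = points.min(axis=0)
    if structure is not None:
        shape = points.max(axis=0) - lo + 1
        sub = np.zeros(shape, dtype=bool)
        local = points - lo
        sub[tuple(local.T)] = True
        labels, _ = ndimage.label(sub, structure=structure)
        want = labels[tuple(local[center_pos])]
        return int((labels[tuple(local.T)] == want).sum())
    # arbitrary-offset adjacency: breadth-first growth over the point set
    ptset = {tuple(p) for p in points}
    start = tuple(points[center_pos])
    seen, frontier = {start}, [start]
    while frontier:
        nxt = []
        for p in frontier:
            for o in adjacency.offsets:
                q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if q in ptset and q not in seen:
                    seen.add(q)
                    nxt.append(q)
        frontier = nxt
    return len(seen)


def global_fcd(
    bold: BoldSeries,
    mask: VolumeMask,
    r_threshold: float = 0.6,
    include_self: bool = False,
    **kwargs,
) -> np.ndarray:
    """Degree map: count of in-mask voxels with r > threshold to each voxel."""
    neighbors = correlation_neighbors(bold, mask, r_threshold, **kwargs)
    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask.mask] = [len(nb) + include_self for nb in neighbors]
    return out


def short_range_fcd(
    bold: BoldSeries,
    mask: VolumeMask,
    r_threshold: float = 0.6,
    adjacency: AdjacencySpec | None = None,
    include_self: bool = False,
    **kwargs,
) -> np.ndarray:
    """Growing-algorithm local FCD map (component count minus the center)."""
    adjacency = adjacency or AdjacencySpec.connectivity(26)
    neighbors = correlation_neighbors(bold, mask, r_threshold, **kwargs)
    return _short_from_neighbors(neighbors, mask, adjacency, include_self)


def _short_from_neighbors(
    neighbors: list[np.ndarray],
    mask: VolumeMask,
    adjacency: AdjacencySpec,
    include_self: bool,
) -> np.ndarray:
    coords = mask.indices()
    vals = np.zeros(len(neighbors), dtype=np.int64)
    for i, nb in enumerate(neighbors):
        if len(nb) == 0:
            vals[i] = include_self
            continue
        pts = coords[np.concatenate(([i], nb))]
        size = _component_size(pts, 0, adjacency)
        vals[i] = size - 1 + include_self
    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask.mask] = vals
    return out


def long_range_fcd(global_map: np.ndarray, short_map: np.ndarray) -> np.ndarray:
    """Distal connections: global - short, which must be non-negative."""
    diff = np.asarray(global_map) - np.asarray(short_map)
    if diff.min() < 0:
        raise RuntimeError(
            "short-range FCD exceeds global FCD somewhere: growing-rule inconsistency"
        )
    return diff


def rescale_fcd(fcd_map: np.ndarray, mask: VolumeMask) -> np.ndarray:
    """Divide in-mask values by their in-mask mean (out-of-mask set to 0)."""
    vals = np.asarray(fcd_map, dtype=float)[mask.mask]
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("cannot rescale: in-mask mean FCD is not positive")
    out = np.zeros(fcd_map.shape, dtype=float)
    out[mask.mask] = vals / mean
    return out


def smooth_map(
    fcd_map: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm,
    mask: VolumeMask | None = None,
    remask: bool = True,
) -> np.ndarray:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    With a mask, the map is cropped to the mask bounding box, smoothed with
    reflecting boundaries, and (by default) re-masked; this avoids the edge
    attenuation of zero-padded convolution.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    arr = np.asarray(fcd_map, dtype=float)
    if fwhm_mm == 0:
        return arr.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    if mask is None:
        return ndimage.gaussian_filter(arr, sigma=sigma_vox, mode="reflect", truncate=6.0)
    idx = mask.indices()
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    out = np.zeros_like(arr)
    out[box] = ndimage.gaussian_filter(arr[box], sigma=sigma_vox, mode="reflect", truncate=6.0)
    if remask:
        out[~mask.mask] = 0.0
    return out


def compute_subject_fcd(
    bold: BoldSeries,
    mask: VolumeMask,
    config: FCDConfig | None = None,
) -> FCDMaps:
    """Full per-subject FCD stage: counts -> rescale -> smooth.

    One chunked correlation pass feeds both the degree and the growing
    algorithm.  Rescaling (per-map in-mask mean by default) happens before
    smoothing.  An all-zero count map cannot be rescaled; depending on
    ``config.empty_map_policy`` it is left as zeros or raises.
    """
    cfg = config or FCDConfig()
    neighbors = correlation_neighbors(
        bold, mask, cfg.r_threshold, cfg.chunk_size, cfg.zero_variance, cfg.dtype
    )
    raw_g = np.zeros(mask.shape, dtype=np.int64)
    raw_g[mask.mask] = [len(nb) + cfg.include_self for nb in neighbors]
    raw_s = _short_from_neighbors(neighbors, mask, cfg.adjacency, cfg.include_self)
    raw_l = long_range_fcd(raw_g, raw_s)

    shared_mean = None
    if cfg.shared_rescale_mean:
        shared_mean = raw_g[mask.mask].mean()

    def _finish(raw: np.ndarray) -> np.ndarray:
        m = np.asarray(raw, dtype=float)
        if cfg.rescale:
            in_mean = shared_mean if shared_mean is not None else m[mask.mask].mean()
            if in_mean <= 0:
                if cfg.empty_map_policy == "error":
                    raise ValueError("cannot rescale an all-zero FCD map")
                warnings.warn("all-zero FCD map left unrescaled")
            else:
                out = np.zeros_like(m)
                out[mask.mask] = m[mask.mask] / in_mean
                m = out
        if cfg.smooth and cfg.fwhm_mm > 0:
            m = smooth_map(m, cfg.fwhm_mm, bold.voxel_size_mm, mask, cfg.remask_after_smoothing)
        return m

    return FCDMaps(
        global_fcd=_finish(raw_g),
        short_fcd=_finish(raw_s),
        long_fcd=_finish(raw_l),
        raw_global=raw_g,
        raw_short=raw_s,
        raw_long=raw_l,
        rescaled=cfg.rescale,
        r_threshold=cfg.r_threshold,
        adjacency=cfg.adjacency,
    )
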