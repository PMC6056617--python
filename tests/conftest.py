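"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use the dumbest correct formulation (full
correlation matrices, pure-Python BFS, explicit normal equations) so they
stay independent of the library's optimized paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from fcdpipe import AdjacencySpec, BoldSeries, VolumeMask


# ---------------------------------------------------------------- builders
def make_bold(data, voxel=3.0, tr=2.0):
    return BoldSeries(np.asarray(data, float), (voxel,) * 3, tr)


def planted_bold(grid_shape, planted, T=60, noise_sd=1.0, seed=0, voxel=3.0):
    """iid-noise volume with voxel sets forced to shared series.

    ``planted``: list of ((n,3) index array, weight) pairs; each set gets
    weight * shared + sqrt(1-weight^2) * own noise (weight=1 -> identical).
    """
    rng = np.random.default_rng(seed)
    data = noise_sd * rng.standard_normal((*grid_shape, T))
    for members, w in planted:
        s = rng.standard_normal(T)
        members = np.atleast_2d(np.asarray(members, int))
        data[tuple(members.T)] = w * s + np.sqrt(max(0.0, 1 - w * w)) * data[tuple(members.T)]
    return make_bold(data, voxel)


def cube_indices(corner, size):
    c = np.asarray(corner, int)
    return np.array(
        [c + (i, j, k) for i in range(size) for j in range(size) for k in range(size)]
    )


def full_mask(shape, voxel=3.0):
    return VolumeMask(np.ones(shape, bool), (voxel,) * 3)


# ---------------------------------------------------------------- oracles
def oracle_fcd(bold, mask, r_threshold, adjacency=None):
    """Naive O(N^2) degree + per-voxel BFS growing; returns (global, short,
    long) count grids."""
    adjacency = adjacency or AdjacencySpec.connectivity(26)
    coords = [tuple(p) for p in np.argwhere(mask.mask)]
    X = np.array([bold.data[p] for p in coords])
    R = np.corrcoef(X)
    n = len(coords)
    g = np.zeros(mask.shape, int)
    s = np.zeros(mask.shape, int)
    pos = {p: i for i, p in enumerate(coords)}
    for i, p in enumerate(coords):
        linked = {coords[j] for j in range(n) if j != i and R[i, j] > r_threshold}
        g[p] = len(linked)
        grown, frontier = {p}, [p]
        while frontier:  # fixed-point growth
            nxt = []
            for q in frontier:
                for o in adjacency.offsets:
                    cand = (q[0] + o[0], q[1] + o[1], q[2] + o[2])
                    if cand in linked and cand not in grown:
                        grown.add(cand)
                        nxt.append(cand)
            frontier = nxt
        s[p] = len(grown) - 1
    return g, s, g - s


def oracle_two_sample_t(a, b):
    """Pooled-variance two-sample t (group a minus group b) per voxel."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(0), b.mean(0)
    sp2 = ((a - ma) ** 2).sum(0) + ((b - mb) ** 2).sum(0)
    sp2 /= na + nb - 2
    return (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))


def oracle_partial_r(x, y, covs):
    """Partial correlation via the inverse correlation matrix."""
    M = np.column_stack([x, y, covs])
    Omega = np.linalg.inv(np.corrcoef(M.T))
    return -Omega[0, 1] / np.sqrt(Omega[0, 0] * Omega[1, 1])


def oracle_flood_fill(binary, offsets):
    """Connected-component labeling by explicit flood fill."""
    binary = np.asarray(binary, bool)
    labels = np.zeros(binary.shape, int)
    nxt_label = 0
    for p in map(tuple, np.argwhere(binary)):
        if labels[p]:
            continue
        nxt_label += 1
        stack = [p]
        labels[p] = nxt_label
        while stack:
            q = stack.pop()
            for o in offsets:
                r = tuple(q[d] + o[d] for d in range(3))
                if all(0 <= r[d] < binary.shape[d] for d in range(3)):
                    if binary[r] and not labels[r]:
                        labels[r] = nxt_label
                        stack.append(r)
    return labels, nxt_label


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
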