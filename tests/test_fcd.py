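"""FCD mapping: analytic block fixtures, brute-force oracle equivalence,
growing-algorithm semantics, rescaling and smoothing identities."""

import numpy as np
import pytest

from fcdpipe import (
    AdjacencySpec,
    FCDConfig,
    VolumeMask,
    compute_subject_fcd,
    global_fcd,
    long_range_fcd,
    rescale_fcd,
    short_range_fcd,
    smooth_map,
)
from fcdpipe.fcd import FWHM_TO_SIGMA, correlation_neighbors

from conftest import cube_indices, full_mask, make_bold, oracle_fcd, planted_bold


def test_contiguous_identical_block():
    """5 identical-series contiguous voxels in independent noise:
    global = short = 4 at each member, long = 0."""
    members = np.array([[3, 3, 3], [4, 3, 3], [5, 3, 3], [3, 4, 3], [3, 3, 4]])
    bold = planted_bold((8, 8, 8), [(members, 1.0)], T=60, seed=2)
    mask = full_mask((8, 8, 8))
    g = global_fcd(bold, mask)
    s = short_range_fcd(bold, mask)
    for p in map(tuple, members):
        assert g[p] == 4 and s[p] == 4
    assert np.all(long_range_fcd(g, s)[tuple(members.T)] == 0)


def test_remote_identical_blocks():
    """Two 4-voxel identical-signal blocks beyond adjacency: global = 7,
    short = 3, long = 4 at every member."""
    a = cube_indices((1, 1, 1), 2)[:4]
    b = cube_indices((6, 6, 6), 2)[:4]
    both = np.vstack([a, b])
    bold = planted_bold((9, 9, 9), [(both, 1.0)], T=60, seed=3)
    mask = full_mask((9, 9, 9))
    g = global_fcd(bold, mask)
    s = short_range_fcd(bold, mask)
    l = long_range_fcd(g, s)
    for p in map(tuple, both):
        assert (g[p], s[p], l[p]) == (7, 3, 4)


def test_orthogonal_series_zero_degree():
    """Mutually orthogonal sinusoids: no connections at all."""
    T = 64
    t = np.arange(T)
    data = np.zeros((4, 1, 1, T))
    for i in range(4):
        data[i, 0, 0] = np.sin(2 * np.pi * (i + 1) * t / T)
    bold = make_bold(data)
    g = global_fcd(bold, VolumeMask(np.ones((4, 1, 1), bool)))
    assert np.all(g == 0)


def test_growing_rule_blocks_uncorrelated_neighbor_and_distant_friend():
    """A spatially adjacent but uncorrelated voxel is never grown; a
    correlated but disconnected voxel counts only in global FCD."""
    center_blob = cube_indices((2, 2, 2), 2)  # 8 contiguous voxels
    distant = np.array([[7, 7, 7]])
    bold = planted_bold((9, 9, 9), [(np.vstack([center_blob, distant]), 1.0)], T=60, seed=4)
    mask = full_mask((9, 9, 9))
    g = global_fcd(bold, mask)
    s = short_range_fcd(bold, mask)
    p = (2, 2, 2)
    assert g[p] == 8  # 7 blob mates + the distant voxel
    assert s[p] == 7  # distant voxel not spatially reachable
    # neighbors of the blob (independent noise at T=60) are not grown
    assert long_range_fcd(g, s)[p] == 1


@pytest.mark.parametrize("seed", range(4))
def test_matches_bruteforce_oracle(seed):
    """Optimized chunked degree + component growing equals the naive
    O(N^2) + BFS oracle exactly on random masked fixtures."""
    rng = np.random.default_rng(seed)
    shape = (6, 6, 6)
    mask_arr = rng.random(shape) < 0.7
    mask_arr[3, 3, 3] = True
    mask = VolumeMask(mask_arr)
    blocks = [(cube_indices((1, 1, 1), 2), 0.95), (cube_indices((3, 3, 3), 2), 0.9)]
    bold = planted_bold(shape, blocks, T=60, seed=100 + seed)
    og, os_, ol = oracle_fcd(bold, mask, 0.6)
    g = global_fcd(bold, mask, chunk_size=37)
    s = short_range_fcd(bold, mask, chunk_size=37)
    np.testing.assert_array_equal(g, og)
    np.testing.assert_array_equal(s, os_)
    np.testing.assert_array_equal(long_range_fcd(g, s), ol)


def test_chunked_equals_full_matrix_path():
    bold = planted_bold((6, 6, 6), [(cube_indices((2, 2, 2), 2), 0.9)], T=80, seed=9)
    mask = full_mask((6, 6, 6))
    chunked = correlation_neighbors(bold, mask, 0.6, chunk_size=17)
    full = correlation_neighbors(bold, mask, 0.6, chunk_size=10**9)
    assert all(np.array_equal(a, b) for a, b in zip(chunked, full))


def test_threshold_monotonicity(rng):
    bold = planted_bold((5, 5, 5), [(cube_indices((1, 1, 1), 3), 0.7)], T=60, seed=11)
    mask = full_mask((5, 5, 5))
    lo = global_fcd(bold, mask, r_threshold=0.4)
    hi = global_fcd(bold, mask, r_threshold=0.6)
    assert np.all(lo >= hi)


def test_degree_equals_adjacency_row_sums():
    """The implied graph is undirected: degree = row sums of the oracle's
    thresholded correlation matrix."""
    bold = planted_bold((5, 5, 5), [(cube_indices((1, 1, 1), 2), 0.9)], T=60, seed=13)
    mask = full_mask((5, 5, 5))
    X = bold.data[mask.mask]
    R = np.corrcoef(X)
    A = (R > 0.6) & ~np.eye(len(R), dtype=bool)
    assert np.array_equal(A, A.T)
    np.testing.assert_array_equal(global_fcd(bold, mask)[mask.mask], A.sum(1))


def test_growing_order_independence():
    """The grown set is a fixed point: permuting the voxel ordering of the
    mask's flat indexing never changes any short-range count."""
    shape = (6, 6, 6)
    bold = planted_bold(shape, [(cube_indices((1, 1, 1), 3), 0.9)], T=60, seed=17)
    mask = full_mask(shape)
    ref = short_range_fcd(bold, mask)
    for perm_seed in range(3):
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(np.array(shape).prod()).reshape(shape)
        order = np.argsort(perm, axis=None)
        # re-grow each center after shuffling its neighbor list order
        neighbors = correlation_neighbors(bold, mask, 0.6)
        shuffled = [nb[rng.permutation(len(nb))] for nb in neighbors]
        from fcdpipe.fcd import _short_from_neighbors

        out = _short_from_neighbors(shuffled, mask, AdjacencySpec.connectivity(26), False)
        np.testing.assert_array_equal(out, ref)


def test_zero_variance_voxel_policies():
    data = np.random.default_rng(0).standard_normal((3, 3, 3, 40))
    data[0, 0, 0] = 5.0  # constant series
    bold = make_bold(data)
    mask = full_mask((3, 3, 3))
    with pytest.raises(ValueError, match="zero variance"):
        global_fcd(bold, mask)
    with pytest.warns(UserWarning):
        g = global_fcd(bold, mask, zero_variance="zero")
    assert g[0, 0, 0] == 0


def test_include_self_shifts_cancel_in_long_range():
    bold = planted_bold((6, 6, 6), [(cube_indices((2, 2, 2), 2), 0.9)], T=60, seed=19)
    mask = full_mask((6, 6, 6))
    cfg0 = FCDConfig(rescale=False, smooth=False)
    cfg1 = FCDConfig(rescale=False, smooth=False, include_self=True)
    m0 = compute_subject_fcd(bold, mask, cfg0)
    m1 = compute_subject_fcd(bold, mask, cfg1)
    np.testing.assert_array_equal(m1.raw_global, m0.raw_global + 1)
    np.testing.assert_array_equal(m1.raw_short, m0.raw_short + 1)
    np.testing.assert_array_equal(m1.raw_long, m0.raw_long)


class TestRescale:
    def test_constant_map_becomes_one(self):
        mask = full_mask((3, 3, 3))
        out = rescale_fcd(np.full((3, 3, 3), 5.0), mask)
        np.testing.assert_allclose(out[mask.mask], 1.0)

    def test_enumerated_values(self):
        m = np.zeros((4, 1, 1))
        m[:, 0, 0] = [1, 2, 3, 2]
        out = rescale_fcd(m, VolumeMask(np.ones((4, 1, 1), bool)))
        np.testing.assert_allclose(out[:, 0, 0], [0.5, 1.0, 1.5, 1.0])

    def test_random_map_mean_one(self, rng):
        m = rng.random((6, 6, 6)) + 0.1
        mask = VolumeMask(rng.random((6, 6, 6)) < 0.5)
        out = rescale_fcd(m, mask)
        assert out[mask.mask].mean() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rescale_fcd(np.zeros((3, 3, 3)), full_mask((3, 3, 3)))


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        m = rng.random((5, 5, 5))
        np.testing.assert_array_equal(smooth_map(m, 0.0, (3, 3, 3)), m)

    def test_impulse_peak_matches_kernel(self):
        """Unit impulse, 6 mm FWHM at 3 mm voxels: the central value equals
        the 3D Gaussian kernel's peak weight computed independently."""
        m = np.zeros((15, 15, 15))
        m[7, 7, 7] = 1.0
        out = smooth_map(m, 6.0, (3.0, 3.0, 3.0))
        sigma = 6.0 * FWHM_TO_SIGMA / 3.0
        ax = np.arange(-7, 8)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        assert out[7, 7, 7] == pytest.approx(k1[7] ** 3, rel=1e-6)

    def test_constant_map_preserved(self):
        m = np.full((6, 6, 6), 2.5)
        out = smooth_map(m, 6.0, (3, 3, 3), full_mask((6, 6, 6)))
        np.testing.assert_allclose(out, 2.5, atol=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((3, 3, 3)), -1.0, (3, 3, 3))


class TestDriver:
    def test_invariants_and_determinism(self):
        bold = planted_bold(
            (7, 7, 7),
            [(cube_indices((1, 1, 1), 2), 0.95), (np.array([[1, 1, 5], [5, 5, 1]]), 0.9)],
            T=80,
            seed=23,
        )
        mask = full_mask((7, 7, 7))
        cfg = FCDConfig()
        maps = compute_subject_fcd(bold, mask, cfg)
        assert np.all(maps.raw_short <= maps.raw_global)
        np.testing.assert_array_equal(maps.raw_long, maps.raw_global - maps.raw_short)
        for m in (maps.global_fcd, maps.short_fcd):
            assert np.isfinite(m).all()
        again = compute_subject_fcd(bold, mask, cfg)
        np.testing.assert_array_equal(maps.short_fcd, again.short_fcd)

    def test_rescaled_mean_is_one_before_smoothing(self):
        bold = planted_bold((6, 6, 6), [(cube_indices((2, 2, 2), 2), 0.9)], T=60, seed=29)
        mask = full_mask((6, 6, 6))
        maps = compute_subject_fcd(bold, mask, FCDConfig(smooth=False))
        assert maps.global_fcd[mask.mask].mean() == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_long_map_policies(self):
        # one contiguous block only: long-range counts vanish everywhere
        bold = planted_bold((6, 6, 6), [(cube_indices((2, 2, 2), 2), 1.0)], T=60, seed=31)
        mask = full_mask((6, 6, 6))
        with pytest.warns(UserWarning, match="all-zero"):
            maps = compute_subject_fcd(bold, mask, FCDConfig(smooth=False))
        assert np.all(maps.long_fcd == 0)
        with pytest.raises(ValueError):
            compute_subject_fcd(bold, mask, FCDConfig(smooth=False, empty_map_policy="error"))


class TestAdjacencySpec:
    def test_connectivity_counts(self):
        assert AdjacencySpec.connectivity(6).n_offsets == 6
        assert AdjacencySpec.connectivity(18).n_offsets == 18
        assert AdjacencySpec.connectivity(26).n_offsets == 26

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencySpec(((1, 0, 0),))
        with pytest.raises(ValueError, match="zero"):
            AdjacencySpec(((0, 0, 0), (1, 0, 0), (-1, 0, 0)))


def test_subject_maps_written_with_sidecar(tmp_path):
    bold = planted_bold((6, 6, 6), [(cube_indices((1, 1, 1), 2), 0.9),
                                    (np.array([[1, 4, 4], [4, 1, 1]]), 0.95)], T=60, seed=37)
    mask = full_mask((6, 6, 6))
    maps = compute_subject_fcd(bold, mask, FCDConfig())
    maps.save(tmp_path, "sub01", bold.voxel_size_mm)
    import json
    import nibabel as nib

    for suffix in ("gfcd", "sfcd", "lfcd"):
        img = nib.load(str(tmp_path / f"sub01_{suffix}.nii.gz"))
        assert img.shape == (6, 6, 6)
    sidecar = json.loads((tmp_path / "sub01_fcd.json").read_text())
    assert sidecar["r_threshold"] == 0.6
    assert sidecar["adjacency"] == "connectivity-26"
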