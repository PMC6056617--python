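"""Group inference: GLM closed forms, connection-radius enumeration, the
Monte-Carlo null simulation, extent thresholding and cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcdpipe import (
    AdjacencySpec,
    DesignMatrix,
    NullClusterDistribution,
    StatMap,
    VolumeMask,
    adjacency_from_radius,
    build_design_matrix,
    cluster_extent_threshold,
    extract_clusters,
    fit_voxelwise_glm,
    simulate_null_cluster_distribution,
)

from conftest import full_mask, oracle_flood_fill, oracle_two_sample_t


def group_design(n_a, n_b):
    g = np.r_[np.ones(n_a), np.zeros(n_b)]
    return DesignMatrix(np.column_stack([g, np.ones(n_a + n_b)]), ["group", "intercept"])


class TestGLM:
    def test_reduces_to_pooled_two_sample_t(self, rng):
        """Design = intercept + group: voxel-wise t equals the classic
        pooled two-sample t to 1e-8."""
        shape = (4, 4, 4)
        a = rng.standard_normal((12, *shape)) + 0.4
        b = rng.standard_normal((15, *shape))
        stat = fit_voxelwise_glm(np.concatenate([a, b]), group_design(12, 15), full_mask(shape))
        np.testing.assert_allclose(stat.t_values, oracle_two_sample_t(a, b), atol=1e-8)
        assert stat.df == 12 + 15 - 2

    def test_null_maps_give_small_centered_t(self, rng):
        shape = (6, 6, 6)
        maps = rng.standard_normal((40, *shape))
        table = pd.DataFrame(
            {
                "group": ["control"] * 20 + ["patient"] * 20,
                "age": rng.normal(50, 10, 40),
                "gender": ["M", "F"] * 20,
                "tiv": rng.normal(1.6, 0.16, 40),
            }
        )
        stat = fit_voxelwise_glm(maps, build_design_matrix(table), full_mask(shape))
        assert abs(stat.t_values.mean()) < 0.2
        assert np.abs(stat.t_values).max() < 6
        assert stat.df == 40 - 5

    def test_covariate_driven_difference_is_adjusted_away(self, rng):
        """Group difference fully generated by TIV: the group t collapses
        once TIV is in the model, but is large without it."""
        n = 40
        tiv = np.r_[rng.normal(1.7, 0.05, 20), rng.normal(1.5, 0.05, 20)]
        maps = (5.0 * tiv[:, None, None, None]) + 0.1 * rng.standard_normal((n, 3, 3, 3))
        table = pd.DataFrame(
            {"group": ["control"] * 20 + ["patient"] * 20, "tiv": tiv}
        )
        adj = fit_voxelwise_glm(maps, build_design_matrix(table, ("tiv",)), full_mask((3, 3, 3)))
        raw = fit_voxelwise_glm(maps, group_design(20, 20), full_mask((3, 3, 3)))
        assert np.abs(raw.t_values).min() > 5
        assert np.abs(adj.t_values).max() < adj.t_cutoff(0.01)

    def test_zero_variance_voxels_get_zero_t(self, rng):
        maps = np.zeros((10, 2, 2, 2))
        maps[:, 0, 0, 0] = rng.standard_normal(10)
        stat = fit_voxelwise_glm(maps, group_design(5, 5), full_mask((2, 2, 2)))
        assert stat.t_values[1, 1, 1] == 0.0
        assert np.isfinite(stat.t_values).all()

    def test_design_validation(self):
        with pytest.raises(ValueError, match="both levels"):
            DesignMatrix(np.column_stack([np.ones(6), np.ones(6)]), ["group", "intercept"])
        with pytest.raises(ValueError, match="rank"):
            g = np.r_[np.ones(3), np.zeros(3)]
            DesignMatrix(np.column_stack([g, 2 * g, np.ones(6)]), ["group", "x", "intercept"])


class TestAdjacencyFromRadius:
    @pytest.mark.parametrize(
        "radius,expected",
        [(5.0, 18), (3.0, 6), (5.2, 26)],
        ids=["r5mm", "r3mm", "r5.2mm"],
    )
    def test_offset_counts_at_3mm_isotropic(self, radius, expected):
        spec = adjacency_from_radius((3.0, 3.0, 3.0), radius)
        assert spec.n_offsets == expected
        # exhaustive distance enumeration oracle
        count = 0
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    if (i, j, k) != (0, 0, 0) and 3.0 * np.sqrt(i * i + j * j + k * k) <= radius:
                        count += 1
        assert count == expected

    def test_radius_below_voxel_rejected(self):
        with pytest.raises(ValueError, match="no neighbors"):
            adjacency_from_radius((3.0, 3.0, 3.0), 2.0)


class TestNullSimulation:
    def test_unsmoothed_suprathreshold_fraction_matches_voxel_p(self):
        """fwhm = 0: voxels are independent, so the two-sided suprathreshold
        fraction is binomial with mean voxel_p; check the simulation's own
        recorded counts within 3 binomial SD over all draws."""
        mask = full_mask((12, 12, 12))
        p, n_iter = 0.01, 200
        null = simulate_null_cluster_distribution(mask, 0.0, p, n_iter, seed=11)
        n_draws = mask.n_voxels * n_iter
        tol = 3 * np.sqrt(p * (1 - p) / n_draws)
        assert abs(null.suprathreshold_fraction(mask.n_voxels) - p) < tol

    def test_unattainable_threshold_gives_zero_clusters(self):
        mask = full_mask((6, 6, 6))
        null = simulate_null_cluster_distribution(mask, 0.0, 1e-9, 50, seed=3)
        assert (null.max_cluster_sizes == 0).mean() > 0.9

    def test_same_seed_identical(self):
        mask = full_mask((8, 8, 8))
        a = simulate_null_cluster_distribution(mask, 6.0, 0.01, 30, seed=9)
        b = simulate_null_cluster_distribution(mask, 6.0, 0.01, 30, seed=9)
        np.testing.assert_array_equal(a.max_cluster_sizes, b.max_cluster_sizes)

    def test_requires_seed_and_mask(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_null_cluster_distribution(full_mask((4, 4, 4)), 6.0, 0.01, 10)
        with pytest.raises(ValueError, match="empty"):
            simulate_null_cluster_distribution(
                VolumeMask(np.zeros((4, 4, 4), bool)), 6.0, 0.01, 10, seed=1
            )


class TestExtentThreshold:
    def null_of(self, sizes):
        return NullClusterDistribution(np.asarray(sizes), {})

    def test_all_zero_gives_one(self):
        assert cluster_extent_threshold(self.null_of([0] * 100)) == 1

    def test_uniform_1_to_100(self):
        """Sizes 1..100 once each at alpha=0.05: tail fraction at k=96 is
        exactly 5/100."""
        assert cluster_extent_threshold(self.null_of(range(1, 101)), 0.05) == 96

    def test_monotone_in_alpha(self):
        sizes = np.random.default_rng(0).integers(0, 50, 500)
        ks = [cluster_extent_threshold(self.null_of(sizes), a) for a in (0.01, 0.05, 0.1, 0.2)]
        assert ks == sorted(ks, reverse=True)

    def test_low_resolution_warns(self):
        with pytest.warns(UserWarning, match="iterations"):
            cluster_extent_threshold(self.null_of([0, 1, 2]), 0.05)


class TestExtractClusters:
    def toy_stat(self, df=30):
        t = np.zeros((8, 8, 8))
        blob = [(2, 2, 2), (3, 2, 2), (2, 3, 2), (2, 2, 3)]
        for p in blob:
            t[p] = 5.0
        t[2, 2, 2] = 6.0
        return StatMap(t, df), blob

    def test_single_blob_size_and_peak(self):
        stat, blob = self.toy_stat()
        table = extract_clusters(stat, 0.01, 3, AdjacencySpec.connectivity(18))
        assert len(table) == 1
        c = table.clusters[0]
        assert c.size == 4 and c.peak_ijk == (2, 2, 2) and c.peak_t == 6.0
        assert c.peak_mm == (6.0, 6.0, 6.0)
        assert c.sign > 0

    def test_extent_threshold_drops_blob(self):
        stat, _ = self.toy_stat()
        assert len(extract_clusters(stat, 0.01, 5, AdjacencySpec.connectivity(18))) == 0

    def test_negative_clusters_reported_separately(self):
        stat, blob = self.toy_stat()
        stat.t_values[(6, 6, 6)] = -5.0
        stat.t_values[(6, 6, 5)] = -5.5
        table = extract_clusters(stat, 0.01, 1, AdjacencySpec.connectivity(18))
        signs = sorted(c.sign for c in table.clusters)
        assert signs == [-1, 1]

    def test_bridge_connectivity_dialects(self):
        """Two blobs joined by an edge-neighbor bridge: one cluster under
        18-connectivity, two under 6-connectivity, matching a flood-fill
        oracle in both dialects."""
        t = np.zeros((6, 6, 6))
        t[1, 1, 1] = t[1, 1, 2] = 5.0
        t[2, 2, 2] = t[2, 2, 3] = 5.0  # touches (1,1,2) only diagonally (edge)
        stat = StatMap(t, 30)
        for conn, expected in ((18, 1), (6, 2)):
            adj = AdjacencySpec.connectivity(conn)
            table = extract_clusters(stat, 0.01, 1, adj)
            _, n_oracle = oracle_flood_fill(t > stat.t_cutoff(0.01), adj.offsets)
            assert len(table) == n_oracle == expected

    def test_labeling_matches_flood_fill_on_random_fields(self, rng):
        adj = AdjacencySpec.connectivity(26)
        for _ in range(5):
            t = rng.standard_normal((7, 7, 7)) * 3
            stat = StatMap(t, 25)
            table = extract_clusters(stat, 0.05, 1, adj)
            cut = stat.t_cutoff(0.05)
            _, npos = oracle_flood_fill(t > cut, adj.offsets)
            _, nneg = oracle_flood_fill(-t > cut, adj.offsets)
            assert len(table) == npos + nneg


def test_null_distribution_json_round_trip(tmp_path):
    mask = full_mask((8, 8, 8))
    null = simulate_null_cluster_distribution(mask, 6.0, 0.01, 25, seed=4)
    path = tmp_path / "null.json"
    null.to_json(path)
    back = NullClusterDistribution.from_json(path)
    np.testing.assert_array_equal(back.max_cluster_sizes, null.max_cluster_sizes)
    np.testing.assert_array_equal(back.supra_counts, null.supra_counts)
    assert back.params == null.params
    assert cluster_extent_threshold(back) == cluster_extent_threshold(null)
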