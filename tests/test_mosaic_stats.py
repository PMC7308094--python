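"""Regularity indices, SCNR, null models and significance tests."""

import numpy as np
import pandas as pd
import pytest

import conemosaic as cm
from conemosaic.mosaic_stats import (
    CSR_NNRI,
    MosaicSample,
    compute_search_radius,
    distribute_true_s,
    knn_count_map,
    nn_distances,
    nnri,
    null_ensemble,
    scnr,
    sample_metrics,
    shuffle_identities,
    significance_test,
    vdri,
    voronoi_cell_areas,
)


class TestSearchRadius:
    def test_one_mm_disk_example(self):
        # A = 785,398 μm², N = 10,000 → 3·√(785398/44428.8) = 12.61 μm
        assert compute_search_radius(785_398.0, 10_000) == pytest.approx(12.61, abs=0.01)

    def test_unit_case(self):
        n = 100
        assert compute_search_radius(np.sqrt(2) * np.pi * n, n) == pytest.approx(3.0)

    def test_quadrupling_n_halves_r(self):
        r1 = compute_search_radius(1e6, 500)
        r4 = compute_search_radius(1e6, 2000)
        assert r1 / r4 == pytest.approx(2.0)

    def test_zero_n_raises(self):
        with pytest.raises(ValueError):
            compute_search_radius(1e6, 0)


class TestKnnCountMap:
    def test_isolated_point(self):
        assert knn_count_map(np.array([[0.0, 0.0]]))[0] == 0

    def test_collinear_triplet(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        np.testing.assert_array_equal(knn_count_map(pts, 18.0), [1, 2, 1])

    def test_sparse_pattern_all_zero(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        assert knn_count_map(pts, 18.0).sum() == 0

    def test_against_brute_force(self):
        rng = np.random.default_rng(14)
        pts = rng.uniform(0, 300, size=(400, 2))
        counts = knn_count_map(pts, 18.0)
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        brute = ((d <= 18.0).sum(axis=1)) - 1
        np.testing.assert_array_equal(counts, brute)


class TestNnri:
    def test_hand_computed_triplet(self):
        # x = 0, 1, 2.5: NN distances (1, 1, 1.5), mean 7/6, sample SD
        # 0.28868 → NNRI = 4.0415
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0]])
        assert nnri(pts) == pytest.approx(4.0415, abs=1e-3)

    def test_perfect_lattice_flagged_infinite(self):
        gx, gy = np.mgrid[0:10, 0:10]
        pts = np.column_stack([gx.ravel() * 10.0, gy.ravel() * 10.0])
        assert np.isinf(nnri(pts))

    def test_csr_limit(self):
        # large Poisson pattern → 0.5·√(4π/(4−π)) ≈ 1.913
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 1000, size=(5000, 2))
        assert nnri(pts) == pytest.approx(CSR_NNRI, abs=0.05)

    def test_nn_distances_match_brute_force(self):
        rng = np.random.default_rng(16)
        pts = rng.uniform(0, 200, size=(300, 2))
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        np.testing.assert_allclose(nn_distances(pts), d.min(axis=1))


class TestVdri:
    def test_square_lattice_flagged(self):
        gx, gy = np.mgrid[0:12, 0:12]
        pts = np.column_stack([gx.ravel() * 10.0, gy.ravel() * 10.0])
        assert np.isinf(vdri(pts))

    def test_csr_limit_against_independent_geometry(self):
        # Poisson–Voronoi cell-area CV ≈ 0.53 → VDRI ≈ 1.9; cross-check the
        # areas against shapely's independent Voronoi construction
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 1000, size=(5000, 2))
        region = cm.Rect(0, 0, 1000, 1000)
        v = vdri(pts, region=region)
        assert v == pytest.approx(1.9, abs=0.1)

        from shapely.geometry import MultiPoint, Point, box
        from shapely.ops import voronoi_diagram

        sub = pts[:200]
        areas = voronoi_cell_areas(pts, region=region)
        cells = voronoi_diagram(MultiPoint([tuple(p) for p in pts]))
        lookup = list(cells.geoms)
        window = box(0, 0, 1000, 1000)
        checked = 0
        for i, p in enumerate(sub):
            if not np.isfinite(areas[i]):
                continue
            for cell in lookup:
                if cell.contains(Point(*p)):
                    if cell.within(window):
                        assert areas[i] == pytest.approx(cell.area, rel=1e-6)
                        checked += 1
                    break
            if checked >= 25:
                break
        assert checked >= 25

    def test_area_conservation(self):
        rng = np.random.default_rng(18)
        pts = rng.uniform(0, 500, size=(800, 2))
        region = cm.Rect(0, 0, 500, 500)
        areas = voronoi_cell_areas(pts, region=region)
        assert np.nansum(areas) <= region.area

    def test_too_few_cells_flagged(self):
        assert np.isnan(vdri(np.array([[0, 0], [1, 0], [0, 1]], dtype=float)))


class TestScnr:
    def _sample(self, pts, labels, radius=50.0):
        disk = cm.Disk(0, 0, 1000.0)
        s = MosaicSample(np.asarray(pts, float), np.asarray(labels, bool), disk)
        return s, radius

    def test_single_focal_ratio(self):
        # focal cone with 3 neighbours, 1 true S → 1/3
        pts = [[0, 0], [5, 0], [0, 5], [-5, 0], [500, 500]]
        labels = [False, True, False, False, False]
        s, r = self._sample(pts, labels)
        res = scnr(s, radius_um=10.0)
        assert res.per_cone.loc[0, "ratio"] == pytest.approx(1 / 3)

    def test_all_true_s_gives_unity(self, small_disk_mosaic):
        s = small_disk_mosaic.with_labels(np.ones(small_disk_mosaic.n_total, bool))
        res = scnr(s)
        assert np.allclose(res.per_cone["ratio"], 1.0)
        assert res.mean_true_s == pytest.approx(1.0)

    def test_shuffled_mean_matches_global_fraction(self, small_disk_mosaic):
        # random-chance prediction: mean SCNR ≈ true-S proportion
        rng = np.random.default_rng(19)
        means = []
        for _ in range(50):
            res = scnr(shuffle_identities(small_disk_mosaic, rng))
            means.append(res.mean_all)
        frac = small_disk_mosaic.n_true_s / small_disk_mosaic.n_total
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - frac) < 3 * se + 1e-3


class TestShuffleIdentities:
    def test_preserves_counts_and_positions(self, small_disk_mosaic):
        out = shuffle_identities(small_disk_mosaic, 21)
        assert out.n_true_s == small_disk_mosaic.n_true_s
        assert out.positions is small_disk_mosaic.positions

    def test_different_seeds_differ(self, small_disk_mosaic):
        a = shuffle_identities(small_disk_mosaic, 1)
        b = shuffle_identities(small_disk_mosaic, 2)
        assert not np.array_equal(a.is_true_s, b.is_true_s)


class TestDistributeTrueS:
    def test_k_equals_n_labels_everything(self, small_disk_mosaic):
        s = small_disk_mosaic.with_labels(np.ones(small_disk_mosaic.n_total, bool))
        out = distribute_true_s(s, n_iter=5)
        assert out.is_true_s.all()

    def test_k_one_valid(self, small_disk_mosaic):
        labels = np.zeros(small_disk_mosaic.n_total, bool)
        labels[0] = True
        out = distribute_true_s(small_disk_mosaic.with_labels(labels), n_iter=5)
        assert out.is_true_s.sum() == 1

    def test_labels_sit_on_real_positions_with_conserved_count(self, small_disk_mosaic):
        out = distribute_true_s(small_disk_mosaic, n_iter=100, rng=3)
        assert out.is_true_s.sum() == small_disk_mosaic.n_true_s
        assert out.positions is small_disk_mosaic.positions

    def test_four_points_spread_beats_shuffles(self):
        # K = 4 in a disk: repulsion + snap reaches a min pairwise distance
        # ≥ 99% of random label draws
        disk = cm.Disk(0, 0, 200.0)
        pts = cm.generate_positions(
            cm.MosaicSpec(retina_radius_um=200, density_profile=6000, seed=22), disk
        )
        labels = np.zeros(len(pts), bool)
        labels[:4] = True
        s = MosaicSample(pts, labels, disk)
        out = distribute_true_s(s, n_iter=300, rng=4)

        def min_pairwise(mask):
            p = pts[mask]
            d = np.hypot(*(p[:, None] - p[None, :]).transpose(2, 0, 1))
            np.fill_diagonal(d, np.inf)
            return d.min()

        rng = np.random.default_rng(23)
        draws = np.array(
            [min_pairwise(rng.permutation(labels)) for _ in range(1000)]
        )
        assert min_pairwise(out.is_true_s) >= np.quantile(draws, 0.99)


class TestNullEnsemble:
    def test_z_is_zero_at_ensemble_mean(self, small_disk_mosaic):
        ens = null_ensemble(small_disk_mosaic, "shuffled", n_sims=30, seed=24)
        fake = ens.values.mean()
        z = (fake - ens.mean) / ens.sd
        assert np.allclose(z, 0.0, atol=1e-12)

    def test_z_two_sd_above_mean(self, small_disk_mosaic):
        ens = null_ensemble(small_disk_mosaic, "shuffled", n_sims=30, seed=25)
        fake = ens.mean + 2 * ens.sd
        z = (fake - ens.mean) / ens.sd
        assert np.allclose(z, 2.0)

    def test_shuffled_metrics_pass_ks_normality(self, small_disk_mosaic):
        ens = null_ensemble(small_disk_mosaic, "shuffled", n_sims=100, seed=26)
        assert (ens.ks_normality() > 0.05).all()

    def test_nsims_below_two_rejected(self, small_disk_mosaic):
        with pytest.raises(ValueError):
            null_ensemble(small_disk_mosaic, "shuffled", n_sims=1)


class TestSignificance:
    def test_all_zero_is_boundary(self):
        t, p, sig = significance_test([0.0, 0.0, 0.0], "greater")
        assert p == pytest.approx(0.5) and not sig

    def test_hand_computed_t(self):
        # z = (3, 4, 5, 3.5): mean 3.875, SD 0.85391, t = 9.075, df 3
        t, p, sig = significance_test([3, 4, 5, 3.5], "greater")
        assert t == pytest.approx(9.075, abs=1e-3)
        assert p < 0.05 and sig

    def test_direction_reversal_symmetry(self):
        _, p_g, _ = significance_test([3, 4, 5, 3.5], "greater")
        _, p_l, _ = significance_test([3, 4, 5, 3.5], "less")
        assert p_g + p_l == pytest.approx(1.0)
        assert p_l > 0.95

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            significance_test([1.0], "greater")


class TestEdgeExclusion:
    def test_focal_set_respects_margin(self, small_disk_mosaic):
        s = small_disk_mosaic
        edge = s.disk.edge_distance(s.positions[:, 0], s.positions[:, 1])
        assert np.array_equal(s.focal, edge >= s.search_radius_um)
        assert s.n_excluded_edge > 0

    def test_excluded_cones_still_serve_as_neighbours(self):
        # a focal point whose only true-S neighbour is edge-excluded still
        # sees it in both NN distance and SCNR
        disk = cm.Disk(0, 0, 100.0)
        pts = np.array([[0.0, 0.0], [20.0, 0.0], [98.0, 0.0], [-30.0, 40.0]])
        s = MosaicSample(pts, np.array([True, False, True, False]), disk)
        s._build_neighbours(10.0)  # margin: only the cone 2 μm from the edge drops
        d = nn_distances(pts[s.is_true_s], s.focal[s.is_true_s])
        assert len(d) == 1  # the edge cone is not focal
        assert d[0] == pytest.approx(98.0)
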