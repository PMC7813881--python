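"""Synthetic liver tissue generation: veins, lobules, parenchyma packing."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from hepamet import tissue_gen as tg
from hepamet.params import ConfigurationError, Domain, ScenarioConfig, TissueParams


class TestPlaceCentralVeins:
    def test_mean_count_matches_density(self):
        """Over many seeds the mean CV count recovers density * area."""
        dom = Domain(10000.0, 10000.0)
        expected = 2e-6 * dom.area  # 200
        counts = [
            len(tg.place_central_veins(dom, 2e-6, seed)) for seed in range(100)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 1e-9

    def test_points_inside_domain_and_uniform(self):
        dom = Domain(2000.0, 1000.0)
        cvs = tg.place_central_veins(dom, 1e-4, 1)
        assert (cvs.points[:, 0] >= 0).all() and (cvs.points[:, 0] <= 2000).all()
        assert (cvs.points[:, 1] >= 0).all() and (cvs.points[:, 1] <= 1000).all()

    def test_zero_expected_count_gives_empty_set(self):
        cvs = tg.place_central_veins(Domain(10.0, 10.0), 1e-12, 0)
        assert len(cvs) == 0

    def test_deterministic_for_fixed_seed(self):
        dom = Domain(5000.0, 5000.0)
        a = tg.place_central_veins(dom, 2e-6, 7)
        b = tg.place_central_veins(dom, 2e-6, 7)
        np.testing.assert_array_equal(a.points, b.points)

    def test_negative_density_rejected(self):
        with pytest.raises(ConfigurationError):
            tg.place_central_veins(Domain(10.0, 10.0), -1.0, 0)


def _brute_force_merge(points: np.ndarray, min_sep: float) -> np.ndarray:
    """Independent oracle: repeated closest-pair midpoint replacement."""
    pts = [p.astype(float) for p in points]
    while len(pts) >= 2:
        best = (None, np.inf)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = float(np.linalg.norm(pts[i] - pts[j]))
                if d < best[1]:
                    best = ((i, j), d)
        if best[1] >= min_sep:
            break
        i, j = best[0]
        mid = 0.5 * (pts[i] + pts[j])
        pts = [p for k, p in enumerate(pts) if k not in (i, j)] + [mid]
    return np.asarray(pts)


class TestMergeClosePairs:
    def test_close_pair_replaced_by_midpoint(self):
        cvs = tg.CentralVeinSet(np.array([[0.0, 0.0], [100.0, 0.0]]), 1.0)
        merged = tg.merge_close_pairs(cvs, 400.0)
        np.testing.assert_allclose(merged.points, [[50.0, 0.0]])

    def test_distant_pair_unchanged(self):
        cvs = tg.CentralVeinSet(np.array([[0.0, 0.0], [1000.0, 0.0]]), 1.0)
        merged = tg.merge_close_pairs(cvs, 400.0)
        assert len(merged) == 2

    def test_collinear_cascade_matches_brute_force(self):
        pts = np.array([[0.0, 0.0], [350.0, 0.0], [700.0, 0.0]])
        merged = tg.merge_close_pairs(tg.CentralVeinSet(pts, 1.0), 400.0)
        oracle = _brute_force_merge(pts, 400.0)
        assert len(merged) == len(oracle)
        np.testing.assert_allclose(
            np.sort(merged.points, axis=0), np.sort(oracle, axis=0)
        )
        # postcondition holds regardless of the merge path
        if len(merged) >= 2:
            from scipy.spatial.distance import pdist

            assert pdist(merged.points).min() >= 400.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1500, size=(25, 2))
        merged = tg.merge_close_pairs(tg.CentralVeinSet(pts, 1.0), 300.0)
        oracle = _brute_force_merge(pts, 300.0)
        np.testing.assert_allclose(
            np.sort(merged.points, axis=0), np.sort(oracle, axis=0), atol=1e-9
        )

    def test_empty_input(self):
        merged = tg.merge_close_pairs(tg.CentralVeinSet(np.zeros((0, 2)), 1.0), 100.0)
        assert len(merged) == 0


class TestLobuleMap:
    def test_two_cvs_split_by_bisector(self):
        dom = Domain(1000.0, 1000.0)
        cvs = tg.CentralVeinSet(np.array([[250.0, 500.0], [750.0, 500.0]]), 1.0)
        lob = tg.build_lobule_map(cvs, dom)
        areas = lob.areas()
        np.testing.assert_allclose(areas, [5e5, 5e5], rtol=1e-9)
        assert lob.region_index([[100.0, 100.0]])[0] == 0
        assert lob.region_index([[900.0, 900.0]])[0] == 1

    def test_single_cv_region_is_whole_domain(self):
        dom = Domain(300.0, 200.0)
        lob = tg.build_lobule_map(
            tg.CentralVeinSet(np.array([[150.0, 100.0]]), 1.0), dom
        )
        assert len(lob.polygons) == 1
        np.testing.assert_allclose(lob.areas()[0], dom.area)

    def test_nearest_cv_agrees_with_polygon_membership(self):
        """Monte-Carlo partition check against a point-in-polygon oracle."""
        dom = Domain(10000.0, 10000.0)
        cvs = tg.place_central_veins(dom, 2e-6, 5)
        lob = tg.build_lobule_map(cvs, dom)
        rng = np.random.default_rng(0)
        queries = rng.uniform(50, 9950, size=(1000, 2))
        nearest = lob.region_index(queries)
        for q, idx in zip(queries, nearest):
            poly = MplPath(lob.polygons[idx])
            assert poly.contains_point(q, radius=1e-6) or poly.contains_point(
                q, radius=-1e-6
            )

    def test_region_areas_partition_domain(self):
        dom = Domain(10000.0, 10000.0)
        cvs = tg.place_central_veins(dom, 2e-6, 9)
        lob = tg.build_lobule_map(cvs, dom)
        np.testing.assert_allclose(lob.areas().sum(), dom.area, rtol=1e-6)

    def test_interior_lobule_diameter_near_800_um(self):
        """Density 2e-6/um^2 with pair merging gives ~800 um lobules."""
        dom = Domain(10000.0, 10000.0)
        diams = []
        for seed in range(5):
            cvs = tg.place_central_veins(dom, 2e-6, seed)
            cvs = tg.merge_close_pairs(cvs, TissueParams().min_separation)
            lob = tg.build_lobule_map(cvs, dom)
            diams.append(lob.equivalent_diameters()[lob.interior].mean())
        assert abs(np.mean(diams) - 800.0) / 800.0 < 0.10


def _enumerate_hex_lattice(width, height, spacing):
    """Independent lattice oracle for the parenchyma packing."""
    dy = spacing * np.sqrt(3) / 2
    pts = []
    j = 0
    y = 0.0
    while y <= height + 1e-9:
        x = 0.5 * spacing if j % 2 else 0.0
        while x <= width + 1e-9:
            pts.append((x, y))
            x += spacing
        j += 1
        y = j * dy
    return np.asarray(pts)


class TestPackParenchyma:
    def test_lattice_matches_direct_enumeration(self):
        dom = Domain(100.0, 100.0)
        layout = tg.pack_parenchyma(dom, None, radius=15.0, spacing=30.0,
                                    cv_exclusion_radius=26.5)
        oracle = _enumerate_hex_lattice(100.0, 100.0, 30.0)
        assert len(layout) == len(oracle)
        got = layout.positions[np.lexsort(layout.positions.T)]
        want = oracle[np.lexsort(oracle.T)]
        np.testing.assert_allclose(got, want)

    def test_rows_are_offset(self):
        layout = tg.pack_parenchyma(Domain(100.0, 100.0), None, 15.0, 30.0, 0.0)
        ys = np.unique(np.round(layout.positions[:, 1], 6))
        row0 = layout.positions[np.isclose(layout.positions[:, 1], ys[0])][:, 0]
        row1 = layout.positions[np.isclose(layout.positions[:, 1], ys[1])][:, 0]
        assert np.isclose(row1.min() - row0.min(), 15.0)

    def test_domain_inside_exclusion_disk_is_empty(self):
        dom = Domain(40.0, 40.0)
        cvs = tg.CentralVeinSet(np.array([[20.0, 20.0]]), 1.0)
        lob = tg.build_lobule_map(cvs, dom)
        layout = tg.pack_parenchyma(dom, lob, 15.0, 30.0, cv_exclusion_radius=100.0)
        assert len(layout) == 0

    def test_cv_exclusion_removes_points(self):
        dom = Domain(200.0, 200.0)
        cvs = tg.CentralVeinSet(np.array([[100.0, 100.0]]), 1.0)
        lob = tg.build_lobule_map(cvs, dom)
        free = tg.pack_parenchyma(dom, lob, 15.0, 30.0, 0.0)
        excl = tg.pack_parenchyma(dom, lob, 15.0, 30.0, 40.0)
        assert len(excl) < len(free)
        d = np.linalg.norm(excl.positions - [100.0, 100.0], axis=1)
        assert (d >= 40.0).all()

    def test_overlap_warning(self):
        with pytest.warns(UserWarning):
            tg.pack_parenchyma(Domain(100.0, 100.0), None, 15.0, 10.0, 0.0)


class TestGenerateTissue:
    def test_deterministic_for_fixed_seed(self, small_config):
        a = tg.generate_tissue(small_config)
        b = tg.generate_tissue(small_config)
        np.testing.assert_array_equal(a.cvs.points, b.cvs.points)
        np.testing.assert_array_equal(a.parenchyma.positions, b.parenchyma.positions)

    def test_different_seeds_differ(self):
        import dataclasses

        cfg = ScenarioConfig(domain=Domain(5000.0, 5000.0), seed=1)
        other = dataclasses.replace(cfg, seed=2)
        a, b = tg.generate_tissue(cfg), tg.generate_tissue(other)
        assert a.cvs.points.shape != b.cvs.points.shape or not np.allclose(
            a.cvs.points, b.cvs.points
        )

    def test_zero_density_gives_uniform_parenchyma(self):
        cfg = ScenarioConfig(
            domain=Domain(500.0, 500.0),
            tissue=TissueParams(cv_density=0.0),
            seed=0,
        )
        tissue = tg.generate_tissue(cfg)
        assert len(tissue.cvs) == 0
        assert tissue.lobules is None
        assert len(tissue.parenchyma) > 0

    def test_roundtrip_io(self, small_tissue, tmp_path):
        tg.write_tissue(small_tissue, tmp_path)
        back = tg.read_tissue(tmp_path)
        np.testing.assert_allclose(back.cvs.points, small_tissue.cvs.points)
        np.testing.assert_allclose(
            back.parenchyma.positions, small_tissue.parenchyma.positions
        )
        assert back.seed == small_tissue.seed
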