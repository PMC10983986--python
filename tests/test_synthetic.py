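"""Generator geometry, planted-truth recovery, determinism."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from lsgi.factorization import factorize, top_genes
from lsgi.gradient import build_windows, filter_gradients, fit_all
from lsgi.synthetic import (
    PlantedGradient,
    PlantedTruth,
    make_default_slide,
    opposed_pair,
    plant_gradients,
    plant_tumor_region,
    simulate_counts,
    simulate_layout,
)


class TestSimulateLayout:
    def test_hex_seven_spots_center_plus_ring(self):
        coords = simulate_layout(25, layout="hex", pitch=2.0)[:7]
        center = coords[0]
        d = np.linalg.norm(coords[1:] - center, axis=1)
        np.testing.assert_allclose(d, 2.0, atol=1e-9)

    def test_square_lattice_is_exact_grid(self):
        coords = simulate_layout(100, layout="square", pitch=1.0)
        assert coords.shape == (100, 2)
        xs = np.unique(coords[:, 0])
        ys = np.unique(coords[:, 1])
        assert len(xs) == 10 and len(ys) == 10

    def test_interior_nearest_neighbor_distance_constant(self):
        coords = simulate_layout(400, layout="hex", pitch=1.5)
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        d, _ = tree.query(coords, k=2)
        centroid = coords.mean(axis=0)
        interior = np.linalg.norm(coords - centroid, axis=1) < 0.6 * np.linalg.norm(
            coords - centroid, axis=1).max()
        np.testing.assert_allclose(d[interior, 1], 1.5, atol=1e-9)


class TestPlantGradients:
    def _truth(self, sigma=0.0, slope=0.3, theta=0.4):
        return PlantedTruth(
            gradients=[PlantedGradient(0, (0.0, 0.0), 6.0, theta, slope,
                                       intercept=3.0, sigma=sigma)],
            n_programs=2, baseline_sigma=0.0, baseline_mean=0.1, seed=0)

    def test_noiseless_region_is_exactly_planar(self):
        coords = simulate_layout(900, layout="hex", pitch=1.0)
        coords = coords - coords.mean(axis=0)
        truth = self._truth()
        W = plant_gradients(coords, truth)
        inside = truth.in_region(coords, truth.gradients[0])
        rel = coords[inside]
        expected = 3.0 + 0.3 * (rel[:, 0] * math.cos(0.4) + rel[:, 1] * math.sin(0.4))
        np.testing.assert_allclose(W[inside, 0], expected, atol=1e-12)

    def test_noiseless_window_fit_recovers_angle_exactly(self):
        coords = simulate_layout(900, layout="hex", pitch=1.0)
        coords = coords - coords.mean(axis=0)
        truth = self._truth()
        W = plant_gradients(coords, truth)
        windows = build_windows(coords, S=5, Q=25, seed=0)
        g = truth.gradients[0]
        for w in windows:
            if np.linalg.norm(coords[w.members] - np.array(g.center),
                              axis=1).max() < g.radius:
                fits = fit_all(W[:, :1], [w], coords)
                assert fits["r2"].iloc[0] > 1 - 1e-9
                angle = math.atan2(fits["dy"].iloc[0], fits["dx"].iloc[0])
                assert abs((angle - g.theta + math.pi) % (2 * math.pi) - math.pi) < 1e-6

    def test_opposed_pair_recovered_180_apart(self):
        coords = simulate_layout(900, layout="hex", pitch=1.0)
        coords = coords - coords.mean(axis=0)
        truth = PlantedTruth(
            gradients=opposed_pair((0.0, 0.0), 6.0, 0.9, 0.3, intercept=3.0,
                                   sigma=0.05),
            n_programs=2, baseline_sigma=0.02, baseline_mean=0.1, seed=0)
        W = plant_gradients(coords, truth)
        windows = build_windows(coords, S=5, Q=25, seed=0)
        # windows fully inside the planted disk see the pure planar field
        inside_ids = [
            w.grid_id for w in windows
            if np.linalg.norm(coords[w.members], axis=1).max() < 6.0]
        assert inside_ids
        fits = fit_all(W, windows, coords)
        gmap = filter_gradients(fits, windows)
        angles = {}
        for prog in (0, 1):
            sub = gmap.passing[(gmap.passing["program"] == prog)
                               & gmap.passing["grid_id"].isin(inside_ids)]
            assert len(sub) > 0
            angles[prog] = np.arctan2(sub["dy"].mean(), sub["dx"].mean())
        sep = abs((angles[0] - angles[1] + math.pi) % (2 * math.pi) - math.pi)
        assert abs(sep - math.pi) < math.radians(5)

    def test_flat_program_never_retained(self):
        retained_counts = 0
        for seed in range(10):
            coords = simulate_layout(600, layout="hex", pitch=1.0, seed=seed)
            truth = PlantedTruth(gradients=[], n_programs=3,
                                 baseline_sigma=0.05, baseline_mean=0.5,
                                 seed=seed)
            W = plant_gradients(coords, truth)
            windows = build_windows(coords, S=5, Q=25, seed=seed)
            gmap = filter_gradients(fit_all(W, windows, coords), windows)
            retained_counts += len(gmap.retained)
        assert retained_counts == 0


class TestSimulateCounts:
    def test_same_seed_identical_counts(self, rng):
        W = rng.uniform(0, 1, (50, 3))
        c1, H1 = simulate_counts(W, G=30, seed=5)
        c2, H2 = simulate_counts(W, G=30, seed=5)
        assert (c1 != c2).nnz == 0
        np.testing.assert_array_equal(H1, H2)

    def test_large_depth_nmf_recovers_planted_loadings(self, rng):
        W0 = rng.uniform(0.2, 1.0, (150, 3))
        W0[:50, 0] *= 4
        W0[50:100, 1] *= 4
        W0[100:, 2] *= 4
        counts, H0 = simulate_counts(W0, G=60, seed=0, depth=50000)
        model = factorize(np.asarray(counts.todense(), float), k=3, seed=0,
                          max_iter=1500, tol=1e-10)
        C = np.corrcoef(np.hstack([W0, model.W]).T)[:3, 3:]
        assert (C.max(axis=1) > 0.9).all()

    def test_top_genes_land_in_true_support(self, rng):
        W0 = np.zeros((90, 3))
        W0[:30, 0] = rng.uniform(1, 2, 30)
        W0[30:60, 1] = rng.uniform(1, 2, 30)
        W0[60:, 2] = rng.uniform(1, 2, 30)
        counts, H0 = simulate_counts(W0, G=6, seed=0, depth=20000)
        model = factorize(np.asarray(counts.todense(), float), k=3, seed=0,
                          max_iter=1500, tol=1e-10,
                          gene_ids=[f"g{j}" for j in range(6)])
        C = np.corrcoef(np.hstack([W0, model.W]).T)[:3, 3:]
        for true_j in range(3):
            fit_j = int(C[true_j].argmax())
            support = {f"g{g}" for g in np.flatnonzero(H0[true_j] > 0)}
            sig = top_genes(model, fit_j, n=2)
            assert set(sig.genes) <= support


class TestPlantTumorRegion:
    def test_disk_covering_whole_slide(self):
        coords = simulate_layout(100, layout="square", pitch=1.0)
        flags = plant_tumor_region(coords, coords.mean(axis=0), radius=1e3)
        assert flags.all()
        windows = build_windows(coords, S=5, Q=25, seed=0)
        from lsgi.spatial_stats import window_tumor_ratio

        assert (window_tumor_ratio(windows, flags) == 1.0).all()

    def test_disk_covering_nothing(self):
        coords = simulate_layout(100, layout="square", pitch=1.0)
        flags = plant_tumor_region(coords, (1e6, 1e6), radius=1.0)
        assert not flags.any()

    def test_half_plane_boundary_windows_intermediate(self):
        coords = simulate_layout(900, layout="hex", pitch=1.0)
        center_x = coords[:, 0].mean()
        flags = coords[:, 0] <= center_x  # half-plane via x threshold
        windows = build_windows(coords, S=5, Q=25, seed=0)
        from lsgi.spatial_stats import window_tumor_ratio

        ratios = window_tumor_ratio(windows, flags)
        for w in windows:
            if abs(w.grid_xy[0] - center_x) < 1.0:
                r = ratios.loc[w.grid_id]
                assert 0.2 < r < 0.8


class TestTruthSerialization:
    def test_json_round_trip(self, tmp_path):
        _, truth, _, _ = make_default_slide(seed=3, n_spots=200, G=30,
                                            with_counts=False)
        truth.to_json(tmp_path / "truth.json")
        back = PlantedTruth.from_json(tmp_path / "truth.json")
        assert back == truth


class TestDefaultSlideEndToEnd:
    def test_planted_programs_retained_and_localized(self):
        # pipeline from planted loadings: exact program retention across seeds
        exact, localized = 0, 0
        for seed in range(10):
            ds, truth, W_true, _ = make_default_slide(seed=seed, with_counts=False)
            windows = build_windows(ds.coords, S=5, Q=25, seed=seed)
            gmap = filter_gradients(fit_all(W_true, windows, ds.coords), windows)
            exact += gmap.retained == [0, 1, 2]
            xy = gmap.passing[["x", "y"]].to_numpy()
            inreg = np.zeros(len(xy), dtype=bool)
            for g in truth.gradients:
                inreg |= np.linalg.norm(xy - np.asarray(g.center),
                                        axis=1) <= g.radius * 1.3
            localized += inreg.mean() >= 0.8
        assert exact >= 8
        assert localized >= 8
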