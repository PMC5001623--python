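"""Multi-layer engine: counting field, combined energy, init, descent."""

import numpy as np
import pytest

from mlgoc.engine import (
    MultiLayerPhaseField,
    SegmentationConfig,
    assign_seeds_to_layers,
    evolve,
    neutral_init,
    overlap_penalty,
    overlap_penalty_gradient,
    phi_plus,
    seeded_init,
    segment_image,
    total_energy,
    total_gradient,
)
from mlgoc.goc import render_circle_field
from mlgoc.intensity import ImageFormationParams, data_energy
from mlgoc.goc import geometric_energy

from conftest import calibrated


class TestPhiPlus:
    def test_phase_values(self):
        shape = (3, 6, 6)
        layers = np.full(shape, -1.0)
        assert np.all(phi_plus(layers) == 0.0)
        layers[0] = 1.0
        assert np.all(phi_plus(layers) == 1.0)
        layers[1] = 1.0
        assert np.all(phi_plus(layers) == 2.0)


class TestOverlapPenalty:
    def test_no_pairs_and_empty_foreground(self):
        assert overlap_penalty(np.full((1, 8, 8), 0.7)) == 0.0
        assert overlap_penalty(np.full((3, 8, 8), -1.0)) == 0.0

    def test_two_full_layers(self):
        layers = np.full((2, 5, 4), 1.0)
        assert overlap_penalty(layers) == 20.0  # one pair, 1 per pixel

    def test_gradient_finite_difference(self, rng):
        layers = rng.uniform(-1.0, 1.0, (3, 10, 10))
        g = overlap_penalty_gradient(layers)
        h = 1e-6
        d = rng.normal(size=layers.shape)
        fd = (overlap_penalty(layers + h * d) - overlap_penalty(layers - h * d)) / (2 * h)
        assert float(np.sum(g * d)) == pytest.approx(fd, rel=1e-6)


class TestTotalEnergyGradient:
    def test_additivity(self, small_goc, small_kernel, imaging_basic, rng):
        layers = rng.uniform(-0.9, 0.9, (2, 20, 20))
        img = rng.uniform(30.0, 230.0, (20, 20))
        cfg = SegmentationConfig(n_layers=2, gamma_d=0.8, overlap_weight=0.0)
        e = total_energy(layers, img, small_goc, small_kernel, imaging_basic, cfg)
        e_geo = sum(geometric_energy(l, small_goc, small_kernel) for l in layers)
        e_dat = data_energy(phi_plus(layers), img, imaging_basic, 0.8)
        assert e == pytest.approx(e_geo + e_dat, rel=1e-12)

    def test_single_layer_reduction(self, small_goc, small_kernel, imaging_basic, rng):
        layer = rng.uniform(-0.9, 0.9, (1, 16, 16))
        img = rng.uniform(30.0, 230.0, (16, 16))
        cfg = SegmentationConfig(n_layers=1, gamma_d=0.5)
        e = total_energy(layer, img, small_goc, small_kernel, imaging_basic, cfg)
        expected = geometric_energy(layer[0], small_goc, small_kernel) + data_energy(
            phi_plus(layer), img, imaging_basic, 0.5
        )
        assert e == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("log_term", [True, False])
    @pytest.mark.parametrize("ow", [0.0, 1.0])
    def test_gradient_finite_difference(self, small_goc, small_kernel, imaging_basic, rng, log_term, ow):
        layers = rng.uniform(-0.9, 0.9, (2, 24, 24))
        img = rng.uniform(30.0, 230.0, (24, 24))
        cfg = SegmentationConfig(
            n_layers=2, gamma_d=0.7, overlap_weight=ow, include_log_term=log_term
        )
        g = total_gradient(layers, img, small_goc, small_kernel, imaging_basic, cfg)
        h = 1e-6
        for _ in range(20):
            d = rng.normal(size=layers.shape)
            ep = total_energy(layers + h * d, img, small_goc, small_kernel, imaging_basic, cfg)
            em = total_energy(layers - h * d, img, small_goc, small_kernel, imaging_basic, cfg)
            assert float(np.sum(g * d)) == pytest.approx((ep - em) / (2 * h), rel=1e-4)

    def test_layer_swap_symmetry(self, small_goc, small_kernel, imaging_basic, rng):
        layers = rng.uniform(-0.9, 0.9, (3, 12, 12))
        img = rng.uniform(30.0, 230.0, (12, 12))
        cfg = SegmentationConfig(n_layers=3, gamma_d=0.5, overlap_weight=0.0)
        g = total_gradient(layers, img, small_goc, small_kernel, imaging_basic, cfg)
        swapped = layers[[0, 2, 1]]
        g2 = total_gradient(swapped, img, small_goc, small_kernel, imaging_basic, cfg)
        np.testing.assert_allclose(g[0], g2[0], rtol=1e-12)

    def test_grid_mismatch(self, small_goc, small_kernel, imaging_basic):
        cfg = SegmentationConfig(n_layers=1)
        with pytest.raises(ValueError):
            total_energy(np.zeros((1, 8, 8)), np.zeros((9, 9)), small_goc, small_kernel, imaging_basic, cfg)


class TestNeutralInit:
    def test_mean_and_determinism(self, small_goc):
        cfg = SegmentationConfig(n_layers=2, rng_seed=7, noise_sd=0.01)
        f1 = neutral_init((400, 400), cfg, small_goc)
        f2 = neutral_init((400, 400), cfg, small_goc)
        np.testing.assert_array_equal(f1.layers, f2.layers)
        target = small_goc.alpha_f / small_goc.lambda_f
        se = 0.01 / 400.0  # sd / sqrt(400*400)
        assert abs(f1.layers[0].mean() - target) <= 3 * se
        # independent layers
        assert not np.array_equal(f1.layers[0], f1.layers[1])

    def test_mean_override(self, small_goc):
        cfg = SegmentationConfig(n_layers=1, rng_seed=0, noise_mean=-0.5, noise_sd=0.01)
        f = neutral_init((100, 100), cfg, small_goc)
        assert abs(f.layers.mean() + 0.5) < 0.01


class TestSeededInit:
    def test_disk_membership(self):
        cfg = SegmentationConfig(n_layers=2, init_mode="seeded")
        r_hat = 16.0
        f = seeded_init((64, 64), cfg, [(32, 32)], r_hat)
        # distance r_hat/2 - 1 inside, r_hat/2 + 1 outside
        assert f.layers[:, 32, 32 + int(r_hat / 2 - 1)].max() == 1.0
        assert f.layers[:, 32, 32 + int(r_hat / 2 + 1)].max() == 0.0

    def test_conflicting_seeds_in_different_layers(self):
        cfg = SegmentationConfig(n_layers=2, init_mode="seeded")
        r_hat = 10.0
        f = seeded_init((64, 64), cfg, [(20, 32), (30, 32)], r_hat)  # distance r_hat
        # each seed's disk lives in its own layer
        layers_at_seeds = {
            int(np.argmax(f.layers[:, 32, 20])),
            int(np.argmax(f.layers[:, 32, 30])),
        }
        assert layers_at_seeds == {0, 1}
        assert f.layers[0, 32, 20] == 1.0 and f.layers[1, 32, 20] == 0.0 or (
            f.layers[1, 32, 20] == 1.0 and f.layers[0, 32, 20] == 0.0
        )

    def test_seed_outside_grid(self):
        cfg = SegmentationConfig(n_layers=1, init_mode="seeded")
        with pytest.raises(ValueError):
            seeded_init((32, 32), cfg, [(40, 10)], 8.0)


class TestAssignSeeds:
    @staticmethod
    def _conflicts(seeds, assignment, r_hat, factor=2.5):
        pts = np.asarray(seeds, dtype=float)
        n = len(pts)
        c = 0
        for i in range(n):
            for j in range(i + 1, n):
                if (
                    np.hypot(*(pts[i] - pts[j])) <= factor * r_hat + 0.5
                    and assignment[i] == assignment[j]
                ):
                    c += 1
        return c

    def test_far_seeds_share_layer_zero(self):
        seeds = [(0, 0), (300, 0), (0, 300)]
        a = assign_seeds_to_layers(seeds, 10.0, 4)
        assert list(a) == [0, 0, 0]

    @pytest.mark.parametrize("n_layers,expected_conflicts", [(3, 0), (2, 1)])
    def test_clique_matches_bruteforce(self, n_layers, expected_conflicts):
        """Brute-force optimum over all layer assignments of a 3-clique."""
        seeds = [(0, 0), (10, 0), (5, 8)]
        r_hat = 10.0
        a = assign_seeds_to_layers(seeds, r_hat, n_layers)
        got = self._conflicts(seeds, a, r_hat)
        import itertools

        best = min(
            self._conflicts(seeds, assign, r_hat)
            for assign in itertools.product(range(n_layers), repeat=3)
        )
        assert best == expected_conflicts
        assert got == best
        if n_layers == 2:
            with pytest.warns(UserWarning):
                assign_seeds_to_layers(seeds, r_hat, n_layers)


@pytest.fixture(scope="module")
def circle_setup():
    goc = calibrated(15.0)
    from mlgoc.goc import build_interaction_kernel

    kernel = build_interaction_kernel(goc.d, goc.epsilon)
    imaging = ImageFormationParams(40.0, 1.0, 60.0, 0.0)
    truth = render_circle_field((80, 80), (40, 40), 15.0, supersample=1) >= 0
    img = np.where(truth, 100.0, 40.0)
    return goc, kernel, imaging, img, truth


class TestEvolve:

    def test_noiseless_circle_recovery(self, circle_setup):
        goc, kernel, imaging, img, truth = circle_setup
        cfg = SegmentationConfig(n_layers=1, gamma_d=1.0, init_mode="seeded", max_iter=500)
        field, inst, diag = segment_image(img, goc, imaging, cfg, seeds=[(40, 40)])
        assert len(inst) == 1
        inter = np.count_nonzero(inst.masks[0] & truth)
        union = np.count_nonzero(inst.masks[0] | truth)
        assert inter / union >= 0.9
        assert np.abs(field.layers).max() <= 1.5  # sanity bound at convergence

    def test_energy_trace_non_increasing(self, circle_setup, rng):
        goc, kernel, imaging, img, _ = circle_setup
        cfg = SegmentationConfig(n_layers=2, gamma_d=0.5, max_iter=60, rng_seed=3)
        f0 = neutral_init(img.shape, cfg, goc)
        _, diag = evolve(f0, img, goc, kernel, imaging, cfg)
        tr = np.array(diag.energy_trace)
        assert np.all(np.diff(tr) <= 1e-9)

    def test_restart_at_converged_state_terminates_quickly(self, circle_setup):
        goc, kernel, imaging, img, _ = circle_setup
        cfg = SegmentationConfig(n_layers=1, gamma_d=1.0, init_mode="seeded", max_iter=800)
        f = seeded_init(img.shape, cfg, [(40, 40)], goc.r_hat)
        f1, d1 = evolve(f, img, goc, kernel, imaging, cfg)
        assert d1.converged
        f2, d2 = evolve(f1, img, goc, kernel, imaging, cfg)
        assert d2.converged and d2.iterations <= 10
        assert d2.energy_trace[-1] == pytest.approx(d1.energy_trace[-1], rel=1e-9)

    def test_converged_gradient_is_small(self, circle_setup):
        goc, kernel, imaging, img, _ = circle_setup
        cfg = SegmentationConfig(
            n_layers=1, gamma_d=1.0, init_mode="seeded", max_iter=3000, tol=1e-12
        )
        f = seeded_init(img.shape, cfg, [(40, 40)], goc.r_hat)
        f1, _ = evolve(f, img, goc, kernel, imaging, cfg)
        g = total_gradient(f1, img, goc, kernel, imaging, cfg)
        assert np.abs(g).max() < 1e-3


class TestSegmentImage:
    def test_blank_image_gives_empty_instances(self):
        goc = calibrated(15.0)
        imaging = ImageFormationParams(40.0, 25.0, 60.0, 0.0)
        cfg = SegmentationConfig(n_layers=3, gamma_d=0.1, max_iter=200, rng_seed=2)
        _, inst, _ = segment_image(np.full((100, 100), 40.0), goc, imaging, cfg)
        assert len(inst) == 0

    def test_two_overlapping_circles_seeded(self):
        goc = calibrated(15.0)
        from mlgoc.synthetic import ShapeInstance, SceneSpec, render_clean

        imaging = ImageFormationParams(40.0, 1.0, 60.0, 0.0)
        shapes = [
            ShapeInstance("circle", (45, 60), (15.0,)),
            ShapeInstance("circle", (70, 60), (15.0,)),  # ~20% overlap
        ]
        img = render_clean(SceneSpec(size=(120, 120), shapes=shapes, imaging=imaging)).astype(float)
        cfg = SegmentationConfig(n_layers=2, gamma_d=1.0, init_mode="seeded", max_iter=500)
        _, inst, _ = segment_image(img, goc, imaging, cfg, seeds=[(45, 60), (70, 60)])
        assert len(inst) == 2
        assert sorted(inst.layer_of) == [0, 1]

    def test_determinism(self):
        goc = calibrated(15.0)
        imaging = ImageFormationParams(40.0, 25.0, 60.0, 0.0)
        rng = np.random.default_rng(5)
        img = np.full((64, 64), 40.0) + rng.normal(0, 5, (64, 64))
        cfg = SegmentationConfig(n_layers=2, gamma_d=0.3, max_iter=100, rng_seed=11)
        f1, i1, _ = segment_image(img, goc, imaging, cfg)
        f2, i2, _ = segment_image(img, goc, imaging, cfg)
        np.testing.assert_array_equal(f1.layers, f2.layers)
        assert len(i1) == len(i2)

    def test_seeded_requires_seeds(self):
        goc = calibrated(15.0)
        imaging = ImageFormationParams(40.0, 25.0, 60.0, 0.0)
        cfg = SegmentationConfig(init_mode="seeded")
        with pytest.raises(ValueError, match="seeds"):
            segment_image(np.full((32, 32), 40.0), goc, imaging, cfg)
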