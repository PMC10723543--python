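"""Manifold capacity (mean-field and simulation), PR, correlations, EV dims."""

import numpy as np
import pytest

from retwave import (Encoder, EncoderSpec, ManifoldSet, WaveSimParams,
                     build_translation_manifolds, build_wave_event_manifolds,
                     center_correlation, explained_variance_dims,
                     extract_activations, meanfield_geometry,
                     participation_ratio, simulation_capacity, simulate_waves,
                     extract_events)
from retwave.geometry import _is_separable


def data_with_eigenvalues(eigs, n_samples=200, seed=0):
    """Samples whose feature covariance has exactly the given eigenvalues."""
    rng = np.random.default_rng(seed)
    n = len(eigs)
    Z = rng.standard_normal((n_samples, n))
    Z -= Z.mean(axis=0)
    # whiten exactly, then recolor with the target spectrum
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    white = U @ Vt * np.sqrt(n_samples - 1)
    return white @ np.diag(np.sqrt(np.asarray(eigs, dtype=float)))


class TestParticipationRatio:
    def test_single_feature_variance_gives_one(self):
        X = np.zeros((50, 8))
        X[:, 3] = np.random.default_rng(0).standard_normal(50)
        assert participation_ratio(X) == pytest.approx(1.0)

    def test_isotropic_gives_n(self):
        X = data_with_eigenvalues([1.0] * 12)
        assert participation_ratio(X) == pytest.approx(12.0, rel=1e-9)

    def test_known_spectrum(self):
        X = data_with_eigenvalues([2.0, 1.0, 1.0])
        assert participation_ratio(X) == pytest.approx(16.0 / 6.0, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            participation_ratio(np.ones((10, 4)))


class TestExplainedVarianceDims:
    def test_dominant_eigenvalue(self):
        X = data_with_eigenvalues([9.0, 1.0])
        assert explained_variance_dims(X, 0.9) == 1

    def test_isotropic_needs_ceil_fraction_of_n(self):
        X = data_with_eigenvalues([1.0] * 20)
        assert explained_variance_dims(X, 0.9) == 18

    def test_low_rank_data_recovers_rank(self):
        rng = np.random.default_rng(1)
        r = 5
        X = rng.standard_normal((100, r)) @ rng.standard_normal((r, 40))
        assert explained_variance_dims(X, 0.999) == r

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            explained_variance_dims(np.eye(3), 1.0)


class TestCenterCorrelation:
    def test_antipodal_centers_fully_correlated(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        pts = np.stack([np.tile(v, (3, 1)), np.tile(-v, (3, 1))])
        ms = ManifoldSet(pts + np.random.default_rng(0).normal(0, 1e-9, pts.shape))
        assert center_correlation(ms) == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_over_pairs(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((6, 4, 10))
        ms = ManifoldSet(pts)
        centers = pts.mean(axis=1)
        centers -= centers.mean(axis=0)
        acc = []
        for i in range(6):
            for j in range(i + 1, 6):
                acc.append(abs(np.corrcoef(centers[i], centers[j])[0, 1]))
        assert center_correlation(ms) == pytest.approx(np.mean(acc), rel=1e-12)

    def test_identical_centers_rejected(self):
        pts = np.tile(np.arange(8.0), (4, 3, 1))
        with pytest.raises(ValueError, match="center"):
            center_correlation(ManifoldSet(pts))


class TestSeparability:
    def test_fraction_one_when_n_exceeds_points(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 50))
        y = np.repeat([1.0, -1.0], 20)
        assert _is_separable(X, y)

    def test_clearly_undersized_space_is_inseparable(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 10))
        y = np.tile([1.0, -1.0], 100)
        assert not _is_separable(X, y)


class TestSimulationCapacity:
    def test_single_point_manifolds_reach_cover_transition(self):
        rng = np.random.default_rng(0)
        ms = ManifoldSet(rng.standard_normal((60, 1, 200)))
        est = simulation_capacity(ms, n_dichotomies=50, seed=1)
        assert est.alpha_sim == pytest.approx(2.0, rel=0.15)

    def test_duplicated_points_match_single_point_case(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((40, 1, 150))
        dup = np.repeat(base, 5, axis=1)
        a = simulation_capacity(ManifoldSet(base), 50, seed=2).alpha_sim
        b = simulation_capacity(ManifoldSet(dup), 50, seed=2).alpha_sim
        assert b == pytest.approx(a, rel=0.1)

    def test_rotation_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((20, 3, 80))
        Q, _ = np.linalg.qr(rng.standard_normal((80, 80)))
        a = simulation_capacity(ManifoldSet(pts), 30, seed=5).alpha_sim
        b = simulation_capacity(ManifoldSet(3.7 * pts @ Q), 30, seed=5).alpha_sim
        assert b == pytest.approx(a, rel=0.15)

    def test_curve_is_recorded(self):
        rng = np.random.default_rng(5)
        est = simulation_capacity(ManifoldSet(rng.standard_normal((20, 1, 60))),
                                  30, seed=0)
        ns, fracs = zip(*est.separability_curve)
        assert est.N_c >= 1 and len(ns) >= 2
        assert all(0 <= f <= 1 for f in fracs)


class TestMeanfieldGeometry:
    def test_zero_extent_manifolds_hit_upper_bound(self):
        rng = np.random.default_rng(0)
        pts = np.repeat(rng.standard_normal((30, 1, 100)), 4, axis=1)
        geo = meanfield_geometry(ManifoldSet(pts), 600, seed=1)
        assert geo.radius_R_M == pytest.approx(0.0, abs=1e-6)
        assert geo.dimension_D_M == pytest.approx(0.0, abs=1e-6)
        assert geo.capacity_alpha_c == pytest.approx(2.0, rel=0.15)

    def test_capacity_respects_point_cloud_bounds(self):
        rng = np.random.default_rng(1)
        for P, M, N in [(15, 4, 60), (10, 8, 40), (20, 2, 100)]:
            pts = rng.standard_normal((P, M, N))
            geo = meanfield_geometry(ManifoldSet(pts), 150, seed=0)
            assert 2.0 / M - 0.05 <= geo.capacity_alpha_c <= 2.0 + 0.25

    def test_rotation_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((12, 5, 50))
        Q, _ = np.linalg.qr(rng.standard_normal((50, 50)))
        a = meanfield_geometry(ManifoldSet(pts), 200, seed=3)
        b = meanfield_geometry(ManifoldSet(2.5 * pts @ Q), 200, seed=3)
        assert b.capacity_alpha_c == pytest.approx(a.capacity_alpha_c, rel=1e-6)
        assert b.radius_R_M == pytest.approx(a.radius_R_M, rel=1e-6)
        assert b.dimension_D_M == pytest.approx(a.dimension_D_M, rel=1e-6)

    def test_shrinking_manifolds_raises_capacity_monotonically(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            pts = rng.standard_normal((12, 6, 60))
            centers = pts.mean(axis=1, keepdims=True)
            caps, dims, radii = [], [], []
            for scale in (1.0, 0.3, 0.05):
                shrunk = centers + scale * (pts - centers)
                geo = meanfield_geometry(ManifoldSet(shrunk), 200, seed=trial)
                caps.append(geo.capacity_alpha_c)
                dims.append(geo.dimension_D_M)
                radii.append(geo.radius_R_M)
            assert caps[0] <= caps[1] <= caps[2] <= 2.0 + 0.1
            assert radii[0] >= radii[1] >= radii[2]
            assert dims[0] >= dims[2]


class TestActivationExtraction:
    def test_pixels_row_count_and_projection_determinism(self, tiny_spec):
        enc = Encoder(tiny_spec, seed=0)
        rng = np.random.default_rng(0)
        imgs = rng.random((7, 16, 16, 3)).astype(np.float32)
        acts = extract_activations(enc, imgs, max_N=50, seed=4)
        assert acts["pixels"].shape == (7, 50)  # 768 pixels projected to 50
        again = extract_activations(enc, imgs, max_N=50, seed=4)
        assert np.array_equal(acts["pixels"], again["pixels"])
        assert list(acts)[0] == "pixels"

    def test_residual_backbone_exposes_nine_blocks_plus_pixels(self):
        spec = EncoderSpec(backbone="resnet18-like", input_size=(32, 32, 3),
                           projector_dims=(16, 16, 16), embedding_dim=512)
        enc = Encoder(spec, seed=0)
        imgs = np.random.default_rng(1).random((2, 32, 32, 3)).astype(np.float32)
        acts = extract_activations(enc, imgs, layer_policy="per-block",
                                   max_N=100, seed=0)
        names = list(acts)
        assert names[0] == "pixels"
        assert len(names) == 10  # stem + 8 residual blocks + pixels

    def test_unknown_policy_rejected(self, tiny_spec):
        enc = Encoder(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="layer_policy"):
            extract_activations(enc, np.zeros((1, 16, 16, 3)), "all")


class TestManifoldBuilders:
    def test_translation_builder_shapes_and_degenerate_radius(self, bases10):
        mans = build_translation_manifolds(bases10, None, M=6, max_shift_px=0,
                                           seed=0, max_N=100)
        ms = mans["pixels"]
        assert ms.points.shape == (10, 6, 100)
        geo = meanfield_geometry(ms, 100, seed=0)
        assert geo.radius_R_M == pytest.approx(0.0, abs=1e-9)

    def test_wave_event_builder_requires_long_events(self):
        movie = simulate_waves(WaveSimParams(height=16, width=16,
                                             n_frames=300, seed=2))
        events = extract_events(movie)
        usable = [e for e in events if len(e) >= 5]
        mans = build_wave_event_manifolds(movie, events, None,
                                          P=min(3, len(usable)), M=5, seed=0,
                                          max_N=64)
        assert mans["pixels"].points.shape[1] == 5
        with pytest.raises(ValueError, match="event"):
            build_wave_event_manifolds(movie, events, None,
                                       P=len(events) + 5, M=5, seed=0)
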