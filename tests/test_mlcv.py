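"""Descriptors, scatter matrices, closed-form LDA and Deep-LDA."""

import numpy as np
import pytest
import scipy.linalg

from lambdabf.mlcv import (DegenerateClassesError, DescriptorDefinition,
                           LdaCv, LdaModel, compute_descriptors, evaluate_cv,
                           fisher_ratio, fit_deep_lda, fit_lda,
                           scatter_matrices)


@pytest.fixture(scope="module")
def gaussian_classes():
    rng = np.random.default_rng(12)
    x0 = rng.normal(0, 1, (2000, 5))
    x1 = rng.normal(0, 1, (2000, 5))
    x1[:, 1] += 6.0
    return x0, x1


@pytest.fixture(scope="module")
def xor_classes():
    rng = np.random.default_rng(3)
    x0 = np.vstack([rng.normal([0, 0], 0.3, (150, 2)),
                    rng.normal([3, 3], 0.3, (150, 2))])
    x1 = np.vstack([rng.normal([0, 3], 0.3, (150, 2)),
                    rng.normal([3, 0], 0.3, (150, 2))])
    return x0, x1


class TestDescriptors:
    def test_distance_to_self_like_pair_is_zero(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 1] = frames[:, 0]
        d = compute_descriptors(frames, [DescriptorDefinition("distance",
                                                              (0, 1))])
        assert np.allclose(d, 0.0)

    def test_equilateral_triangle_angles(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        defs = [DescriptorDefinition("angle", (1, 0, 2)),
                DescriptorDefinition("angle", (0, 1, 2)),
                DescriptorDefinition("angle", (0, 2, 1))]
        d = compute_descriptors(pts[None], defs)
        assert np.allclose(d, np.pi / 3)

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 2, (4, 3))
        defs = [DescriptorDefinition("distance", (0, 1)),
                DescriptorDefinition("distance", (2, 3)),
                DescriptorDefinition("angle", (0, 1, 2))]
        d0 = compute_descriptors(pts[None], defs)
        rot = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -1.0, 7.0])
        assert np.allclose(compute_descriptors(moved[None], defs), d0)

    def test_collinear_angle_guarded(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        d = compute_descriptors(pts[None],
                                [DescriptorDefinition("angle", (0, 1, 2))])
        assert np.isfinite(d).all()
        assert d[0, 0] == pytest.approx(np.pi)

    def test_bad_definitions_rejected(self):
        with pytest.raises(ValueError):
            DescriptorDefinition("distance", (0, 1, 2))
        with pytest.raises(ValueError):
            DescriptorDefinition("dihedral", (0, 1, 2, 3))
        with pytest.raises(IndexError):
            compute_descriptors(np.zeros((1, 2, 3)),
                                [DescriptorDefinition("distance", (0, 5))])


class TestScatterMatrices:
    def test_identical_classes_give_zero_between_scatter(self):
        x = np.random.default_rng(0).normal(0, 1, (50, 3))
        _, sb = scatter_matrices(x, x.copy())
        assert np.allclose(sb, 0.0)

    def test_1d_two_point_toy(self):
        sw, sb = scatter_matrices(np.array([[0.0], [0.0]]),
                                  np.array([[1.0], [1.0]]))
        assert np.allclose(sw, 0.0)
        assert np.allclose(sb, 1.0)

    def test_matches_naive_frame_loop(self):
        rng = np.random.default_rng(6)
        x0 = rng.normal(0, 1, (40, 4))
        x1 = rng.normal(1, 2, (40, 4))
        sw, _ = scatter_matrices(x0, x1, balanced=False)
        naive = np.zeros((4, 4))
        for block in (x0, x1):
            mu = block.mean(axis=0)
            for row in block:
                naive += np.outer(row - mu, row - mu)
        assert np.allclose(sw, naive, atol=1e-10)

    def test_one_class_too_small(self):
        with pytest.raises(DegenerateClassesError):
            scatter_matrices(np.zeros((1, 2)), np.ones((5, 2)))


class TestFitLda:
    def test_separated_isotropic_clouds_align_with_mean_difference(
            self, gaussian_classes):
        x0, x1 = gaussian_classes
        model = fit_lda(x0, x1)
        dmu = x1.mean(axis=0) - x0.mean(axis=0)
        dmu = dmu / np.linalg.norm(dmu)
        assert abs(model.w @ dmu) > 0.999
        # Holo projects positive
        assert model.project(x1).mean() > model.project(x0).mean()

    def test_matches_generalized_eigenproblem(self, gaussian_classes):
        x0, x1 = gaussian_classes
        model = fit_lda(x0, x1)
        sw, sb = scatter_matrices(x0, x1)
        vals, vecs = scipy.linalg.eigh(
            sb, sw + model.delta * np.eye(sw.shape[0]))
        w_eig = vecs[:, -1] / np.linalg.norm(vecs[:, -1])
        assert min(np.linalg.norm(model.w - w_eig),
                   np.linalg.norm(model.w + w_eig)) < 1e-8
        assert model.fisher() == pytest.approx(vals[-1], rel=1e-8)

    def test_equivariant_under_orthogonal_rotation(self, gaussian_classes):
        x0, x1 = gaussian_classes
        rng = np.random.default_rng(9)
        q, _ = np.linalg.qr(rng.normal(0, 1, (5, 5)))
        m1 = fit_lda(x0, x1, regularization=1e-9)
        m2 = fit_lda(x0 @ q.T, x1 @ q.T, regularization=1e-9)
        assert np.allclose(m2.w, q @ m1.w, atol=1e-8)

    def test_fitted_direction_beats_random_directions(self, gaussian_classes):
        x0, x1 = gaussian_classes
        model = fit_lda(x0, x1)
        sw, sb = scatter_matrices(x0, x1)
        swr = sw + model.delta * np.eye(5)
        best = model.fisher()
        rng = np.random.default_rng(10)
        for _ in range(1000):
            w = rng.normal(0, 1, 5)
            w /= np.linalg.norm(w)
            assert fisher_ratio(w, swr, sb) <= best * (1 + 1e-9)

    def test_identical_classes_rejected(self):
        x = np.random.default_rng(0).normal(0, 1, (30, 3))
        with pytest.raises(DegenerateClassesError):
            fit_lda(x, x.copy())


class TestDeepLda:
    def test_linear_network_recovers_plain_lda_ratio(self, gaussian_classes):
        x0, x1 = gaussian_classes
        plain = fit_lda(x0, x1)
        # project data through the trained linear network and measure the
        # Fisher ratio of the end-to-end linear CV on the original inputs
        deep = fit_deep_lda(x0, x1, hidden=(8, 6), seed=0, epochs=300,
                            activation="linear")
        s0 = deep.project(x0)
        s1 = deep.project(x1)
        sw, sb = scatter_matrices(s0[:, None], s1[:, None])
        ratio_deep = float(sb[0, 0] / sw[0, 0])
        s0p = plain.project(x0)
        s1p = plain.project(x1)
        swp, sbp = scatter_matrices(s0p[:, None], s1p[:, None])
        ratio_plain = float(sbp[0, 0] / swp[0, 0])
        assert ratio_deep >= ratio_plain * 0.99

    def test_solves_xor_where_plain_lda_fails(self, xor_classes):
        x0, x1 = xor_classes
        plain = fit_lda(x0, x1)
        assert plain.fisher() < 1e-3
        deep = fit_deep_lda(x0, x1, hidden=(24, 12), seed=1, epochs=400)
        p0 = deep.project(x0)
        p1 = deep.project(x1)
        lo = min(p0.min(), p1.min())
        hi = max(p0.max(), p1.max())
        h0, _ = np.histogram(p0, bins=40, range=(lo, hi))
        h1, _ = np.histogram(p1, bins=40, range=(lo, hi))
        overlap = np.minimum(h0 / h0.sum(), h1 / h1.sum()).sum()
        assert overlap < 0.10

    def test_training_is_deterministic(self, xor_classes):
        x0, x1 = xor_classes
        m1 = fit_deep_lda(x0, x1, hidden=(10, 6), seed=4, epochs=50)
        m2 = fit_deep_lda(x0, x1, hidden=(10, 6), seed=4, epochs=50)
        for (w1, b1), (w2, b2) in zip(m1.layers, m2.layers):
            assert np.array_equal(w1, w2)
            assert np.array_equal(b1, b2)
        assert np.array_equal(m1.w, m2.w)

    def test_json_roundtrip(self, tmp_path, xor_classes):
        x0, x1 = xor_classes
        model = fit_deep_lda(x0, x1, hidden=(10, 6), seed=4, epochs=50)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LdaModel.from_json(path)
        d = x0[:5]
        assert np.allclose(back.project(d), model.project(d))


class TestLearnedCvDrivesSampling:
    """A Deep-LDA CV trained on Apo/Holo runs finds the transition
    coordinate of a 2D double well that a naively chosen single
    coordinate misses entirely."""

    def test_deep_lda_bias_crosses_where_wrong_coordinate_fails(self):
        from lambdabf.opes import AxisPositionCV, OpesBias, run_opes
        from lambdabf.systems import (AxisHarmonicRestraint, DoubleWell1D,
                                      LangevinSettings, ParticleSystem,
                                      run_langevin)

        anchors = np.array([[3.0, 0, 0], [0, 3.0, 0], [-2.0, -2, 0]])

        def make(y0):
            pos = np.vstack([anchors, [[0.0, y0, 0.0]]])
            return ParticleSystem(
                positions=pos, masses=np.array([30.0] * 3 + [6.0]),
                charges=np.zeros(4), lj_epsilon=np.zeros(4),
                lj_sigma=np.full(4, 3.0),
                roles=np.asarray(["site"] * 3 + ["ligand"], dtype=object),
                frozen=np.array([True] * 3 + [False]))

        # transition coordinate is y; x and z are confined spectators
        well = DoubleWell1D(particle=3, axis=1, height=5.0,
                            half_distance=1.2)
        confine = AxisHarmonicRestraint(3, (0, 2), k=2.0)

        def train_run(y0, seed):
            st = LangevinSettings(temperature=300.0, friction=3.0,
                                  timestep=2.0, n_steps=4000, seed=seed,
                                  save_stride=4)
            return run_langevin(make(y0), st, attachments=[well, confine])

        defs = [DescriptorDefinition("distance", (3, i)) for i in range(3)]
        x_apo = compute_descriptors(train_run(-1.2, 21).positions, defs)
        x_holo = compute_descriptors(train_run(1.2, 22).positions, defs)
        model = fit_deep_lda(x_apo, x_holo, hidden=(16, 8), seed=5,
                             epochs=200)
        cv = LdaCv(model, defs)

        def crossings(y):
            yf = y[np.abs(y) > 0.6]
            return int(np.sum(np.abs(np.diff(np.sign(yf))) > 0))

        settings = LangevinSettings(temperature=300.0, friction=3.0,
                                    timestep=2.0, n_steps=30000, seed=31,
                                    save_stride=10)
        # kernel width = standard deviation of the CV in the starting
        # basin (the saturated tanh output makes this tiny), floored so
        # the bias force stays within the integrator's stability range
        s_apo = np.array([cv.value(p)
                          for p in train_run(-1.2, 21).positions[::10]])
        sigma = max(float(s_apo.std()), 1e-3)
        bias = OpesBias(sigma=sigma, barrier=12.0, temperature=300.0,
                        pace=300)
        traj, _ = run_opes(make(-1.2), cv, bias, settings,
                           attachments=[well, confine])
        assert crossings(traj.positions[:, 3, 1]) >= 5

        bias_x = OpesBias(sigma=0.3, barrier=12.0, temperature=300.0,
                          pace=300)
        traj_x, _ = run_opes(make(-1.2), AxisPositionCV(3, 0), bias_x,
                             settings, attachments=[well, confine])
        assert crossings(traj_x.positions[:, 3, 1]) == 0


class TestEvaluateCv:
    def test_cubic_transform_values(self):
        model = LdaModel(w=np.array([1.0]), mean_apo=np.zeros(1),
                         mean_holo=np.ones(1), sw=np.eye(1), sb=np.eye(1),
                         delta=0.0)
        s, s_w = evaluate_cv(model, np.array([0.0]))
        assert (s, s_w) == (0.0, 0.0)
        s, s_w = evaluate_cv(model, np.array([2.0]))
        assert (s, s_w) == (2.0, 10.0)

    def test_cubic_transform_strictly_increasing(self):
        model = LdaModel(w=np.array([1.0]), mean_apo=np.zeros(1),
                         mean_holo=np.ones(1), sw=np.eye(1), sb=np.eye(1),
                         delta=0.0)
        svals = np.linspace(-3, 3, 101)[:, None]
        _, sw_vals = evaluate_cv(model, svals)
        assert np.all(np.diff(sw_vals) > 0)

    def test_wrong_length_rejected(self, xor_classes):
        x0, x1 = xor_classes
        model = fit_lda(x0, x1)
        with pytest.raises(ValueError):
            evaluate_cv(model, np.zeros(7))

    def test_dynamic_cv_gradient_matches_finite_difference(self, xor_classes):
        x0, x1 = xor_classes
        model = fit_deep_lda(x0, x1, hidden=(8, 6), seed=2, epochs=100)
        defs = [DescriptorDefinition("distance", (0, 1)),
                DescriptorDefinition("distance", (1, 2))]
        cv = LdaCv(model, defs)
        rng = np.random.default_rng(8)
        pos = rng.normal(0, 2, (3, 3))
        g = cv.gradient(pos)
        h = 1e-6
        for i in range(3):
            for ax in range(3):
                pp = pos.copy()
                pp[i, ax] += h
                pm = pos.copy()
                pm[i, ax] -= h
                fd = (cv.value(pp) - cv.value(pm)) / (2 * h)
                assert g[i, ax] == pytest.approx(fd, abs=1e-5 * max(
                    1.0, np.abs(g).max()))
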