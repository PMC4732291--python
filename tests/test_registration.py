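import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from clemtarget.registration import (
    AffineTransform,
    CompositeTransform,
    DegenerateConfigurationError,
    FrameMismatchError,
    LandmarkPairs,
    TPSTransform,
    apply,
    fit_affine,
    fit_rigid,
    fit_similarity,
    fit_tps,
    fre,
    invert,
    load_transform,
    loo_tre,
    register_two_stage,
    save_transform,
)
from clemtarget.segmentation import PointSet


def _rot(deg, axis=(0, 0, 1)):
    return Rotation.from_rotvec(np.deg2rad(deg) * np.asarray(axis, float)).as_matrix()


def _pairs(src, dst, **kw):
    return LandmarkPairs(src, dst, **kw)


class TestClosedFormFits:
    def test_identity_recovery(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 100, (8, 3))
        t = fit_rigid(_pairs(src, src))
        assert np.allclose(t.matrix, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-10)

    def test_rigid_generate_and_recover(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 100, (8, 3))
        R = _rot(30)
        tvec = np.array([5.0, -2.0, 7.0])
        t = fit_rigid(_pairs(src, src @ R.T + tvec))
        assert np.allclose(t.matrix, R, atol=1e-9)
        assert np.allclose(t.translation, tvec, atol=1e-9)

    def test_rigid_reflection_returns_proper_rotation(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 50, (10, 3))
        mirrored = src * np.array([1, 1, -1.0])
        t = fit_rigid(_pairs(src, mirrored))
        assert np.linalg.det(t.matrix) == pytest.approx(1.0, abs=1e-9)

    def test_similarity_pure_shrink(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 100, (6, 3))
        t = fit_similarity(_pairs(src, 0.9 * src))
        assert t.scale == pytest.approx(0.9, abs=1e-12)
        assert np.allclose(t.matrix, 0.9 * np.eye(3), atol=1e-10)
        assert np.allclose(t.translation, 0, atol=1e-9)

    def test_similarity_generate_and_recover(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(0, 100, (10, 3))
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        c, tvec = 1.3, np.array([-4.0, 11.0, 2.5])
        t = fit_similarity(_pairs(src, c * src @ R.T + tvec))
        assert np.allclose(t.matrix, c * R, atol=1e-9)
        assert np.allclose(t.translation, tvec, atol=1e-8)

    def test_similarity_exact_three_points_zero_fre(self):
        src = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]])
        dst = 0.85 * src @ _rot(20).T + np.array([1, 2, 3.0])
        t = fit_similarity(_pairs(src, dst))
        assert fre(t, _pairs(src, dst)) == pytest.approx(0.0, abs=1e-9)

    def test_affine_anisotropic_scaling_exact(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(0, 100, (7, 3))
        A = np.diag([0.9, 0.95, 0.8])
        t = fit_affine(_pairs(src, src @ A.T))
        assert np.allclose(t.matrix, A, atol=1e-10)

    def test_affine_shear_recovery(self):
        rng = np.random.default_rng(6)
        src = rng.uniform(0, 100, (10, 3))
        A = np.eye(3) + np.array([[0, 0.2, 0], [0, 0, 0.1], [0, 0, 0]])
        tvec = np.array([3.0, -1.0, 8.0])
        t = fit_affine(_pairs(src, src @ A.T + tvec))
        assert np.allclose(t.matrix, A, atol=1e-9)
        assert np.allclose(t.translation, tvec, atol=1e-8)

    def test_affine_interpolates_four_points(self):
        rng = np.random.default_rng(7)
        src = rng.uniform(0, 10, (4, 3))
        dst = rng.uniform(0, 10, (4, 3))
        t = fit_affine(_pairs(src, dst))
        assert fre(t, _pairs(src, dst)) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize(
        "fitter, bad_src",
        [
            (fit_rigid, np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])),  # collinear
            (fit_rigid, np.zeros((2, 3))),  # too few
            (fit_affine, np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])),  # coplanar
        ],
    )
    def test_degenerate_configurations_rejected(self, fitter, bad_src):
        with pytest.raises(DegenerateConfigurationError):
            fitter(_pairs(bad_src, bad_src + 1.0))


class TestTPS:
    def _random_pairs(self, n=12, seed=8):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 100, (n, 3))
        dst = src + rng.normal(0, 2.0, (n, 3))
        return _pairs(src, dst)

    def test_affine_input_gives_zero_kernel_weights(self):
        rng = np.random.default_rng(9)
        src = rng.uniform(0, 50, (10, 3))
        A = np.diag([0.9, 1.1, 0.95])
        tvec = np.array([1.0, 2.0, 3.0])
        t = fit_tps(_pairs(src, src @ A.T + tvec), lam=0.0)
        assert np.abs(t.kernel_weights).max() < 1e-8
        assert np.allclose(t.affine_part.matrix, A, atol=1e-8)
        assert np.allclose(t.affine_part.translation, tvec, atol=1e-7)

    def test_lambda_zero_interpolates(self):
        pairs = self._random_pairs()
        t = fit_tps(pairs, lam=0.0)
        assert fre(t, pairs) < 1e-6

    def test_fre_nondecreasing_in_lambda(self):
        pairs = self._random_pairs()
        fres = [fre(fit_tps(pairs, lam=l), pairs) for l in (0.0, 0.1, 1.0, 10.0, 100.0)]
        assert all(b >= a - 1e-9 for a, b in zip(fres, fres[1:]))

    def test_large_lambda_approaches_affine_fit(self):
        pairs = self._random_pairs()
        t_tps = fit_tps(pairs, lam=1e6)
        t_aff = fit_affine(pairs)
        grid = np.random.default_rng(10).uniform(0, 100, (30, 3))
        assert np.allclose(
            t_tps.transform_points(grid), t_aff.transform_points(grid), atol=1e-2
        )

    def test_matches_independent_rbf_solution(self):
        # scipy's linear RBF with degree-1 polynomial solves the same bordered
        # system; identical solutions must agree everywhere, not just at nodes
        from scipy.interpolate import RBFInterpolator

        pairs = self._random_pairs(n=15, seed=11)
        t = fit_tps(pairs, lam=0.0)
        ref = RBFInterpolator(pairs.source, pairs.target, kernel="linear", degree=1)
        grid = np.random.default_rng(12).uniform(-10, 110, (50, 3))
        assert np.allclose(t.transform_points(grid), ref(grid), atol=1e-9)

    def test_duplicate_control_points_rejected(self):
        src = np.vstack([np.zeros(3), np.zeros(3), np.eye(3) * 10, [[5, 5, 5]]])
        with pytest.raises(DegenerateConfigurationError):
            fit_tps(_pairs(src, src), lam=0.0)

    def test_side_conditions_validated(self):
        with pytest.raises(ValueError, match="side condition"):
            TPSTransform(
                np.eye(3) * 10,
                np.ones((3, 3)),
                AffineTransform(np.eye(3), np.zeros(3)),
            )


class TestApplyInvert:
    def test_apply_updates_frame(self):
        t = AffineTransform(np.eye(3), np.array([1.0, 0, 0]), kind="rigid",
                            source_frame="ivm", target_frame="microct")
        ps = PointSet(np.zeros((2, 3)), frame="ivm")
        out = apply(t, ps)
        assert out.frame == "microct"
        assert np.allclose(out.points, [[1, 0, 0], [1, 0, 0]])

    def test_apply_frame_mismatch(self):
        t = AffineTransform(np.eye(3), np.zeros(3), kind="rigid",
                            source_frame="ivm", target_frame="microct")
        with pytest.raises(FrameMismatchError):
            apply(t, PointSet(np.zeros((1, 3)), frame="microct"))

    def test_invert_similarity_analytic(self):
        R = _rot(25, (0, 1, 0))
        t = AffineTransform(0.9 * R, np.array([5.0, -3.0, 1.0]), kind="similarity")
        inv = invert(t)
        assert np.allclose(inv.matrix, R.T / 0.9, atol=1e-12)
        pts = np.random.default_rng(13).uniform(0, 10, (5, 3))
        assert np.allclose(inv.transform_points(t.transform_points(pts)), pts, atol=1e-10)

    def test_invert_tps_roundtrip(self):
        rng = np.random.default_rng(14)
        src = rng.uniform(0, 100, (12, 3))
        dst = 0.9 * src + rng.normal(0, 2.0, src.shape)
        t = fit_tps(_pairs(src, dst), lam=0.0)
        inv = invert(t)
        grid = rng.uniform(20, 80, (20, 3))
        round_trip = t.transform_points(inv.transform_points(t.transform_points(grid)))
        assert np.abs(round_trip - t.transform_points(grid)).max() < 1e-3

    def test_invert_composite_reverses_order(self):
        a = AffineTransform(2.0 * np.eye(3), np.zeros(3), kind="similarity")
        b = AffineTransform(np.eye(3), np.array([1.0, 0, 0]), kind="rigid")
        comp = CompositeTransform([a, b])
        inv = invert(comp)
        pts = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(inv.transform_points(comp.transform_points(pts)), pts)


class TestDiagnostics:
    def test_fre_exact_and_single_offset(self):
        src = np.random.default_rng(15).uniform(0, 10, (5, 3))
        ident = AffineTransform(np.eye(3), np.zeros(3), kind="rigid")
        assert fre(ident, _pairs(src, src)) == 0.0
        dst = src.copy()
        dst[0] += [3.0, 0, 0]
        assert fre(ident, _pairs(src, dst)) == pytest.approx(3.0 / np.sqrt(5))

    def test_fre_matches_hand_computed_rms(self):
        rng = np.random.default_rng(16)
        src = rng.uniform(0, 10, (6, 3))
        resid = rng.normal(0, 1, (6, 3))
        ident = AffineTransform(np.eye(3), np.zeros(3), kind="rigid")
        expect = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert fre(ident, _pairs(src, src + resid)) == pytest.approx(expect)

    def test_model_nesting_inequality(self):
        rng = np.random.default_rng(17)
        src = rng.uniform(0, 100, (12, 3))
        dst = 0.9 * src @ _rot(10).T + rng.normal(0, 2.0, src.shape)
        pairs = _pairs(src, dst)
        f_r = fre(fit_rigid(pairs), pairs)
        f_s = fre(fit_similarity(pairs), pairs)
        f_a = fre(fit_affine(pairs), pairs)
        assert f_a <= f_s + 1e-12 <= f_r + 1e-12

    def test_loo_tre_zero_for_consistent_pairs(self):
        rng = np.random.default_rng(18)
        src = rng.uniform(0, 100, (8, 3))
        dst = 0.9 * src @ _rot(15).T + 5.0
        assert loo_tre("similarity", _pairs(src, dst)) < 1e-8

    def test_loo_tre_matches_bruteforce(self):
        rng = np.random.default_rng(19)
        src = rng.uniform(0, 100, (9, 3))
        dst = src + rng.normal(0, 1.5, src.shape)
        pairs = _pairs(src, dst)
        # independent brute-force loop
        errs = []
        for i in range(len(pairs)):
            keep = np.arange(len(pairs)) != i
            t = fit_similarity(_pairs(src[keep], dst[keep]))
            errs.append(np.sum((t.transform_points(src[i]) - dst[i]) ** 2))
        expect = np.sqrt(np.mean(errs))
        assert loo_tre("similarity", pairs) == pytest.approx(expect, rel=1e-12)

    def test_loo_tre_increases_with_noise(self):
        rng = np.random.default_rng(20)
        src = rng.uniform(0, 100, (10, 3))
        by_noise = []
        for sd in (0.5, 2.0):
            vals = [
                loo_tre("similarity", _pairs(src, src + rng.normal(0, sd, src.shape)))
                for _ in range(100)
            ]
            by_noise.append(np.mean(vals))
        assert by_noise[1] > by_noise[0]

    def test_translation_error_shrinks_with_more_landmarks(self):
        rng = np.random.default_rng(21)
        errs = []
        for n in (5, 10, 20):
            trans_err = []
            for _ in range(100):
                src = rng.uniform(0, 100, (n, 3))
                tvec = rng.uniform(-10, 10, 3)
                dst = 0.9 * src + tvec + rng.normal(0, 1.0, src.shape)
                t = fit_similarity(_pairs(src, dst))
                # compare predicted centroid shift at the source centroid
                pred = t.transform_points(src.mean(axis=0))
                truth = 0.9 * src.mean(axis=0) + tvec
                trans_err.append(np.linalg.norm(pred - truth))
            errs.append(np.mean(trans_err))
        assert errs[0] > errs[1] > errs[2]


class TestTwoStage:
    def test_consistent_fine_stage_is_identity(self):
        rng = np.random.default_rng(22)
        src = rng.uniform(0, 100, (10, 3))
        dst = 0.9 * src @ _rot(12).T + np.array([4.0, 5.0, -6.0])
        pairs = _pairs(src, dst)
        comp, report = register_two_stage(pairs, pairs, "similarity", "affine")
        fine = comp.transforms[1]
        assert np.allclose(fine.matrix, np.eye(3), atol=1e-8)
        assert np.allclose(fine.translation, 0, atol=1e-6)
        assert report.n_landmarks == 10
        assert report.fre_rms < 1e-8

    def test_two_stage_beats_coarse_alone_when_deformation_dominates(self):
        # the fine TPS stage pays off when the nonlinear embedding distortion
        # exceeds the landmark localization noise; paired comparison over 100
        # phantoms in that regime
        from clemtarget.phantom import generate_registration_case

        cfg = {"landmark_noise_um": 0.3, "max_nonlinear_um": 6.0}
        rng = np.random.default_rng(23)
        e_coarse, e_two = [], []
        for _ in range(100):
            seed = int(rng.integers(0, 2**31 - 1))
            pairs, truth = generate_registration_case(seed, cfg)
            coarse = fit_similarity(pairs)
            e_coarse.append(np.linalg.norm(
                coarse.transform_points(truth.target_ivm) - truth.target_microct
            ))
            comp, _ = register_two_stage(pairs, pairs, "similarity", "tps", tps_lambda=0.01)
            e_two.append(np.linalg.norm(
                comp.transform_points(truth.target_ivm) - truth.target_microct
            ))
        assert np.mean(e_two) <= np.mean(e_coarse)


class TestSerialization:
    def test_transform_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(24)
        src = rng.uniform(0, 100, (10, 3))
        dst = src + rng.normal(0, 2, src.shape)
        comp, _ = register_two_stage(_pairs(src, dst), _pairs(src, dst))
        save_transform(comp, tmp_path / "t.json")
        back = load_transform(tmp_path / "t.json")
        grid = rng.uniform(0, 100, (10, 3))
        assert np.allclose(back.transform_points(grid), comp.transform_points(grid))

    def test_landmark_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(25)
        pairs = _pairs(rng.uniform(0, 10, (5, 3)), rng.uniform(0, 10, (5, 3)),
                       labels=[f"m{i}" for i in range(5)])
        pairs.to_csv(tmp_path / "lm.csv")
        back = LandmarkPairs.from_csv(tmp_path / "lm.csv")
        assert np.allclose(back.source, pairs.source)
        assert np.allclose(back.target, pairs.target)
        assert back.labels == pairs.labels
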