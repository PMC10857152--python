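"""Landmark displacement metrics (FLE, TRE, FRE, Frobenius norm)."""

import numpy as np
import pytest

from navphantom import (
    NoiseModel,
    PhantomParams,
    RigidFit,
    compute_fle,
    compute_fn,
    compute_fre,
    compute_tre,
    decompose_fn,
    fit_rigid,
    generate_case,
    summarize_landmarks,
)

from conftest import make_set


class TestInterpolatedMetrics:
    def test_zero_when_sets_coincide(self, random_points):
        c = make_set(random_points)
        fle = compute_fle(c, c)
        np.testing.assert_array_equal(fle.vectors, 0.0)
        np.testing.assert_array_equal(fle.magnitudes, 0.0)

    def test_single_marker_pythagoras(self):
        c = make_set([[0.0, 0.0, 0.0]])
        v = make_set([[1.0, 2.0, 2.0]])
        assert compute_fle(v, c).magnitudes[0] == pytest.approx(3.0)

    def test_magnitudes_match_norm_oracle(self, rng, random_points):
        c = make_set(random_points)
        v = make_set(random_points + rng.normal(0, 1.0, random_points.shape))
        fle = compute_fle(v, c)
        # one-line elementwise recomputation
        expected = [
            float(np.sqrt(np.sum((a - b) ** 2)))
            for a, b in zip(v.points, c.points)
        ]
        np.testing.assert_allclose(fle.magnitudes, expected, atol=1e-12)

    def test_uniform_shift_gives_constant_tre(self, random_points):
        c = make_set(random_points)
        p = make_set(random_points + np.array([0.0, 0.0, 3.0]))
        np.testing.assert_allclose(compute_tre(p, c).magnitudes, 3.0)

    def test_tre_closed_form_under_known_misregistration(self):
        # zero probe noise: TRE_i must equal ||T_err(C_i) - C_i|| exactly
        params = PhantomParams(lesion_volume_range=(8.0, 9.0))
        case = generate_case(
            params, NoiseModel(sigma_probe=0.0), seed=11
        )
        c = case.fiducials_C
        expected = np.linalg.norm(
            case.true_misregistration.apply(c.points) - c.points, axis=1
        )
        tre = compute_tre(case.fiducials_P, c)
        np.testing.assert_allclose(tre.magnitudes, expected, atol=1e-9)

    def test_label_mismatch_rejected(self, random_points):
        c = make_set(random_points, labels=range(1, 8))
        v = make_set(random_points, labels=range(2, 9))
        with pytest.raises(ValueError, match="label mismatch"):
            compute_fle(v, c)


class TestFRE:
    def test_exact_rigid_motion_leaves_no_residual(self, rng, random_points):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.1, -0.2, 0.3]).as_matrix()
        c = make_set(random_points)
        p = make_set(random_points @ rot.T + np.array([4.0, 1.0, -2.0]))
        fit = fit_rigid(c, p)
        np.testing.assert_allclose(
            compute_fre(c, p, fit).magnitudes, 0.0, atol=1e-9
        )

    def test_stretched_pair_splits_residual_equally(self):
        # Two collinear points stretched 2 mm: the optimal rigid alignment
        # splits the excess equally, residual magnitude 1 at each point.
        # Oracle: brute-force over the translation along the common axis.
        c_pts = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        p_pts = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        ts = np.linspace(-5, 5, 100001)
        cost = (ts - 0.0) ** 2 + (10.0 + ts - 12.0) ** 2
        t_best = ts[np.argmin(cost)]
        assert t_best == pytest.approx(1.0, abs=1e-4)
        fit = RigidFit(
            np.eye(3),
            np.array([t_best, 0.0, 0.0]),
            c_pts + np.array([t_best, 0.0, 0.0]) - p_pts,
            (1, 2),
        )
        fre = compute_fre(make_set(c_pts), make_set(p_pts), fit)
        np.testing.assert_allclose(fre.magnitudes, [1.0, 1.0], atol=1e-4)

    def test_fre_equals_fit_residual_norms(self, rng, random_points):
        c = make_set(random_points)
        p = make_set(random_points + rng.normal(0, 1.5, random_points.shape))
        fit = fit_rigid(c, p)
        fre = compute_fre(c, p, fit)
        np.testing.assert_allclose(
            fre.magnitudes, np.linalg.norm(fit.residuals, axis=1), atol=1e-12
        )

    def test_inconsistent_fit_rejected(self, rng, random_points):
        c = make_set(random_points)
        p = make_set(random_points + 1.0)
        fit = fit_rigid(c, p)
        other = make_set(random_points[:5], labels=range(10, 15))
        with pytest.raises(ValueError, match="labels"):
            compute_fre(other, make_set(p.points[:5], labels=range(10, 15)), fit)


class TestFrobeniusNorm:
    def test_identity_is_zero(self):
        assert compute_fn(RigidFit.identity()) == 0.0

    def test_pure_translation_three_four_zero(self):
        fit = RigidFit(np.eye(3), [3.0, 4.0, 0.0], np.zeros((1, 3)), (1,))
        assert compute_fn(fit) == pytest.approx(5.0)

    def test_half_turn_rotation(self):
        fit = RigidFit(
            np.diag([-1.0, -1.0, 1.0]), np.zeros(3), np.zeros((1, 3)), (1,)
        )
        assert compute_fn(fit) == pytest.approx(np.sqrt(8.0))

    def test_decomposition_is_pythagorean(self, rng, random_points):
        c = make_set(random_points)
        p = make_set(random_points + rng.normal(0, 2.0, random_points.shape))
        parts = decompose_fn(fit_rigid(c, p))
        assert parts["fn"] == pytest.approx(
            np.hypot(parts["rotation_part"], parts["translation_part"])
        )

    def test_zero_iff_identity(self, rng, random_points):
        c = make_set(random_points)
        assert compute_fn(fit_rigid(c, c)) == pytest.approx(0.0, abs=1e-9)
        p = make_set(random_points + np.array([1.0, 0.0, 0.0]))
        assert compute_fn(fit_rigid(c, p)) > 0.1


class TestCaseSummary:
    def test_known_magnitudes_mean_and_sample_sd(self):
        # FLE magnitudes {1, 2, 3} -> mean 2, sample SD 1
        c = make_set([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        v = make_set(
            [[1.0, 0, 0], [12.0, 0, 0], [0, 13.0, 0], [0, 0, 12.0]]
        )
        fle = compute_fle(v, c)
        np.testing.assert_allclose(fle.magnitudes, [1, 2, 3, 2])
        sub = compute_fle(make_set(v.points[:3]), make_set(c.points[:3]))
        assert sub.mean == pytest.approx(2.0)
        assert sub.sd == pytest.approx(1.0)

    def test_all_zero_errors_summarize_to_zero(self, random_points):
        c = make_set(random_points)
        fit = fit_rigid(c, c)
        s = summarize_landmarks("case", "supine", c, c, c, fit)
        for key in ("mean_fle", "mean_tre", "mean_fre", "fn"):
            assert s.as_dict()[key] == pytest.approx(0.0, abs=1e-9)

    def test_summary_matches_spreadsheet_recomputation(self, default_case):
        case = default_case
        fit = fit_rigid(case.fiducials_C, case.fiducials_P)
        s = summarize_landmarks(
            case.case_id, case.position, case.fiducials_C,
            case.fiducials_V, case.fiducials_P, fit,
        )
        # independent recomputation straight from the raw coordinates
        d = case.fiducials_V.points - case.fiducials_C.points
        mags = np.sqrt((d**2).sum(axis=1))
        assert s.mean_fle == pytest.approx(mags.mean())
        assert s.sd_fle == pytest.approx(mags.std(ddof=1))
        assert s.acquisition_order == ("V", "P")

    def test_rigid_misregistration_fre_below_tre(self):
        # pure rigid error, no probe noise: the fit removes it entirely
        params = PhantomParams(lesion_volume_range=(8.0, 9.0))
        case = generate_case(params, NoiseModel(sigma_probe=0.0), seed=5)
        c, p = case.fiducials_C, case.fiducials_P
        fit = fit_rigid(c, p)
        fre = compute_fre(c, p, fit)
        tre = compute_tre(p, c)
        assert fre.mean == pytest.approx(0.0, abs=1e-9)
        assert tre.mean > 0.1


def test_mean_fle_monotone_in_probe_noise():
    from navphantom import simulate_fle_magnitudes

    means = [
        simulate_fle_magnitudes(700, sigma_probe=s, seed=9).mean()
        for s in (0.5, 1.0, 2.0)
    ]
    assert means[0] < means[1] < means[2]
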