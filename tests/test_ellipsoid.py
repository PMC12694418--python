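"""Geometric metrics: chi-square critical value, eigenstructure, axis
lengths, volume, eccentricity, and parameter recovery on synthetic clouds."""

import numpy as np
import pytest

from cytomorph.ellipsoid import (
    assign_eigenvalues_to_axes,
    axis_lengths,
    chi2_quantile,
    compute_ellipsoid,
    containment_fraction,
    covariance_eigen,
    eccentricity,
    ellipsoid_volume,
)
from cytomorph.errors import DegenerateCloudError

from conftest import blob_cloud, make_cloud


class TestChi2Quantile:
    def test_90pct_3df_is_the_printed_constant(self):
        assert round(chi2_quantile(0.90, 3), 3) == 6.251

    def test_median_2df_is_2ln2(self):
        # chi-square with 2 df is Exp(1/2); its median is 2 ln 2
        assert chi2_quantile(0.5, 2) == pytest.approx(2 * np.log(2), rel=1e-9)

    def test_95pct_1df_is_squared_normal_quantile(self):
        from scipy.stats import norm

        assert chi2_quantile(0.95, 1) == pytest.approx(norm.ppf(0.975) ** 2, rel=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            chi2_quantile(p, 3)


def _exact_cov_cloud(variances):
    """Six points with exactly diagonal sample covariance (ddof=1)."""
    scale = np.sqrt(np.asarray(variances) * 5.0 / 2.0)
    pts = np.vstack([np.diag(scale), -np.diag(scale)])
    return make_cloud(pts + 3.0)


class TestCovarianceEigen:
    def test_constructed_diagonal_covariance_recovered_exactly(self):
        cloud = _exact_cov_cloud([4.0, 1.0, 0.25])
        evals, evecs = covariance_eigen(cloud)
        np.testing.assert_allclose(evals, [4.0, 1.0, 0.25], atol=1e-12)
        # eigenvectors are the coordinate axes (up to sign)
        np.testing.assert_allclose(np.abs(evecs), np.eye(3), atol=1e-9)

    def test_points_on_a_line_rank_one(self, rng):
        t = rng.normal(size=200)
        cloud = make_cloud(np.outer(t, [1.0, 2.0, -1.0]))
        evals, _ = covariance_eigen(cloud)
        assert evals[1] == 0.0 and evals[2] == 0.0

    def test_isotropic_monte_carlo(self, rng):
        cloud = make_cloud(rng.standard_normal((100_000, 3)))
        evals, _ = covariance_eigen(cloud)
        np.testing.assert_allclose(evals, 1.0, rtol=0.02)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateCloudError):
            covariance_eigen(make_cloud(np.ones((10, 3))))

    def test_too_few_events(self):
        with pytest.raises(DegenerateCloudError):
            covariance_eigen(make_cloud(np.eye(3)))


class TestAxisAssignment:
    def test_diagonal_case_reads_off_the_diagonal(self):
        lam = assign_eigenvalues_to_axes(
            np.array([2.0, 5.0, 1.0]), np.eye(3)
        )
        assert lam == (2.0, 5.0, 1.0)

    def test_small_rotation_keeps_dominant_axis(self):
        # diag(5,1,1) rotated 10 degrees in the SSC-FL1 plane: the largest
        # eigenvalue's eigenvector is (cos10, sin10, 0) -> loads on SSC
        th = np.deg2rad(10)
        R = np.array(
            [
                [np.cos(th), -np.sin(th), 0],
                [np.sin(th), np.cos(th), 0],
                [0, 0, 1],
            ]
        )
        cov = R @ np.diag([5.0, 1.0, 1.0]) @ R.T
        evals, evecs = np.linalg.eigh(cov)
        lam_ssc, lam_fl1, lam_fsc = assign_eigenvalues_to_axes(evals, evecs)
        assert lam_ssc == pytest.approx(5.0)

    def test_isotropic_assignment_is_symmetric(self):
        lam = assign_eigenvalues_to_axes(np.ones(3), np.eye(3))
        assert lam == (1.0, 1.0, 1.0)

    def test_assignment_is_a_bijection(self, rng):
        A = rng.standard_normal((3, 3))
        cov = A @ A.T
        evals, evecs = np.linalg.eigh(cov)
        lam = assign_eigenvalues_to_axes(evals, evecs)
        assert sorted(lam) == sorted(evals.tolist())


class TestAxisLengthsVolumeEccentricity:
    def test_unit_eigenvalues(self):
        w, h, l = axis_lengths(1.0, 1.0, 1.0, 6.251)
        assert w == h == l == pytest.approx(2 * np.sqrt(6.251))

    def test_distinct_eigenvalues(self):
        w, h, l = axis_lengths(4.0, 1.0, 0.25, 6.251)
        assert w == pytest.approx(2 * np.sqrt(6.251 * 4))
        assert h == pytest.approx(2 * np.sqrt(6.251))
        assert l == pytest.approx(2 * np.sqrt(6.251 * 0.25))

    def test_zero_eigenvalue_gives_zero_axis(self):
        assert axis_lengths(1.0, 0.0, 1.0, 6.251)[1] == 0.0

    def test_negative_eigenvalue_errors(self):
        with pytest.raises(ValueError):
            axis_lengths(-1.0, 1.0, 1.0, 6.251)

    def test_volume_sphere_and_box(self):
        assert ellipsoid_volume(2, 2, 2) == pytest.approx(4 * np.pi / 3)
        assert ellipsoid_volume(2, 4, 6) == pytest.approx(8 * np.pi)
        assert ellipsoid_volume(2, 0, 6) == 0.0

    def test_eccentricity_equal_axes_exactly_zero(self):
        e, degen = eccentricity(2.0, 2.0)
        assert e == 0.0 and not degen

    def test_eccentricity_two_to_one(self):
        e, _ = eccentricity(4.0, 2.0)
        assert e == pytest.approx(np.sqrt(3) / 2)

    def test_eccentricity_collapsed_axis_flagged(self):
        e, degen = eccentricity(3.0, 0.0)
        assert e == 1.0 and degen

    def test_eccentricity_both_zero_errors(self):
        with pytest.raises(DegenerateCloudError):
            eccentricity(0.0, 0.0)


class TestComputeEllipsoid:
    def test_isotropic_recovery(self):
        cloud, _ = blob_cloud([[3.3, 3.6, 3.2]], [1.0], n=100_000, var=0.04, seed=11)
        m = compute_ellipsoid(cloud)
        expect = 2 * np.sqrt(m.chi2_critical * 0.04)
        for axis in (m.W, m.H, m.L):
            assert axis == pytest.approx(expect, rel=0.02)

    def test_volume_identity_holds_exactly(self, gaussian_cloud):
        m = compute_ellipsoid(gaussian_cloud)
        assert m.V == pytest.approx(np.pi * m.W * m.H * m.L / 6, rel=1e-12)

    def test_translation_invariance(self, gaussian_cloud):
        m1 = compute_ellipsoid(gaussian_cloud)
        shifted = make_cloud(gaussian_cloud.values + 1.75)
        m2 = compute_ellipsoid(shifted)
        for attr in ("W", "H", "L", "V", "eccentricity"):
            assert getattr(m1, attr) == pytest.approx(getattr(m2, attr), rel=1e-9)
        assert m2.centroid_SSC == pytest.approx(m1.centroid_SSC + 1.75)

    def test_permutation_invariance(self, gaussian_cloud, rng):
        m1 = compute_ellipsoid(gaussian_cloud)
        perm = rng.permutation(gaussian_cloud.n_events)
        m2 = compute_ellipsoid(make_cloud(gaussian_cloud.values[perm]))
        assert m1.as_dict() == pytest.approx(m2.as_dict())

    def test_fl1_scaling_cannot_decrease_height(self, gaussian_cloud):
        m1 = compute_ellipsoid(gaussian_cloud)
        scaled = gaussian_cloud.values.copy()
        scaled[:, 1] *= 3.0
        m2 = compute_ellipsoid(make_cloud(scaled))
        assert m2.H >= m1.H

    def test_identical_points_error(self):
        with pytest.raises(DegenerateCloudError):
            compute_ellipsoid(make_cloud(np.full((3, 3), 2.0)))

    def test_diagonal_mode_uses_raw_variances(self, gaussian_cloud):
        m = compute_ellipsoid(gaussian_cloud, mode="diagonal")
        cov = np.cov(gaussian_cloud.values, rowvar=False)
        assert m.W == pytest.approx(2 * np.sqrt(m.chi2_critical * cov[0, 0]))

    def test_containment_is_90pct(self, rng):
        # full-rank anisotropic covariance, large sample
        A = np.array([[0.3, 0.1, 0.0], [0.0, 0.2, 0.05], [0.0, 0.0, 0.1]])
        pts = rng.standard_normal((100_000, 3)) @ A.T
        m = compute_ellipsoid(make_cloud(pts))
        frac = containment_fraction(pts, m)
        assert frac == pytest.approx(0.90, abs=0.005)

    def test_parameter_recovery_conditioned_cloud(self):
        cloud, truth = blob_cloud([[3.3, 3.6, 3.2]], [1.0], n=10_000, seed=21)
        m = compute_ellipsoid(cloud)
        expect = truth["pooled_axis_lengths"]
        np.testing.assert_allclose([m.W, m.H, m.L], expect, rtol=0.05)
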