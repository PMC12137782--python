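import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msdager import gp
from msdager.scheme import QSpaceScheme, two_shell_scheme


class TestAngularDistance:
    def test_identity_is_zero(self):
        q = np.array([0.0, 0.6, 0.8])
        assert gp.angular_distance(q, q) == pytest.approx(0.0)

    def test_antipodal_pair_is_zero(self):
        q = np.array([0.0, 0.6, 0.8])
        assert gp.angular_distance(q, -q, antipodal=True) == pytest.approx(0.0)

    def test_120_degrees_antipodal_maps_to_60(self):
        a = np.array([1.0, 0, 0])
        b = np.array([np.cos(np.deg2rad(120)), np.sin(np.deg2rad(120)), 0])
        assert gp.angular_distance(a, b, antipodal=True) == pytest.approx(np.pi / 3)
        assert gp.angular_distance(a, b, antipodal=False) == pytest.approx(2 * np.pi / 3)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            gp.angular_distance(np.zeros(3), np.array([1.0, 0, 0]))


class TestCovarianceFunctions:
    @pytest.mark.parametrize("theta,a,expected", [
        (0.0, 1.0, 1.0),
        (1.0, 1.0, 0.0),              # boundary of the support
        (0.5, 1.0, 0.3125),           # 1 - 3/4 + 1/16
        (2.0, 1.0, 0.0),              # beyond support
    ])
    def test_spherical_closed_form(self, theta, a, expected):
        assert gp.cov_within_shell(theta, a) == pytest.approx(expected)

    def test_cross_shell_closed_form(self):
        assert gp.cov_between_shells(1000, 2000, 1.0) == pytest.approx(
            np.exp(-np.log(2) ** 2 / 2))  # ~0.78648
        assert gp.cov_between_shells(1500, 1500, 0.3) == pytest.approx(1.0)
        # infinite length-scale decouples nothing
        assert gp.cov_between_shells(1000, 3000, 1e8) == pytest.approx(1.0)

    def test_cross_shell_rejects_b0(self):
        with pytest.raises(ValueError):
            gp.cov_between_shells(0, 1000, 1.0)

    @given(theta=st.floats(0, np.pi / 2), a=st.floats(0.01, np.pi / 2))
    @settings(max_examples=50, deadline=None)
    def test_spherical_bounded_in_unit_interval(self, theta, a):
        c = float(gp.cov_within_shell(theta, a))
        assert 0.0 <= c <= 1.0


class TestBuildCovariance:
    def test_lambda_zero_gives_pure_noise_matrix(self, scheme36):
        sub = scheme36.subset(scheme36.dwi_indices)
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=0.0,
                                 sigma_n2=np.array([0.1, 0.2]))
        m = gp.build_covariance(sub, h)
        assert np.allclose(m.cov_sigma, 0)
        d = np.diag(m.cov_sigma_y)
        assert set(np.round(np.unique(d), 6)) == {0.1, 0.2}

    def test_three_direction_toy_hand_values(self):
        # two directions 30 deg apart on b=1000, one collinear on b=2000
        v1 = np.array([1.0, 0, 0])
        v2 = np.array([np.cos(np.pi / 6), np.sin(np.pi / 6), 0])
        sch = QSpaceScheme([1000, 1000, 2000], np.vstack([v1, v2, v1]))
        h = gp.GPHyperparameters(a=np.pi / 3, l=1.0, lambda_=1.0,
                                 sigma_n2=np.array([0.1, 0.1]))
        m = gp.build_covariance(sch, h)
        ctheta30 = 0.3125
        cb = np.exp(-np.log(2) ** 2 / 2)
        assert m.cov_sigma[0, 1] == pytest.approx(ctheta30)
        assert m.cov_sigma[0, 2] == pytest.approx(cb)
        assert m.cov_sigma[1, 2] == pytest.approx(ctheta30 * cb, rel=1e-12)
        assert np.allclose(np.diag(m.cov_sigma), 1.0)

    def test_psd_over_random_schemes_and_hyperparameters(self, rng):
        for _ in range(10):
            n = rng.integers(6, 40)
            sch = two_shell_scheme(n, n_b0=0, seed=int(rng.integers(1000)))
            h = gp.GPHyperparameters(
                a=rng.uniform(0.05, np.pi / 2), l=rng.uniform(0.1, 3),
                lambda_=rng.uniform(0.1, 10),
                sigma_n2=rng.uniform(0.01, 1, 2))
            m = gp.build_covariance(sch, h)
            ev = np.linalg.eigvalsh(m.cov_sigma)
            assert ev.min() >= -1e-9 * h.lambda_


class TestLogMarginalLikelihood:
    def test_scalar_standard_normal(self):
        sch = QSpaceScheme([1000.0], [[1, 0, 0]])
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=0.0, sigma_n2=np.array([1.0]))
        m = gp.build_covariance(sch, h)
        val = gp.log_marginal_likelihood(np.array([[0.0]]), m,
                                         mean=np.array([[0.0]]))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_dense_gaussian_oracle(self, rng):
        """Independent oracle: scipy multivariate normal log-pdf."""
        from scipy.stats import multivariate_normal
        sch = two_shell_scheme(3, n_b0=0, seed=3)  # 6 directions
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=2.0,
                                 sigma_n2=np.array([0.5, 0.7]))
        m = gp.build_covariance(sch, h)
        y = rng.normal(size=(4, 6))
        mean = np.zeros((4, 6))
        expected = sum(multivariate_normal.logpdf(y[v], np.zeros(6), m.cov_sigma_y)
                       for v in range(4))
        assert gp.log_marginal_likelihood(y, m, mean=mean) == pytest.approx(expected)

    def test_quadratic_term_scale_invariance(self, rng):
        """Scaling sigma_n2, lambda and y^2 jointly by c leaves the quadratic
        term invariant (only the log-det shifts)."""
        sch = two_shell_scheme(4, n_b0=0, seed=1)
        y = rng.normal(size=(5, 8))
        mean = np.zeros_like(y)
        c = 7.3
        h1 = gp.GPHyperparameters(a=0.8, l=1.0, lambda_=1.0, sigma_n2=np.array([0.3, 0.4]))
        h2 = gp.GPHyperparameters(a=0.8, l=1.0, lambda_=c, sigma_n2=c * np.array([0.3, 0.4]))
        m1 = gp.build_covariance(sch, h1)
        m2 = gp.build_covariance(sch, h2)
        l1 = gp.log_marginal_likelihood(y, m1, mean=mean)
        l2 = gp.log_marginal_likelihood(np.sqrt(c) * y, m2, mean=mean)
        nd, nv = 8, 5
        logdet_shift = 0.5 * nv * nd * np.log(c)
        assert l2 == pytest.approx(l1 - logdet_shift, rel=1e-9)


class TestGPPredict:
    def test_scalar_closed_form(self):
        sch = QSpaceScheme([1000.0], [[1, 0, 0]])
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=1.0, sigma_n2=np.array([1.0]))
        m = gp.build_covariance(sch, h)
        mean, var = gp.gp_predict(m, np.array([[2.0]]), mean=np.array([[0.0]]))
        assert mean[0, 0] == pytest.approx(1.0)  # 2 * 1/(1+1)
        assert var[0] == pytest.approx(0.5)

    def test_noise_free_limit_interpolates(self, rng):
        sch = two_shell_scheme(6, n_b0=0, seed=2)
        h = gp.GPHyperparameters(a=1.2, l=1.0, lambda_=1.0,
                                 sigma_n2=np.array([1e-12, 1e-12]))
        m = gp.build_covariance(sch, h)
        y = rng.normal(size=(3, 12))
        mean, _ = gp.gp_predict(m, y)
        assert np.allclose(mean, y, atol=1e-5)

    def test_lambda_zero_returns_prior_mean(self, rng):
        sch = two_shell_scheme(6, n_b0=0, seed=2)
        h = gp.GPHyperparameters(a=1.2, l=1.0, lambda_=0.0,
                                 sigma_n2=np.array([1.0, 1.0]))
        m = gp.build_covariance(sch, h)
        y = rng.normal(size=(3, 12))
        mu = gp.shell_means(y, sch)
        mean, _ = gp.gp_predict(m, y)
        assert np.allclose(mean, mu)

    def test_matches_dense_normal_equation_oracle(self, rng):
        """Posterior mean solves argmin 1/(2 sn2)||u-y||^2 + 1/2 (u-mu)' S^-1 (u-mu):
        dense oracle solves (S^-1 + I/sn2) u = y/sn2 + S^-1 mu directly."""
        sch = two_shell_scheme(5, n_b0=0, seed=4)  # 10 directions
        sn2 = 0.3
        h = gp.GPHyperparameters(a=1.0, l=0.8, lambda_=1.5,
                                 sigma_n2=np.array([sn2, sn2]))
        m = gp.build_covariance(sch, h)
        y = rng.normal(size=(2, 10))
        mu = gp.shell_means(y, sch)
        S = m.cov_sigma + 1e-12 * np.eye(10)
        Sinv = np.linalg.inv(S)
        lhs = Sinv + np.eye(10) / sn2
        for v in range(2):
            u_oracle = np.linalg.solve(lhs, y[v] / sn2 + Sinv @ mu[v])
            u_gp, _ = gp.gp_predict(m, y[v:v + 1])
            assert np.linalg.norm(u_gp[0] - u_oracle) / np.linalg.norm(u_oracle) < 1e-8

    def test_shrinkage_monotone_in_noise(self):
        """Scalar posterior mean moves monotonically toward the prior mean as
        the noise variance grows."""
        sch = QSpaceScheme([1000.0], [[1, 0, 0]])
        y = np.array([[3.0]])
        prev = 3.0
        for sn2 in (0.1, 0.5, 1.0, 5.0, 50.0):
            h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=1.0,
                                     sigma_n2=np.array([sn2]))
            m = gp.build_covariance(sch, h)
            mean, _ = gp.gp_predict(m, y, mean=np.array([[0.0]]))
            assert 0 < mean[0, 0] < prev
            prev = mean[0, 0]

    def test_rotation_equivariance(self, rng):
        """Jointly rotating all gradient directions leaves predictions
        unchanged (the covariance depends only on relative geometry)."""
        sch = two_shell_scheme(8, n_b0=0, seed=5)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        sch_rot = QSpaceScheme(sch.bvals, sch.bvecs @ R.T, sch.shell_ids)
        h = gp.GPHyperparameters(a=1.0, l=1.0, lambda_=1.0,
                                 sigma_n2=np.array([0.2, 0.2]))
        y = rng.normal(size=(3, 16))
        m1, _ = gp.gp_predict(gp.build_covariance(sch, h), y)
        m2, _ = gp.gp_predict(gp.build_covariance(sch_rot, h), y)
        assert np.allclose(m1, m2, atol=1e-10)


class TestFitHyperparameters:
    def test_noise_free_gp_draws_fit_tiny_noise(self, rng):
        sch = two_shell_scheme(24, n_b0=0, seed=1)
        h = gp.GPHyperparameters(a=np.deg2rad(50), l=1.0, lambda_=1.0,
                                 sigma_n2=np.array([1e-10, 1e-10]))
        m = gp.build_covariance(sch, h)
        L = np.linalg.cholesky(m.cov_sigma + 1e-10 * np.eye(48))
        y = 5.0 + (L @ rng.normal(size=(48, 400))).T
        fit = gp.fit_hyperparameters_single(y, sch, init_sigma2=1e-4, seed=0,
                                            maxiter=100)
        assert np.all(fit.sigma_n2 < 1e-3 * fit.lambda_)

    def test_scale_equivariance(self, rng):
        """Doubling the signal amplitude quadruples lambda and leaves the
        geometry hyperparameters a and l unchanged within tolerance."""
        sch = two_shell_scheme(24, n_b0=0, seed=2)
        h = gp.GPHyperparameters(a=np.deg2rad(45), l=1.0, lambda_=1.0,
                                 sigma_n2=np.array([1e-3, 1e-3]))
        m = gp.build_covariance(sch, h)
        L = np.linalg.cholesky(m.cov_sigma + 1e-10 * np.eye(48))
        base = (L @ rng.normal(size=(48, 400))).T
        noise = rng.normal(0, np.sqrt(1e-3), (400, 48))
        f1 = gp.fit_hyperparameters_single(5 + base + noise, sch,
                                           init_sigma2=1e-3, seed=0, maxiter=100)
        f2 = gp.fit_hyperparameters_single(2 * (5 + base + noise), sch,
                                           init_sigma2=4e-3, seed=0, maxiter=100)
        assert np.sqrt(f2.lambda_ / f1.lambda_) == pytest.approx(2.0, rel=0.1)
        assert abs(np.degrees(f2.a - f1.a)) < 5
        assert f2.l == pytest.approx(f1.l, rel=0.3)

    def test_empty_tissue_class_falls_back_with_warning(self, rng):
        sch = two_shell_scheme(12, n_b0=0, seed=3)
        y = 5 + rng.normal(0, 0.1, (100, 24))
        labels = np.array(["white"] * 100)
        with pytest.warns(UserWarning, match="gray"):
            out = gp.fit_hyperparameters(y, sch, tissue_labels=labels,
                                         init_sigma2=0.01, maxiter=30,
                                         max_voxels=100)
        assert set(out) == {"white", "gray", "other"}
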