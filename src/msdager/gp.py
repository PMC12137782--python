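"""Gaussian-process model of multi-shell diffusion MRI signals in q-space.

The signal of one voxel across all diffusion directions is modelled as a
multivariate Gaussian u ~ N(mu, Sigma).  The covariance between two q-space
samples factorizes into a within-shell angular part and a cross-shell part:

    C(q, q') = C_theta(theta; a) * C_b(b, b'; l)

where C_theta is the compact-support spherical covariance with angular range
``a`` and C_b is squared-exponential in log(b) with length-scale ``l``.  The
angular distance uses antipodal symmetry (the diffusion signal at q and -q is
identical), so theta lives in [0, pi/2].

Noisy data y adds per-shell noise variance on the diagonal:
Sigma_y = Sigma + diag(sigma_n^2 per shell).  Per-shell noise accounts for
Rician bias of magnitude data varying with shell SNR.  Hyperparameters
(a, l, lambda, sigma_n^2 per shell) are fitted by maximizing the marginal
likelihood over voxels; the MAP signal estimate is the GP posterior mean

    u_bar = mu + Sigma (Sigma_y)^-1 (y - mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .scheme import QSpaceScheme


def angular_distance(q1, q2, antipodal: bool = True) -> np.ndarray:
    """Great-circle distance between unit direction(s), optionally antipodal.

    With ``antipodal=True`` (the dMRI case) returns arccos(|q1.q2|) in
    [0, pi/2]; otherwise arccos(q1.q2) in [0, pi].
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    for q in (q1, q2):
        n = np.linalg.norm(q, axis=-1)
        if np.any(n < 1e-12):
            raise ValueError("zero vector has no direction")
        if np.any(np.abs(n - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors")
    dot = np.sum(q1 * q2, axis=-1)
    if antipodal:
        dot = np.abs(dot)
    return np.arccos(np.clip(dot, -1.0, 1.0))


def cov_within_shell(theta, a: float) -> np.ndarray:
    """Spherical covariance: 1 - 3 theta/(2a) + theta^3/(2 a^3) for theta <= a, else 0."""
    if a <= 0:
        raise ValueError("angular range a must be positive")
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("angular distance must be nonnegative")
    t = theta / a
    c = 1.0 - 1.5 * t + 0.5 * t ** 3
    return np.where(theta <= a, c, 0.0)


def cov_between_shells(b1, b2, l: float) -> np.ndarray:
    """Squared-exponential covariance in log b: exp(-(log b1 - log b2)^2 / (2 l^2))."""
    if l <= 0:
        raise ValueError("length-scale l must be positive")
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if np.any(b1 <= 0) or np.any(b2 <= 0):
        raise ValueError("b-values must be positive (b=0 volumes are outside the GP)")
    d = np.log(b1) - np.log(b2)
    return np.exp(-(d ** 2) / (2.0 * l ** 2))


@dataclass
class GPHyperparameters:
    """Hyperparameters of the multi-shell q-space GP.

    a : angular support of the spherical covariance, radians, in (0, pi/2].
    l : log-b length-scale of the cross-shell covariance (unitless).
    lambda_ : signal variance (image-intensity units squared).
    sigma_n2 : per-shell noise variance, one entry per DWI shell.
    """

    a: float
    l: float
    lambda_: float
    sigma_n2: np.ndarray

    def __post_init__(self):
        self.sigma_n2 = np.atleast_1d(np.asarray(self.sigma_n2, dtype=float))
        if not (0 < self.a <= np.pi / 2 + 1e-9):
            raise ValueError("a must lie in (0, pi/2]")
        if self.l <= 0:
            raise ValueError("l must be positive")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")
        if np.any(self.sigma_n2 <= 0):
            raise ValueError("sigma_n2 must be positive for every shell")

    def to_dict(self) -> dict:
        return {"a": float(self.a), "l": float(self.l), "lambda": float(self.lambda_),
                "sigma_n2": [float(s) for s in self.sigma_n2]}


@dataclass
class GPModel:
    """A fitted GP over the DWI volumes of a scheme (b=0 volumes excluded)."""

    hyper: GPHyperparameters
    scheme: QSpaceScheme  # DWI-only scheme
    cov_sigma: np.ndarray
    cov_sigma_y: np.ndarray
    cross_shell: bool = True

    @property
    def n_directions(self) -> int:
        return self.scheme.n_volumes


def build_covariance(scheme: QSpaceScheme, hyper: GPHyperparameters,
                     cross_shell: bool = True) -> GPModel:
    """Assemble Sigma and Sigma_y for all DWI volumes of ``scheme``.

    Sigma_ij = lambda * C_theta(theta_ij; a) * C_b(b_i, b_j; l) with antipodal
    angular distance.  With ``cross_shell=False`` the cross-shell factor is
    replaced by a same-shell indicator (the single-shell ablation: shells are
    decoupled).  Sigma_y adds each volume's shell noise variance on the
    diagonal.
    """
    if np.any(scheme.is_b0):
        raise ValueError("GP operates on DWI volumes only; drop b=0 volumes first")
    g = scheme.bvecs
    dot = np.abs(g @ g.T)
    theta = np.arccos(np.clip(dot, -1.0, 1.0))
    ctheta = cov_within_shell(theta, hyper.a)
    if cross_shell:
        cb = cov_between_shells(scheme.bvals[:, None], scheme.bvals[None, :], hyper.l)
    else:
        cb = (scheme.shell_ids[:, None] == scheme.shell_ids[None, :]).astype(float)
    sigma = hyper.lambda_ * ctheta * cb
    sigma = 0.5 * (sigma + sigma.T)
    shell_idx = _shell_index(scheme)
    sigma_y = sigma + np.diag(hyper.sigma_n2[shell_idx])
    return GPModel(hyper=hyper, scheme=scheme, cov_sigma=sigma, cov_sigma_y=sigma_y,
                   cross_shell=cross_shell)


def _shell_index(scheme: QSpaceScheme) -> np.ndarray:
    """Map each volume's shell id to a dense 0..n_shells-1 index."""
    ids = np.unique(scheme.shell_ids)
    lut = {int(s): k for k, s in enumerate(ids)}
    return np.array([lut[int(s)] for s in scheme.shell_ids])


def _chol(mat: np.ndarray, scale: float):
    """Cholesky with escalating jitter fallback (logged via warnings)."""
    jitter = 0.0
    base = max(scale, 1e-30)
    for attempt in range(6):
        try:
            return cho_factor(mat + jitter * np.eye(mat.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = base * 10.0 ** (attempt - 8)
    warnings.warn(f"covariance not positive definite even with jitter {jitter:g}")
    raise np.linalg.LinAlgError("covariance matrix is not positive definite")


def shell_means(signals: np.ndarray, scheme: QSpaceScheme) -> np.ndarray:
    """Per-voxel, per-shell mean signal, broadcast back to (V, Nd).

    This is the GP mean mu: a per-shell constant respects the large intensity
    offset between shells while leaving angular structure to the covariance.
    """
    signals = np.atleast_2d(signals)
    mu = np.empty_like(signals, dtype=float)
    for s in np.unique(scheme.shell_ids):
        cols = scheme.shell_ids == s
        mu[:, cols] = signals[:, cols].mean(axis=1, keepdims=True)
    return mu


def log_marginal_likelihood(signals: np.ndarray, model: GPModel,
                            mean: np.ndarray | None = None) -> float:
    """Sum over voxels of the Gaussian log evidence under Sigma_y.

    ``signals`` is (V, Nd) magnitude data; ``mean`` defaults to the per-voxel
    per-shell mean.
    """
    y = np.atleast_2d(np.asarray(signals, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("signals must be finite")
    mu = shell_means(y, model.scheme) if mean is None else np.atleast_2d(mean)
    r = (y - mu).T  # (Nd, V)
    nd, nv = r.shape
    c = _chol(model.cov_sigma_y, model.hyper.lambda_ + model.hyper.sigma_n2.max())
    alpha = cho_solve(c, r)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    quad = float(np.sum(r * alpha))
    return -0.5 * quad - 0.5 * nv * logdet - 0.5 * nv * nd * np.log(2 * np.pi)


def gp_predict(model: GPModel, observed: np.ndarray,
               mean: np.ndarray | None = None):
    """MAP estimate of the q-space signal and its posterior variance.

    Closed form of the Gaussian posterior: u_bar = mu + Sigma Sigma_y^-1 (y - mu),
    posterior covariance Sigma - Sigma Sigma_y^-1 Sigma (its diagonal is
    returned; it is direction-wise and voxel-independent).
    """
    y = np.atleast_2d(np.asarray(observed, dtype=float))
    mu = shell_means(y, model.scheme) if mean is None else np.atleast_2d(mean)
    c = _chol(model.cov_sigma_y, model.hyper.lambda_ + model.hyper.sigma_n2.max())
    alpha = cho_solve(c, (y - mu).T)  # (Nd, V)
    post_mean = mu + (model.cov_sigma @ alpha).T
    inv_sigma = cho_solve(c, model.cov_sigma)
    post_var = np.diag(model.cov_sigma) - np.einsum("ij,ji->i", model.cov_sigma, inv_sigma)
    return post_mean, np.maximum(post_var, 0.0)


def loo_error_variance(signals: np.ndarray, model: GPModel) -> np.ndarray:
    """Leave-one-direction-out prediction error variance per shell.

    Closed form from the precision matrix (Rasmussen & Williams 5.4.2): the
    LOO residual for direction i is alpha_i / [K^-1]_ii with
    alpha = K^-1 (y - mu).  This measures how well the fitted GP actually
    predicts held-out directions of ``signals`` — an empirical error bar for
    the GP prediction that stays honest when the covariance model is
    misspecified (e.g. when reconstruction artifacts contaminate the data).
    """
    y = np.atleast_2d(np.asarray(signals, dtype=float))
    mu = shell_means(y, model.scheme)
    r = (y - mu).T  # (Nd, V)
    c = _chol(model.cov_sigma_y, model.hyper.lambda_ + model.hyper.sigma_n2.max())
    kinv = cho_solve(c, np.eye(r.shape[0]))
    d = np.diag(kinv)
    resid = (kinv @ r) / d[:, None]
    sid = _shell_index(model.scheme)
    return np.array([float(np.mean(resid[sid == s] ** 2))
                     for s in range(sid.max() + 1)])


def restricted_lml(signals: np.ndarray, model: GPModel) -> float:
    """REML evidence with the per-voxel per-shell mean integrated out.

    The GP mean is a per-shell constant estimated from the same data; the
    plain likelihood of empirically centered residuals is biased toward
    diagonal (all-noise) covariances because centering removes exactly the
    smooth signal component.  The restricted likelihood accounts for the
    mean estimation: with X the per-shell constant design and V = Sigma_y,

        l = -1/2 [ log det V + log det(X^T V^-1 X) + min_beta (y - X beta)^T
            V^-1 (y - X beta) ]  + const,

    summed over voxels (V is shared, the GLS mean beta is per-voxel).
    """
    y = np.atleast_2d(np.asarray(signals, dtype=float)).T  # (Nd, V)
    nd, nv = y.shape
    scheme = model.scheme
    ids = np.unique(scheme.shell_ids)
    X = (scheme.shell_ids[:, None] == ids[None, :]).astype(float)  # (Nd, S)
    c = _chol(model.cov_sigma_y, model.hyper.lambda_ + model.hyper.sigma_n2.max())
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    A = X.T @ Vi_X  # (S, S)
    XtViy = X.T @ Vi_y  # (S, V)
    cA = cho_factor(A, lower=True)
    quad = float(np.sum(y * Vi_y)) - float(np.sum(XtViy * cho_solve(cA, XtViy)))
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    logdet_a = 2.0 * np.sum(np.log(np.diag(cA[0])))
    p = X.shape[1]
    return (-0.5 * quad - 0.5 * nv * (logdet_v + logdet_a)
            - 0.5 * nv * (nd - p) * np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# hyperparameter fitting

def _pack(hyper: GPHyperparameters) -> np.ndarray:
    za = hyper.a / (np.pi / 2)
    za = np.clip(za, 1e-4, 1 - 1e-4)
    return np.concatenate([[np.log(za / (1 - za)), np.log(hyper.l),
                            np.log(max(hyper.lambda_, 1e-12))],
                           np.log(hyper.sigma_n2)])


def _unpack(x: np.ndarray, n_shells: int) -> GPHyperparameters:
    a = (np.pi / 2) / (1.0 + np.exp(-x[0]))
    return GPHyperparameters(a=float(a), l=float(np.exp(x[1])),
                             lambda_=float(np.exp(x[2])),
                             sigma_n2=np.exp(x[3:3 + n_shells]))


def fit_hyperparameters_single(signals: np.ndarray, scheme: QSpaceScheme,
                               init_sigma2: float, cross_shell: bool = True,
                               max_voxels: int = 2000, seed: int = 0,
                               maxiter: int = 150,
                               sigma2_floor: float = 0.0,
                               lambda_min: float = 0.0) -> GPHyperparameters:
    """Maximize the restricted marginal likelihood for one voxel population.

    Bound-constrained quasi-Newton (L-BFGS-B) on log/logit-transformed
    parameters, multi-start from three deterministic initial points spanning
    narrow/wide angular support.  Voxels beyond ``max_voxels`` are subsampled
    for tractability.

    ``sigma2_floor`` and ``lambda_min`` bound the fitted variances from
    below.  They are used during reconstruction, where independent
    measurements exist: the VST noise estimate (the fit must not claim less
    noise than measured) and the initial signal-variance estimate (the
    q-space signal variance of the object does not shrink while the
    alternation denoises, so the fit must not explain it away — without this
    the alternation has a degenerate fixed point that smooths all angular
    structure into the mean).
    """
    y = np.atleast_2d(np.asarray(signals, dtype=float))
    if y.shape[0] > max_voxels:
        rng = np.random.default_rng(seed)
        y = y[rng.choice(y.shape[0], max_voxels, replace=False)]
    mu = shell_means(y, scheme)
    resid_var = float(np.mean((y - mu) ** 2))
    resid_var = max(resid_var, 1e-12)
    n_shells = np.unique(scheme.shell_ids).size
    s2 = float(max(init_sigma2, 1e-10))

    lam0 = max(resid_var - s2, 0.1 * resid_var)
    starts = [
        GPHyperparameters(a=np.deg2rad(30), l=1.0, lambda_=lam0, sigma_n2=np.full(n_shells, s2)),
        GPHyperparameters(a=np.deg2rad(60), l=0.5, lambda_=lam0, sigma_n2=np.full(n_shells, s2)),
        GPHyperparameters(a=np.deg2rad(85), l=2.0, lambda_=0.5 * resid_var,
                          sigma_n2=np.full(n_shells, max(0.5 * resid_var, 1e-10))),
    ]

    def neg_lml(x):
        try:
            h = _unpack(x, n_shells)
            model = build_covariance(scheme, h, cross_shell=cross_shell)
            return -restricted_lml(y, model)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12

    # bounds keep a in [0.9deg, 89.5deg], l in [e^-3, e^3] and the variances
    # within 12 decades of the residual scale (prevents degenerate collapse)
    log_scale = np.log(resid_var)
    s2_lo = max(log_scale - 14, np.log(sigma2_floor) if sigma2_floor > 0 else -np.inf)
    lam_lo = max(log_scale - 14, np.log(lambda_min) if lambda_min > 0 else -np.inf)
    bounds = ([(-4.6, 5.3), (-3.0, 3.0),
               (min(lam_lo, log_scale + 5), log_scale + 6)]
              + [(min(s2_lo, log_scale + 5), log_scale + 6)] * n_shells)
    best_x, best_f = None, np.inf
    for h0 in starts:
        x0 = np.clip(_pack(h0), [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-10})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return _unpack(best_x, n_shells)


def fit_hyperparameters(signals: np.ndarray, scheme: QSpaceScheme,
                        tissue_labels: np.ndarray | None = None,
                        init_sigma2: float = 1e-4, cross_shell: bool = True,
                        max_voxels: int = 2000, seed: int = 0,
                        maxiter: int = 150, sigma2_floor: float = 0.0,
                        lambda_min: float = 0.0) -> dict:
    """Per-tissue-class hyperparameter fits.

    ``tissue_labels`` assigns each voxel-row of ``signals`` to ``"white"``,
    ``"gray"`` or ``"other"``; "other" reuses the gray-matter values (white
    and gray matter dominate and differ most in diffusivity).  With no labels
    (or an empty class) a whole-population fit is used, with a warning for
    the empty-class case.
    """
    y = np.atleast_2d(np.asarray(signals, dtype=float))
    if tissue_labels is None:
        h = fit_hyperparameters_single(y, scheme, init_sigma2, cross_shell,
                                       max_voxels, seed, maxiter, sigma2_floor,
                                       lambda_min)
        return {"white": h, "gray": h, "other": h}
    labels = np.asarray(tissue_labels)
    out: dict = {}
    fallback = None
    for cls in ("white", "gray"):
        m = labels == cls
        if m.sum() < 10:
            warnings.warn(f"tissue class '{cls}' has too few voxels; using whole-brain fit")
            if fallback is None:
                fallback = fit_hyperparameters_single(y, scheme, init_sigma2, cross_shell,
                                                      max_voxels, seed, maxiter,
                                                      sigma2_floor, lambda_min)
            out[cls] = fallback
        else:
            out[cls] = fit_hyperparameters_single(y[m], scheme, init_sigma2, cross_shell,
                                                  max_voxels, seed, maxiter, sigma2_floor,
                                                  lambda_min)
    out["other"] = replace(out["gray"])
    return out
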