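"""Univariate polygenic variance-component model.

The polygenic model for a quantitative trait y measured on n pedigree members
is y ~ N(X beta, Omega) with

    Omega = 2*Phi * sigma_a^2 + I_n * sigma_e^2,

where 2*Phi is the additive-relationship matrix, sigma_a^2 the additive
genetic variance and sigma_e^2 the individual-specific environmental
variance. Narrow-sense heritability is h^2 = sigma_a^2 / (sigma_a^2 +
sigma_e^2). Fitting is by maximum likelihood: a single eigendecomposition of
2*Phi turns every likelihood evaluation into diagonal weighted least squares,
and both beta (by GLS) and the total variance are profiled out in closed
form, leaving a one-dimensional search over h^2 in [0, 1).

The test of h^2 = 0 is a likelihood-ratio test against the boundary mixture
(1/2) chi2_0 + (1/2) chi2_1, the standard null for a variance component
constrained to be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .pedigree import KinshipMatrix
from .traits import CovariateDesign

__all__ = [
    "VarianceComponentFit",
    "PolygenicModel",
    "polygenic_loglik",
    "fit_polygenic",
    "h2_lrt",
]

_LOG2PI = np.log(2.0 * np.pi)

#: heritability values above this are treated as the upper boundary
_H2_MAX = 1.0 - 1e-6


def _as_two_phi(kinship) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(kinship, KinshipMatrix):
        return kinship.two_phi, list(kinship.ids)
    arr = np.asarray(kinship, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("kinship must be a square matrix or KinshipMatrix")
    return arr, None


def _as_design(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    """Return (matrix, column labels, ids) from a design of any accepted form."""
    if isinstance(X, CovariateDesign):
        return X.matrix, list(X.columns), list(X.ids)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None, None


def _validate_xy(X: np.ndarray, y: np.ndarray, two_phi: np.ndarray):
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    n = y.shape[0]
    if X.shape[0] != n or two_phi.shape[0] != n:
        raise ValueError(
            f"dimension mismatch: n={n}, X rows={X.shape[0]}, "
            f"kinship rows={two_phi.shape[0]}"
        )
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("y and X must be finite (apply complete-case filtering first)")


def _eigen_two_phi(two_phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of 2*Phi with eigenvalues clipped at zero."""
    d, U = np.linalg.eigh(np.asarray(two_phi, dtype=float))
    return np.maximum(d, 0.0), U


def _profile(h2: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profile loglik at fixed h2: closed-form GLS beta and total variance.

    V(h2) = h2 * 2Phi + (1 - h2) * I has eigenvalues w = 1 + h2 (d - 1).
    Returns (loglik, beta, sigma_p2, Q) with Q the GLS residual quadratic
    form in V-metric (so sigma_p2 = Q / n).
    """
    n = yt.shape[0]
    w = 1.0 + h2 * (d - 1.0)
    w = np.maximum(w, 1e-12)
    wi = 1.0 / w
    Xw = Xt * wi[:, None]
    xtx = Xt.T @ Xw
    xty = Xw.T @ yt
    beta = np.linalg.solve(xtx, xty)
    r = yt - Xt @ beta
    Q = float(np.dot(r * wi, r))
    sigma_p2 = max(Q / n, 1e-300)
    loglik = -0.5 * (n * _LOG2PI + n * np.log(sigma_p2) + np.log(w).sum() + n)
    return loglik, beta, sigma_p2, Q


def polygenic_loglik(y, X, two_phi, sigma_a2: float, sigma_e2: float, beta) -> float:
    """Log-likelihood of the polygenic model at explicit parameter values.

    Evaluates -1/2 [n ln 2pi + ln|Omega| + (y - X beta)' Omega^{-1} (y - X beta)]
    with Omega = 2Phi sigma_a2 + I sigma_e2, via the eigendecomposition of
    2Phi (reusable across variance evaluations).
    """
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    if sigma_a2 < 0:
        raise ValueError("sigma_a2 must be non-negative")
    X, _, _ = _as_design(X)
    y = np.asarray(y, dtype=float)
    two_phi, _ = _as_two_phi(two_phi)
    _validate_xy(X, y, two_phi)
    d, U = _eigen_two_phi(two_phi)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    r = U.T @ (y - X @ beta)
    w = sigma_a2 * d + sigma_e2
    if np.any(w <= 0):
        raise ValueError("Omega is numerically singular")
    n = y.shape[0]
    return float(-0.5 * (n * _LOG2PI + np.log(w).sum() + np.dot(r / w, r)))


def h2_lrt(loglik_full: float, loglik_null: float) -> float:
    """Boundary LRT p-value for h^2 = 0 under the 1/2 chi2_0 + 1/2 chi2_1 mixture.

    Lambda = 2 (l_full - l_null), clipped at 0; p = 0.5 P(chi2_1 >= Lambda),
    so Lambda = 0 gives p = 0.5.
    """
    if loglik_full < loglik_null - 1e-6:
        raise ValueError("full-model log-likelihood below null (models not nested?)")
    lam = max(0.0, 2.0 * (loglik_full - loglik_null))
    return float(0.5 * stats.chi2.sf(lam, df=1)) if lam > 0 else 0.5


@dataclass
class VarianceComponentFit:
    """Result of a univariate polygenic fit."""

    h2: float
    h2_se: float
    sigma_a2: float
    sigma_e2: float
    beta_cov: np.ndarray
    loglik: float
    loglik_null: float
    p_h2: float
    n_used: int
    columns: list[str] | None = None
    converged: bool = True
    degenerate: bool = False
    beta_se: np.ndarray | None = field(default=None, repr=False)

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2


class PolygenicModel(BaseEstimator):
    """Maximum-likelihood univariate polygenic model (sklearn-style estimator).

    Parameters
    ----------
    kinship : KinshipMatrix or (n, n) array
        The additive-relationship structure. A :class:`KinshipMatrix` carries
        ids and is aligned to the design by id when the design is a
        :class:`CovariateDesign`; a raw array is taken as 2*Phi already
        aligned to the rows of ``X``.
    n_grid : int
        Points in the coarse h^2 grid that brackets the 1-D refinement.
    tol : float
        Absolute tolerance on h^2 in the bounded refinement.
    se_step : float
        Central-difference step for the observed-information standard error,
        taken in (h^2, ln sigma_p^2) coordinates.

    Attributes (after fit)
    ----------------------
    h2_, h2_se_, sigma_a2_, sigma_e2_, sigma_p2_, beta_, beta_se_, loglik_,
    loglik_null_, p_value_ (boundary LRT of h^2 = 0), n_used_, converged_,
    degenerate_, result_ (a :class:`VarianceComponentFit`).
    """

    def __init__(self, kinship=None, n_grid: int = 21, tol: float = 1e-9,
                 se_step: float = 1e-4):
        self.kinship = kinship
        self.n_grid = n_grid
        self.tol = tol
        self.se_step = se_step

    # -- internal ---------------------------------------------------------

    def _resolve(self, X, y):
        if self.kinship is None:
            raise ValueError("PolygenicModel requires a kinship matrix")
        Xm, columns, x_ids = _as_design(X)
        y = np.asarray(y, dtype=float).ravel()
        two_phi, k_ids = _as_two_phi(self.kinship)
        if x_ids is not None and k_ids is not None:
            kin = self.kinship.subset(x_ids)
            two_phi = kin.two_phi
        _validate_xy(Xm, y, two_phi)
        if y.shape[0] <= Xm.shape[1] + 2:
            raise ValueError(
                f"too few individuals (n={y.shape[0]}) for "
                f"{Xm.shape[1]} design columns"
            )
        return Xm, columns, y, two_phi

    def fit(self, X, y, eigen=None):
        """Fit by ML. ``eigen=(d, U)`` may pass a precomputed decomposition
        of the aligned 2*Phi (reused across traits or SNPs on the same
        individuals)."""
        Xm, columns, y, two_phi = self._resolve(X, y)
        n = y.shape[0]
        if eigen is None:
            d, U = _eigen_two_phi(two_phi)
        else:
            d, U = eigen
        yt = U.T @ y
        Xt = U.T @ Xm

        grid = np.linspace(0.0, _H2_MAX, self.n_grid)
        lls = np.array([_profile(h, d, yt, Xt)[0] for h in grid])
        k = int(np.argmax(lls))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        converged = True
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda h: -_profile(h, d, yt, Xt)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": self.tol},
            )
            h2_hat = float(res.x)
            converged = bool(res.success)
            if -res.fun < lls[k]:  # safeguard: keep the better grid point
                h2_hat = float(grid[k])
        else:
            h2_hat = float(grid[k])
        # snap to the boundary when indistinguishable from it
        ll_at = _profile(h2_hat, d, yt, Xt)[0]
        ll_0 = lls[0]
        if h2_hat < 1e-6 or ll_at <= ll_0 + 1e-12:
            if ll_0 >= ll_at - 1e-12:
                h2_hat = 0.0

        loglik, beta, sigma_p2, _ = _profile(h2_hat, d, yt, Xt)
        loglik_null = float(lls[0])
        var_y = float(np.var(y)) if n > 1 else 0.0
        degenerate = sigma_p2 * (1.0 - h2_hat) <= 1e-10 * max(var_y, 1e-30)

        self.h2_ = float(h2_hat)
        self.sigma_p2_ = float(sigma_p2)
        self.sigma_a2_ = float(h2_hat * sigma_p2)
        self.sigma_e2_ = float((1.0 - h2_hat) * sigma_p2)
        self.beta_ = beta
        self.loglik_ = float(loglik)
        self.loglik_null_ = loglik_null
        self.p_value_ = h2_lrt(self.loglik_, self.loglik_null_)
        self.n_used_ = int(n)
        self.converged_ = converged
        self.degenerate_ = bool(degenerate)
        self.columns_ = columns
        self.h2_se_ = self._h2_se(d, yt, Xt, h2_hat, sigma_p2)
        self.beta_se_ = self._beta_se(d, Xt, h2_hat, sigma_p2)
        self._eigen_ = (d, U)
        self.result_ = VarianceComponentFit(
            h2=self.h2_, h2_se=self.h2_se_, sigma_a2=self.sigma_a2_,
            sigma_e2=self.sigma_e2_, beta_cov=self.beta_, loglik=self.loglik_,
            loglik_null=self.loglik_null_, p_h2=self.p_value_,
            n_used=self.n_used_, columns=columns, converged=converged,
            degenerate=self.degenerate_, beta_se=self.beta_se_,
        )
        return self

    def _h2_se(self, d, yt, Xt, h2_hat, sigma_p2) -> float:
        """SE from the observed information in (h2, ln sigma_p2) coordinates."""
        eps = self.se_step
        if self.degenerate_ or h2_hat < eps or h2_hat > 1.0 - eps:
            return float("nan")
        n = yt.shape[0]
        s_hat = np.log(sigma_p2)

        def ll(h2, s):
            w = np.maximum(1.0 + h2 * (d - 1.0), 1e-12)
            wi = 1.0 / w
            Xw = Xt * wi[:, None]
            beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
            r = yt - Xt @ beta
            Q = float(np.dot(r * wi, r))
            return -0.5 * (n * _LOG2PI + n * s + np.log(w).sum() + Q * np.exp(-s))

        f0 = ll(h2_hat, s_hat)
        H = np.empty((2, 2))
        f_pp = ll(h2_hat + eps, s_hat + eps)
        f_pm = ll(h2_hat + eps, s_hat - eps)
        f_mp = ll(h2_hat - eps, s_hat + eps)
        f_mm = ll(h2_hat - eps, s_hat - eps)
        H[0, 0] = (ll(h2_hat + eps, s_hat) - 2 * f0 + ll(h2_hat - eps, s_hat)) / eps**2
        H[1, 1] = (ll(h2_hat, s_hat + eps) - 2 * f0 + ll(h2_hat, s_hat - eps)) / eps**2
        H[0, 1] = H[1, 0] = (f_pp - f_pm - f_mp + f_mm) / (4 * eps**2)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return float("nan")
        v = cov[0, 0]
        return float(np.sqrt(v)) if v > 0 else float("nan")

    def _beta_se(self, d, Xt, h2, sigma_p2) -> np.ndarray:
        w = np.maximum(1.0 + h2 * (d - 1.0), 1e-12)
        xtx = Xt.T @ (Xt / w[:, None])
        cov = sigma_p2 * np.linalg.inv(xtx)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))


def fit_polygenic(y, X, two_phi, **kwargs) -> VarianceComponentFit:
    """Functional wrapper over :class:`PolygenicModel`."""
    model = PolygenicModel(kinship=two_phi, **kwargs).fit(X, y)
    return model.result_
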