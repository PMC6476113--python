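"""Bivariate polygenic model: genetic and environmental cross-trait correlation.

For traits A and B on the same n pedigree members, the 2n-dimensional normal
model has within-trait covariance blocks 2Phi sigma_a^2 + I sigma_e^2 (as in
the univariate model) and cross-trait block

    2Phi * rho_g sigma_aA sigma_aB + I * rho_e sigma_eA sigma_eB,

where rho_g is the additive genetic correlation and rho_e the environmental
correlation. The derived phenotypic correlation is

    rho_p = rho_g sqrt(h2_A h2_B) + rho_e sqrt((1 - h2_A)(1 - h2_B)).

rho_g indexes pleiotropy: |rho_g| = 1 means a fully shared genetic basis
("complete"), rho_g = 0 none, anything between "incomplete". The likelihood
is evaluated through one eigendecomposition of 2Phi, which block-diagonalizes
the 2n x 2n covariance into n independent 2x2 problems (O(n) per evaluation);
fixed effects for both traits are profiled out jointly by GLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .traits import CovariateDesign
from .vc import _as_design, _as_two_phi, _eigen_two_phi, _validate_xy, PolygenicModel

__all__ = [
    "BivariateFit",
    "BivariateModel",
    "bivariate_loglik",
    "fit_bivariate",
    "classify_pleiotropy",
    "phenotypic_correlation",
]

_LOG2PI = np.log(2.0 * np.pi)

#: |rho_g| at or beyond this is treated as the boundary (complete pleiotropy)
_RHO_BOUNDARY = 1.0 - 1e-6


def phenotypic_correlation(rho_g, rho_e, h2_a, h2_b) -> float:
    """rho_p from its genetic and environmental parts (exact identity)."""
    return float(
        rho_g * np.sqrt(h2_a * h2_b) + rho_e * np.sqrt((1.0 - h2_a) * (1.0 - h2_b))
    )


def classify_pleiotropy(rho_g: float, tol: float = 1e-6) -> str:
    """Map a fitted genetic correlation to its pleiotropy class."""
    if abs(rho_g) >= 1.0 - tol:
        return "complete"
    if abs(rho_g) <= tol:
        return "none"
    return "incomplete"


def _blocks(theta: np.ndarray, d: np.ndarray):
    """Per-eigenvalue 2x2 covariance entries for parameter vector theta.

    theta = (rho_g, rho_e, ln sigma_aA^2, ln sigma_eA^2,
             ln sigma_aB^2, ln sigma_eB^2).
    """
    rho_g, rho_e = theta[0], theta[1]
    saa, sea, sab, seb = np.exp(theta[2:6])
    c11 = saa * d + sea
    c22 = sab * d + seb
    c12 = rho_g * np.sqrt(saa * sab) * d + rho_e * np.sqrt(sea * seb)
    det = c11 * c22 - c12 * c12
    return c11, c22, c12, det


def _loglik_profile_beta(theta, d, yAt, yBt, XAt, XBt):
    """Log-likelihood at theta with both traits' fixed effects profiled (GLS)."""
    c11, c22, c12, det = _blocks(theta, d)
    if np.any(det <= 0) or np.any(c11 <= 0):
        return -np.inf, None
    w11 = c22 / det
    w22 = c11 / det
    w12 = -c12 / det
    pA = XAt.shape[1]
    M = np.empty((pA + XBt.shape[1], pA + XBt.shape[1]))
    M[:pA, :pA] = XAt.T @ (XAt * w11[:, None])
    M[pA:, pA:] = XBt.T @ (XBt * w22[:, None])
    M[:pA, pA:] = XAt.T @ (XBt * w12[:, None])
    M[pA:, :pA] = M[:pA, pA:].T
    v = np.concatenate([
        XAt.T @ (w11 * yAt + w12 * yBt),
        XBt.T @ (w12 * yAt + w22 * yBt),
    ])
    try:
        beta = np.linalg.solve(M, v)
    except np.linalg.LinAlgError:
        return -np.inf, None
    rA = yAt - XAt @ beta[:pA]
    rB = yBt - XBt @ beta[pA:]
    Q = float(np.dot(w11 * rA, rA) + 2.0 * np.dot(w12 * rA, rB) + np.dot(w22 * rB, rB))
    n = d.shape[0]
    ll = -0.5 * (2 * n * _LOG2PI + np.log(det).sum() + Q)
    return ll, beta


def bivariate_loglik(yA, yB, XA, XB, two_phi, rho_g, rho_e,
                     sigma_aA2, sigma_eA2, sigma_aB2, sigma_eB2,
                     beta_a, beta_b) -> float:
    """Bivariate log-likelihood at explicit parameter values (oracle hook)."""
    XA, _, _ = _as_design(XA)
    XB, _, _ = _as_design(XB)
    yA = np.asarray(yA, dtype=float)
    yB = np.asarray(yB, dtype=float)
    two_phi, _ = _as_two_phi(two_phi)
    _validate_xy(XA, yA, two_phi)
    _validate_xy(XB, yB, two_phi)
    d, U = _eigen_two_phi(two_phi)
    theta = np.array([
        rho_g, rho_e, np.log(sigma_aA2), np.log(sigma_eA2),
        np.log(sigma_aB2), np.log(sigma_eB2),
    ])
    c11, c22, c12, det = _blocks(theta, d)
    if np.any(det <= 0):
        raise ValueError("covariance is numerically singular at these parameters")
    rA = U.T @ (yA - XA @ np.atleast_1d(np.asarray(beta_a, float)))
    rB = U.T @ (yB - XB @ np.atleast_1d(np.asarray(beta_b, float)))
    Q = np.sum((c22 * rA * rA - 2.0 * c12 * rA * rB + c11 * rB * rB) / det)
    n = d.shape[0]
    return float(-0.5 * (2 * n * _LOG2PI + np.log(det).sum() + Q))


@dataclass
class BivariateFit:
    """Result of a bivariate polygenic fit."""

    rho_g: float
    rho_e: float
    rho_p: float
    h2_a: float
    h2_b: float
    sigma_aA2: float
    sigma_eA2: float
    sigma_aB2: float
    sigma_eB2: float
    loglik: float
    loglik_rho_g0: float
    p_rho_g: float
    rho_g_se: float
    rho_p_se: float
    pleiotropy: str
    n_used: int
    converged: bool = True
    beta_a: np.ndarray | None = field(default=None, repr=False)
    beta_b: np.ndarray | None = field(default=None, repr=False)


class BivariateModel(BaseEstimator):
    """Maximum-likelihood bivariate polygenic model (sklearn-style estimator).

    ``fit(X, Y)`` takes ``Y`` as an (n, 2) column stack of the two traits and
    ``X`` as either one shared design or a pair ``(XA, XB)``; rows of all
    inputs refer to the same individuals (complete pairs), aligned by the
    caller or by :func:`fit_bivariate`. Traits are standardized internally;
    variance components are reported on the original trait scales and the
    correlations are scale-free.
    """

    def __init__(self, kinship=None, rho_g_starts=(0.0, -0.5, 0.5),
                 tol: float = 1e-9, se_step: float = 1e-4):
        self.kinship = kinship
        self.rho_g_starts = rho_g_starts
        self.tol = tol
        self.se_step = se_step

    def fit(self, X, Y, eigen=None):
        """Fit by ML; ``eigen=(d, U)`` may pass a precomputed decomposition
        of the aligned 2*Phi."""
        if self.kinship is None:
            raise ValueError("BivariateModel requires a kinship matrix")
        if isinstance(X, (tuple, list)) and len(X) == 2:
            XA_in, XB_in = X
        else:
            XA_in = XB_in = X
        XA, colsA, idsA = _as_design(XA_in)
        XB, colsB, _ = _as_design(XB_in)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must be an (n, 2) array of the two traits")
        yA, yB = Y[:, 0].copy(), Y[:, 1].copy()
        two_phi, k_ids = _as_two_phi(self.kinship)
        if idsA is not None and k_ids is not None:
            two_phi = self.kinship.subset(idsA).two_phi
        _validate_xy(XA, yA, two_phi)
        _validate_xy(XB, yB, two_phi)
        n = yA.shape[0]
        if n <= XA.shape[1] + XB.shape[1] + 5:
            raise ValueError("too few complete pairs for the bivariate model")

        sdA = float(np.std(yA)) or 1.0
        sdB = float(np.std(yB)) or 1.0
        yAs, yBs = yA / sdA, yB / sdB

        d, U = _eigen_two_phi(two_phi) if eigen is None else eigen
        yAt, yBt = U.T @ yAs, U.T @ yBs
        XAt, XBt = U.T @ XA, U.T @ XB

        # univariate fits give start values for the variance components
        uniA = PolygenicModel(kinship=two_phi).fit(XA, yAs, eigen=(d, U))
        uniB = PolygenicModel(kinship=two_phi).fit(XB, yBs, eigen=(d, U))

        def comp_logs(h2, sp2):
            h2 = min(max(h2, 0.02), 0.95)
            return np.log(max(h2 * sp2, 1e-8)), np.log(max((1 - h2) * sp2, 1e-8))

        laA, leA = comp_logs(uniA.h2_, uniA.sigma_p2_)
        laB, leB = comp_logs(uniB.h2_, uniB.sigma_p2_)
        rho_e0 = float(np.clip(np.corrcoef(
            yAt - XAt @ uniA.beta_, yBt - XBt @ uniB.beta_)[0, 1], -0.9, 0.9))

        bounds = [(-1.0, 1.0), (-0.995, 0.995)] + [(-15.0, 4.0)] * 4

        def nll(theta):
            return -_loglik_profile_beta(theta, d, yAt, yBt, XAt, XBt)[0]

        best = None
        for rg0 in self.rho_g_starts:
            theta0 = np.array([rg0, rho_e0, laA, leA, laB, leB])
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        theta_hat = best.x
        ll_full, beta = _loglik_profile_beta(theta_hat, d, yAt, yBt, XAt, XBt)

        # constrained rho_g = 0 refit for the LRT
        def nll0(psi):
            return nll(np.concatenate([[0.0], psi]))

        res0 = optimize.minimize(
            nll0, np.concatenate([[rho_e0], theta_hat[2:]]),
            method="L-BFGS-B", bounds=bounds[1:],
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        ll_null = -float(res0.fun)
        if ll_null > ll_full:  # rho_g=0 is nested: never allow ll_null above
            theta_hat = np.concatenate([[0.0], res0.x])
            ll_full, beta = _loglik_profile_beta(theta_hat, d, yAt, yBt, XAt, XBt)

        rho_g, rho_e = float(theta_hat[0]), float(theta_hat[1])
        saa, sea, sab, seb = np.exp(theta_hat[2:6])
        h2_a = saa / (saa + sea)
        h2_b = sab / (sab + seb)
        lam = max(0.0, 2.0 * (ll_full - ll_null))
        at_boundary = abs(rho_g) >= _RHO_BOUNDARY
        if at_boundary:
            # complete pleiotropy: constrained boundary, 1/2 chi2 mixture
            p_rho_g = 0.5 if lam == 0 else float(0.5 * stats.chi2.sf(lam, df=1))
        else:
            p_rho_g = float(stats.chi2.sf(lam, df=1)) if lam > 0 else 1.0

        rho_p = phenotypic_correlation(rho_g, rho_e, h2_a, h2_b)
        rho_g_se, rho_p_se = self._ses(theta_hat, d, yAt, yBt, XAt, XBt, at_boundary)

        pA = XA.shape[1]
        self.rho_g_ = rho_g
        self.rho_e_ = rho_e
        self.rho_p_ = rho_p
        self.h2_a_ = float(h2_a)
        self.h2_b_ = float(h2_b)
        self.sigma_aA2_ = float(saa * sdA**2)
        self.sigma_eA2_ = float(sea * sdA**2)
        self.sigma_aB2_ = float(sab * sdB**2)
        self.sigma_eB2_ = float(seb * sdB**2)
        # loglik on the original trait scale (Jacobian of the standardization)
        self.loglik_ = float(ll_full - n * (np.log(sdA) + np.log(sdB)))
        self.loglik_rho_g0_ = float(ll_null - n * (np.log(sdA) + np.log(sdB)))
        self.p_rho_g_ = p_rho_g
        self.rho_g_se_ = rho_g_se
        self.rho_p_se_ = rho_p_se
        self.pleiotropy_ = classify_pleiotropy(rho_g)
        self.n_used_ = int(n)
        self.converged_ = bool(best.success)
        self.beta_a_ = beta[:pA] * sdA
        self.beta_b_ = beta[pA:] * sdB
        self.result_ = BivariateFit(
            rho_g=rho_g, rho_e=rho_e, rho_p=rho_p, h2_a=self.h2_a_,
            h2_b=self.h2_b_, sigma_aA2=self.sigma_aA2_, sigma_eA2=self.sigma_eA2_,
            sigma_aB2=self.sigma_aB2_, sigma_eB2=self.sigma_eB2_,
            loglik=self.loglik_, loglik_rho_g0=self.loglik_rho_g0_,
            p_rho_g=p_rho_g, rho_g_se=rho_g_se, rho_p_se=rho_p_se,
            pleiotropy=self.pleiotropy_, n_used=self.n_used_,
            converged=self.converged_, beta_a=self.beta_a_, beta_b=self.beta_b_,
        )
        return self

    def _ses(self, theta_hat, d, yAt, yBt, XAt, XBt, at_boundary):
        """Observed-information SEs for rho_g and (delta method) rho_p."""
        if at_boundary:
            return float("nan"), float("nan")
        eps = self.se_step
        k = theta_hat.shape[0]

        def ll(th):
            return _loglik_profile_beta(th, d, yAt, yBt, XAt, XBt)[0]

        H = np.empty((k, k))
        f0 = ll(theta_hat)
        for i in range(k):
            ei = np.zeros(k); ei[i] = eps
            H[i, i] = (ll(theta_hat + ei) - 2 * f0 + ll(theta_hat - ei)) / eps**2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = eps
                H[i, j] = H[j, i] = (
                    ll(theta_hat + ei + ej) - ll(theta_hat + ei - ej)
                    - ll(theta_hat - ei + ej) + ll(theta_hat - ei - ej)
                ) / (4 * eps**2)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")

        def rho_p_of(th):
            saa, sea, sab, seb = np.exp(th[2:6])
            return phenotypic_correlation(
                th[0], th[1], saa / (saa + sea), sab / (sab + seb))

        grad = np.array([
            (rho_p_of(theta_hat + np.eye(k)[i] * eps)
             - rho_p_of(theta_hat - np.eye(k)[i] * eps)) / (2 * eps)
            for i in range(k)
        ])
        v_g = cov[0, 0]
        v_p = float(grad @ cov @ grad)
        return (
            float(np.sqrt(v_g)) if v_g > 0 else float("nan"),
            float(np.sqrt(v_p)) if v_p > 0 else float("nan"),
        )


def _subset_rows(design, ids):
    """Restrict a CovariateDesign to ``ids`` (kept in the given order)."""
    lookup = {m: k for k, m in enumerate(design.ids)}
    idx = [lookup[i] for i in ids]
    return CovariateDesign(
        ids=list(ids), columns=list(design.columns),
        matrix=design.matrix[idx], age_center=design.age_center,
    )


def fit_bivariate(yA, yB, XA, XB, two_phi, **kwargs) -> BivariateFit:
    """Functional wrapper: aligns complete pairs when designs carry ids.

    ``yA``/``yB`` align with ``XA``/``XB`` rows. When both designs are
    :class:`CovariateDesign` instances their id intersection (in XA order)
    defines the analyzed pair set; otherwise all inputs must already be
    aligned.
    """
    if isinstance(XA, CovariateDesign) and isinstance(XB, CovariateDesign):
        common = [i for i in XA.ids if i in set(XB.ids)]
        posA = {m: k for k, m in enumerate(XA.ids)}
        posB = {m: k for k, m in enumerate(XB.ids)}
        yA = np.asarray(yA, float)[[posA[i] for i in common]]
        yB = np.asarray(yB, float)[[posB[i] for i in common]]
        XA = _subset_rows(XA, common)
        XB = _subset_rows(XB, common)
        if isinstance(two_phi, np.ndarray):
            raise ValueError("pass a KinshipMatrix when designs carry ids")
    model = BivariateModel(kinship=two_phi, **kwargs).fit(
        (XA, XB), np.column_stack([np.asarray(yA, float), np.asarray(yB, float)])
    )
    return model.result_
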