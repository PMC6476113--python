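"""Variance-component linkage: MIBD tracks, LOD scans, 1-LOD support intervals.

At each map position the QTL model extends the polygenic covariance with a
locus-specific component structured by the multipoint IBD-sharing matrix
Pi-hat (pairwise expected proportion of alleles shared identical by descent
at that position):

    Omega = Pi_hat sigma_q^2 + 2Phi sigma_a^2 + I sigma_e^2,   sigma_q^2 >= 0.

The LOD score is the base-10 log likelihood ratio of this model against the
polygenic-only model (its sigma_q^2 = 0 submodel), clipped at zero. A peak
is called significant at LOD >= 3.0 and suggestive at 2.0 <= LOD < 3.0, and
the 1-LOD support interval (approximate 95% confidence region for QTL
location) is the contiguous run of grid positions around the peak with
LOD >= peak - 1.

Because Pi-hat changes at every position, no single eigendecomposition can be
shared across loci; each locus fit profiles the fixed effects and the
environmental variance in closed form and optimizes the two variance ratios
(sigma_q^2/sigma_e^2, sigma_a^2/sigma_e^2) by bounded quasi-Newton,
warm-started from the neighbouring locus. A "fast" mode holds the polygenic
ratio at its null-model value (a nested submodel, so its LOD never exceeds
the full one); ``refine_window`` re-fits positions near the peak fully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize
from sklearn.base import BaseEstimator

from .pedigree import KinshipMatrix
from .vc import PolygenicModel, _as_design, _as_two_phi, _eigen_two_phi

__all__ = [
    "MibdTrack",
    "LinkageScan",
    "QtlLocusFit",
    "VarianceComponentLinkage",
    "fit_qtl_locus",
    "lod_score",
    "genome_scan",
    "one_lod_interval",
    "LOD_SIGNIFICANT",
    "LOD_SUGGESTIVE",
]

_LOG2PI = np.log(2.0 * np.pi)

#: fixed LOD thresholds for declaring linkage
LOD_SIGNIFICANT = 3.0
LOD_SUGGESTIVE = 2.0

_GAMMA_MAX = 1e3  # upper bound on each variance ratio sigma^2 / sigma_e^2


class MibdTrack:
    """Per-position pairwise IBD-sharing matrices on a cM grid.

    Either stores explicit matrices (as read from MIBD files) or is backed by
    per-position founder-allele labels from gene dropping, in which case each
    Pi-hat matrix is materialized on demand (exact IBD sharing, not an
    estimate). Positions are strictly increasing within each chromosome.
    """

    def __init__(self, ids, positions: pd.DataFrame, matrices=None, labels=None):
        self.ids = [str(i) for i in ids]
        pos = positions.reset_index(drop=True).copy()
        if "pos_bp" not in pos.columns:
            pos["pos_bp"] = np.nan
        self.positions = pos[["chrom", "pos_cM", "pos_bp"]].copy()
        self.positions["chrom"] = self.positions["chrom"].astype(str)
        if (matrices is None) == (labels is None):
            raise ValueError("provide exactly one of matrices or labels")
        self._matrices = matrices
        self._labels = labels  # (n_pos, n, 2) founder allele labels
        for chrom, grp in self.positions.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos_cM"].to_numpy()) > 0):
                raise ValueError(
                    f"MIBD positions must be strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def matrix(self, k: int) -> np.ndarray:
        """The n x n Pi-hat matrix at grid index ``k``."""
        if self._matrices is not None:
            return np.asarray(self._matrices[k], dtype=float)
        lab = self._labels[k]
        pi = np.zeros((lab.shape[0],) * 2)
        for a in range(2):
            for b in range(2):
                pi += lab[:, a][:, None] == lab[:, b][None, :]
        pi *= 0.5
        # diagonal: 1 + F-at-locus (2 if the two own alleles are IBD)
        np.fill_diagonal(pi, 1.0 + (lab[:, 0] == lab[:, 1]))
        return pi

    def subset(self, ids) -> "MibdTrack":
        lookup = {m: k for k, m in enumerate(self.ids)}
        idx = np.array([lookup[str(i)] for i in ids], dtype=int)
        if self._matrices is not None:
            mats = [np.asarray(m)[np.ix_(idx, idx)] for m in self._matrices]
            return MibdTrack(list(ids), self.positions, matrices=mats)
        return MibdTrack(list(ids), self.positions, labels=self._labels[:, idx, :])

    def validate(self) -> None:
        """Check structural invariants on every stored matrix."""
        for k in range(len(self)):
            pi = self.matrix(k)
            if not np.allclose(pi, pi.T):
                raise ValueError(f"Pi-hat at index {k} is not symmetric")
            off = pi[~np.eye(pi.shape[0], dtype=bool)]
            if off.min() < 0 or off.max() > 2.0 + 1e-9:
                raise ValueError(f"Pi-hat entries out of range at index {k}")
            if np.any(np.diag(pi) < 1.0 - 1e-9):
                raise ValueError(f"Pi-hat diagonal below 1 at index {k}")


@dataclass
class QtlLocusFit:
    """ML fit of the QTL + polygenic + environmental model at one locus."""

    loglik: float
    sigma_q2: float
    sigma_a2: float
    sigma_e2: float
    converged: bool = True
    confounded: bool = False
    gamma: tuple[float, float] = field(default=(0.0, 0.0), repr=False)

    @property
    def sigma_p2(self) -> float:
        return self.sigma_q2 + self.sigma_a2 + self.sigma_e2


def _locus_nll(gamma, Pi, two_phi, X, y):
    """Negative profile loglik at variance ratios gamma = (gq, ga).

    V = I + gq Pi + ga 2Phi; beta by GLS and sigma_e^2 = Q/n in closed form.
    """
    gq, ga = gamma
    n = y.shape[0]
    V = gq * Pi + ga * two_phi
    V[np.diag_indices_from(V)] += 1.0
    try:
        L = sla.cholesky(V, lower=True, check_finite=False, overwrite_a=True)
    except sla.LinAlgError:
        return np.inf, None, None
    logdet = 2.0 * np.log(np.diag(L)).sum()
    yc = sla.solve_triangular(L, y, lower=True, check_finite=False)
    Xc = sla.solve_triangular(L, X, lower=True, check_finite=False)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    r = yc - Xc @ beta
    Q = float(r @ r)
    sigma_e2 = max(Q / n, 1e-300)
    ll = -0.5 * (n * (_LOG2PI + 1.0) + n * np.log(sigma_e2) + logdet)
    return -ll, beta, sigma_e2


def fit_qtl_locus(y, X, two_phi, Pi_hat, start=None, fixed_ga=None) -> QtlLocusFit:
    """ML fit of Omega = Pi sigma_q^2 + 2Phi sigma_a^2 + I sigma_e^2.

    ``start`` warm-starts the variance ratios (gq, ga); ``fixed_ga`` holds
    the polygenic/environmental ratio fixed (fast nested mode). When Pi-hat
    coincides with 2Phi the two genetic components are structurally
    confounded: the fit is flagged and the locus model adds nothing.
    """
    X, _, _ = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    two_phi, _ = _as_two_phi(two_phi)
    Pi = np.asarray(Pi_hat, dtype=float)
    if Pi.shape != two_phi.shape or Pi.shape[0] != y.shape[0]:
        raise ValueError("Pi-hat is misaligned with the analyzed individuals")

    confounded = np.allclose(Pi, two_phi, atol=1e-9)
    x0 = np.array(start if start is not None else (0.05, 0.2), dtype=float)
    x0 = np.clip(x0, 1e-6, _GAMMA_MAX / 2)

    if fixed_ga is not None:

        def nll1(g):
            return _locus_nll((float(g[0]), fixed_ga), Pi, two_phi, X, y)[0]

        res = optimize.minimize(
            nll1, x0[:1], method="L-BFGS-B", bounds=[(0.0, _GAMMA_MAX)],
            options={"ftol": 1e-11},
        )
        gq, ga = float(res.x[0]), float(fixed_ga)
    else:

        def nll(g):
            return _locus_nll((float(g[0]), float(g[1])), Pi, two_phi, X, y)[0]

        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(0.0, _GAMMA_MAX), (0.0, _GAMMA_MAX)],
            options={"ftol": 1e-11},
        )
        gq, ga = float(res.x[0]), float(res.x[1])

    neg_ll, beta, sigma_e2 = _locus_nll((gq, ga), Pi, two_phi, X, y)
    return QtlLocusFit(
        loglik=-neg_ll, sigma_q2=gq * sigma_e2, sigma_a2=ga * sigma_e2,
        sigma_e2=sigma_e2, converged=bool(res.success), confounded=confounded,
        gamma=(gq, ga),
    )


def lod_score(loglik_qtl: float, loglik_poly: float) -> float:
    """LOD = (l_qtl - l_poly) / ln 10, clipped at 0."""
    if loglik_qtl < loglik_poly - 1e-6:
        raise ValueError("QTL-model log-likelihood below the nested polygenic model")
    return max(0.0, (loglik_qtl - loglik_poly) / np.log(10.0))


@dataclass
class LinkageScan:
    """LOD profile over a MIBD track with peak, classification and interval."""

    table: pd.DataFrame  # chrom, pos_cM, pos_bp, lod
    peak_chrom: str
    peak_cM: float
    peak_bp: float
    peak_lod: float
    classification: str  # "significant" | "suggestive" | "none"
    loglik_polygenic: float

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos_cM"].to_numpy()

    @property
    def lods(self) -> np.ndarray:
        return self.table["lod"].to_numpy()


def _classify(peak_lod: float, significant: float, suggestive: float) -> str:
    if peak_lod >= significant:
        return "significant"
    if peak_lod >= suggestive:
        return "suggestive"
    return "none"


class VarianceComponentLinkage(BaseEstimator):
    """Genome-wide variance-component linkage scan (sklearn-style estimator).

    Parameters
    ----------
    kinship : KinshipMatrix or (n, n) array
        Polygenic structuring matrix (retained at every locus).
    mibd : MibdTrack
        IBD-sharing matrices on the scan grid, aligned (or alignable by id)
        to the analyzed individuals.
    mode : "full" | "fast"
        Full joint ML over both variance ratios per locus, or the nested
        fast mode with the polygenic ratio held at its null-fit value.
    refine_window : float
        In fast mode, re-fit positions within this many cM of the fast-scan
        peak with the full model (0 disables).

    Attributes (after fit): ``scan_`` (a :class:`LinkageScan`), ``lods_``,
    ``peak_lod_``, ``classification_``, ``interval_`` (1-LOD support
    interval, None when peak LOD <= 1), ``polygenic_`` (the null fit).
    """

    def __init__(self, kinship=None, mibd=None, mode: str = "full",
                 refine_window: float = 10.0,
                 lod_significant: float = LOD_SIGNIFICANT,
                 lod_suggestive: float = LOD_SUGGESTIVE):
        self.kinship = kinship
        self.mibd = mibd
        self.mode = mode
        self.refine_window = refine_window
        self.lod_significant = lod_significant
        self.lod_suggestive = lod_suggestive

    def fit(self, X, y):
        if self.mibd is None or len(self.mibd) < 1:
            raise ValueError("linkage scan requires a MIBD track with >= 1 position")
        if self.mode not in ("full", "fast"):
            raise ValueError("mode must be 'full' or 'fast'")
        Xm, _, x_ids = _as_design(X)
        y = np.asarray(y, dtype=float).ravel()
        two_phi, k_ids = _as_two_phi(self.kinship)
        track = self.mibd
        if x_ids is not None:
            if k_ids is not None:
                two_phi = self.kinship.subset(x_ids).two_phi
            track = track.subset(x_ids)
        if track.n_individuals != y.shape[0]:
            raise ValueError("MIBD track is misaligned with the analyzed individuals")

        poly = PolygenicModel(kinship=two_phi).fit(Xm, y)
        ll0 = poly.loglik_
        ga0 = poly.sigma_a2_ / max(poly.sigma_e2_, 1e-300)

        n_pos = len(track)
        lods = np.zeros(n_pos)
        fits: list[QtlLocusFit] = [None] * n_pos
        chroms = track.positions["chrom"].to_numpy()
        warm = None
        fixed = ga0 if self.mode == "fast" else None
        screen = self._score_screen(Xm, y, two_phi, ga0) if fixed is not None else None
        n = y.shape[0]
        for k in range(n_pos):
            if k > 0 and chroms[k] != chroms[k - 1]:
                warm = None
            Pi = track.matrix(k)
            if screen is not None:
                # score for sigma_q^2 at 0: when <= 0 the boundary is the
                # (fast-mode) optimum and the locus adds nothing
                V0inv, u, Q0 = screen
                score = 0.5 * (n * float(u @ Pi @ u) / Q0
                               - float(np.sum(V0inv * Pi)))
                if score <= 0.0:
                    lods[k] = 0.0
                    fits[k] = QtlLocusFit(
                        loglik=ll0, sigma_q2=0.0, sigma_a2=poly.sigma_a2_,
                        sigma_e2=poly.sigma_e2_, gamma=(0.0, ga0))
                    warm = None
                    continue
            start = warm if warm is not None else (0.05, ga0)
            fit = fit_qtl_locus(y, Xm, two_phi, Pi, start=start, fixed_ga=fixed)
            if fit.confounded:
                lods[k] = 0.0
            else:
                lods[k] = lod_score(max(fit.loglik, ll0), ll0)
            fits[k] = fit
            warm = (max(fit.gamma[0], 1e-4), fit.gamma[1])

        if self.mode == "fast" and self.refine_window > 0:
            peak = int(np.argmax(lods))
            pos = track.positions["pos_cM"].to_numpy()
            near = (chroms == chroms[peak]) & (
                np.abs(pos - pos[peak]) <= self.refine_window)
            warm = None
            for k in np.where(near)[0]:
                start = warm if warm is not None else (fits[k].gamma[0], ga0)
                fit = fit_qtl_locus(y, Xm, two_phi, track.matrix(k), start=start)
                if not fit.confounded:
                    lods[k] = lod_score(max(fit.loglik, ll0), ll0)
                fits[k] = fit
                warm = (max(fit.gamma[0], 1e-4), fit.gamma[1])

        table = track.positions.copy()
        table["lod"] = lods
        peak = int(np.argmax(lods))  # argmax takes the first (lowest-cM) tie
        scan = LinkageScan(
            table=table,
            peak_chrom=str(table["chrom"].iloc[peak]),
            peak_cM=float(table["pos_cM"].iloc[peak]),
            peak_bp=float(table["pos_bp"].iloc[peak]),
            peak_lod=float(lods[peak]),
            classification=_classify(
                lods[peak], self.lod_significant, self.lod_suggestive),
            loglik_polygenic=ll0,
        )
        self.scan_ = scan
        self.lods_ = lods
        self.peak_lod_ = scan.peak_lod
        self.classification_ = scan.classification
        self.polygenic_ = poly
        self.locus_fits_ = fits
        self.interval_ = (
            one_lod_interval(scan) if scan.peak_lod > 1.0 else None)
        return self

    def _score_screen(self, Xm, y, two_phi, ga0):
        """Precompute the ingredients of the profile score for sigma_q^2 at 0.

        With V0 = I + ga0 * 2Phi (the null covariance up to scale), the
        derivative of the fast-mode profile log-likelihood at sigma_q^2 = 0
        is  (n/2) (u' Pi u)/Q0 - (1/2) tr(V0^{-1} Pi)  with u = V0^{-1} r0;
        each locus then needs only O(n^2) work to decide whether its ML
        estimate sits at the boundary.
        """
        n = y.shape[0]
        V0 = ga0 * two_phi
        V0[np.diag_indices_from(V0)] += 1.0
        L = sla.cholesky(V0, lower=True, check_finite=False)
        V0inv = sla.cho_solve((L, True), np.eye(n), check_finite=False)
        XtVi = Xm.T @ V0inv
        beta = np.linalg.solve(XtVi @ Xm, XtVi @ y)
        r0 = y - Xm @ beta
        u = V0inv @ r0
        Q0 = float(r0 @ u)
        return V0inv, u, Q0

    def predict(self, X=None):  # pragma: no cover - estimator API convenience
        """Return the fitted LOD profile."""
        return self.lods_


def one_lod_interval(scan: LinkageScan):
    """1-LOD support interval around the scan peak.

    The maximal contiguous run of grid positions, on the peak chromosome and
    containing the peak, with LOD >= peak - 1. Returns (cM_lo, cM_hi) or
    (cM_lo, cM_hi, bp_lo, bp_hi) when bp coordinates are present, bp bounds
    linearly interpolated on the cM->bp map. A peak with LOD <= 1 has no
    defined interval: the whole chromosome is returned with a warning.
    """
    mask = scan.table["chrom"].astype(str).to_numpy() == str(scan.peak_chrom)
    pos = scan.table.loc[mask, "pos_cM"].to_numpy()
    bp = scan.table.loc[mask, "pos_bp"].to_numpy()
    lod = scan.table.loc[mask, "lod"].to_numpy()
    peak = int(np.argmax(lod))

    def _with_bp(lo_cm, hi_cm):
        if np.all(np.isfinite(bp)):
            return (
                float(lo_cm), float(hi_cm),
                float(np.interp(lo_cm, pos, bp)), float(np.interp(hi_cm, pos, bp)),
            )
        return (float(lo_cm), float(hi_cm))

    if lod[peak] <= 1.0:
        warnings.warn(
            "peak LOD <= 1: 1-LOD interval undefined, returning the whole "
            "chromosome", stacklevel=2,
        )
        return _with_bp(pos[0], pos[-1])

    thr = lod[peak] - 1.0
    lo = peak
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    return _with_bp(pos[lo], pos[hi])


def genome_scan(y, X, two_phi, track: MibdTrack, **kwargs) -> LinkageScan:
    """Functional wrapper over :class:`VarianceComponentLinkage`."""
    model = VarianceComponentLinkage(kinship=two_phi, mibd=track, **kwargs)
    model.fit(X, y)
    return model.scan_
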