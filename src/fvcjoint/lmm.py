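"""Longitudinal sub-model: a Gaussian linear mixed-effects model of FVC% predicted.

Model for subject *i* at time *t* (years since randomisation):

    y_i(t) = b0 + b_ata * ATA_i + b_base * (FVC0_i - c)
             + (b_t + b_tx * arm_i) * t
             + u0_i + u1_i * t + eps,

with random intercept/slope (u0, u1) ~ N(0, D) (unstructured 2x2) and
residual eps ~ N(0, sigma^2).  ATA status and centered baseline FVC shift
the level only; the arm enters through the slope, so ``b_tx`` is the
treatment-vs-control difference in the annual rate of FVC change.

Fitting is maximum likelihood: the fixed effects are profiled out by
generalised least squares, and the variance parameters (log-Cholesky factor
of D and log residual SD) are optimised by quasi-Newton.  The per-subject
marginal covariance Z D Z' + sigma^2 I is handled through closed-form
2x2 Woodbury identities, so the likelihood is exact and fast for any
number of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy.optimize import minimize

from .data import JointDataset, SubjectData

FIXED_EFFECT_NAMES = (
    "intercept",
    "ata_positive",
    "baseline_fvc_centered",
    "time_years",
    "arm_x_time_years",
)

_LOG2PI = float(np.log(2.0 * np.pi))


class IdentifiabilityError(RuntimeError):
    """The fixed-effect design is singular; the message names the columns."""


@dataclass
class LmmParams:
    """Parameters of the longitudinal sub-model.

    ``beta`` is ordered as :data:`FIXED_EFFECT_NAMES`; ``D`` is the 2x2
    covariance of (random intercept, random slope); ``sigma2`` the residual
    variance in (% predicted)^2.
    """

    beta: np.ndarray
    D: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.beta.shape != (5,):
            raise ValueError("beta must have 5 entries")
        if self.D.shape != (2, 2) or not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric 2x2")
        if np.linalg.eigvalsh(self.D).min() < -1e-10:
            raise ValueError("D must be positive semi-definite")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")


def design_row(
    arm: int,
    ata_positive: int,
    baseline_fvc_pct: float,
    t_years: float,
    center: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed- and random-effect design rows at one time point."""
    if t_years < 0:
        raise ValueError("t_years must be >= 0")
    fixed = np.array(
        [
            1.0,
            float(ata_positive),
            baseline_fvc_pct - center,
            t_years,
            arm * t_years,
        ]
    )
    return fixed, np.array([1.0, t_years])


def subject_slope(params: LmmParams, arm: int, b1: float = 0.0) -> float:
    """Annual FVC%-predicted slope of a subject: b_t + b_tx*arm + u1."""
    return float(params.beta[3] + params.beta[4] * arm + b1)


def current_value(
    params: LmmParams,
    arm: int,
    ata_positive: int,
    baseline_fvc_pct: float,
    center: float,
    b0: float,
    b1: float,
    t_years: float,
) -> float:
    """Error-free trajectory value m_i(t): fixed plus random parts."""
    fixed, _ = design_row(arm, ata_positive, baseline_fvc_pct, t_years, center)
    return float(fixed @ params.beta + b0 + b1 * t_years)


# ---------------------------------------------------------------------------
# sufficient statistics and Woodbury-based likelihood pieces


@dataclass
class LongitudinalStats:
    """Per-subject cross-products of the longitudinal design.

    Only subjects with at least one retained measurement appear; ``idx``
    maps back to positions in the originating dataset's subject list.
    Because each subject's fixed design is (constants) x (1, t), every
    needed cross-product is a function of n_i, sums of t, t^2, y, t*y, y^2
    and the subject-level covariates.
    """

    idx: np.ndarray
    n: np.ndarray
    ata: np.ndarray
    cb: np.ndarray  # centered baseline FVC
    arm: np.ndarray
    St: np.ndarray
    Stt: np.ndarray
    Sy: np.ndarray
    Sty: np.ndarray
    Syy: np.ndarray
    XtX: np.ndarray  # (m, 5, 5)
    Xty: np.ndarray  # (m, 5)
    W: np.ndarray  # Z'X, (m, 2, 5)
    Zty: np.ndarray  # (m, 2)
    center: float

    @property
    def n_obs(self) -> int:
        return int(self.n.sum())


def prepare_stats(dataset: JointDataset, center: float) -> LongitudinalStats:
    """Assemble the cross-products for all subjects with measurements."""
    rows = [
        (i, s) for i, s in enumerate(dataset.subjects) if len(s.times_years) > 0
    ]
    m = len(rows)
    idx = np.array([i for i, _ in rows], dtype=int)
    n = np.array([len(s.times_years) for _, s in rows], dtype=float)
    ata = np.array([s.ata_positive for _, s in rows], dtype=float)
    cb = np.array([s.baseline_fvc_pct - center for _, s in rows], dtype=float)
    arm = np.array([s.arm for _, s in rows], dtype=float)
    St = np.array([s.times_years.sum() for _, s in rows])
    Stt = np.array([(s.times_years**2).sum() for _, s in rows])
    Sy = np.array([s.fvc.sum() for _, s in rows])
    Sty = np.array([(s.times_years * s.fvc).sum() for _, s in rows])
    Syy = np.array([(s.fvc**2).sum() for _, s in rows])

    W = np.zeros((m, 2, 5))
    W[:, 0, 0] = n
    W[:, 0, 1] = ata * n
    W[:, 0, 2] = cb * n
    W[:, 0, 3] = St
    W[:, 0, 4] = arm * St
    W[:, 1, 0] = St
    W[:, 1, 1] = ata * St
    W[:, 1, 2] = cb * St
    W[:, 1, 3] = Stt
    W[:, 1, 4] = arm * Stt

    # X'X from the same sums: column j of X is const_j * (1 or t)
    XtX = np.zeros((m, 5, 5))
    consts = np.stack([np.ones(m), ata, cb], axis=1)  # level columns 0..2
    for a in range(3):
        for b in range(3):
            XtX[:, a, b] = consts[:, a] * consts[:, b] * n
        XtX[:, a, 3] = consts[:, a] * St
        XtX[:, 3, a] = XtX[:, a, 3]
        XtX[:, a, 4] = consts[:, a] * arm * St
        XtX[:, 4, a] = XtX[:, a, 4]
    XtX[:, 3, 3] = Stt
    XtX[:, 3, 4] = arm * Stt
    XtX[:, 4, 3] = XtX[:, 3, 4]
    XtX[:, 4, 4] = arm**2 * Stt

    Xty = np.stack([Sy, ata * Sy, cb * Sy, Sty, arm * Sty], axis=1)
    Zty = np.stack([Sy, Sty], axis=1)

    return LongitudinalStats(
        idx=idx, n=n, ata=ata, cb=cb, arm=arm, St=St, Stt=Stt, Sy=Sy,
        Sty=Sty, Syy=Syy, XtX=XtX, Xty=Xty, W=W, Zty=Zty, center=center,
    )


def _inv2x2(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched 2x2 inverse; returns (inverse, log-determinant)."""
    det = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    inv = np.empty_like(a)
    inv[..., 0, 0] = a[..., 1, 1]
    inv[..., 1, 1] = a[..., 0, 0]
    inv[..., 0, 1] = -a[..., 0, 1]
    inv[..., 1, 0] = -a[..., 1, 0]
    inv /= det[..., None, None]
    return inv, np.log(det)


def posterior_moments(
    stats: LongitudinalStats, beta: np.ndarray, D: np.ndarray, sigma2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian posterior of (u0, u1) given each subject's measurements.

    Returns ``(mu, Sigma, logdetV, quad)`` where ``mu`` (m,2) and ``Sigma``
    (m,2,2) are the posterior mean and covariance, and ``logdetV``/``quad``
    are the log-determinant and Mahalanobis quadratic form of the marginal
    covariance V = Z D Z' + sigma^2 I used by the marginal likelihood.
    """
    m = len(stats.n)
    Dinv, logdetD = _inv2x2(D[None, :, :])
    ZtZ = np.zeros((m, 2, 2))
    ZtZ[:, 0, 0] = stats.n
    ZtZ[:, 0, 1] = stats.St
    ZtZ[:, 1, 0] = stats.St
    ZtZ[:, 1, 1] = stats.Stt
    Minv = Dinv + ZtZ / sigma2
    M, logdetMinv = _inv2x2(Minv)

    # Z'r with r = y - X beta
    Ztr = stats.Zty - stats.W @ beta
    mu = np.einsum("mab,mb->ma", M, Ztr) / sigma2

    Srr = (
        stats.Syy
        - 2.0 * stats.Xty @ beta
        + np.einsum("a,mab,b->m", beta, stats.XtX, beta)
    )
    quad = (Srr - np.einsum("ma,mab,mb->m", Ztr, M, Ztr) / sigma2) / sigma2
    logdetV = stats.n * np.log(sigma2) + logdetMinv + logdetD
    return mu, M, logdetV, quad


def marginal_loglik_from_stats(
    stats: LongitudinalStats, beta: np.ndarray, D: np.ndarray, sigma2: float
) -> float:
    _, _, logdetV, quad = posterior_moments(stats, beta, D, sigma2)
    return float(-0.5 * (stats.n_obs * _LOG2PI + logdetV.sum() + quad.sum()))


def marginal_loglik(params: LmmParams, dataset: JointDataset, center: float) -> float:
    """Exact marginal Gaussian log-likelihood (random effects integrated out)."""
    stats = prepare_stats(dataset, center)
    return marginal_loglik_from_stats(stats, params.beta, params.D, params.sigma2)


# ---------------------------------------------------------------------------
# ML fitting


def chol_from_theta(theta3: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of D from its log-Cholesky parameters."""
    L = np.zeros((2, 2))
    L[0, 0] = np.exp(theta3[0])
    L[1, 0] = theta3[1]
    L[1, 1] = np.exp(theta3[2])
    return L


def theta_from_D(D: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(D)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


@dataclass
class LmmFit:
    """Result of a standalone maximum-likelihood LMM fit."""

    params: LmmParams
    center: float
    loglik: float
    beta_se: np.ndarray
    vcov_beta: np.ndarray
    converged: bool
    n_subjects: int
    n_obs: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "fixed_effects": {
                    name: {"estimate": float(b), "se": float(se)}
                    for name, b, se in zip(
                        FIXED_EFFECT_NAMES, self.params.beta, self.beta_se
                    )
                },
                "D": self.params.D.tolist(),
                "sigma2": self.params.sigma2,
                "loglik": self.loglik,
                "center": self.center,
                "converged": self.converged,
                "n_subjects": self.n_subjects,
                "n_obs": self.n_obs,
            },
            indent=2,
        )


def _check_identifiable(stats: LongitudinalStats) -> None:
    G = stats.XtX.sum(axis=0)
    scale = np.sqrt(np.maximum(np.diag(G), 1e-300))
    C = G / np.outer(scale, scale)
    w, v = np.linalg.eigh(C)
    if w[0] < 1e-10:
        load = np.abs(v[:, 0])
        cols = [FIXED_EFFECT_NAMES[j] for j in np.where(load > 0.3)[0]]
        raise IdentifiabilityError(
            f"singular fixed-effect design; collinear columns: {cols}"
        )


def _gls_beta(stats: LongitudinalStats, D: np.ndarray, sigma2: float):
    """Profiled GLS estimate of beta and its information matrix."""
    Dinv, _ = _inv2x2(D[None, :, :])
    m = len(stats.n)
    ZtZ = np.zeros((m, 2, 2))
    ZtZ[:, 0, 0] = stats.n
    ZtZ[:, 0, 1] = stats.St
    ZtZ[:, 1, 0] = stats.St
    ZtZ[:, 1, 1] = stats.Stt
    M, _ = _inv2x2(Dinv + ZtZ / sigma2)
    A = (
        stats.XtX - np.einsum("mai,mab,mbj->mij", stats.W, M, stats.W) / sigma2
    ) / sigma2
    b = (stats.Xty - np.einsum("mai,mab,mb->mi", stats.W, M, stats.Zty) / sigma2) / sigma2
    A_tot = A.sum(axis=0)
    beta = np.linalg.solve(A_tot, b.sum(axis=0))
    return beta, A_tot


def fit_lmm(dataset: JointDataset, center: float | None = None) -> LmmFit:
    """Maximum-likelihood fit of the longitudinal sub-model.

    Baseline FVC is centered at ``center`` (default: sample mean over the
    dataset's subjects); the centering constant is stored on the fit.

    Raises
    ------
    IdentifiabilityError
        if the fixed-effect design is singular (e.g. a single-arm dataset).
    """
    if center is None:
        center = float(np.mean([s.baseline_fvc_pct for s in dataset.subjects]))
    stats = prepare_stats(dataset, center)
    if len(stats.n) < 2:
        raise ValueError("need at least 2 subjects with measurements")
    _check_identifiable(stats)

    # moment-based starting values from a pooled OLS fit
    beta0, _ = _gls_beta(stats, np.eye(2), 1.0)
    _, _, _, quad0 = posterior_moments(stats, beta0, np.eye(2) * 1e-6, 1.0)
    resid_var = max(float(quad0.sum() / stats.n_obs), 1e-4)
    x0 = np.array(
        [
            0.5 * np.log(max(resid_var / 2.0, 1e-4)),
            0.0,
            0.0,
            0.25 * np.log(max(resid_var / 2.0, 1e-4)),
        ]
    )

    def negll(theta: np.ndarray) -> float:
        L = chol_from_theta(theta[:3])
        D = L @ L.T
        sigma2 = float(np.exp(2.0 * theta[3]))
        beta, _ = _gls_beta(stats, D, sigma2)
        ll = marginal_loglik_from_stats(stats, beta, D, sigma2)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(-8.0, 8.0), (-60.0, 60.0), (-8.0, 8.0), (-8.0, 8.0)]
    res = minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    L = chol_from_theta(res.x[:3])
    D = L @ L.T
    sigma2 = float(np.exp(2.0 * res.x[3]))
    beta, A_tot = _gls_beta(stats, D, sigma2)
    vcov_beta = np.linalg.inv(A_tot)
    return LmmFit(
        params=LmmParams(beta=beta, D=D, sigma2=sigma2),
        center=center,
        loglik=-float(res.fun),
        beta_se=np.sqrt(np.diag(vcov_beta)),
        vcov_beta=vcov_beta,
        converged=bool(res.success),
        n_subjects=dataset.n,
        n_obs=stats.n_obs,
    )
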