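"""Shared-parameter joint model of FVC% predicted and time to first event.

The longitudinal LMM (see :mod:`fvcjoint.lmm`) and the ATA-stratified
piecewise-exponential hazard (see :mod:`fvcjoint.hazard`) are linked
through the subject's random effects.  With association ``slope`` the
hazard is

    h_i(t) = h0_s(t) * exp(alpha * slope_i),    slope_i = b_t + b_tx*arm_i + u1_i,

so a subject declining one percentage point per year faster multiplies
their hazard by exp(-alpha).  With association ``current_value`` the
hazard depends on the error-free trajectory value m_i(t) at time t:

    h_i(t) = h0_s(t) * exp(alpha * m_i(t)),

and the cumulative hazard over each constant-hazard piece [a, b) has the
closed form  h0_j * exp(alpha*A_i) * (exp(alpha*C_i*b) - exp(alpha*C_i*a))
/ (alpha*C_i)  with A_i, C_i the intercept and slope of m_i.

The marginal likelihood integrates the random effects out of the product
of the two conditional densities.  Because the longitudinal factor is
Gaussian, the integral is rewritten exactly as

    f(y_i) * E[ f_surv(b) | y_i ],   b | y_i ~ N(mu_i, Sigma_i),

where f(y_i) is the closed-form LMM marginal and the posterior moments
are available analytically.  The remaining expectation is evaluated by
Gauss-Hermite quadrature centered and scaled at that posterior — one
dimensional for the slope association (the survival factor involves only
the random slope), two dimensional for the current-value association.
This keeps the rule accurate even when the random-effect prior is much
wider than the per-subject posterior.

Estimation is maximum likelihood on an unconstrained parameterisation
(log-Cholesky for D, log scales for sigma and the hazard pieces), with
two-stage initialisation (standalone LMM and piecewise-exponential fits,
alpha = 0) and quasi-Newton maximisation; standard errors come from the
central-difference Hessian at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import JointDataset, SubjectData, UnfittableEndpointError
from .hazard import PiecewiseHazard, choose_knots, fit_pe, piece_overlaps, serialize
from .lmm import (
    FIXED_EFFECT_NAMES,
    LmmParams,
    LongitudinalStats,
    chol_from_theta,
    fit_lmm,
    posterior_moments,
    prepare_stats,
    theta_from_D,
)

_LOG2PI = float(np.log(2.0 * np.pi))

ASSOCIATIONS = ("slope", "current_value")


class NonFiniteLikelihoodError(RuntimeError):
    """The joint likelihood is non-finite at the requested parameter point."""


class ConvergenceError(RuntimeError):
    """The optimiser failed; the message carries the diagnostics."""


@dataclass
class JointModelSpec:
    """Configuration of a joint-model fit.

    ``gh_nodes`` is the number of Gauss-Hermite nodes per random-effect
    dimension; ``min_events`` guards against endpoints with too few events
    for a stable fit.
    """

    association: str = "slope"
    n_internal_knots: int = 5
    gh_nodes: int = 9
    min_events: int = 20
    maxiter: int = 1000
    gtol: float = 1e-6
    endpoint: str = "all_cause"
    period: str = "52w"

    def __post_init__(self) -> None:
        if self.association not in ASSOCIATIONS:
            raise ValueError(f"association must be one of {ASSOCIATIONS}")
        if self.gh_nodes < 3:
            raise ValueError("gh_nodes must be >= 3")


@dataclass
class JointParams:
    """All free parameters of the joint model on their natural scale."""

    beta: np.ndarray  # fixed effects, ordered as FIXED_EFFECT_NAMES
    D: np.ndarray  # 2x2 random-effect covariance
    sigma2: float
    log_h0: np.ndarray  # (2 strata, n_pieces) log baseline-hazard heights
    alpha: float  # association coefficient

    @property
    def n_pieces(self) -> int:
        return self.log_h0.shape[1]


def pack(params: JointParams) -> np.ndarray:
    """Flatten to the unconstrained optimisation vector."""
    return np.concatenate(
        [
            params.beta,
            theta_from_D(params.D),
            [0.5 * np.log(params.sigma2)],
            params.log_h0.ravel(),
            [params.alpha],
        ]
    )


def unpack(theta: np.ndarray, n_pieces: int) -> JointParams:
    beta = theta[:5]
    L = chol_from_theta(theta[5:8])
    sigma2 = float(np.exp(2.0 * theta[8]))
    log_h0 = theta[9 : 9 + 2 * n_pieces].reshape(2, n_pieces)
    return JointParams(
        beta=beta, D=L @ L.T, sigma2=sigma2, log_h0=log_h0, alpha=float(theta[-1])
    )


def param_names(n_pieces: int) -> list[str]:
    names = list(FIXED_EFFECT_NAMES)
    names += ["log_chol_d11", "chol_d21", "log_chol_d22", "log_sigma"]
    names += [
        f"log_h0[{s}][{j}]" for s in ("ata_neg", "ata_pos") for j in range(n_pieces)
    ]
    names += ["alpha"]
    return names


# ---------------------------------------------------------------------------
# prepared per-dataset arrays


@dataclass
class _Prepared:
    stats: LongitudinalStats
    has_obs: np.ndarray  # position in stats arrays, -1 if no measurements
    arm: np.ndarray
    ata: np.ndarray
    cb: np.ndarray
    T: np.ndarray
    delta: np.ndarray
    overlaps: np.ndarray  # (n, n_pieces) exposure of [0, T_i] to each piece
    piece_at_T: np.ndarray
    edges_lo: np.ndarray  # (n, n_pieces) clipped piece bounds within [0, T_i]
    edges_hi: np.ndarray
    subject_ids: list[str]
    center: float
    knots: np.ndarray


def prepare(dataset: JointDataset, knots, center: float) -> _Prepared:
    knots = np.atleast_1d(np.asarray(knots, dtype=float))
    stats = prepare_stats(dataset, center)
    n = dataset.n
    has_obs = np.full(n, -1, dtype=int)
    for pos, i in enumerate(stats.idx):
        has_obs[i] = pos
    arm = np.array([s.arm for s in dataset.subjects], dtype=float)
    ata = np.array([s.ata_positive for s in dataset.subjects], dtype=int)
    cb = np.array([s.baseline_fvc_pct - center for s in dataset.subjects])
    T = np.array([s.event_time_years for s in dataset.subjects])
    delta = np.array([s.event_indicator for s in dataset.subjects], dtype=float)
    overlaps = piece_overlaps(knots, T)
    piece_at_T = np.searchsorted(knots, T, side="right")
    edges = np.concatenate([[0.0], knots])
    lo = np.minimum(edges[None, :], T[:, None])
    hi = lo + overlaps
    return _Prepared(
        stats=stats, has_obs=has_obs, arm=arm, ata=ata, cb=cb, T=T,
        delta=delta, overlaps=overlaps, piece_at_T=piece_at_T,
        edges_lo=lo, edges_hi=hi,
        subject_ids=[s.subject_id for s in dataset.subjects],
        center=center, knots=knots,
    )


def _posterior_all(prep: _Prepared, params: JointParams):
    """Posterior moments of b for every subject (prior where no data)."""
    n = len(prep.T)
    mu = np.zeros((n, 2))
    Sig = np.broadcast_to(params.D, (n, 2, 2)).copy()
    lmm_ll = np.zeros(n)
    if len(prep.stats.n):
        m_mu, m_Sig, logdetV, quad = posterior_moments(
            prep.stats, params.beta, params.D, params.sigma2
        )
        obs = prep.stats.idx
        mu[obs] = m_mu
        Sig[obs] = m_Sig
        lmm_ll[obs] = -0.5 * (prep.stats.n * _LOG2PI + logdetV + quad)
    return mu, Sig, lmm_ll


def subject_survival_terms(
    params: JointParams,
    knots: np.ndarray,
    association: str,
    arm: float,
    ata: int,
    cb: float,
    T: float,
    delta: float,
    b: np.ndarray,
    center: float = 0.0,
):
    """(log hazard at T if event, -Lambda_i(T)) for one subject at fixed b.

    For the slope association the subject's hazard is the baseline times a
    constant exp(alpha*slope_i); for the current-value association the
    exponent uses the trajectory centered at ``center`` (the baseline
    heights then refer to a subject at FVC = center, which keeps alpha and
    the log heights well conditioned; hazard ratios are unaffected), and
    the cumulative hazard is summed in closed form over the hazard pieces
    with a midpoint limit when |alpha*C*(b-a)| is tiny.
    """
    pw = PiecewiseHazard(knots=np.atleast_1d(knots), log_h0=params.log_h0)
    h = pw.heights(ata)
    overlaps = piece_overlaps(pw.knots, np.array([T]))[0]
    edges = np.concatenate([[0.0], pw.knots])
    lo = np.minimum(edges, T)
    hi = lo + overlaps
    b = np.asarray(b, dtype=float)
    slope = params.beta[3] + params.beta[4] * arm + b[1]
    log_h0_T = params.log_h0[ata][int(pw.piece_index(T))]
    a_ = params.alpha
    if association == "slope":
        lam = np.exp(a_ * slope) * float(overlaps @ h)
        log_haz = log_h0_T + a_ * slope
    else:
        A = (
            params.beta[0] + params.beta[1] * ata + params.beta[2] * cb
            + b[0] - center
        )
        C = slope
        ac = a_ * C
        width = hi - lo
        with np.errstate(over="ignore"):
            exact = h * np.exp(a_ * A) * (np.exp(ac * hi) - np.exp(ac * lo)) / (
                ac if ac != 0 else 1.0
            )
            mid = h * np.exp(a_ * A + ac * (lo + hi) / 2.0) * width
        pieces = np.where(np.abs(ac * width) < 1e-8, mid, exact)
        lam = float(np.where(width > 0, pieces, 0.0).sum())
        log_haz = log_h0_T + a_ * (A + C * T)
    return (float(log_haz) if delta else None, -float(lam))


def _loglik_by_subject(params: JointParams, prep: _Prepared, spec: JointModelSpec):
    """Vector of per-subject marginal log-likelihood contributions."""
    mu, Sig, lmm_ll = _posterior_all(prep, params)
    x, w = hermgauss(spec.gh_nodes)
    logw = np.log(w) - 0.5 * np.log(np.pi)

    H = np.exp(params.log_h0)[prep.ata]  # (n, P) heights per subject stratum
    Lam0T = (prep.overlaps * H).sum(axis=1)
    log_h0_T = params.log_h0[prep.ata, prep.piece_at_T]
    a_ = params.alpha

    if spec.association == "slope":
        sd1 = np.sqrt(np.maximum(Sig[:, 1, 1], 1e-300))
        b1 = mu[:, 1:2] + np.sqrt(2.0) * sd1[:, None] * x[None, :]  # (n, K)
        s = params.beta[3] + params.beta[4] * prep.arm[:, None] + b1
        with np.errstate(over="ignore"):
            log_f = (
                prep.delta[:, None] * (log_h0_T[:, None] + a_ * s)
                - np.exp(a_ * s) * Lam0T[:, None]
            )
        surv_ll = logsumexp(log_f + logw[None, :], axis=1)
    else:
        # batched Cholesky of the 2x2 posterior covariances
        l11 = np.sqrt(Sig[:, 0, 0])
        l21 = Sig[:, 1, 0] / l11
        l22 = np.sqrt(np.maximum(Sig[:, 1, 1] - l21**2, 1e-300))
        u0, u1 = np.meshgrid(x, x, indexing="ij")
        u0, u1 = u0.ravel(), u1.ravel()  # (K^2,)
        lw2 = (logw[:, None] + logw[None, :]).ravel()
        b0 = mu[:, 0:1] + np.sqrt(2.0) * l11[:, None] * u0[None, :]
        b1 = mu[:, 1:2] + np.sqrt(2.0) * (
            l21[:, None] * u0[None, :] + l22[:, None] * u1[None, :]
        )
        A = (
            params.beta[0]
            + params.beta[1] * prep.ata[:, None]
            + params.beta[2] * prep.cb[:, None]
            + b0
            - prep.center
        )  # (n, K^2)
        C = params.beta[3] + params.beta[4] * prep.arm[:, None] + b1
        ac = a_ * C  # (n, K^2)
        lo = prep.edges_lo[:, None, :]  # (n, 1, P)
        hi = prep.edges_hi[:, None, :]
        width = hi - lo
        acw = ac[:, :, None] * width
        with np.errstate(over="ignore", invalid="ignore"):
            safe_ac = np.where(ac == 0.0, 1.0, ac)
            exact = (
                np.exp(ac[:, :, None] * hi) - np.exp(ac[:, :, None] * lo)
            ) / safe_ac[:, :, None]
            midp = np.exp(ac[:, :, None] * (lo + hi) / 2.0) * width
            pieces = np.where(np.abs(acw) < 1e-8, midp, exact)
            lam = np.exp(a_ * A) * np.einsum(
                "nkp,np->nk", np.where(width > 0, pieces, 0.0), H
            )
            log_f = (
                prep.delta[:, None]
                * (log_h0_T[:, None] + a_ * (A + C * prep.T[:, None]))
                - lam
            )
        surv_ll = logsumexp(log_f + lw2[None, :], axis=1)

    return lmm_ll + surv_ll


def joint_loglik(
    params: JointParams,
    dataset: JointDataset,
    spec: JointModelSpec,
    knots,
    center: float,
) -> float:
    """Marginal joint log-likelihood at a parameter point.

    Raises :class:`NonFiniteLikelihoodError` naming the first offending
    subject if any contribution is non-finite.
    """
    prep = prepare(dataset, knots, center)
    ll = _loglik_by_subject(params, prep, spec)
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise NonFiniteLikelihoodError(
            f"non-finite likelihood for subject {prep.subject_ids[bad]!r} "
            f"(alpha={params.alpha:.4g}, sigma2={params.sigma2:.4g})"
        )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# fitting


@dataclass
class JointModelFit:
    """Fitted joint model: sub-model parameters, association, and inference."""

    spec: JointModelSpec
    params: JointParams
    knots: np.ndarray
    center: float
    loglik: float
    vcov: np.ndarray  # on the unconstrained scale, NaN rows for fixed params
    names: list[str]
    converged: bool
    n_iter: int
    grad_norm: float
    n: int
    n_events: int

    @property
    def lmm(self) -> LmmParams:
        return LmmParams(
            beta=self.params.beta, D=self.params.D, sigma2=self.params.sigma2
        )

    @property
    def hazard(self) -> PiecewiseHazard:
        return PiecewiseHazard(knots=self.knots, log_h0=self.params.log_h0)

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def alpha_se(self) -> float:
        return float(np.sqrt(self.vcov[-1, -1]))

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.vcov[i, i]))

    def to_json(self) -> str:
        ses = np.sqrt(np.diag(self.vcov))
        return json.dumps(
            {
                "association": self.spec.association,
                "endpoint": self.spec.endpoint,
                "period": self.spec.period,
                "coefficients": {
                    nm: {"estimate": float(v), "se_transformed_scale": float(s)}
                    for nm, v, s in zip(self.names, pack(self.params), ses)
                },
                "D": self.params.D.tolist(),
                "sigma2": self.params.sigma2,
                "hazard": serialize(self.hazard),
                "alpha": self.alpha,
                "alpha_se": self.alpha_se,
                "center": self.center,
                "loglik": self.loglik,
                "converged": self.converged,
                "n": self.n,
                "n_events": self.n_events,
                "gh_nodes": self.spec.gh_nodes,
            },
            indent=2,
        )


def _central_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.zeros((p, p))
    f0 = f(x0)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = f(x0 + ei)
        fmm = f(x0 - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_joint(dataset: JointDataset, spec: JointModelSpec | None = None) -> JointModelFit:
    """Fit the joint model by maximum likelihood.

    Two-stage initialisation (standalone LMM, closed-form piecewise-
    exponential fit, alpha = 0) followed by quasi-Newton maximisation of
    the joint likelihood; deterministic given the data and spec.

    Raises
    ------
    UnfittableEndpointError
        if the dataset has fewer than ``spec.min_events`` events.
    ConvergenceError
        if the optimiser reports failure.
    """
    spec = spec or JointModelSpec()
    n_events = dataset.n_events
    if n_events < spec.min_events:
        raise UnfittableEndpointError(
            f"unfittable endpoint {dataset.endpoint!r}: {n_events} events "
            f"< minimum {spec.min_events}"
        )
    center = float(np.mean([s.baseline_fvc_pct for s in dataset.subjects]))
    lmm_fit = fit_lmm(dataset, center=center)
    knots = choose_knots(dataset.event_times(), spec.n_internal_knots)
    pw, _ = fit_pe(dataset, knots)

    # initial log heights: smooth empty cells instead of -inf
    from .hazard import exposure_and_events

    exposure, events = exposure_and_events(dataset, knots)
    log_h0 = np.where(
        exposure > 0,
        np.log(np.maximum(events + 0.5, 0.5) / np.maximum(exposure, 1e-12)),
        -8.0,
    )

    params0 = JointParams(
        beta=lmm_fit.params.beta,
        D=lmm_fit.params.D,
        sigma2=lmm_fit.params.sigma2,
        log_h0=log_h0,
        alpha=0.0,
    )
    theta0 = pack(params0)
    n_pieces = log_h0.shape[1]
    prep = prepare(dataset, knots, center)

    def negll(theta: np.ndarray) -> float:
        p = unpack(theta, n_pieces)
        ll = _loglik_by_subject(p, prep, spec)
        total = ll.sum()
        return -float(total) if np.isfinite(total) else 1e12

    lb = -12.0
    ub = 8.0
    bounds = (
        [(None, None)] * 5
        + [(-8.0, 8.0), (-60.0, 60.0), (-8.0, 8.0), (-8.0, 8.0)]
        + [(lb, ub)] * (2 * n_pieces)
        + [(None, None)]
    )
    res = minimize(
        negll, theta0, method="L-BFGS-B", bounds=bounds,
        options={
            "maxiter": spec.maxiter,
            "maxfun": 200_000,
            "ftol": 1e-11,
            "gtol": spec.gtol,
        },
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    if not res.success and "ROUNDOFF" not in str(res.message).upper():
        raise ConvergenceError(
            f"joint-model optimisation failed: {res.message}; "
            f"max|grad|={grad_norm:.3g}, loglik={-res.fun:.6f}"
        )

    theta_hat = res.x
    # parameters pinned at a bound (e.g. empty hazard cells) are excluded
    # from the observed-information inversion
    at_bound = np.zeros(len(theta_hat), dtype=bool)
    for i, (b, v) in enumerate(zip(bounds, theta_hat)):
        if b[0] is not None and (v - b[0] < 1e-6 or b[1] - v < 1e-6):
            at_bound[i] = True
    free = ~at_bound
    H = _central_hessian(negll, theta_hat)
    vcov = np.full_like(H, np.nan)
    Hf = H[np.ix_(free, free)]
    try:
        vf = np.linalg.inv(Hf)
    except np.linalg.LinAlgError:
        vf = np.linalg.pinv(Hf)
    if np.any(np.diag(vf) < 0):
        vf = np.linalg.pinv(Hf)
    vcov[np.ix_(free, free)] = vf

    return JointModelFit(
        spec=spec,
        params=unpack(theta_hat, n_pieces),
        knots=knots,
        center=center,
        loglik=-float(res.fun),
        vcov=vcov,
        names=param_names(n_pieces),
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        n=dataset.n,
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# subject-level prediction


def empirical_bayes(
    fit: JointModelFit, subject: SubjectData
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode of a subject's random effects and its curvature.

    Maximises the log of the subject's joint-likelihood integrand; with
    no longitudinal data and alpha = 0 this reduces to the prior mode
    (0, 0), and with alpha = 0 generally to the standard LMM BLUP.
    Returns ``(mode, covariance)`` where the covariance is the inverse
    curvature at the mode (diagnostic use only).
    """
    p = fit.params
    Dinv = np.linalg.inv(p.D)
    t = subject.times_years
    y = subject.fvc
    cb = subject.baseline_fvc_pct - fit.center
    fixed = (
        p.beta[0]
        + p.beta[1] * subject.ata_positive
        + p.beta[2] * cb
        + (p.beta[3] + p.beta[4] * subject.arm) * t
    )

    def neg_log_integrand(b: np.ndarray) -> float:
        resid = y - fixed - b[0] - b[1] * t
        ll = -0.5 * np.sum(resid**2) / p.sigma2 - 0.5 * b @ Dinv @ b
        log_haz, neg_lam = subject_survival_terms(
            p, fit.knots, fit.spec.association,
            subject.arm, subject.ata_positive, cb,
            subject.event_time_years, subject.event_indicator, b,
            center=fit.center,
        )
        ll += neg_lam
        if subject.event_indicator:
            ll += log_haz
        return -ll

    res = minimize(neg_log_integrand, np.zeros(2), method="BFGS")
    H = _central_hessian(neg_log_integrand, res.x, rel_step=1e-5)
    return res.x, np.linalg.inv(H)
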