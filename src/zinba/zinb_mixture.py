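"""Three-component zero-inflated negative binomial mixture regression.

Window counts y_i are modeled as a mixture of a point mass at zero (the
zero-inflated component, reachable only when y_i = 0), a background negative
binomial, and an enrichment negative binomial.  Each component has its own
covariate model: the zero-inflation probability pi_i0 follows a logistic
regression on X_i0, and the NB means follow log-linear regressions
mu_ij = exp(X_ij . beta_j) with component dispersions theta_j
(variance mu + mu^2 / theta).

The model is fit by EM.  The E-step updates the per-window posterior
membership probabilities (tau_i0, tau_i1, tau_i2); the M-step maximizes the
expected complete-data log-likelihood with weighted GLMs (IRLS) using the
posteriors as weights, profiling each dispersion by bounded 1-D likelihood
maximization.  Several starting partitions of the data (top 0.1%, 1%, 5%,
10%, 15% of windows by count seeded as enriched) are run to convergence and
the best-likelihood run is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, gammaln

from .covariates import WindowTable

logger = logging.getLogger(__name__)

DEFAULT_INIT_FRACTIONS = (0.001, 0.01, 0.05, 0.10, 0.15)

_ETA_CLIP = 30.0
_THETA_BOUNDS = (1e-3, 1e5)
_PI_FLOOR = 1e-6
_MIN_EFFECTIVE_WINDOWS = 10.0


@dataclass
class MixtureParams:
    """Fitted coefficients: gamma (zero-inflation logit), beta/theta per NB
    component, and global conditional mixture proportions pi1 + pi2 = 1."""

    gamma: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    theta1: float
    theta2: float
    pi1: float
    pi2: float

    def validate(self) -> None:
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise ValueError("dispersions must be positive")
        if not (0 < self.pi1 < 1 and 0 < self.pi2 < 1):
            raise ValueError("mixture proportions must lie in (0, 1)")
        if abs(self.pi1 + self.pi2 - 1.0) > 1e-8:
            raise ValueError("pi1 + pi2 must equal 1")


@dataclass
class PosteriorMatrix:
    """Per-window posterior membership probabilities; rows sum to one and
    tau0 is exactly zero wherever y > 0."""

    tau0: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.tau0, self.tau1, self.tau2])


@dataclass
class MixtureFit:
    params: MixtureParams
    posteriors: PosteriorMatrix
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    init_fraction: float

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def nb_log_pmf(y, mu, theta) -> np.ndarray:
    """Log pmf of the NB distribution with mean mu and variance mu + mu^2/theta."""
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.integer):
        yf = np.asarray(y, dtype=np.float64)
        if np.any(yf < 0) or np.any(yf != np.floor(yf)):
            raise ValueError("y must contain non-negative integers")
        y = yf
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


# ---------------------------------------------------------------------------
# fast internal kernels (counts are small integers, so gammaln terms in y are
# served from a lookup over 0..max(y))


class _CountTables:
    """Precomputed lookups over the observed count range for one dataset."""

    def __init__(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=np.float64)
        self.ymax = int(self.y.max())
        self.grid = np.arange(self.ymax + 1, dtype=np.float64)
        self.lgamma_y1 = gammaln(self.y + 1.0)
        self.yi = self.y.astype(np.int64)

    def lgamma_y_plus(self, theta: float) -> np.ndarray:
        """gammaln(y + theta) per window via a lookup over unique counts."""
        return gammaln(self.grid + theta)[self.yi]


def _nb_loglik_vec(tables: _CountTables, mu: np.ndarray, theta: float) -> np.ndarray:
    y = tables.y
    return (
        tables.lgamma_y_plus(theta)
        - gammaln(theta)
        - tables.lgamma_y1
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def _weighted_nb_loglik(tables: _CountTables, w: np.ndarray, mu: np.ndarray, theta: float) -> float:
    # gammaln(y + theta) aggregated over the count histogram of the weights
    hist = np.bincount(tables.yi, weights=w, minlength=tables.ymax + 1)
    wsum = hist.sum()
    const = hist @ gammaln(tables.grid + theta) - wsum * gammaln(theta) - w @ tables.lgamma_y1
    lin = theta * (wsum * np.log(theta) - w @ np.log(theta + mu))
    lin += w @ (tables.y * (np.log(mu) - np.log(theta + mu)))
    return float(const + lin)


def _irls_nb(
    tables: _CountTables,
    X: np.ndarray,
    w: np.ndarray,
    theta: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Weighted NB regression with log link by IRLS (step-halved for safety)."""
    y = tables.y
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max((w @ y) / max(w.sum(), 1e-12), 1e-8))
    else:
        beta = beta0.copy()
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = _weighted_nb_loglik(tables, w, mu, theta)
    for _ in range(max_iter):
        W = w * mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        XtW = X.T * W
        try:
            delta = np.linalg.solve(XtW @ X, XtW @ z) - beta
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"rank-deficient weighted NB design (p={p}); drop collinear columns"
            ) from exc
        step = 1.0
        for _ in range(12):
            cand = beta + step * delta
            eta_c = np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.exp(eta_c)
            ll_c = _weighted_nb_loglik(tables, w, mu_c, theta)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break  # no improving step: converged to numerical precision
        beta, eta, mu = cand, eta_c, mu_c
        improved = ll_c - ll
        ll = ll_c
        if improved < tol * (1.0 + abs(ll)):
            break
    return beta


def _profile_theta(
    tables: _CountTables, w: np.ndarray, mu: np.ndarray, lo: float, hi: float
) -> float:
    hist = np.bincount(tables.yi, weights=w, minlength=tables.ymax + 1)
    wsum = hist.sum()
    w_lgy1 = w @ tables.lgamma_y1
    wy = w * tables.y
    wy_logmu = wy @ np.log(mu)

    def neg(log_theta: float) -> float:
        th = np.exp(log_theta)
        log_thmu = np.log(th + mu)
        val = (
            hist @ gammaln(tables.grid + th)
            - wsum * gammaln(th)
            - w_lgy1
            + th * (wsum * np.log(th) - w @ log_thmu)
            + wy_logmu
            - wy @ log_thmu
        )
        return -val

    res = minimize_scalar(
        neg, bounds=(np.log(lo), np.log(hi)), method="bounded", options={"xatol": 1e-3}
    )
    return float(np.exp(res.x))


def _irls_logistic(
    resp: np.ndarray,
    X: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 40,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fractional-response logistic regression (responses in [0, 1], unit weights)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if beta0 is None:
        m = np.clip(resp.mean(), 1e-8, 1 - 1e-8)
        beta[0] = np.log(m / (1 - m))

    def loglik(mu):
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(resp @ np.log(mu) + (1 - resp) @ np.log(1 - mu))

    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    ll = loglik(mu)
    for _ in range(max_iter):
        W = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (resp - mu) / W
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("rank-deficient logistic design") from exc
        delta = new - beta
        step = 1.0
        for _ in range(12):
            cand = beta + step * delta
            eta_c = np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP)
            mu_c = expit(eta_c)
            ll_c = loglik(mu_c)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break
        beta, eta, mu = cand, eta_c, mu_c
        if ll_c - ll < tol * (1.0 + abs(ll_c)):
            ll = ll_c
            break
        ll = ll_c
    return beta


# ---------------------------------------------------------------------------
# EM steps


def init_partitions(y: np.ndarray, fractions=DEFAULT_INIT_FRACTIONS) -> list[PosteriorMatrix]:
    """Hard starting partitions: top ceil(f*n) windows by count seeded enriched,
    remaining positive windows background, zero windows zero-inflated.
    Ties at the cut are broken by genome order (earlier windows first)."""
    y = np.asarray(y)
    n = len(y)
    n_pos = int((y > 0).sum())
    if n_pos == 0:
        raise ValueError("all window counts are zero; nothing to partition")
    order = np.argsort(-y, kind="stable")  # stable: ties keep genome order
    out = []
    for f in fractions:
        k = min(int(np.ceil(f * n)), n_pos)
        tau0 = (y == 0).astype(np.float64)
        tau1 = (y > 0).astype(np.float64)
        tau2 = np.zeros(n)
        top = order[:k]
        tau1[top] = 0.0
        tau2[top] = 1.0
        out.append(PosteriorMatrix(tau0, tau1, tau2))
    return out


def m_step(
    y: np.ndarray,
    X0: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    tau: PosteriorMatrix,
    prev: MixtureParams | None = None,
    theta_rounds: int = 1,
    _tables: _CountTables | None = None,
) -> MixtureParams:
    """Maximize the expected complete-data log-likelihood.

    The posteriors weight three GLMs: a fractional-response logistic
    regression for the zero-inflation probability (response tau0) and one
    weighted NB regression per count component, alternating IRLS for beta
    with bounded profile maximization for theta.  Components with fewer than
    10 effective windows keep their previous estimates for the iteration.
    """
    tables = _tables if _tables is not None else _CountTables(np.asarray(y))

    gamma = _irls_logistic(tau.tau0, X0, None if prev is None else prev.gamma)

    betas, thetas = [], []
    for j, (X, w) in enumerate(((X1, tau.tau1), (X2, tau.tau2)), start=1):
        prev_beta = getattr(prev, f"beta{j}", None) if prev is not None else None
        prev_theta = getattr(prev, f"theta{j}") if prev is not None else 1.0
        if w.sum() < _MIN_EFFECTIVE_WINDOWS:
            if prev is None:
                # moment-matched intercept-only start; the E-step reassigns mass
                logger.warning(
                    "component %d starts with effective weight %.2f; "
                    "using a moment-based initial fit",
                    j,
                    w.sum(),
                )
                beta = np.zeros(X.shape[1])
                beta[0] = np.log(max((w @ tables.y) / max(w.sum(), 1e-12), 1e-3))
                betas.append(beta)
                thetas.append(1.0)
                continue
            logger.warning("component %d update skipped: effective weight %.2f", j, w.sum())
            betas.append(prev_beta.copy())
            thetas.append(prev_theta)
            continue
        theta = prev_theta
        beta = prev_beta
        for _ in range(theta_rounds):
            beta = _irls_nb(tables, X, w, theta, beta)
            mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
            theta = _profile_theta(tables, w, mu, *_THETA_BOUNDS)
        beta = _irls_nb(tables, X, w, theta, beta)
        betas.append(beta)
        thetas.append(theta)

    denom = tau.tau1.sum() + tau.tau2.sum()
    pi2 = tau.tau2.sum() / max(denom, 1e-12)
    pi2 = float(np.clip(pi2, _PI_FLOOR, 1 - _PI_FLOOR))
    return MixtureParams(gamma, betas[0], betas[1], thetas[0], thetas[1], 1 - pi2, pi2)


def _log_components(
    y: np.ndarray,
    X0: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    params: MixtureParams,
    tables: _CountTables | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window log joint terms for each mixture branch (log-space)."""
    tables = tables if tables is not None else _CountTables(np.asarray(y))
    pi0 = expit(np.clip(X0 @ params.gamma, -_ETA_CLIP, _ETA_CLIP))
    pi0 = np.clip(pi0, 1e-12, 1 - 1e-12)
    mu1 = np.exp(np.clip(X1 @ params.beta1, -_ETA_CLIP, _ETA_CLIP))
    mu2 = np.exp(np.clip(X2 @ params.beta2, -_ETA_CLIP, _ETA_CLIP))
    l0 = np.where(tables.y == 0, np.log(pi0), -np.inf)
    log1m = np.log1p(-pi0)
    l1 = log1m + np.log(params.pi1) + _nb_loglik_vec(tables, mu1, params.theta1)
    l2 = log1m + np.log(params.pi2) + _nb_loglik_vec(tables, mu2, params.theta2)
    return l0, l1, l2


def e_step(
    y: np.ndarray,
    X0: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    params: MixtureParams,
    _tables: _CountTables | None = None,
) -> PosteriorMatrix:
    """Posterior membership probabilities by Bayes' rule in log-space.

    The zero-inflated branch carries an indicator that y_i = 0, so tau0 is
    exactly zero for any window with a positive count.
    """
    l0, l1, l2 = _log_components(y, X0, X1, X2, params, _tables)
    m = np.maximum(np.maximum(l0, l1), l2)
    e0 = np.exp(l0 - m)
    e1 = np.exp(l1 - m)
    e2 = np.exp(l2 - m)
    tot = e0 + e1 + e2
    return PosteriorMatrix(e0 / tot, e1 / tot, e2 / tot)


def marginal_log_likelihood(
    y: np.ndarray,
    X0: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    params: MixtureParams,
    _tables: _CountTables | None = None,
) -> float:
    """Observed-data log-likelihood, log-sum-exp stabilized."""
    l0, l1, l2 = _log_components(y, X0, X1, X2, params, _tables)
    m = np.maximum(np.maximum(l0, l1), l2)
    return float(np.sum(m + np.log(np.exp(l0 - m) + np.exp(l1 - m) + np.exp(l2 - m))))


def _mean_level(X: np.ndarray, beta: np.ndarray) -> float:
    return float(np.exp(np.mean(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))))


class _EMRun:
    """State of one EM run (one starting partition), advanced incrementally."""

    def __init__(self, frac, tau, y, X0, X1, X2, tables):
        self.frac = frac
        self.tau = tau
        self.y, self.X0, self.X1, self.X2 = y, X0, X1, X2
        self.tables = tables
        self.params = m_step(y, X0, X1, X2, tau, prev=None, _tables=tables)
        self.trace: list[float] = []
        self.converged = False
        self.n_iter = 0

    def advance(self, n: int, tol: float, lag: int) -> None:
        for _ in range(n):
            if self.converged:
                return
            self.tau = e_step(self.y, self.X0, self.X1, self.X2, self.params, _tables=self.tables)
            self.params = m_step(
                self.y, self.X0, self.X1, self.X2, self.tau, prev=self.params, _tables=self.tables
            )
            self.trace.append(
                marginal_log_likelihood(
                    self.y, self.X0, self.X1, self.X2, self.params, _tables=self.tables
                )
            )
            self.n_iter += 1
            if self.n_iter > lag and abs(self.trace[-1] - self.trace[-1 - lag]) < tol:
                self.converged = True

    @property
    def loglik(self) -> float:
        return self.trace[-1] if self.trace else -np.inf


def fit_mixture(
    table: WindowTable,
    tol: float = 1e-5,
    lag: int = 10,
    max_iter: int = 500,
    init_fractions=DEFAULT_INIT_FRACTIONS,
    prescreen_iters: int = 25,
) -> MixtureFit:
    """Fit the mixture by EM over the starting partitions and keep the best run.

    Each starting partition is advanced ``prescreen_iters`` EM iterations;
    the partition with the best marginal log-likelihood is then run until
    the absolute change in log-likelihood from ``lag`` iterations prior
    drops below ``tol`` (or ``max_iter`` is reached, flagged via
    ``converged=False``).  Set ``prescreen_iters >= max_iter`` to run every
    partition to full convergence.  After convergence the components are
    relabeled if needed so that component 2 ("enrichment") has the larger
    mean level.
    """
    y = np.asarray(table.y)
    if len(np.unique(y[y > 0])) < 2:
        raise ValueError("need at least two distinct positive counts to fit the mixture")
    X0, X1, X2 = table.X0, table.X1, table.X2
    tables = _CountTables(y)

    runs = [
        _EMRun(frac, tau, y, X0, X1, X2, tables)
        for frac, tau in zip(init_fractions, init_partitions(y, init_fractions))
    ]
    if len(runs) > 1:
        for run in runs:
            run.advance(min(prescreen_iters, max_iter), tol, lag)
        runs.sort(key=lambda r: r.loglik, reverse=True)
        logger.info(
            "prescreen kept init fraction %.3f (loglik %.3f)", runs[0].frac, runs[0].loglik
        )
    survivors = runs[:1]

    best: MixtureFit | None = None
    for run in survivors:
        run.advance(max_iter - run.n_iter, tol, lag)
        if not run.converged:
            logger.warning("EM (init fraction %.3f) hit max_iter=%d", run.frac, max_iter)
        params, tau = run.params, run.tau

        # relabel so component 2 is the high-mean ("enrichment") component
        if _mean_level(X1, params.beta1) > _mean_level(X2, params.beta2):
            logger.info("relabeling components (init fraction %.3f)", run.frac)
            tau = PosteriorMatrix(tau.tau0, tau.tau2, tau.tau1)
            same_shape = X1.shape[1] == X2.shape[1]
            swapped = MixtureParams(
                params.gamma,
                params.beta2 if same_shape else params.beta1,
                params.beta1 if same_shape else params.beta2,
                params.theta2,
                params.theta1,
                params.pi2,
                params.pi1,
            )
            params = m_step(y, X0, X1, X2, tau, prev=swapped, _tables=tables)
            tau = e_step(y, X0, X1, X2, params, _tables=tables)
            run.trace.append(marginal_log_likelihood(y, X0, X1, X2, params, _tables=tables))
        else:
            tau = e_step(y, X0, X1, X2, params, _tables=tables)

        fit = MixtureFit(params, tau, np.asarray(run.trace), run.converged, run.n_iter, run.frac)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    logger.info(
        "best init fraction %.3f: loglik %.3f after %d iterations (converged=%s)",
        best.init_fraction,
        best.loglik,
        best.n_iter,
        best.converged,
    )
    return best
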