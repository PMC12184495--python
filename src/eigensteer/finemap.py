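"""Bayesian selection of causal eigengenes.

A ridge-regularized logistic regression on the projected data gives per-sample
log-odds ``zeta``; summary quantities ``xi = X.T zeta / d`` and
``R = X.T X / (d sigma^2)`` feed a multivariate-normal likelihood over binary
inclusion vectors ``gamma``:

    p(zeta, X | gamma) = N(xi | 0, R + R Sigma_gamma R),
    Sigma_gamma = d s^2 diag(gamma),

with the prior q_k = (1/d)^k (1 - 1/d)^(d-k) on the number of causal effects.
A Metropolis chain flips single inclusion indicators (with an occasional
log-normal random-walk update of the scale hyperparameter s) and posterior
inclusion probabilities are the post-burn-in means of the indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, recall_score

from .eigengenes import ProjectedData

__all__ = [
    "RegressionFit",
    "FineMapHyper",
    "FineMapResult",
    "fit_logistic",
    "z_value",
    "correlation_matrix",
    "log_likelihood",
    "log_prior",
    "run_mcmc",
    "select_causal",
    "causal_order_accuracy_curve",
]

RHO_CLAMP = 1e-6


@dataclass
class RegressionFit:
    beta: np.ndarray
    intercept: float
    rho: np.ndarray  # clamped class-1 probabilities
    zeta: np.ndarray  # log-odds log(rho / (1 - rho))
    sigma2: float  # residual variance of zeta - X beta - intercept
    accuracy: float
    f1: float
    recall: float


@dataclass
class FineMapHyper:
    s: float = 0.05
    n_steps: int = 100_000
    burn_in: int = 1_000
    seed: int = 0
    s_update_every: int = 10
    s_proposal_sd: float = 0.1
    keep_samples: bool = True

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be positive")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("require 0 <= burn_in < n_steps")


@dataclass
class FineMapResult:
    pip: np.ndarray
    samples: np.ndarray | None  # retained gamma draws (post burn-in), bool
    s_trace: np.ndarray
    xi: np.ndarray
    R: np.ndarray
    acceptance_rate: float
    selected: np.ndarray | None = None


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ProjectedData):
        return X.X
    return np.asarray(X, dtype=float)


def fit_logistic(
    X,
    labels: np.ndarray,
    ridge: float = 1.0,
    clamp: float = RHO_CLAMP,
    sigma2: str | float = "logistic",
) -> RegressionFit:
    """Ridge-penalized logistic fit; probabilities clamped away from {0, 1}.

    The design is standardized internally for the penalty; returned
    coefficients are on the original scale.

    ``sigma2`` selects the noise-variance estimator for the log-odds model:
    ``"logistic"`` (default) uses pi^2/3, the variance of the logistic
    distribution implicit in the latent-variable view of the regression;
    ``"residual"`` uses the sample variance of ``zeta - X beta - intercept``,
    which degenerates toward zero in-sample (the fitted log-odds ARE the
    linear predictor, up to clamping) and is kept only for comparison; a float
    fixes the value directly.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    clf = LogisticRegression(C=1.0 / ridge, max_iter=5000)
    clf.fit(Xs, labels)
    rho = np.clip(clf.predict_proba(Xs)[:, 1], clamp, 1 - clamp)
    zeta = np.log(rho / (1 - rho))

    beta = clf.coef_.ravel() / sd
    intercept = float(clf.intercept_[0] - (clf.coef_.ravel() * mu / sd).sum())
    if sigma2 == "logistic":
        sigma2_val = np.pi**2 / 3.0
    elif sigma2 == "residual":
        resid = zeta - X @ beta - intercept
        sigma2_val = max(
            float(np.var(resid, ddof=1)) if len(resid) > 1 else 0.0, 1e-12
        )
    else:
        sigma2_val = float(sigma2)
        if sigma2_val <= 0:
            raise ValueError("sigma2 must be positive")

    pred = (rho > 0.5).astype(int)
    return RegressionFit(
        beta=beta,
        intercept=intercept,
        rho=rho,
        zeta=zeta,
        sigma2=sigma2_val,
        accuracy=float(accuracy_score(labels, pred)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
    )


def z_value(X, zeta: np.ndarray, d: int | None = None) -> np.ndarray:
    """xi = X.T zeta / d."""
    X = _as_matrix(X)
    if d is None:
        d = X.shape[1]
    return X.T @ np.asarray(zeta, dtype=float) / d


def correlation_matrix(X, sigma2: float, d: int | None = None) -> np.ndarray:
    """R = X.T X / (d sigma^2), symmetrized."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    X = _as_matrix(X)
    if d is None:
        d = X.shape[1]
    R = X.T @ X / (d * sigma2)
    return (R + R.T) / 2.0


def _chol_logpdf(xi: np.ndarray, cov: np.ndarray) -> float:
    """MVN(0, cov) log-density with escalating jitter if needed."""
    d = cov.shape[0]
    base = 1e-8 * np.trace(cov) / d
    jitter = 0.0
    for _ in range(8):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(d) if jitter else cov)
            break
        except np.linalg.LinAlgError:
            jitter = base if jitter == 0.0 else jitter * 10.0
    else:
        raise np.linalg.LinAlgError(
            "covariance not factorizable even after maximum jitter"
        )
    alpha = np.linalg.solve(L, xi)
    return float(
        -0.5 * alpha @ alpha - np.log(np.diag(L)).sum() - 0.5 * d * np.log(2 * np.pi)
    )


def log_likelihood(
    xi: np.ndarray, R: np.ndarray, gamma: np.ndarray, s: float, d: int | None = None
) -> float:
    """log N(xi | 0, R + R Sigma_gamma R) with Sigma_gamma = d s^2 diag(gamma)."""
    xi = np.asarray(xi, dtype=float)
    R = np.asarray(R, dtype=float)
    gamma = np.asarray(gamma)
    if d is None:
        d = R.shape[0]
    active = np.flatnonzero(gamma)
    cov = R.copy()
    if active.size:
        Rs = R[:, active]
        cov = cov + (d * s * s) * (Rs @ Rs.T)
    return _chol_logpdf(xi, cov)


def log_prior(gamma: np.ndarray, d: int) -> float:
    """k log(1/d) + (d - k) log(1 - 1/d); -inf where the mass is zero."""
    if d < 1:
        raise ValueError("d must be at least 1")
    k = int(np.sum(gamma))
    if d == 1:
        return 0.0 if k == 1 else -np.inf
    return k * np.log(1.0 / d) + (d - k) * np.log(1.0 - 1.0 / d)


def run_mcmc(xi: np.ndarray, R: np.ndarray, hyper: FineMapHyper) -> FineMapResult:
    """Metropolis chain over (gamma, s); PIPs are post-burn-in indicator means.

    Each step flips one uniformly chosen indicator; every ``s_update_every``-th
    step instead proposes ``s' = s * exp(N(0, sd))`` with the Hastings
    correction for the multiplicative proposal.  The chain starts from
    gamma = 0 and the configured initial s.
    """
    xi = np.asarray(xi, dtype=float)
    R = np.asarray(R, dtype=float)
    d = R.shape[0]
    rng = np.random.default_rng(hyper.seed)

    gamma = np.zeros(d, dtype=bool)
    s = hyper.s
    cur_ll = log_likelihood(xi, R, gamma, s, d)
    cur_lp = log_prior(gamma, d)
    if not np.isfinite(cur_ll + cur_lp):
        raise ValueError("non-finite target at chain initialization")

    n_keep = hyper.n_steps - hyper.burn_in
    pip_sum = np.zeros(d)
    samples = np.zeros((n_keep, d), dtype=bool) if hyper.keep_samples else None
    s_trace = np.empty(hyper.n_steps)
    n_accept = 0

    for t in range(hyper.n_steps):
        if hyper.s_update_every and (t + 1) % hyper.s_update_every == 0:
            s_new = s * np.exp(hyper.s_proposal_sd * rng.standard_normal())
            new_ll = log_likelihood(xi, R, gamma, s_new, d)
            # Hastings ratio for the multiplicative random walk: q ratio = s'/s
            log_acc = new_ll - cur_ll + np.log(s_new / s)
            if np.log(rng.random()) < log_acc:
                s, cur_ll = s_new, new_ll
                n_accept += 1
        else:
            i = rng.integers(d)
            gamma[i] = ~gamma[i]
            new_ll = log_likelihood(xi, R, gamma, s, d)
            new_lp = log_prior(gamma, d)
            if np.log(rng.random()) < (new_ll + new_lp) - (cur_ll + cur_lp):
                cur_ll, cur_lp = new_ll, new_lp
                n_accept += 1
            else:
                gamma[i] = ~gamma[i]  # reject: restore
        s_trace[t] = s
        if t >= hyper.burn_in:
            pip_sum += gamma
            if samples is not None:
                samples[t - hyper.burn_in] = gamma

    return FineMapResult(
        pip=pip_sum / n_keep,
        samples=samples,
        s_trace=s_trace,
        xi=xi,
        R=R,
        acceptance_rate=n_accept / hyper.n_steps,
    )


def exhaustive_pip(
    xi: np.ndarray, R: np.ndarray, s: float, d: int | None = None
) -> np.ndarray:
    """Exact PIPs by enumerating all 2^d inclusion vectors (small d only).

    Independent oracle for the MCMC: sums the unnormalized posterior over
    every configuration at fixed s.
    """
    R = np.asarray(R, dtype=float)
    if d is None:
        d = R.shape[0]
    if d > 20:
        raise ValueError("exhaustive enumeration is limited to d <= 20")
    log_posts = np.empty(2**d)
    configs = np.empty((2**d, d), dtype=bool)
    for code in range(2**d):
        gamma = np.array([(code >> i) & 1 for i in range(d)], dtype=bool)
        configs[code] = gamma
        log_posts[code] = log_likelihood(xi, R, gamma, s, d) + log_prior(gamma, d)
    w = np.exp(log_posts - log_posts.max())
    w /= w.sum()
    return w @ configs


def select_causal(result: FineMapResult | np.ndarray, r: int) -> np.ndarray:
    """Indices of the r largest PIPs, descending; ties go to the lower index."""
    pip = result.pip if isinstance(result, FineMapResult) else np.asarray(result)
    if r > len(pip):
        raise ValueError(f"r={r} exceeds the number of eigengenes d={len(pip)}")
    order = np.lexsort((np.arange(len(pip)), -pip))
    return order[:r]


def causal_order_accuracy_curve(
    X, labels: np.ndarray, order: np.ndarray, ridge: float = 1.0
) -> np.ndarray:
    """In-sample accuracy of logistic fits on growing eigengene prefixes.

    Entry ``i`` uses the first ``i`` eigengenes of ``order``; entry 0 is the
    majority-class rate.  Supports causal-order, singular-value-order, and
    random-order baselines by passing the corresponding permutation.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    order = np.asarray(order, dtype=int)
    majority = max(np.mean(labels == 1), np.mean(labels == 0))
    acc = [float(majority)]
    for i in range(1, len(order) + 1):
        fit = fit_logistic(X[:, order[:i]], labels, ridge=ridge)
        acc.append(fit.accuracy)
    return np.array(acc)
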