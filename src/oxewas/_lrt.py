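"""Likelihood-ratio test engines shared across the association modules.

Both the continuous (Gaussian) and binary (logistic) scans in this package
use the same inferential recipe: fit the model with and without the term of
interest by maximum likelihood and refer -2 log(L0/L1) to a chi-square
distribution with one degree of freedom.

For the Gaussian linear model the error variance is profiled out, which
reduces the statistic to ``n * log(RSS0 / RSS1)``.  For the logistic model
the statistic is the drop in deviance.  A batched Newton solver is provided
so that label-permutation tests can refit thousands of models at once.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CollinearDesignError",
    "ConstantExposureError",
    "PerfectSeparationError",
    "LinearLrtResult",
    "LogisticLrtResult",
    "add_intercept",
    "gaussian_lrt",
    "logistic_deviance",
    "logistic_fit",
    "logistic_lrt",
    "logistic_deviance_batch",
]


class CollinearDesignError(ValueError):
    """Design matrix is rank deficient; message names the offending columns."""


class ConstantExposureError(ValueError):
    """Exposure has no variation among the complete cases."""


class PerfectSeparationError(RuntimeError):
    """Logistic ML estimate diverges (classes perfectly separated)."""


@dataclass(frozen=True)
class LinearLrtResult:
    slope: float
    lrt_stat: float
    p: float
    n_used: int


@dataclass(frozen=True)
class LogisticLrtResult:
    coef: float
    se: float
    lrt_stat: float
    p: float
    n_used: int


def add_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Return a design matrix with a leading intercept column."""
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    return np.column_stack([np.ones(len(cov)), cov])


def _check_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify near-dependent columns from the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
        if names is None:
            names = [f"col{j}" for j in range(X.shape[1])]
        offenders = ", ".join(names[j] for j in bad) or "unidentified"
        raise CollinearDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {offenders}"
        )


def gaussian_lrt(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    column_names: list[str] | None = None,
) -> LinearLrtResult:
    """Gaussian ML likelihood-ratio test of ``y ~ x + covariates`` vs ``y ~ covariates``.

    With the error variance profiled out, the statistic is
    ``n * log(RSS0 / RSS1)`` and is referred to chi-square(1).  Inputs must
    already be restricted to complete cases.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    if np.ptp(x) == 0:
        raise ConstantExposureError("exposure is constant among complete cases")
    X0 = add_intercept(covariates, n)
    X1 = np.column_stack([X0, x])
    if n < X1.shape[1] + 2:
        raise ValueError(f"too few complete cases ({n}) for {X1.shape[1]} parameters")
    names = ["intercept"]
    if column_names is not None:
        names += list(column_names)
    else:
        names += [f"cov{j}" for j in range(X0.shape[1] - 1)]
    _check_rank(X1, names + ["exposure"])

    beta0, rss0_arr, *_ = np.linalg.lstsq(X0, y, rcond=None)
    beta1, rss1_arr, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss0 = float(rss0_arr[0]) if rss0_arr.size else float(np.sum((y - X0 @ beta0) ** 2))
    rss1 = float(rss1_arr[0]) if rss1_arr.size else float(np.sum((y - X1 @ beta1) ** 2))
    if rss1 <= 0.0:
        lrt = math.inf
        p = 0.0
    else:
        lrt = max(n * math.log(rss0 / rss1), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
    return LinearLrtResult(slope=float(beta1[-1]), lrt_stat=lrt, p=p, n_used=n)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(eta, -35.0, 35.0)))


def logistic_deviance(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -35.0, 35.0)
    # -2 sum [y*log(mu) + (1-y)*log(1-mu)] written in a numerically safe form
    return float(2.0 * np.sum(np.log1p(np.exp(eta)) - y * eta))


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Newton-Raphson logistic ML fit.

    Returns (coefficients, deviance, observed-information matrix).  Raises
    :class:`PerfectSeparationError` when the estimate diverges.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")
    n, p = X.shape
    beta = np.zeros(p)
    # start from the marginal log-odds in the intercept (assumed first column of 1s)
    ybar = y.mean()
    beta[0] = math.log(ybar / (1.0 - ybar))
    dev = logistic_deviance(X, y, beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35.0, 35.0)
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise PerfectSeparationError("singular information matrix") from exc
        # damped Newton: halve until the deviance does not increase
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            cand_dev = logistic_deviance(X, y, cand)
            if cand_dev <= dev + 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        new_dev = logistic_deviance(X, y, beta)
        if abs(dev - new_dev) < tol and np.max(np.abs(lam * step)) < 1e-8:
            dev = new_dev
            break
        dev = new_dev
    # a vanishing deviance means the classes are (quasi-)separated: the
    # likelihood has no finite maximiser
    if dev < max(1e-6, 1e-10 * n):
        raise PerfectSeparationError(
            "deviance vanished; classes appear perfectly separated"
        )
    eta = np.clip(X @ beta, -35.0, 35.0)
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    return beta, dev, info


def logistic_lrt(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    column_names: list[str] | None = None,
) -> LogisticLrtResult:
    """Logistic LRT of the ``x`` term: deviance drop referred to chi-square(1)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    if np.ptp(x) == 0:
        raise ConstantExposureError("exposure is constant among complete cases")
    X0 = add_intercept(covariates, n)
    X1 = np.column_stack([X0, x])
    names = ["intercept"]
    if column_names is not None:
        names += list(column_names)
    else:
        names += [f"cov{j}" for j in range(X0.shape[1] - 1)]
    _check_rank(X1, names + ["exposure"])
    _, dev0, _ = logistic_fit(X0, y)
    beta1, dev1, info1 = logistic_fit(X1, y)
    cov = np.linalg.inv(info1)
    se = float(math.sqrt(cov[-1, -1]))
    lrt = max(dev0 - dev1, 0.0)
    return LogisticLrtResult(
        coef=float(beta1[-1]),
        se=se,
        lrt_stat=lrt,
        p=float(stats.chi2.sf(lrt, df=1)),
        n_used=n,
    )


def logistic_deviance_batch(
    X: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-8,
) -> np.ndarray:
    """Deviances of logistic fits of a fixed design ``X`` against many outcomes.

    ``Y`` is an ``n x B`` 0/1 matrix (one permuted outcome per column); the
    return value is a length-``B`` vector of fitted deviances.  All columns
    are iterated together with a plain (undamped) Newton update, which is
    stable here because permuted outcomes keep the case fraction of the
    observed data and the designs of interest are well conditioned.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    B = Y.shape[1]
    Beta = np.zeros((B, p))
    ybar = Y.mean(axis=0)
    ybar = np.clip(ybar, 1e-12, 1 - 1e-12)
    Beta[:, 0] = np.log(ybar / (1.0 - ybar))
    for _ in range(max_iter):
        Eta = np.clip(X @ Beta.T, -35.0, 35.0)  # n x B
        Mu = _sigmoid(Eta)
        W = Mu * (1.0 - Mu)
        Grad = X.T @ (Y - Mu)  # p x B
        Info = np.einsum("np,nb,nq->bpq", X, W, X, optimize=True)
        try:
            Step = np.linalg.solve(Info, Grad.T[:, :, None])[:, :, 0]  # B x p
        except np.linalg.LinAlgError:
            # fall back to per-column pseudo-inverse for the rare singular case
            Step = np.stack(
                [np.linalg.lstsq(Info[b], Grad[:, b], rcond=None)[0] for b in range(B)]
            )
        Beta += Step
        if np.max(np.abs(Step)) < tol:
            break
    Eta = np.clip(X @ Beta.T, -35.0, 35.0)
    return 2.0 * np.sum(np.log1p(np.exp(Eta)) - Y * Eta, axis=0)


def distinct_label_arrangements(n: int, n_cases: int, limit: int = 500_000) -> np.ndarray:
    """All distinct binary label vectors with ``n_cases`` ones, as an n x N matrix."""
    n_arr = math.comb(n, n_cases)
    if n_arr > limit:
        raise ValueError(f"{n_arr} arrangements exceed the exhaustive-mode limit {limit}")
    out = np.zeros((n, n_arr))
    for j, idx in enumerate(itertools.combinations(range(n), n_cases)):
        out[list(idx), j] = 1.0
    return out
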