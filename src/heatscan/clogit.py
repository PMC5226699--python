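"""Conditional logistic regression for 1-case : M-control matched sets.

The conditional likelihood for matched sets with exactly one case per set is

    L(beta) = prod_s exp(x_case . beta) / sum_{j in s} exp(x_j . beta)

Any covariate that is constant within a stratum — including the intercept
and any main effect of a time-invariant variable such as a decedent's
above/below-split indicator — cancels from this ratio and is inestimable.
That is why the split-scan interaction model is parameterised with two
estimable slopes (humidex within the below-split group and humidex within
the above-split group) rather than a main effect plus interaction.

The maximiser is a damped Newton-Raphson with analytic gradient and Hessian:
the score is the sum over strata of (case covariates minus the within-stratum
softmax mean), and the observed information is the sum of within-stratum
softmax covariances.  Step-halving guards against likelihood decreases;
non-convergence (e.g. complete separation, where the likelihood increases
without bound along a direction) is flagged rather than raised.  With one
case per stratum there are no ties, so no Breslow/Efron method is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["DesignRow", "ClogitFit", "fit", "fit_rows", "or_ci", "stack_strata"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DesignRow:
    """One person-day: stratum label, case indicator, covariate vector."""

    stratum_id: object
    outcome: int
    covariates: tuple


@dataclass
class ClogitFit:
    """Result of a conditional-logistic fit."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_strata: int
    n_informative_strata: int
    n_iter: int = 0
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def _segment_starts(groups_sorted: np.ndarray) -> np.ndarray:
    n = groups_sorted.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.intp)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = groups_sorted[1:] != groups_sorted[:-1]
    return np.flatnonzero(change)


def _loglik_parts(beta, X, starts, seg_id, case_rows):
    """Log-likelihood, softmax probabilities, per-stratum stabiliser."""
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - m[seg_id])
    denom = np.add.reduceat(z, starts)
    p = z / denom[seg_id]
    ll = float(np.sum(eta[case_rows] - m - np.log(denom)))
    return ll, p


def fit(
    y,
    X,
    groups,
    beta0=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> ClogitFit:
    """Maximise the conditional likelihood for 1:M matched sets.

    Parameters
    ----------
    y : (n,) 0/1 outcomes, exactly one 1 per stratum.
    X : (n, p) covariate matrix.
    groups : (n,) stratum labels (any hashable/sortable dtype).
    beta0 : optional warm-start coefficient vector.
    tol : convergence when the largest absolute score component is below it.
    max_iter : Newton iteration cap; hitting it flags non-convergence.

    Strata with no within-stratum covariate variation carry no information;
    they still contribute their constant ``-log |s|`` to the reported
    log-likelihood but are counted out of ``n_informative_strata``.  If no
    stratum is informative a ``ValueError`` is raised.
    """
    y = np.asarray(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    groups = np.asarray(groups)
    n, p = X.shape

    order = np.argsort(groups, kind="stable")
    y_s, X_s, g_s = y[order], X[order], groups[order]
    starts = _segment_starts(g_s)
    n_strata = starts.shape[0]
    seg_id = np.zeros(n, dtype=np.intp)
    seg_id[starts[1:]] = 1
    seg_id = np.cumsum(seg_id)

    cases_per_stratum = np.add.reduceat(y_s.astype(int), starts)
    if not np.all(cases_per_stratum == 1):
        raise ValueError(
            "fit: every stratum must contain exactly one case "
            f"(found counts {np.unique(cases_per_stratum)})"
        )
    case_rows = np.flatnonzero(y_s == 1)

    col_min = np.minimum.reduceat(X_s, starts, axis=0)
    col_max = np.maximum.reduceat(X_s, starts, axis=0)
    informative = np.any(col_max > col_min, axis=1)
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise ValueError("fit: no informative strata (no within-stratum covariate variation)")

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    x_case_sum = X_s[case_rows].sum(axis=0)

    ll, prob = _loglik_parts(beta, X_s, starts, seg_id, case_rows)
    converged = False
    message = "max iterations reached"
    it = 0
    for it in range(1, max_iter + 1):
        pX = prob[:, None] * X_s
        score = x_case_sum - pX.sum(axis=0)
        if np.max(np.abs(score)) < tol:
            converged = True
            message = "converged"
            break
        m_s = np.add.reduceat(pX, starts, axis=0)  # within-stratum mean * 1
        info = X_s.T @ pX - m_s.T @ m_s  # observed information (positive semi-definite)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(40):
            ll_new, prob_new = _loglik_parts(beta + scale * step, X_s, starts, seg_id, case_rows)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll, prob = ll_new, prob_new
        if np.max(np.abs(beta)) > 35.0:
            message = "diverging coefficients (possible complete separation)"
            break
    else:
        it = max_iter

    if converged and np.max(np.abs(beta)) > 15.0:
        # the score can vanish numerically on a flat likelihood plateau even
        # though the optimum is at infinity (complete separation)
        converged = False
        message = "diverging coefficients (possible complete separation)"
    pX = prob[:, None] * X_s
    m_s = np.add.reduceat(pX, starts, axis=0)
    info = X_s.T @ pX - m_s.T @ m_s
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        converged = False
        message = "singular information matrix"
    if not converged:
        log.debug("fit: non-convergence after %d iteration(s): %s", it, message)
    return ClogitFit(
        coefficients=beta,
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        n_strata=n_strata,
        n_informative_strata=n_informative,
        n_iter=it,
        message=message,
    )


def fit_rows(rows: Sequence[DesignRow], **kwargs) -> ClogitFit:
    """Convenience wrapper: fit from a sequence of :class:`DesignRow`."""
    y = np.array([r.outcome for r in rows])
    X = np.array([r.covariates for r in rows], dtype=float)
    groups = np.array([r.stratum_id for r in rows])
    return fit(y, X, groups, **kwargs)


def or_ci(fit_result: ClogitFit, index: int = 0, delta: float = 1.0) -> tuple:
    """Odds ratio and 95% CI for a ``delta``-unit exposure increment.

    ``OR = exp(delta * beta_k)`` with Wald interval
    ``exp(delta * (beta_k +/- 1.96 * SE_k))``.  Requires a converged fit.
    """
    if not fit_result.converged:
        raise ValueError(f"or_ci: fit did not converge ({fit_result.message})")
    b = float(fit_result.coefficients[index])
    se = float(fit_result.se[index])
    return (
        float(np.exp(delta * b)),
        float(np.exp(delta * (b - _Z95 * se))),
        float(np.exp(delta * (b + _Z95 * se))),
    )


def stack_strata(strata) -> "StratumStack":
    """Flatten cohort strata into aligned arrays for repeated fitting.

    Rows are grouped contiguously by stratum in uid order; the scan reuses
    one stack across all 100 splits, masking rows by each split's
    above/below membership.
    """
    uids, row_stratum, y, H = [], [], [], []
    case_dates = []
    for i, s in enumerate(strata):
        dates = s.dates
        uids.append(s.uid)
        case_dates.append(s.case_date)
        for d in dates:
            row_stratum.append(i)
            y.append(s.outcome(d))
            H.append(s.exposure[d])
    return StratumStack(
        uids=np.array(uids),
        case_dates=np.array(case_dates, dtype=object),
        row_stratum=np.array(row_stratum, dtype=np.intp),
        y=np.array(y, dtype=np.int8),
        exposure=np.array(H, dtype=float),
    )


@dataclass
class StratumStack:
    """Long-format view of an analytic set (rows sorted by stratum)."""

    uids: np.ndarray        # (n_strata,) uid per stratum
    case_dates: np.ndarray  # (n_strata,) case day per stratum
    row_stratum: np.ndarray  # (n_rows,) stratum index per row
    y: np.ndarray           # (n_rows,) case indicator
    exposure: np.ndarray    # (n_rows,) daily mean humidex

    @property
    def n_strata(self) -> int:
        return self.uids.shape[0]
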