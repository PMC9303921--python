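"""Treatment-effect tests on a 7-level ordinal outcome (mRS 0–6).

End-of-trial analysis uses (i) a proportional-odds (ordinal logistic)
regression of the outcome on the arm indicator and (ii) a binary logistic
regression at each of the six dichotomous cutpoints.  With a single binary
covariate both models collapse onto their sufficient 2×7 / 2×2 tables,
so they are fit here directly from counts: the logistic Wald test has the
closed form z = log(ad/bc) / sqrt(1/a + 1/b + 1/c + 1/d) (identical to the
logistic MLE with one binary regressor), and the proportional-odds model
is maximized by BFGS on the 2×7 table with analytic gradients.  Both are
cross-validated against statsmodels in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy import stats as sps

__all__ = ["TestResult", "outcome_table", "proportional_odds_test", "cutpoint_logistic_test"]

N_LEVELS = 7


@dataclass(frozen=True)
class TestResult:
    """Arm-effect estimate from one outcome model."""

    beta: float
    se: float
    p_value: float
    converged: bool


def outcome_table(arms, outcomes, n_levels: int = N_LEVELS) -> np.ndarray:
    """2×K count table: row 0 = arm B (control), row 1 = arm A (treatment)."""
    arms = np.asarray(arms)
    outcomes = np.asarray(outcomes, dtype=int)
    table = np.zeros((2, n_levels))
    is_a = (arms == "A") | (arms == 1)
    for g, mask in enumerate((~is_a, is_a)):
        if mask.any():
            table[g] = np.bincount(outcomes[mask], minlength=n_levels)
    return table


def _po_nll_grad(params: np.ndarray, table: np.ndarray):
    """Negative log-likelihood and gradient of the two-group PO model.

    params = (a_0, ..., a_{K-2}, beta) with cutpoints theta_0 = a_0,
    theta_j = theta_{j-1} + exp(a_j); P(Y <= j | g) = expit(theta_j - beta*g).
    """
    k = table.shape[1]
    a = params[:-1]
    beta = params[-1]
    theta = np.empty(k - 1)
    theta[0] = a[0]
    for j in range(1, k - 1):
        theta[j] = theta[j - 1] + math.exp(a[j])

    nll = 0.0
    grad_theta = np.zeros(k - 1)
    grad_beta = 0.0
    for g in (0, 1):
        eta = theta - beta * g
        cdf = special.expit(eta)
        pdf = cdf * (1.0 - cdf)
        cum = np.concatenate(([0.0], cdf, [1.0]))
        dens = np.concatenate(([0.0], pdf, [0.0]))
        p = np.diff(cum)
        p = np.clip(p, 1e-300, None)
        n = table[g]
        nll -= float((n * np.log(p)).sum())
        w = n / p
        # d p_j / d theta_j = pdf_j ; d p_{j+1} / d theta_j = -pdf_j
        contrib = dens[1:k] * (w[: k - 1] - w[1:k])
        grad_theta -= contrib
        grad_beta += g * float(contrib.sum())
    # chain rule to the increment parametrization
    grad_a = np.empty(k - 1)
    csum = np.cumsum(grad_theta[::-1])[::-1]
    grad_a[0] = csum[0]
    for j in range(1, k - 1):
        grad_a[j] = csum[j] * math.exp(params[j])
    return nll, np.concatenate([grad_a, [grad_beta]])


def proportional_odds_test(table: np.ndarray) -> TestResult:
    """Wald test of the arm effect in a proportional-odds model on a 2×K table.

    Empty outcome levels are dropped before fitting.  Returns a
    non-converged result when fewer than two levels remain, one arm is
    empty, or the optimizer fails.
    """
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    k = t.shape[1]
    failed = TestResult(math.nan, math.nan, math.nan, False)
    if k < 2 or t[0].sum() == 0 or t[1].sum() == 0:
        return failed
    # one arm concentrated in a single extreme level => separation risk is
    # handled by the optimizer result check below
    pooled = t.sum(axis=0)
    cum = np.clip(np.cumsum(pooled)[:-1] / pooled.sum(), 1e-4, 1 - 1e-4)
    theta0 = np.log(cum / (1 - cum))
    a0 = np.empty(k - 1)
    a0[0] = theta0[0]
    incr = np.clip(np.diff(theta0), 1e-6, None)
    a0[1:] = np.log(incr)
    x0 = np.concatenate([a0, [0.0]])

    res = optimize.minimize(_po_nll_grad, x0, args=(t,), jac=True, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 200})
    if not np.all(np.isfinite(res.x)):
        return failed
    # observed information via central differences of the analytic gradient
    p = res.x
    h = 1e-5
    m = p.size
    hess = np.empty((m, m))
    for i in range(m):
        pp = p.copy()
        pp[i] += h
        _, gp = _po_nll_grad(pp, t)
        pp[i] -= 2 * h
        _, gm = _po_nll_grad(pp, t)
        hess[i] = (gp - gm) / (2 * h)
    hess = (hess + hess.T) / 2
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return failed
    var_b = cov[-1, -1]
    if not (var_b > 0) or not np.isfinite(var_b):
        return failed
    beta = float(p[-1])
    se = math.sqrt(var_b)
    if abs(beta) > 30 or se > 100:  # effectively separated
        return failed
    pval = 2.0 * sps.norm.sf(abs(beta) / se)
    return TestResult(beta, se, pval, bool(np.linalg.norm(res.jac) < 1e-3 or res.success))


def cutpoint_logistic_test(table: np.ndarray, cut: int) -> TestResult:
    """Wald test of the arm log-odds-ratio for the dichotomy Y <= cut vs Y > cut.

    Equivalent to binary logistic regression of the indicator on the arm;
    a zero cell marks the fit non-convergent (separation) and the result
    is flagged for exclusion.
    """
    t = np.asarray(table, dtype=float)
    lo = t[:, : cut + 1].sum(axis=1)
    hi = t[:, cut + 1:].sum(axis=1)
    a, b = hi[1], lo[1]  # treatment arm: above / at-or-below the cut
    c, d = hi[0], lo[0]
    if min(a, b, c, d) <= 0:
        return TestResult(math.nan, math.nan, math.nan, False)
    beta = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return TestResult(beta, se, 2.0 * sps.norm.sf(abs(beta) / se), True)
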