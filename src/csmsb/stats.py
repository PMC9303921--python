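"""Common-scale imbalance statistics for two-arm trials.

The common scale is the Wilcoxon–Mann–Whitney (WMW) odds: the odds that a
randomly chosen arm-A patient has a higher value than a randomly chosen
arm-B patient, with tied pairs split evenly between numerator and
denominator.  It is the tie-aware descendant of Agresti's generalized odds
ratio, is defined for numeric, ordinal and (dummy-coded) categorical data
alike, and is approximately log-normal — which is what lets per-covariate
imbalances be pooled by inverse-variance weighting downstream.

This module also provides the conventional per-covariate balance tests
(Student's t, Pearson's chi-square with a Fisher fallback, Cohen's d) that
the classic minimal-sufficient-balance randomizer votes with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairwiseCounts",
    "WmwEstimate",
    "ImbalanceTest",
    "pairwise_counts",
    "wmw_odds",
    "wmw_log_odds_from_u",
    "dummy_code",
    "conventional_imbalance",
    "cohens_d",
]

@dataclass(frozen=True)
class PairwiseCounts:
    """Cross-arm pair comparison counts.

    ``wins + ties + losses == n_a * n_b`` always holds.
    """

    wins: int
    ties: int
    losses: int
    n_a: int
    n_b: int

    @property
    def n_pairs(self) -> int:
        return self.n_a * self.n_b


@dataclass(frozen=True)
class WmwEstimate:
    """WMW odds for one covariate, with its log-scale standard error.

    ``wmwor == exp(log_wmwor)``.  ``separable`` flags a perfectly separated
    comparison where a Haldane-style continuity correction (0.5 added to
    both half-counts) was applied to keep the log odds finite.
    ``degenerate`` flags a comparison carrying no information (all values
    tied across both arms); its standard error is NaN and callers should
    treat the covariate as abstaining.
    """

    wmwor: float
    log_wmwor: float
    se_log: float
    n_a: int
    n_b: int
    separable: bool = False
    degenerate: bool = False

    @property
    def z(self) -> float:
        return self.log_wmwor / self.se_log

    @property
    def p_value(self) -> float:
        """Two-sided normal p-value for log WMWOR = 0."""
        if self.degenerate:
            return 1.0
        return 2.0 * sps.norm.sf(abs(self.z))


@dataclass(frozen=True)
class ImbalanceTest:
    """One conventional balance test: statistic, p-value, optional effect size."""

    test: str
    statistic: float
    p_value: float
    effect_size: float | None = None


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"group '{name}' is empty")
    return arr


def pairwise_counts(treatment_values, control_values) -> PairwiseCounts:
    """Count (treatment, control) pairs where treatment is higher / tied / lower.

    Exhaustive over all ``n_a × n_b`` cross-arm pairs, computed in
    O(n log n) by binary search on the sorted control values.
    """
    x = _as_array(treatment_values, "treatment")
    y = _as_array(control_values, "control")
    sy = np.sort(y)
    lt = np.searchsorted(sy, x, side="left")  # controls strictly below each x
    le = np.searchsorted(sy, x, side="right")
    wins = int(lt.sum())
    ties = int((le - lt).sum())
    losses = x.size * y.size - wins - ties
    return PairwiseCounts(wins, ties, losses, x.size, y.size)


def wmw_log_odds_from_u(u: float, n_a: int, n_b: int) -> tuple[float, bool]:
    """log WMW odds from the tie-corrected win count ``u = wins + ties/2``.

    Returns ``(log_wmwor, separable)``; a 0.5 continuity increment is added
    to both half-counts when one of them is exactly zero so the log stays
    finite early in a trial.
    """
    n = n_a * n_b
    if u <= 0.0 or u >= n:
        return math.log((u + 0.5) / (n - u + 0.5)), True
    return math.log(u / (n - u)), False


def _delong_variance(x: np.ndarray, y: np.ndarray) -> float:
    """Consistent variance of the tie-corrected win probability p = U/(na·nb).

    DeLong-style structural components: V10_i = mean_j S(x_i, y_j),
    V01_j = mean_i S(x_i, y_j), with S scoring 1 / 0.5 / 0.
    """
    na, nb = x.size, y.size
    sy = np.sort(y)
    v10 = (np.searchsorted(sy, x, "left") + 0.5 * (np.searchsorted(sy, x, "right") - np.searchsorted(sy, x, "left"))) / nb
    sx = np.sort(x)
    gt = x.size - np.searchsorted(sx, y, "right")  # x strictly above each y
    eq = np.searchsorted(sx, y, "right") - np.searchsorted(sx, y, "left")
    v01 = (gt + 0.5 * eq) / na
    s10 = v10.var(ddof=1) if na > 1 else 0.0
    s01 = v01.var(ddof=1) if nb > 1 else 0.0
    return s10 / na + s01 / nb


def _null_variance(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected null variance of p = U/(na·nb)."""
    na, nb = x.size, y.size
    n = na + nb
    if n < 2:
        return 0.0
    comb = np.sort(np.concatenate([x, y]))
    _, counts = np.unique(comb, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var_u = na * nb / 12.0 * ((n + 1) - tie_term)
    return var_u / (na * nb) ** 2


def wmw_odds(treatment_values, control_values) -> WmwEstimate:
    """WMW odds of one covariate between the two arms.

    The point estimate is ``(wins + ties/2) / (losses + ties/2)``.  The
    log-scale standard error is the delta-method transform of the
    consistent (DeLong) variance of the win probability; when that variance
    is exactly zero (perfect separation, or a constant arm) the
    tie-corrected null variance is used instead, and when even that is zero
    (every value in both arms identical) the estimate is flagged degenerate.
    """
    x = _as_array(treatment_values, "treatment")
    y = _as_array(control_values, "control")
    pc = pairwise_counts(x, y)
    u = pc.wins + pc.ties / 2.0
    n = pc.n_pairs
    log_w, separable = wmw_log_odds_from_u(u, pc.n_a, pc.n_b)
    p = (u + 0.5) / (n + 1.0) if separable else u / n

    var_p = _delong_variance(x, y)
    if var_p <= 0.0:
        var_p = _null_variance(x, y)
    if var_p <= 0.0:
        return WmwEstimate(1.0, 0.0, float("nan"), pc.n_a, pc.n_b, separable=False, degenerate=True)
    se_log = math.sqrt(var_p) / (p * (1.0 - p))
    return WmwEstimate(math.exp(log_w), log_w, se_log, pc.n_a, pc.n_b, separable=separable)


def dummy_code(values, target_category) -> np.ndarray:
    """0/1 indicator of ``target_category`` (length-preserving).

    The WMW odds of a nominal covariate is evaluated on one such dummy at a
    time; the randomizer uses the incoming patient's own category, so
    imbalance on categories the patient cannot affect is ignored.
    """
    arr = np.asarray(values, dtype=object)
    return (arr == target_category).astype(int)


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled standard deviation; 0 when both arms are constant."""
    a = _as_array(a, "a")
    b = _as_array(b, "b")
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    denom_df = na + nb - 2
    if denom_df <= 0:
        return 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / denom_df
    if sp2 <= 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


def _contingency(a_vals, b_vals, categories=None) -> np.ndarray:
    cats = list(categories) if categories is not None else sorted(set(a_vals) | set(b_vals), key=str)
    a = np.asarray(a_vals, dtype=object)
    b = np.asarray(b_vals, dtype=object)
    return np.array([[int((a == c).sum()), int((b == c).sum())] for c in cats], dtype=float)


def chi2_from_table(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) on an r×2 table.

    Rows with zero total are dropped. Returns (statistic, p, df).
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0]
    col = t.sum(axis=0)
    if t.shape[0] < 2 or (col > 0).sum() < 2:
        return 0.0, 1.0, 0
    expected = np.outer(t.sum(axis=1), col) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * 1
    return stat, float(sps.chi2.sf(stat, df)), df


def conventional_imbalance(treatment_values, control_values, kind: str,
                           categories=None) -> ImbalanceTest:
    """Conventional balance test for one covariate, chosen by its kind.

    numeric  -> two-sample (pooled-variance) t-test p-value plus Cohen's d
    binary / nominal -> Pearson chi-square; Fisher's exact test replaces it
        on 2×2 tables with any expected cell below 5
    ordinal  -> WMW-odds z-test p-value (its |log WMWOR| as effect size)
    """
    if kind == "numeric":
        a = _as_array(treatment_values, "treatment")
        b = _as_array(control_values, "control")
        d = cohens_d(a, b)
        va = a.var(ddof=1) if a.size > 1 else 0.0
        vb = b.var(ddof=1) if b.size > 1 else 0.0
        if va == 0.0 and vb == 0.0:
            # no within-arm variance: the t statistic is undefined; report balance
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
        return ImbalanceTest("t", float(stat), float(p), effect_size=d)
    if kind == "ordinal":
        est = wmw_odds(treatment_values, control_values)
        if est.degenerate:
            return ImbalanceTest("wmw", 0.0, 1.0, effect_size=0.0)
        return ImbalanceTest("wmw", est.z, est.p_value, effect_size=abs(est.log_wmwor))
    if kind in ("binary", "nominal"):
        table = _contingency(treatment_values, control_values, categories)
        stat, p, df = chi2_from_table(table)
        nz = table[table.sum(axis=1) > 0]
        if nz.shape[0] == 2 and nz.sum() > 0:
            expected = np.outer(nz.sum(axis=1), nz.sum(axis=0)) / nz.sum()
            if (expected < 5).any():
                _, p = sps.fisher_exact(nz)
                return ImbalanceTest("fisher", stat, float(p), effect_size=None)
        return ImbalanceTest("chi2", stat, p, effect_size=None)
    raise ValueError(f"unknown covariate kind: {kind!r}")
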