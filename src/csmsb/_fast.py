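"""Compiled sequential engine for replicated trial simulation.

This mirrors the reference path (`randomizers.decide_allocation` inside
`engine.run_trial`) record for record — a dedicated test asserts equality
on seeded streams — but runs the whole patient loop inside one numba
kernel so that evaluation experiments can afford tens of thousands of
replicate trials.

Encoding: every covariate is a float64 row of the ``vals`` matrix —
numeric values as-is, ordinal/binary as level indices, nominal as category
codes (the kernel re-dummies them per decision on the incoming patient's
own category), NaN for missing.  Significance thresholds are precomputed
(t and chi-square critical values per degree of freedom, the normal
z-threshold for WMW and pooled tests) so the kernel never needs scipy.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps

from .randomizers import RandomizerConfig

__all__ = ["encode_stream", "prepare", "simulate_trial", "FastTrial"]

_METHOD = {"pure": 0, "msb": 1, "csmsb": 2}
_VOTING = {"majority": 0, "weighted": 1, "pooled": 2}
_KIND = {"numeric": 0, "ordinal": 1, "binary": 2, "nominal": 3}


# ---------------------------------------------------------------------------
# kernels


@njit(cache=True)
def _close(a, b):
    return abs(a - b) <= 1e-12 * max(abs(a), abs(b)) + 1e-15


@njit(cache=True)
def _abs_log_u(u, n):
    # |log WMW odds| from the tie-corrected win count over n pairs
    if u <= 0.0 or u >= n:
        return abs(math.log((u + 0.5) / (n - u + 0.5)))
    return abs(math.log(u / (n - u)))


@njit(cache=True)
def _wmw_core(sa, sb):
    """u, signed log WMWOR, SE(log) and a degeneracy flag from sorted arms."""
    na, nb = sa.size, sb.size
    npairs = na * nb
    u = 0.0
    v10 = np.empty(na)
    for i in range(na):
        lt = np.searchsorted(sb, sa[i], side="left")
        rt = np.searchsorted(sb, sa[i], side="right")
        s = lt + 0.5 * (rt - lt)
        u += s
        v10[i] = s / nb
    v01 = np.empty(nb)
    for j in range(nb):
        lt = np.searchsorted(sa, sb[j], side="left")
        rt = np.searchsorted(sa, sb[j], side="right")
        v01[j] = ((na - rt) + 0.5 * (rt - lt)) / na
    s10 = _var1(v10)
    s01 = _var1(v01)
    var_p = s10 / na + s01 / nb

    if u <= 0.0 or u >= npairs:
        logw = math.log((u + 0.5) / (npairs - u + 0.5))
        p = (u + 0.5) / (npairs + 1.0)
    else:
        logw = math.log(u / (npairs - u))
        p = u / npairs

    if var_p <= 0.0:
        var_p = _null_var(sa, sb)
    if var_p <= 0.0:
        return u, 0.0, np.nan, True
    se = math.sqrt(var_p) / (p * (1.0 - p))
    return u, logw, se, False


@njit(cache=True)
def _var1(x):
    n = x.size
    if n < 2:
        return 0.0
    m = 0.0
    for i in range(n):
        m += x[i]
    m /= n
    s = 0.0
    for i in range(n):
        d = x[i] - m
        s += d * d
    return s / (n - 1)


@njit(cache=True)
def _null_var(sa, sb):
    # tie-corrected null variance of p over the merged sorted sample
    na, nb = sa.size, sb.size
    n = na + nb
    if n < 2:
        return 0.0
    tie = 0.0
    i = 0
    j = 0
    while i < na or j < nb:
        if j >= nb or (i < na and sa[i] <= sb[j]):
            v = sa[i]
        else:
            v = sb[j]
        c = 0
        while i < na and sa[i] == v:
            i += 1
            c += 1
        while j < nb and sb[j] == v:
            j += 1
            c += 1
        tie += c**3 - c
    var_u = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    return var_u / (na * nb) ** 2


@njit(cache=True)
def _add_counts(sorted_arr, v):
    lt = np.searchsorted(sorted_arr, v, side="left")
    rt = np.searchsorted(sorted_arr, v, side="right")
    return lt + 0.5 * (rt - lt), (sorted_arr.size - rt) + 0.5 * (rt - lt)


@njit(cache=True)
def _t_stat(a, b):
    na, nb = a.size, b.size
    if na + nb <= 2:
        return 0.0
    va = _var1(a)
    vb = _var1(b)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 <= 0.0:
        return 0.0
    ma = 0.0
    for i in range(na):
        ma += a[i]
    mb = 0.0
    for j in range(nb):
        mb += b[j]
    return (ma / na - mb / nb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))


@njit(cache=True)
def _chi2_stat(table):
    """Pearson chi-square on a K×2 count table, zero rows dropped.

    Returns (stat, df); df = 0 marks an untestable table (stat forced 0)."""
    K = table.shape[0]
    rows = 0
    tot = 0.0
    c0 = 0.0
    c1 = 0.0
    for k in range(K):
        r = table[k, 0] + table[k, 1]
        if r > 0:
            rows += 1
        tot += r
        c0 += table[k, 0]
        c1 += table[k, 1]
    if rows < 2 or c0 <= 0 or c1 <= 0:
        return 0.0, 0
    stat = 0.0
    for k in range(K):
        r = table[k, 0] + table[k, 1]
        if r <= 0:
            continue
        e0 = r * c0 / tot
        e1 = r * c1 / tot
        stat += (table[k, 0] - e0) ** 2 / e0 + (table[k, 1] - e1) ** 2 / e1
    return stat, rows - 1


@njit(cache=True)
def _fisher_needed(table):
    """True when the nonzero-row table is 2×2 with any expected count < 5."""
    K = table.shape[0]
    rows = 0
    r0 = r1 = -1
    for k in range(K):
        if table[k, 0] + table[k, 1] > 0:
            rows += 1
            if r0 < 0:
                r0 = k
            else:
                r1 = k
    if rows != 2:
        return False, r0, r1
    tot = table[r0, 0] + table[r0, 1] + table[r1, 0] + table[r1, 1]
    c0 = table[r0, 0] + table[r1, 0]
    c1 = table[r0, 1] + table[r1, 1]
    for k in (r0, r1):
        r = table[k, 0] + table[k, 1]
        if r * c0 / tot < 5.0 or r * c1 / tot < 5.0:
            return True, r0, r1
    return False, r0, r1


@njit(cache=True)
def _log_hyper(k, r1, r2, c1):
    # log pmf of the hypergeometric count k in cell (row1, col1)
    return (
        math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1) - math.lgamma(r2 - (c1 - k) + 1)
        - (math.lgamma(r1 + r2 + 1) - math.lgamma(c1 + 1) - math.lgamma(r1 + r2 - c1 + 1))
    )


@njit(cache=True)
def _fisher_p(a, b, c, d):
    """Two-sided Fisher exact p for [[a, b], [c, d]] (sum of no-more-likely tables)."""
    r1 = a + b
    r2 = c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    lp_obs = _log_hyper(a, r1, r2, c1)
    p = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hyper(k, r1, r2, c1)
        if lp <= lp_obs + 1e-7:
            p += math.exp(lp)
    return min(p, 1.0)


@njit(cache=True)
def simulate_trial(vals, kinds, ncats, weights, method, voting, coin_mode, xi,
                   slope, z_alpha, t_crit, chi2_crit, u_alloc):
    """Run one full sequential trial; returns (prob_A, arm, intervened, bd, se_bd).

    ``arm`` is 1 for A, 0 for B.  ``bd``/``se_bd`` are NaN outside pooled mode.
    """
    ncov, N = vals.shape
    prob = np.empty(N)
    arm = np.empty(N, np.int8)
    interv = np.zeros(N, np.bool_)
    bd_out = np.full(N, np.nan)
    se_out = np.full(N, np.nan)
    xa_buf = np.empty(N)
    xb_buf = np.empty(N)

    adaptive = method != 0 and np.isfinite(z_alpha)
    for t in range(N):
        p = 0.5
        intervened = False
        if adaptive and voting == 2:
            bd_out[t] = 0.0  # pooled evidence defaults to BD = 0, no contributors
        if adaptive and t >= 4:
            # vote accumulators
            tally_a = 0
            tally_b = 0
            mag_a = 0.0
            mag_b = 0.0
            num = 0.0
            den = 0.0
            den2 = 0.0
            n_contrib = 0
            for i in range(ncov):
                v = vals[i, t]
                if math.isnan(v):
                    continue
                na = 0
                nb = 0
                nominal = kinds[i] == 3
                for j in range(t):
                    w = vals[i, j]
                    if math.isnan(w):
                        continue
                    x = (1.0 if w == v else 0.0) if nominal else w
                    if arm[j] == 1:
                        xa_buf[na] = x
                        na += 1
                    else:
                        xb_buf[nb] = x
                        nb += 1
                if na < 2 or nb < 2:
                    continue
                se = np.nan
                logw = 0.0
                if method == 2 or kinds[i] == 1:
                    # common-scale vote (also ordinal under classic MSB)
                    sa = np.sort(xa_buf[:na])
                    sb = np.sort(xb_buf[:nb])
                    vv = 1.0 if nominal else v
                    u, logw, se, degen = _wmw_core(sa, sb)
                    if degen:
                        continue
                    add_a, _ga = _add_counts(sb, vv)
                    _lb, add_b = _add_counts(sa, vv)
                    prosp_a = _abs_log_u(u + add_a, (na + 1) * nb)
                    prosp_b = _abs_log_u(u + add_b, na * (nb + 1))
                    if _close(prosp_a, prosp_b):
                        direction = 0
                    elif prosp_a < prosp_b:
                        direction = 1
                    else:
                        direction = 2
                    significant = abs(logw) / se > z_alpha
                else:
                    direction, significant = _conventional_vote(
                        vals, arm, kinds[i], int(ncats[i]), i, t, v,
                        xa_buf, xb_buf, t_crit, chi2_crit)

                if voting == 2:
                    inv = 1.0 / (se * se)
                    sgn = 0.0
                    if direction == 1:
                        sgn = -1.0
                    elif direction == 2:
                        sgn = 1.0
                    num += weights[i] * sgn * abs(logw) * inv
                    den += weights[i] * inv
                    den2 += weights[i] * weights[i] * inv
                    n_contrib += 1
                elif significant and direction != 0:
                    wmag = weights[i] * abs(logw)
                    if direction == 1:
                        tally_a += 1
                        mag_a += wmag
                    else:
                        tally_b += 1
                        mag_b += wmag

            if voting == 2:
                if n_contrib > 0 and den > 0.0:
                    bd = num / den
                    se_bd = math.sqrt(den2) / den
                    bd_out[t] = bd
                    se_out[t] = se_bd
                    if bd != 0.0 and abs(bd) / se_bd > z_alpha:
                        intervened = True
                        p_fav = xi if coin_mode == 0 else min(0.5 + slope * abs(bd), 1.0)
                        p = p_fav if bd < 0.0 else 1.0 - p_fav
            elif voting == 0:
                if tally_a != tally_b:
                    intervened = True
                    fav_a = tally_a > tally_b
                    x = mag_a if fav_a else mag_b
                    p_fav = xi if coin_mode == 0 else min(0.5 + slope * x, 1.0)
                    p = p_fav if fav_a else 1.0 - p_fav
            else:
                if not _close(mag_a, mag_b):
                    intervened = True
                    fav_a = mag_a > mag_b
                    p_fav = xi if coin_mode == 0 else min(0.5 + slope * abs(mag_a - mag_b), 1.0)
                    p = p_fav if fav_a else 1.0 - p_fav

        prob[t] = p
        interv[t] = intervened
        arm[t] = 1 if u_alloc[t] < p else 0
    return prob, arm, interv, bd_out, se_out


@njit(cache=True)
def _conventional_vote(vals, arm, kind, K, i, t, v, xa_buf, xb_buf, t_crit, chi2_crit):
    """Classic-MSB vote: conventional significance, direction from the arm
    whose hypothetical assignment most reduces the test statistic."""
    if kind == 0:  # numeric: Student's t
        na = 0
        nb = 0
        for j in range(t):
            w = vals[i, j]
            if math.isnan(w):
                continue
            if arm[j] == 1:
                xa_buf[na] = w
                na += 1
            else:
                xb_buf[nb] = w
                nb += 1
        a = xa_buf[:na]
        b = xb_buf[:nb]
        tstat = abs(_t_stat(a, b))
        df = na + nb - 2
        significant = tstat > t_crit[df]
        aa = np.empty(na + 1)
        aa[:na] = a
        aa[na] = v
        bb = np.empty(nb + 1)
        bb[:nb] = b
        bb[nb] = v
        m_a = abs(_t_stat(aa, b))
        m_b = abs(_t_stat(a, bb))
    else:  # binary / nominal: chi-square with 2x2 Fisher fallback
        table = np.zeros((K, 2))
        for j in range(t):
            w = vals[i, j]
            if math.isnan(w):
                continue
            table[int(w), 0 if arm[j] == 1 else 1] += 1.0
        stat, df = _chi2_stat(table)
        fisher, r0, r1 = _fisher_needed(table)
        vc = int(v)
        if fisher:
            p_obs = _fisher_p(int(table[r0, 0]), int(table[r0, 1]),
                              int(table[r1, 0]), int(table[r1, 1]))
            # strict margin: Fisher p can equal alpha exactly on small tables
            significant = df > 0 and p_obs < _alpha_from(t_crit) * (1 - 1e-9)
            table[vc, 0] += 1.0
            m_a = -_fisher_2x2_from(table, r0, r1, vc)
            table[vc, 0] -= 1.0
            table[vc, 1] += 1.0
            m_b = -_fisher_2x2_from(table, r0, r1, vc)
            table[vc, 1] -= 1.0
        else:
            significant = df > 0 and stat > chi2_crit[df]
            table[vc, 0] += 1.0
            m_a, _ = _chi2_stat(table)
            table[vc, 0] -= 1.0
            table[vc, 1] += 1.0
            m_b, _ = _chi2_stat(table)
            table[vc, 1] -= 1.0
    if _close(m_a, m_b):
        return 0, significant
    return (1 if m_a < m_b else 2), significant


@njit(cache=True)
def _alpha_from(t_crit):
    # alpha is stashed in t_crit[0] (df=0 slot is otherwise unused)
    return t_crit[0]


@njit(cache=True)
def _fisher_2x2_from(table, r0, r1, vc):
    # the incoming category may revive a zero row; recollect nonzero rows
    K = table.shape[0]
    a = b = c = d = 0.0
    rows = 0
    for k in range(K):
        if table[k, 0] + table[k, 1] > 0:
            rows += 1
            if rows == 1:
                a = table[k, 0]
                b = table[k, 1]
            elif rows == 2:
                c = table[k, 0]
                d = table[k, 1]
    if rows != 2:
        return 1.0
    return _fisher_p(int(a), int(b), int(c), int(d))


# ---------------------------------------------------------------------------
# python-side preparation


def encode_stream(stream, covariates) -> np.ndarray:
    """Encode a patient stream into the (n_cov, N) float matrix the kernel uses."""
    if isinstance(stream, pd.DataFrame):
        patients = stream.to_dict("records")
    else:
        patients = [dict(p) for p in stream]
    N = len(patients)
    vals = np.full((len(covariates), N), np.nan)
    for i, cov in enumerate(covariates):
        for j, p in enumerate(patients):
            v = p.get(cov.name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if cov.kind == "nominal":
                vals[i, j] = float(cov.categories.index(v))
            else:
                vals[i, j] = float(cov.encode(v))
    return vals


class FastTrial:
    """Pre-encoded trial problem: call with a uniform draw array (or seed).

    Encoding the stream and the significance thresholds once lets thousands
    of replicate trials share the setup cost.
    """

    def __init__(self, stream, config: RandomizerConfig):
        self.config = config
        covs = config.covariates
        self.vals = encode_stream(stream, covs)
        self.n = self.vals.shape[1]
        self.kinds = np.array([_KIND[c.kind] for c in covs], dtype=np.int64)
        self.ncats = np.array([len(c.categories) if c.categories else 0 for c in covs],
                              dtype=np.int64)
        self.weights = np.array([c.weight for c in covs], dtype=float)
        self.method = _METHOD[config.method]
        self.voting = _VOTING[config.voting]
        self.coin_mode = 0 if config.coin.mode == "static" else 1
        alpha = config.alpha
        self.z_alpha = math.inf if alpha == 0 else float(sps.norm.ppf(1 - alpha / 2))
        dfs = np.arange(1, self.n + 1)
        t_crit = np.full(self.n + 1, np.inf)
        if alpha > 0:
            t_crit[1:] = sps.t.ppf(1 - alpha / 2, dfs)
        t_crit[0] = alpha  # stashed for the Fisher-fallback significance test
        self.t_crit = t_crit
        max_df = max(int(self.ncats.max(initial=0)), 2)
        chi2_crit = np.full(max_df + 1, np.inf)
        if alpha > 0:
            chi2_crit[1:] = sps.chi2.ppf(1 - alpha, np.arange(1, max_df + 1))
        self.chi2_crit = chi2_crit

    def run(self, uniforms=None, seed=None):
        if uniforms is None:
            uniforms = np.random.default_rng(seed).random(self.n)
        return simulate_trial(self.vals, self.kinds, self.ncats, self.weights,
                              self.method, self.voting, self.coin_mode,
                              self.config.coin.xi, self.config.coin.slope,
                              self.z_alpha, self.t_crit, self.chi2_crit, uniforms)
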