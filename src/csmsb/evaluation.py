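"""Simulation experiments comparing randomizers on synthetic populations.

The experiments mirror the standard evaluation design for adaptive
randomization methods:

* calibration — the map from the intervention threshold α to the achieved
  intervention-rate (IR) distribution is nonlinear and population
  dependent, so α is chosen by simulation to hit a target IR percentile;
* trade-off — matched percentiles of IR against end-of-trial covariate
  imbalance (|log WMW odds|) across an (α, ξ) grid;
* power / Type-I error — replicated trials whose outcomes are drawn from
  per-patient counterfactual vectors, analyzed by ordinal logistic
  regression and by binary logistic regression at each mRS cutpoint;
* agreement — Lin's concordance correlation coefficient and reduced major
  axis regression between two methods' power/Type-I vectors.

All replicate loops run on the compiled engine; paired comparisons between
methods reuse the same per-replicate uniforms (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as cs
from ._fast import FastTrial
from .ordinal import cutpoint_logistic_test, outcome_table, proportional_odds_test
from .randomizers import RandomizerConfig
from .synthetic import TrialFixture, sample_outcomes

__all__ = [
    "simulate_interventions",
    "calibration_curve",
    "calibrate_alpha",
    "CalibrationResult",
    "tradeoff_curve",
    "PowerResult",
    "empirical_power",
    "matched_power_vectors",
    "AgreementStats",
    "agreement_stats",
]

OUTCOME_TESTS = ("ordinal", "cut0", "cut1", "cut2", "cut3", "cut4", "cut5")

DEFAULT_ALPHA_GRID = tuple(np.geomspace(1e-4, 0.99, 17))


def simulate_interventions(stream, config: RandomizerConfig, n_reps: int, seed=None,
                           return_arms: bool = False):
    """Replicate trials; returns intervention rates (and optionally arms/EB)."""
    ft = FastTrial(stream, config)
    rng = np.random.default_rng(seed)
    irs = np.empty(n_reps)
    ebs = np.empty(n_reps)
    arms = np.empty((n_reps, ft.n), dtype=np.int8) if return_arms else None
    for r in range(n_reps):
        u = rng.random(ft.n)
        prob, arm, interv, _, _ = ft.run(uniforms=u)
        irs[r] = interv.mean()
        ebs[r] = np.abs(prob - 0.5).mean()
        if return_arms:
            arms[r] = arm
    if return_arms:
        return irs, ebs, arms
    return irs, ebs


def calibration_curve(stream, config: RandomizerConfig, alpha_grid=DEFAULT_ALPHA_GRID,
                      n_reps: int = 200, seed=None,
                      percentiles=(25, 50, 75)) -> pd.DataFrame:
    """IR percentiles as a function of α for a fixed method/coin/population."""
    rows = []
    for i, alpha in enumerate(alpha_grid):
        irs, _ = simulate_interventions(stream, config.with_alpha(float(alpha)),
                                        n_reps, seed=None if seed is None else seed + i)
        row = {"alpha": float(alpha), "n_reps": n_reps}
        for p in percentiles:
            row[f"ir_p{p}"] = float(np.percentile(irs, p))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df


@dataclass(frozen=True)
class CalibrationResult:
    alpha: float
    achieved_ir: float
    target_ir: float
    percentile: int
    curve: pd.DataFrame = field(repr=False)

    @property
    def attained(self) -> bool:
        return abs(self.achieved_ir - self.target_ir) <= 0.05


def calibrate_alpha(stream, config: RandomizerConfig, target_ir: float,
                    percentile: int = 50, alpha_grid=DEFAULT_ALPHA_GRID,
                    n_reps: int = 200, seed=None, refine: int = 1) -> CalibrationResult:
    """Choose the α whose simulated IR percentile is closest to the target.

    A coarse log grid is optionally refined once around the best point.
    When the target is unattainable (IR ceiling below it) the best
    achievable α is returned; ``attained`` flags the miss.
    """
    if not (0.0 <= target_ir < 1.0):
        raise ValueError("target_ir must lie in [0, 1)")
    if target_ir == 0.0:
        curve = pd.DataFrame({"alpha": [0.0], f"ir_p{percentile}": [0.0], "n_reps": [0]})
        return CalibrationResult(0.0, 0.0, 0.0, percentile, curve)
    col = f"ir_p{percentile}"
    curve = calibration_curve(stream, config, alpha_grid, n_reps, seed,
                              percentiles=(percentile,))
    for _ in range(refine):
        i = int((curve[col] - target_ir).abs().idxmin())
        lo = curve["alpha"].iloc[max(i - 1, 0)]
        hi = curve["alpha"].iloc[min(i + 1, len(curve) - 1)]
        if hi <= lo:
            break
        fine = np.geomspace(lo, hi, 7)[1:-1]
        extra = calibration_curve(stream, config, fine, n_reps,
                                  None if seed is None else seed + 1000,
                                  percentiles=(percentile,))
        curve = pd.concat([curve, extra], ignore_index=True).sort_values("alpha",
                                                                         ignore_index=True)
    i = int((curve[col] - target_ir).abs().idxmin())
    return CalibrationResult(float(curve["alpha"].iloc[i]), float(curve[col].iloc[i]),
                             target_ir, percentile, curve)


def _dummy_columns(covariates):
    """(label, covariate, category) rows for per-covariate imbalance reporting."""
    out = []
    for cov in covariates:
        if cov.kind == "nominal":
            for c in cov.categories:
                out.append((f"{cov.name}={c}", cov, c))
        else:
            out.append((cov.name, cov, None))
    return out


def _final_abs_log_wmw(ft: FastTrial, arms: np.ndarray, columns) -> dict:
    out = {}
    for j, (label, cov, cat) in enumerate(columns):
        i = [c.name for c in ft.config.covariates].index(cov.name)
        v = ft.vals[i]
        ok = ~np.isnan(v)
        if cat is not None:
            code = float(cov.categories.index(cat))
            x = (v[ok] == code).astype(float)
        else:
            x = v[ok]
        a = x[arms[ok] == 1]
        b = x[arms[ok] == 0]
        if a.size == 0 or b.size == 0:
            out[label] = math.nan
            continue
        est = cs.wmw_odds(a, b)
        out[label] = 0.0 if est.degenerate else abs(est.log_wmwor)
    return out


def tradeoff_curve(stream, configs: dict, alpha_grid, n_reps: int = 200, seed=0,
                   percentiles=(25, 50, 75)) -> pd.DataFrame:
    """Matched percentiles of IR and end-of-trial imbalance per covariate.

    ``configs`` maps a label to a (method/voting/coin) configuration whose
    α is swept over the grid.  Matched percentiles give the worst-case
    reading of the trade-off: the q-th percentile imbalance is paired with
    the q-th percentile intervention rate.
    """
    rows = []
    for label, config in configs.items():
        columns = _dummy_columns(config.covariates)
        for alpha in alpha_grid:
            cfg = config.with_alpha(float(alpha))
            ft = FastTrial(stream, cfg)
            irs, ebs, arms = simulate_interventions(stream, cfg, n_reps, seed,
                                                    return_arms=True)
            imb = {lab: np.empty(n_reps) for lab, _, _ in columns}
            for r in range(n_reps):
                vals = _final_abs_log_wmw(ft, arms[r], columns)
                for lab, v in vals.items():
                    imb[lab][r] = v
            for p in percentiles:
                row = {"config": label, "alpha": float(alpha), "percentile": p,
                       "ir": float(np.percentile(irs, p)),
                       "eb": float(np.percentile(ebs, p)), "n_reps": n_reps}
                for lab, v in imb.items():
                    row[f"imb[{lab}]"] = float(np.nanpercentile(v, p))
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PowerResult:
    """Proportion of significant arm effects per outcome test."""

    scenario: str
    level: float
    n_reps: int
    significant: dict  # test -> count significant
    used: dict  # test -> count of converged replicates
    excluded: dict  # test -> count excluded (non-convergent fits)

    def proportion(self, test: str) -> float:
        n = self.used[test]
        return self.significant[test] / n if n else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"test": list(OUTCOME_TESTS),
             "proportion": [self.proportion(t) for t in OUTCOME_TESTS],
             "n_used": [self.used[t] for t in OUTCOME_TESTS],
             "n_excluded": [self.excluded[t] for t in OUTCOME_TESTS]})


def empirical_power(fixture: TrialFixture, config: RandomizerConfig, scenario: str,
                    n_reps: int = 1000, seed=0, level: float = 0.05) -> PowerResult:
    """Empirical power (scenario='effect') or Type-I error (scenario='null').

    Each replicate randomizes the fixture's stream, draws each patient's
    outcome from the counterfactual vector matching the scenario and the
    realized arm, and tests the arm effect with the ordinal model and each
    dichotomized logistic model at the stated significance level.
    Non-convergent fits (separated cutpoints) are excluded and counted.
    """
    ft = FastTrial(fixture.stream, config)
    cf = fixture.counterfactuals
    rng = np.random.default_rng(seed)
    sig = {t: 0 for t in OUTCOME_TESTS}
    used = {t: 0 for t in OUTCOME_TESTS}
    for _ in range(n_reps):
        u_alloc = rng.random(ft.n)
        u_out = rng.random(ft.n)
        _, arm, _, _, _ = ft.run(uniforms=u_alloc)
        mrs = sample_outcomes(cf, scenario, arm, u_out)
        table = outcome_table(arm, mrs)
        res = proportional_odds_test(table)
        if res.converged:
            used["ordinal"] += 1
            sig["ordinal"] += res.p_value < level
        for c in range(6):
            res = cutpoint_logistic_test(table, c)
            if res.converged:
                used[f"cut{c}"] += 1
                sig[f"cut{c}"] += res.p_value < level
    excluded = {t: n_reps - used[t] for t in OUTCOME_TESTS}
    return PowerResult(scenario, level, n_reps, sig, used, excluded)


def matched_power_vectors(fixture: TrialFixture, methods: dict, target_irs,
                          scenarios=("effect", "null"), n_power: int = 1000,
                          n_calib: int = 150, seed: int = 0, level: float = 0.05,
                          percentile: int = 50):
    """Power/Type-I vectors for several methods over matched configurations.

    For every (target IR, scenario) configuration, each method's α is
    calibrated to the target median IR on the fixture, then power is
    simulated with shared per-replicate random numbers.  Returns a tidy
    DataFrame with one row per (configuration, outcome test, method).
    """
    rows = []
    alphas = {}
    for m, (label, config) in enumerate(methods.items()):
        for g, target in enumerate(target_irs):
            cal = calibrate_alpha(fixture.stream, config, target, percentile=percentile,
                                  n_reps=n_calib, seed=seed + 7919 * m + 104729 * g)
            alphas[label, target] = cal
    for label, config in methods.items():
        for g, target in enumerate(target_irs):
            cal = alphas[label, target]
            cfg = config.with_alpha(cal.alpha)
            for s, scenario in enumerate(scenarios):
                pr = empirical_power(fixture, cfg, scenario, n_reps=n_power,
                                     seed=seed + 31 * g + 1009 * s, level=level)
                for test in OUTCOME_TESTS:
                    rows.append({"method": label, "target_ir": target,
                                 "scenario": scenario, "alpha": cal.alpha,
                                 "achieved_ir": cal.achieved_ir, "test": test,
                                 "proportion": pr.proportion(test),
                                 "n_used": pr.used[test],
                                 "n_excluded": pr.excluded[test]})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgreementStats:
    """Lin's CCC plus reduced-major-axis agreement between two methods."""

    ccc: float
    pearson_r: float
    rma_slope: float
    rma_intercept: float
    slope_se: float
    intercept_se: float
    slope_p_vs_1: float
    intercept_p_vs_0: float
    mean_diff: float
    sd_diff: float
    n: int


def agreement_stats(x, y) -> AgreementStats:
    """Agreement between matched proportion vectors (method 1 vs method 2).

    CCC uses Lin's moment formula with 1/n variances; the RMA slope is
    sign(r)·sd(y)/sd(x) with its standard asymptotic standard error.
    Degenerate (zero-variance) inputs yield NaN statistics.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 matched pairs")
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    if sx2 == 0.0 or sy2 == 0.0:
        nan = math.nan
        return AgreementStats(nan, nan, nan, nan, nan, nan, nan, nan,
                              float((y - x).mean()), float((y - x).std(ddof=1)), n)
    ccc = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / math.sqrt(sx2 * sy2)
    slope = math.copysign(math.sqrt(sy2 / sx2), r if r != 0 else 1.0)
    intercept = my - slope * mx
    se_slope = abs(slope) * math.sqrt(max(1 - r * r, 0.0) / (n - 2))
    se_inter = se_slope * math.sqrt(sx2 + mx * mx)
    tdist = sps.t(df=n - 2)
    p_slope = 2 * tdist.sf(abs(slope - 1.0) / se_slope) if se_slope > 0 else math.nan
    p_inter = 2 * tdist.sf(abs(intercept) / se_inter) if se_inter > 0 else math.nan
    return AgreementStats(float(ccc), float(r), float(slope), float(intercept),
                          float(se_slope), float(se_inter), float(p_slope),
                          float(p_inter), float((y - x).mean()),
                          float((y - x).std(ddof=1)), n)
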