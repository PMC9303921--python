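"""Allocation-decision logic for minimal-sufficient-balance randomization.

Two-arm (A/B) covariate-adaptive randomizers that leave the coin fair
unless the accumulated covariate imbalance justifies intervening:

* classic MSB — each covariate is tested with a conventional statistic
  (Student's t, Pearson chi-square / Fisher, WMW z for ordinal data);
  significant covariates vote for the arm that would reduce their
  imbalance and a strict majority triggers a statically biased coin.
* CS-MSB — every covariate's imbalance is measured on the common
  log-WMW-odds scale.  Variants: majority voting over significant
  covariates, weighted voting (votes weighted by w_i·|log WMWOR_i|), or
  pooled imbalance, where the signed log imbalances are combined by
  inverse-variance weighting into a single bias direction

      BD = [Σ w_i · sgn_i · |log WMWOR_i| / SE_i²] / [Σ w_i / SE_i²]
      SE(BD)² = [Σ w_i² / SE_i²] / [Σ w_i / SE_i²]²

  with sgn_i = sgn(|log WMWOR_i(A)| − |log WMWOR_i(B)|) from the
  prospective imbalance under each hypothetical assignment.  Intervention
  occurs when Φ(|BD|/SE(BD)) > 1 − α/2, favoring arm A when BD < 0.

Coins are static (fixed ξ ∈ (0.5, 1]) or linear, ξ = min(0.5 + s·x, 1),
where x is the relevant imbalance magnitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats as sps

from . import stats as cs

__all__ = [
    "Covariate",
    "TrialState",
    "CovariateVote",
    "PooledImbalance",
    "CoinSpec",
    "AllocationDecision",
    "RandomizerConfig",
    "covariate_vote",
    "pooled_bias",
    "pooled_decision",
    "coin_probability",
    "majority_vote_decision",
    "weighted_vote_decision",
    "decide_allocation",
]

KINDS = ("numeric", "ordinal", "binary", "nominal")
#: both arms need this many observed values before a covariate may vote
MIN_GROUP = 2


def _isclose(a: float, b: float) -> bool:
    return abs(a - b) <= 1e-12 * max(abs(a), abs(b)) + 1e-15


@dataclass(frozen=True)
class Covariate:
    """A named baseline covariate with its kind and importance weight."""

    name: str
    kind: str
    categories: tuple | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if not self.weight > 0:
            raise ValueError(f"covariate {self.name!r}: weight must be > 0")
        if self.kind in ("ordinal", "nominal", "binary"):
            if self.categories is None:
                if self.kind == "binary":
                    object.__setattr__(self, "categories", (0, 1))
                else:
                    raise ValueError(f"covariate {self.name!r}: {self.kind} needs categories")
            elif len(self.categories) == 0:
                raise ValueError(f"covariate {self.name!r}: empty category set")
            else:
                object.__setattr__(self, "categories", tuple(self.categories))

    def encode(self, value):
        """Numeric code used for rank comparison: level index for ordered
        kinds, float for numeric, the raw label for nominal. NaN = missing."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return math.nan
        if self.kind == "numeric":
            return float(value)
        if self.kind in ("ordinal", "binary"):
            try:
                return float(self.categories.index(value))
            except ValueError:
                # numeric-coded ordinal/binary values are accepted as-is
                if isinstance(value, (int, float)) and float(value) in [float(i) for i in range(len(self.categories))]:
                    return float(value)
                raise ValueError(f"covariate {self.name!r}: value {value!r} not in categories")
        if value not in self.categories:
            raise ValueError(f"covariate {self.name!r}: value {value!r} not in categories")
        return value


class TrialState:
    """Covariate values and arm labels of the already-randomized patients."""

    def __init__(self, covariates: list[Covariate]):
        self.covariates = list(covariates)
        self._by_name = {c.name: c for c in covariates}
        self.records: list[dict] = []
        self.arms: list[str] = []

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: dict, arm: str) -> None:
        if arm not in ("A", "B"):
            raise ValueError(f"arm label must be 'A' or 'B', got {arm!r}")
        self.records.append(dict(record))
        self.arms.append(arm)

    def arm_size(self, arm: str) -> int:
        return sum(1 for a in self.arms if a == arm)

    def values(self, name: str, arm: str) -> list:
        """Non-missing raw values of one covariate in one arm."""
        cov = self._by_name[name]
        out = []
        for rec, a in zip(self.records, self.arms):
            if a != arm:
                continue
            v = rec.get(name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            out.append(v)
        return out


@dataclass(frozen=True)
class CovariateVote:
    """One covariate's vote on the direction of the biased coin."""

    name: str
    direction: str  # 'A', 'B', or 'abstain'
    current_abs_log_imbalance: float
    se_log: float
    prospective_abs_A: float
    prospective_abs_B: float
    significant: bool
    eligible: bool
    weight: float = 1.0


@dataclass(frozen=True)
class PooledImbalance:
    """Inverse-variance weighted bias direction BD and its standard error."""

    bd: float
    se_bd: float
    n_contributing: int

    @property
    def z(self) -> float:
        if self.n_contributing == 0 or not (self.se_bd > 0):
            return 0.0
        return self.bd / self.se_bd


@dataclass(frozen=True)
class CoinSpec:
    """Biased-coin specification: a fixed ξ or a linear ramp min(0.5+s·x, 1)."""

    mode: str = "static"
    xi: float = 0.9
    slope: float = 4.0

    def __post_init__(self):
        if self.mode not in ("static", "linear"):
            raise ValueError(f"coin mode must be 'static' or 'linear', got {self.mode!r}")
        if self.mode == "static" and not (0.5 < self.xi <= 1.0):
            raise ValueError("static coin requires 0.5 < xi <= 1")
        if self.mode == "linear" and not self.slope > 0:
            raise ValueError("linear coin requires slope > 0")


@dataclass(frozen=True)
class AllocationDecision:
    """Probability of arm A for the incoming patient, plus its evidence."""

    prob_A: float
    intervened: bool
    favored_arm: str  # 'A', 'B', or 'none'
    evidence: object = None

    def __post_init__(self):
        if not self.intervened and self.prob_A != 0.5:
            raise ValueError("non-intervention must carry prob_A == 0.5")


def coin_probability(coin: CoinSpec, x: float) -> float:
    """Probability assigned to the favored arm for imbalance magnitude x >= 0."""
    if x < 0:
        raise ValueError("imbalance magnitude must be nonnegative")
    if coin.mode == "static":
        return coin.xi
    return min(0.5 + coin.slope * x, 1.0)


# ---------------------------------------------------------------------------
# per-covariate votes


def _abs_log_from_counts(u: float, n_a: int, n_b: int) -> float:
    lw, _ = cs.wmw_log_odds_from_u(u, n_a, n_b)
    return abs(lw)


def _wmw_vote(xa: np.ndarray, xb: np.ndarray, v: float, alpha: float) -> tuple:
    """Current |log WMWOR| + SE and the two prospective |log WMWOR| values."""
    est = cs.wmw_odds(xa, xb)
    pc = cs.pairwise_counts(xa, xb)
    u = pc.wins + pc.ties / 2.0
    # appending v to arm A adds pairs (v, each b); to arm B adds (each a, v)
    add_a = float((xb < v).sum()) + 0.5 * float((xb == v).sum())
    add_b = float((xa > v).sum()) + 0.5 * float((xa == v).sum())
    prosp_a = _abs_log_from_counts(u + add_a, pc.n_a + 1, pc.n_b)
    prosp_b = _abs_log_from_counts(u + add_b, pc.n_a, pc.n_b + 1)
    return est, prosp_a, prosp_b


def _direction(prosp_a: float, prosp_b: float) -> str:
    if _isclose(prosp_a, prosp_b):
        return "abstain"
    return "A" if prosp_a < prosp_b else "B"


def covariate_vote(state: TrialState, covariate: Covariate, value,
                   alpha: float, test: str = "wmw") -> CovariateVote:
    """Vote of one covariate on where the incoming patient should go.

    ``test='wmw'`` (CS-MSB family) measures imbalance as |log WMWOR| with
    significance from its normal z-test; ``test='conventional'`` (classic
    MSB) tests significance with the kind-appropriate conventional test and
    directs the vote toward the arm whose hypothetical assignment most
    reduces that test's statistic.  Ineligible covariates (fewer than two
    observed values in either arm, or a missing incoming value) abstain.
    """
    abstain = CovariateVote(covariate.name, "abstain", 0.0, math.nan, 0.0, 0.0,
                            significant=False, eligible=False, weight=covariate.weight)
    enc_v = covariate.encode(value)
    if isinstance(enc_v, float) and math.isnan(enc_v):
        return abstain
    raw_a, raw_b = state.values(covariate.name, "A"), state.values(covariate.name, "B")
    if len(raw_a) < MIN_GROUP or len(raw_b) < MIN_GROUP:
        return abstain

    if covariate.kind == "nominal":
        # common scale on the incoming patient's own category dummy
        xa = cs.dummy_code(raw_a, value).astype(float)
        xb = cs.dummy_code(raw_b, value).astype(float)
        v = 1.0
    else:
        xa = np.array([covariate.encode(r) for r in raw_a], dtype=float)
        xb = np.array([covariate.encode(r) for r in raw_b], dtype=float)
        v = float(enc_v)

    if test == "wmw" or covariate.kind == "ordinal":
        est, prosp_a, prosp_b = _wmw_vote(xa, xb, v, alpha)
        if est.degenerate:
            return abstain
        direction = _direction(prosp_a, prosp_b)
        z_crit = float(sps.norm.ppf(1.0 - alpha / 2.0)) if alpha > 0 else math.inf
        significant = abs(est.log_wmwor) / est.se_log > z_crit
        return CovariateVote(covariate.name, direction, abs(est.log_wmwor), est.se_log,
                             prosp_a, prosp_b, significant=significant, eligible=True,
                             weight=covariate.weight)
    if test == "conventional":
        # classic MSB: direction and significance come from the conventional
        # test on the full data; no common-scale magnitude is attached
        direction, significant = _conventional_vote(covariate, raw_a, raw_b, value, alpha)
        return CovariateVote(covariate.name, direction, 0.0, math.nan, 0.0, 0.0,
                             significant=significant, eligible=True,
                             weight=covariate.weight)
    raise ValueError(f"unknown vote test {test!r}")


def _conventional_vote(covariate, raw_a, raw_b, value, alpha) -> tuple[str, bool]:
    """Direction & significance for classic MSB's conventional tests."""
    if covariate.kind == "numeric":
        a = np.array(raw_a, dtype=float)
        b = np.array(raw_b, dtype=float)
        res = cs.conventional_imbalance(a, b, "numeric")
        m_a = abs(_t_stat(np.append(a, float(value)), b))
        m_b = abs(_t_stat(a, np.append(b, float(value))))
    else:  # binary / nominal: chi-square (or Fisher) on the full table
        cats = covariate.categories
        res = cs.conventional_imbalance(raw_a, raw_b, "binary" if covariate.kind == "binary" else "nominal",
                                        categories=cats)
        t_a = cs._contingency(list(raw_a) + [value], raw_b, cats)
        t_b = cs._contingency(raw_a, list(raw_b) + [value], cats)
        if res.test == "fisher":
            # more balanced = larger Fisher p
            m_a = -_fisher_dir_p(t_a)
            m_b = -_fisher_dir_p(t_b)
        else:
            m_a = cs.chi2_from_table(t_a)[0]
            m_b = cs.chi2_from_table(t_b)[0]
    direction = _direction(m_a, m_b)
    # Fisher p-values on small tables are rationals that can equal alpha
    # exactly; require a strict margin so the decision is float-stable
    thresh = alpha * (1 - 1e-9) if res.test == "fisher" else alpha
    return direction, bool(res.p_value < thresh)


def _nonzero_rows(t: np.ndarray) -> np.ndarray:
    return t[t.sum(axis=1) > 0]


def _fisher_dir_p(table: np.ndarray) -> float:
    """Fisher p of a prospective table; 1.0 when it is no longer 2×2
    (the incoming category cannot repair a two-category imbalance)."""
    nz = _nonzero_rows(table)
    if nz.shape[0] != 2:
        return 1.0
    return float(sps.fisher_exact(nz)[1])


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    if na + nb <= 2:
        return 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 <= 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


# ---------------------------------------------------------------------------
# combining votes into a decision


def pooled_bias(votes: list[CovariateVote], weights: dict | None = None) -> PooledImbalance:
    """Inverse-variance weighted bias direction over all eligible covariates.

    Every eligible covariate contributes regardless of its own
    significance; covariates whose two prospective imbalances tie
    contribute sgn = 0 to the numerator but keep their weight in the
    denominator.  Ineligible covariates drop out entirely.
    """
    num = den = den2 = 0.0
    n_contrib = 0
    for v in votes:
        if not v.eligible or not (v.se_log > 0) or math.isnan(v.se_log):
            continue
        w = weights.get(v.name, v.weight) if weights is not None else v.weight
        inv = 1.0 / (v.se_log ** 2)
        sgn = 0.0 if v.direction == "abstain" else (-1.0 if v.direction == "A" else 1.0)
        num += w * sgn * v.current_abs_log_imbalance * inv
        den += w * inv
        den2 += w * w * inv
        n_contrib += 1
    if n_contrib == 0 or den <= 0:
        return PooledImbalance(0.0, math.nan, 0)
    return PooledImbalance(num / den, math.sqrt(den2) / den, n_contrib)


def _alpha_z(alpha: float) -> float:
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    if alpha == 0.0:
        return math.inf
    return float(sps.norm.ppf(1.0 - alpha / 2.0))


def pooled_decision(pooled: PooledImbalance, alpha: float, coin: CoinSpec) -> AllocationDecision:
    """Φ(|BD|/SE(BD)) > 1 − α/2 triggers a coin biased toward A if BD < 0."""
    z_crit = _alpha_z(alpha)
    if pooled.n_contributing == 0 or pooled.bd == 0.0 or not abs(pooled.z) > z_crit:
        return AllocationDecision(0.5, False, "none", evidence=pooled)
    favored = "A" if pooled.bd < 0 else "B"
    p_fav = coin_probability(coin, abs(pooled.bd))
    prob_a = p_fav if favored == "A" else 1.0 - p_fav
    return AllocationDecision(prob_a, True, favored, evidence=pooled)


def majority_vote_decision(votes: list[CovariateVote], alpha: float,
                           coin: CoinSpec, weights: dict | None = None) -> AllocationDecision:
    """Strict majority of *significant* covariate votes picks the favored arm.

    With a linear coin (WMW majority variant), the coin magnitude is the
    summed w_j·|log WMWOR_j| of the significant covariates that won the
    vote; nonsignificant leanings never count.
    """
    _alpha_z(alpha)  # validate alpha
    tally = {"A": 0, "B": 0}
    mag = {"A": 0.0, "B": 0.0}
    for v in votes:
        if not v.eligible or not v.significant or v.direction == "abstain":
            continue
        w = weights.get(v.name, v.weight) if weights is not None else v.weight
        tally[v.direction] += 1
        mag[v.direction] += w * v.current_abs_log_imbalance
    if tally["A"] == tally["B"]:
        return AllocationDecision(0.5, False, "none", evidence=dict(tally))
    favored = "A" if tally["A"] > tally["B"] else "B"
    p_fav = coin_probability(coin, mag[favored])
    prob_a = p_fav if favored == "A" else 1.0 - p_fav
    return AllocationDecision(prob_a, True, favored, evidence=dict(tally))


def weighted_vote_decision(votes: list[CovariateVote], alpha: float,
                           coin: CoinSpec, weights: dict | None = None) -> AllocationDecision:
    """Significant votes weighted by w_i·|log WMWOR_i|; heaviest side wins.

    With a linear coin, ξ = f(|x_A − x_B|) where x_A, x_B are the summed
    weights for each side.
    """
    _alpha_z(alpha)
    x = {"A": 0.0, "B": 0.0}
    for v in votes:
        if not v.eligible or not v.significant or v.direction == "abstain":
            continue
        w = weights.get(v.name, v.weight) if weights is not None else v.weight
        x[v.direction] += w * v.current_abs_log_imbalance
    if _isclose(x["A"], x["B"]):
        return AllocationDecision(0.5, False, "none", evidence=dict(x))
    favored = "A" if x["A"] > x["B"] else "B"
    p_fav = coin_probability(coin, abs(x["A"] - x["B"]))
    prob_a = p_fav if favored == "A" else 1.0 - p_fav
    return AllocationDecision(prob_a, True, favored, evidence=dict(x))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RandomizerConfig:
    """Full randomizer configuration, round-trippable through YAML/JSON."""

    method: str = "csmsb"  # 'pure', 'msb', or 'csmsb'
    voting: str = "pooled"  # 'majority', 'weighted', or 'pooled'
    coin: CoinSpec = field(default_factory=CoinSpec)
    alpha: float = 0.05
    covariates: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("pure", "msb", "csmsb"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.voting not in ("majority", "weighted", "pooled"):
            raise ValueError(f"unknown voting mode {self.voting!r}")
        if self.method == "msb" and (self.voting != "majority" or self.coin.mode != "static"):
            raise ValueError("classic MSB uses majority voting with a static coin")
        _alpha_z(self.alpha)
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def vote_test(self) -> str:
        return "conventional" if self.method == "msb" else "wmw"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "voting": self.voting,
            "coin": {"mode": self.coin.mode, "xi": self.coin.xi, "slope": self.coin.slope},
            "alpha": self.alpha,
            "covariates": [
                {"name": c.name, "kind": c.kind, "weight": c.weight,
                 "categories": list(c.categories) if c.categories is not None else None}
                for c in self.covariates
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RandomizerConfig":
        coin = CoinSpec(**d.get("coin", {}))
        covs = tuple(
            Covariate(name=c["name"], kind=c["kind"], weight=c.get("weight", 1.0),
                      categories=tuple(c["categories"]) if c.get("categories") else None)
            for c in d.get("covariates", [])
        )
        return cls(method=d.get("method", "csmsb"), voting=d.get("voting", "pooled"),
                   coin=coin, alpha=d.get("alpha", 0.05), covariates=covs,
                   seed=d.get("seed"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RandomizerConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "RandomizerConfig":
        return cls.from_dict(json.loads(text))

    def with_alpha(self, alpha: float) -> "RandomizerConfig":
        return replace(self, alpha=alpha)


def decide_allocation(state: TrialState, patient: dict,
                      config: RandomizerConfig) -> AllocationDecision:
    """One allocation decision for the incoming patient (reference path)."""
    if config.method == "pure" or config.alpha == 0.0:
        return AllocationDecision(0.5, False, "none", evidence=None)
    votes = [covariate_vote(state, c, patient.get(c.name), config.alpha, test=config.vote_test)
             for c in config.covariates]
    if config.method == "msb" or config.voting == "majority":
        return majority_vote_decision(votes, config.alpha, config.coin)
    if config.voting == "weighted":
        return weighted_vote_decision(votes, config.alpha, config.coin)
    pooled = pooled_bias(votes)
    return pooled_decision(pooled, config.alpha, config.coin)
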