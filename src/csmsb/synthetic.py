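"""Synthetic stroke-trial populations with counterfactual ordinal outcomes.

The real EXTEND / EXTEND-IA / TNK trial datasets are not publicly
available, so this module generates populations that emulate their
published structure: mixed-kind baseline covariates with matched marginal
summaries (median/IQR for numerics, category proportions otherwise) and a
7-level modified Rankin scale (mRS) outcome, 0 (no symptoms) to 6 (death).

Each synthetic patient carries three counterfactual outcome probability
vectors — under treatment, under control, and under no treatment effect —
estimated by distance-weighted k-nearest neighbors trained on,
respectively, the treatment arm, the control arm, and all patients of a
source population whose observed outcomes come from a built-in
proportional-odds model.  Power and Type-I error of a randomizer can then
be simulated from a single population.

Numeric marginals are matched to a median/IQR target with a
shifted-scaled gamma (reflected when the target is left-skewed), the
standard minimal-information fit when only quartiles are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps
from sklearn.neighbors import NearestNeighbors

from .randomizers import Covariate

__all__ = [
    "CovariateSpec",
    "CounterfactualOutcomes",
    "OutcomeModel",
    "TrialFixture",
    "generate_covariates",
    "knn_counterfactuals",
    "sample_outcome",
    "sample_outcomes",
    "make_trial_fixture",
    "FIXTURE_NAMES",
]

N_LEVELS = 7


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution and prognostic effect of one baseline covariate.

    numeric: ``median``, ``q25``, ``q75`` (optionally ``lo``/``hi`` clipping
    bounds) and ``coef``, the log-odds increase in worse outcome per IQR/1.349
    (≈ one SD) above the median.  Categorical kinds: ``categories`` with
    ``probs`` and per-category ``effects`` on the same log-odds scale.
    """

    name: str
    kind: str
    median: float | None = None
    q25: float | None = None
    q75: float | None = None
    lo: float | None = None
    hi: float | None = None
    coef: float = 0.0
    categories: tuple = ()
    probs: tuple = ()
    effects: tuple = ()
    weight: float = 1.0

    def __post_init__(self):
        if self.kind == "numeric":
            if None in (self.median, self.q25, self.q75):
                raise ValueError(f"spec {self.name!r}: numeric needs median/q25/q75")
            if not (self.q25 < self.median < self.q75):
                raise ValueError(f"spec {self.name!r}: quartiles must straddle the median")
        else:
            if not self.categories or not self.probs:
                raise ValueError(f"spec {self.name!r}: categorical needs categories and probs")
            if len(self.categories) != len(self.probs):
                raise ValueError(f"spec {self.name!r}: categories/probs length mismatch")
            total = float(sum(self.probs))
            object.__setattr__(self, "probs", tuple(p / total for p in self.probs))
            if not self.effects:
                object.__setattr__(self, "effects", tuple(0.0 for _ in self.categories))
            elif len(self.effects) != len(self.categories):
                raise ValueError(f"spec {self.name!r}: effects/categories length mismatch")

    def as_covariate(self) -> Covariate:
        cats = tuple(self.categories) if self.kind != "numeric" else None
        return Covariate(self.name, self.kind, categories=cats, weight=self.weight)

    @property
    def scale(self) -> float:
        """Approximate SD implied by the IQR (normal-reference 1.349)."""
        return (self.q75 - self.q25) / 1.349


def _gamma_quantile_ratio(shape: float) -> float:
    q = sps.gamma.ppf([0.25, 0.5, 0.75], shape)
    return (q[2] - q[1]) / (q[1] - q[0])


def _fit_quantile_dist(median: float, q25: float, q75: float):
    """Distribution matching three quartiles: shifted-scaled gamma, reflected
    for left skew, normal when the quartiles are symmetric.

    Returns ``(sampler)`` where ``sampler(rng, n)`` draws n values.
    """
    ratio = (q75 - median) / (median - q25)
    if abs(ratio - 1.0) < 1e-3:
        sd = (q75 - q25) / (2 * sps.norm.ppf(0.75))
        return lambda rng, n: rng.normal(median, sd, n)
    flip = ratio < 1.0
    if flip:
        median, q25, q75 = -median, -q75, -q25
        ratio = 1.0 / ratio

    def f(log_k):
        return _gamma_quantile_ratio(math.exp(log_k)) - ratio

    log_k = optimize.brentq(f, math.log(1e-2), math.log(1e4))
    shape = math.exp(log_k)
    q = sps.gamma.ppf([0.25, 0.5, 0.75], shape)
    scale = (q75 - q25) / (q[2] - q[0])
    loc = median - scale * q[1]

    def sampler(rng, n):
        x = loc + scale * rng.gamma(shape, 1.0, n)
        return -x if flip else x

    return sampler


def generate_covariates(specs, n: int, seed=None) -> pd.DataFrame:
    """Draw a patient stream of n records from the covariate specs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = {}
    for spec in specs:
        if spec.kind == "numeric":
            sampler = _fit_quantile_dist(spec.median, spec.q25, spec.q75)
            x = sampler(rng, n)
            if spec.lo is not None or spec.hi is not None:
                x = np.clip(x, spec.lo, spec.hi)
            data[spec.name] = x
        else:
            data[spec.name] = rng.choice(np.asarray(spec.categories, dtype=object),
                                         size=n, p=spec.probs)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# outcome source model


@dataclass(frozen=True)
class OutcomeModel:
    """Proportional-odds source model for the observed mRS.

    P(mRS <= j | x, arm) = expit(theta_j - eta(x) + tau * treated), where
    theta_j are the cumulative logits of ``base_probs`` and eta sums the
    specs' prognostic terms; tau > 0 is the treatment benefit in common
    log-odds (tau = log of the common odds ratio).
    """

    specs: tuple
    base_probs: tuple = (0.10, 0.12, 0.15, 0.16, 0.20, 0.12, 0.15)
    treatment_log_or: float = 0.6

    def linear_predictor(self, stream: pd.DataFrame) -> np.ndarray:
        eta = np.zeros(len(stream))
        for spec in self.specs:
            col = stream[spec.name]
            if spec.kind == "numeric":
                eta += spec.coef * (col.to_numpy(float) - spec.median) / spec.scale
            else:
                eff = dict(zip(spec.categories, spec.effects))
                eta += np.array([eff[v] for v in col])
        return eta

    def level_probs(self, stream: pd.DataFrame, treated) -> np.ndarray:
        """(n, 7) outcome probabilities given the treatment indicator(s)."""
        theta = np.log(np.cumsum(self.base_probs)[:-1] / (1 - np.cumsum(self.base_probs)[:-1]))
        eta = self.linear_predictor(stream) - self.treatment_log_or * np.asarray(treated, float)
        cdf = special.expit(theta[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def sample(self, stream: pd.DataFrame, treated, rng) -> np.ndarray:
        probs = self.level_probs(stream, treated)
        u = rng.random(len(stream))
        return (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)


# ---------------------------------------------------------------------------
# counterfactual outcomes


@dataclass
class CounterfactualOutcomes:
    """Per-patient outcome probability vectors for the three scenarios."""

    treatment: np.ndarray  # (n, 7)
    control: np.ndarray
    null: np.ndarray

    def __post_init__(self):
        for name in ("treatment", "control", "null"):
            v = getattr(self, name)
            if (v < 0).any() or np.abs(v.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} vectors must be nonnegative and sum to 1")

    def __len__(self) -> int:
        return self.treatment.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name in ("treatment", "control", "null"):
            v = getattr(self, name)
            for j in range(v.shape[1]):
                cols[f"{name}_mrs{j}"] = v[:, j]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CounterfactualOutcomes":
        return cls(*(np.column_stack([df[f"{n}_mrs{j}"] for j in range(N_LEVELS)])
                     for n in ("treatment", "control", "null")))


def _feature_matrix(stream: pd.DataFrame, specs) -> np.ndarray:
    """Mixed-type features for distances: standardized numerics plus
    one-hot categoricals, every column rescaled to unit variance."""
    cols = []
    for spec in specs:
        if spec.kind == "numeric":
            cols.append(stream[spec.name].to_numpy(float))
        else:
            vals = stream[spec.name].to_numpy(object)
            for c in spec.categories:
                cols.append((vals == c).astype(float))
    x = np.column_stack(cols)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _knn_probs(train_x, train_y, query_x, k: int, weighting: str) -> np.ndarray:
    if k < 1 or k > train_x.shape[0]:
        raise ValueError(f"k={k} outside the training subset size {train_x.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(train_x)
    dist, idx = nn.kneighbors(query_x)
    out = np.zeros((query_x.shape[0], N_LEVELS))
    for q in range(query_x.shape[0]):
        d = dist[q]
        if weighting == "uniform":
            w = np.ones_like(d)
        else:
            zero = d < 1e-12
            # zero-distance neighbors dominate in the 1/d limit
            w = zero.astype(float) if zero.any() else 1.0 / d
        np.add.at(out[q], train_y[idx[q]], w)
        out[q] /= w.sum()
    return out


def knn_counterfactuals(source_stream: pd.DataFrame, source_arms, source_mrs,
                        query_stream: pd.DataFrame, specs, k: int = 10,
                        weighting: str = "distance") -> CounterfactualOutcomes:
    """Estimate the three counterfactual vectors for every query patient.

    Training subsets: the treatment arm (for outcome-under-treatment), the
    control arm (under control), and everyone (no treatment effect).
    Distances are Euclidean on the standardized mixed-type features;
    neighbor weights are inverse distance with exact matches dominating.
    """
    arms = np.asarray(source_arms)
    y = np.asarray(source_mrs, dtype=int)
    combined = pd.concat([source_stream, query_stream], ignore_index=True)
    x_all = _feature_matrix(combined, specs)
    ns = len(source_stream)
    xs, xq = x_all[:ns], x_all[ns:]
    is_a = (arms == "A") | (arms == 1)
    if weighting not in ("distance", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    return CounterfactualOutcomes(
        treatment=_knn_probs(xs[is_a], y[is_a], xq, k, weighting),
        control=_knn_probs(xs[~is_a], y[~is_a], xq, k, weighting),
        null=_knn_probs(xs, y, xq, k, weighting),
    )


def sample_outcome(cf: CounterfactualOutcomes, scenario: str, arm, seed=None, rng=None):
    """Draw one mRS level per patient under the scenario ('effect' or 'null').

    Under 'effect', arm A draws from the treatment vectors and arm B from
    the control vectors; under 'null' the arm is ignored.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(len(cf))
    return sample_outcomes(cf, scenario, arm, u)


def sample_outcomes(cf: CounterfactualOutcomes, scenario: str, arm, uniforms) -> np.ndarray:
    """Vectorized outcome draw from per-patient uniforms (shared-seed safe)."""
    if scenario == "null":
        probs = cf.null
    elif scenario == "effect":
        arm = np.asarray(arm)
        is_a = (arm == "A") | (arm == 1)
        probs = np.where(is_a[:, None], cf.treatment, cf.control)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    u = np.asarray(uniforms)
    return (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# named fixtures emulating the published trial populations


def _binary(name, n_no, n_yes, effect_yes=0.0, weight=1.0, cats=("no", "yes")):
    return CovariateSpec(name, "binary", categories=cats, probs=(n_no, n_yes),
                         effects=(0.0, effect_yes), weight=weight)


_FIXTURES: dict[str, tuple[tuple[CovariateSpec, ...], int]] = {}

_FIXTURES["extend_like"] = ((
    CovariateSpec("age", "numeric", median=76, q25=64, q75=81, lo=18, hi=100, coef=0.5),
    CovariateSpec("nihss", "numeric", median=11, q25=7, q75=17, lo=0, hi=42, coef=0.8),
    CovariateSpec("region", "binary", categories=("aus_nz_fin", "asia"),
                  probs=(178, 47), effects=(0.0, 0.1)),
    CovariateSpec("time_window", "ordinal",
                  categories=("4.5-6h", "6-9h", "wake_up"),
                  probs=(23, 56, 146), effects=(0.0, 0.15, 0.3)),
), 225)

_FIXTURES["extendia_like"] = ((
    CovariateSpec("age", "numeric", median=71, q25=63, q75=78, lo=18, hi=100, coef=0.5),
    CovariateSpec("stratum", "nominal", categories=("ica", "m1", "m2"),
                  probs=(17, 44, 9), effects=(0.6, 0.0, -0.4)),
    CovariateSpec("nihss", "numeric", median=15, q25=12, q75=19, lo=0, hi=42, coef=0.8),
), 70)

_FIXTURES["tnk1_like"] = ((
    CovariateSpec("age", "numeric", median=74, q25=65, q75=81.25, lo=18, hi=100, coef=0.5),
    CovariateSpec("nihss", "numeric", median=17, q25=12, q75=22, lo=0, hi=42, coef=0.8),
    CovariateSpec("occlusion", "nominal", categories=("ica_basilar", "m1", "m2"),
                  probs=(55, 119, 28), effects=(0.6, 0.0, -0.4)),
), 202)

_TNK2_CORE = (
    CovariateSpec("age", "numeric", median=74, q25=65, q75=81.25, lo=18, hi=100, coef=0.5),
    CovariateSpec("nihss", "numeric", median=16.5, q25=10, q75=21, lo=0, hi=42, coef=0.8),
    CovariateSpec("location", "binary", categories=("metro", "rural"),
                  probs=(259, 41), effects=(0.0, 0.1)),
    CovariateSpec("occlusion", "binary", categories=("ica_basilar", "mca"),
                  probs=(71, 229), effects=(0.5, 0.0)),
)

_FIXTURES["tnk2_like"] = (_TNK2_CORE, 300)

_FIXTURES["tnk2_expanded_like"] = (_TNK2_CORE + (
    _binary("sex", 141, 159, 0.1, cats=("female", "male")),
    _binary("atrial_fibrillation", 219, 87, 0.3),
    _binary("hypertension", 103, 197, 0.15),
    _binary("lipid_disorders", 182, 118, 0.0),
    _binary("prior_stroke_tia", 262, 38, 0.25),
    _binary("ischaemic_heart_disease", 233, 67, 0.15),
    _binary("diabetes", 241, 59, 0.2),
    _binary("peripheral_vascular_disease", 289, 11, 0.1),
), 300)

FIXTURE_NAMES = tuple(_FIXTURES)


@dataclass
class TrialFixture:
    """A synthetic population ready for randomization experiments."""

    name: str
    stream: pd.DataFrame
    specs: tuple
    counterfactuals: CounterfactualOutcomes
    source_arms: np.ndarray
    source_mrs: np.ndarray
    outcome_model: OutcomeModel

    @property
    def covariates(self) -> tuple:
        return tuple(s.as_covariate() for s in self.specs)

    def __len__(self) -> int:
        return len(self.stream)


def make_trial_fixture(name: str, n: int | None = None, seed=None, k: int = 10,
                       treatment_log_or: float = 0.6) -> TrialFixture:
    """Build a named fixture: covariates, source outcomes, counterfactuals.

    The source population is the stream itself under a 50/50 randomization,
    with observed mRS drawn from the proportional-odds model; the kNN step
    then converts those draws into the three counterfactual vectors.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    specs, default_n = _FIXTURES[name]
    if n is None:
        n = default_n
    rng = np.random.default_rng(seed)
    stream = generate_covariates(specs, n, seed=rng)
    model = OutcomeModel(specs=specs, treatment_log_or=treatment_log_or)
    arms = np.where(rng.random(n) < 0.5, "A", "B")
    mrs = model.sample(stream, arms == "A", rng)
    cf = knn_counterfactuals(stream, arms, mrs, stream, specs, k=k)
    return TrialFixture(name, stream, tuple(specs), cf, arms, mrs, model)
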