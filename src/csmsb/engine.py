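"""Sequential trial engine: replay a patient stream through a randomizer.

Patients are processed strictly in stream order; each allocation decision
sees only the covariates and arms of previously randomized patients, and
the realized arm is a Bernoulli draw of the decision probability from a
seeded generator.  The engine logs the pre-draw probability for every
patient because the expected-bias metric

    EB = (1/N) Σ |Prob(X_i = A) − 0.5|

is defined on probabilities, not realized arms; for a static coin it
reduces exactly to IR × (ξ − 0.5) where IR is the intervention rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as cs
from .randomizers import (
    Covariate,
    PooledImbalance,
    RandomizerConfig,
    TrialState,
    decide_allocation,
)

__all__ = [
    "AllocationRecord",
    "TrialResult",
    "run_trial",
    "intervention_rate",
    "expected_bias",
    "end_of_trial_imbalance",
    "read_stream",
    "write_allocation_log",
]


@dataclass(frozen=True)
class AllocationRecord:
    index: int
    prob_A: float
    arm: str
    intervened: bool
    bd: float = math.nan
    se_bd: float = math.nan
    favored_arm: str = "none"


@dataclass
class TrialResult:
    records: list
    state: TrialState
    config: RandomizerConfig
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.records],
                "prob_A": [r.prob_A for r in self.records],
                "arm": [r.arm for r in self.records],
                "intervened": [r.intervened for r in self.records],
                "bd": [r.bd for r in self.records],
                "se_bd": [r.se_bd for r in self.records],
            }
        )

    @property
    def arms(self) -> list[str]:
        return [r.arm for r in self.records]


def _validate_patient(idx: int, patient: dict, covariates) -> None:
    for cov in covariates:
        if cov.name not in patient:
            raise ValueError(f"patient {idx}: missing covariate {cov.name!r}")
        try:
            cov.encode(patient[cov.name])
        except ValueError as e:
            raise ValueError(f"patient {idx}: {e}") from e


def run_trial(stream, config: RandomizerConfig, seed: int | None = None) -> TrialResult:
    """Randomize every patient in the stream, in order.

    ``stream`` is a DataFrame (one row per patient, one column per
    configured covariate) or an equivalent list of dicts.  The seeded
    generator is consumed only for the final Bernoulli draw of each
    allocation, so results are reproducible given (stream, config, seed).
    """
    if isinstance(stream, pd.DataFrame):
        patients = stream.to_dict("records")
    else:
        patients = [dict(p) for p in stream]
    if not patients:
        raise ValueError("patient stream is empty")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    uniforms = rng.random(len(patients))

    state = TrialState(list(config.covariates))
    records = []
    for i, patient in enumerate(patients):
        _validate_patient(i, patient, config.covariates)
        decision = decide_allocation(state, patient, config)
        arm = "A" if uniforms[i] < decision.prob_A else "B"
        bd = se_bd = math.nan
        if isinstance(decision.evidence, PooledImbalance):
            bd, se_bd = decision.evidence.bd, decision.evidence.se_bd
        records.append(AllocationRecord(i, decision.prob_A, arm, decision.intervened,
                                        bd, se_bd, decision.favored_arm))
        state.add(patient, arm)
    return TrialResult(records, state, config, seed)


def intervention_rate(result: TrialResult) -> float:
    """Proportion of allocations made with a biased coin."""
    if len(result) == 0:
        raise ValueError("empty trial result")
    return sum(r.intervened for r in result.records) / len(result)


def expected_bias(result: TrialResult) -> float:
    """Mean absolute deviation of the allocation probabilities from 0.5."""
    if len(result) == 0:
        raise ValueError("empty trial result")
    return sum(abs(r.prob_A - 0.5) for r in result.records) / len(result)


def end_of_trial_imbalance(result: TrialResult) -> pd.DataFrame:
    """Per-covariate imbalance between the final arms.

    One row per covariate (one per category dummy for nominal covariates):
    the log WMW odds with its SE and p-value, plus the kind-matched
    conventional statistic (Cohen's d for numeric, chi-square for
    categorical).  A trial that left an arm empty yields a degenerate
    report with no statistics.
    """
    state = result.state
    rows = []
    degenerate = state.arm_size("A") == 0 or state.arm_size("B") == 0
    for cov in state.covariates:
        labels = [None]
        if cov.kind == "nominal":
            labels = list(cov.categories)
        for lab in labels:
            row = {"covariate": cov.name if lab is None else f"{cov.name}={lab}",
                   "kind": cov.kind, "degenerate": degenerate}
            if not degenerate:
                a, b = state.values(cov.name, "A"), state.values(cov.name, "B")
                if lab is None and cov.kind != "numeric":
                    xa = np.array([cov.encode(v) for v in a], dtype=float)
                    xb = np.array([cov.encode(v) for v in b], dtype=float)
                elif lab is None:
                    xa, xb = np.asarray(a, float), np.asarray(b, float)
                else:
                    xa = cs.dummy_code(a, lab).astype(float)
                    xb = cs.dummy_code(b, lab).astype(float)
                est = cs.wmw_odds(xa, xb)
                row.update(log_wmwor=est.log_wmwor, se_log=est.se_log,
                           wmw_p=est.p_value if not est.degenerate else 1.0)
                if cov.kind == "numeric":
                    conv = cs.conventional_imbalance(a, b, "numeric")
                elif cov.kind == "ordinal":
                    conv = cs.conventional_imbalance(xa, xb, "ordinal")
                elif cov.kind == "binary":
                    conv = cs.conventional_imbalance(a, b, "binary", categories=cov.categories)
                else:  # one dummy of a nominal covariate
                    conv = cs.conventional_imbalance(xa, xb, "binary", categories=(0, 1))
                row.update(conv_test=conv.test, conv_stat=conv.statistic,
                           conv_p=conv.p_value, effect_size=conv.effect_size)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text I/O


def read_stream(path, covariates: list[Covariate]) -> pd.DataFrame:
    """Read a patient stream CSV; column typing comes from the covariate
    config, never inferred from the file."""
    df = pd.read_csv(path, dtype=object)
    for cov in covariates:
        if cov.name not in df.columns:
            raise ValueError(f"stream is missing covariate column {cov.name!r}")
        if cov.kind == "numeric":
            df[cov.name] = pd.to_numeric(df[cov.name])
        elif all(isinstance(c, (int, float)) for c in cov.categories):
            df[cov.name] = pd.to_numeric(df[cov.name])
    return df[[c.name for c in covariates]]


def write_allocation_log(result: TrialResult, path) -> None:
    result.to_frame().to_csv(path, index=False)
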