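"""Randomize a patient stream with CS-MSB and inspect the allocation log.

Builds a small TNK-I-like synthetic population, replays it through the
pooled-imbalance CS-MSB randomizer with a static biased coin, and prints
the trial-level metrics and the end-of-trial imbalance report.
"""

import numpy as np

from csmsb import (
    CoinSpec,
    RandomizerConfig,
    end_of_trial_imbalance,
    expected_bias,
    intervention_rate,
    make_trial_fixture,
    run_trial,
)

fixture = make_trial_fixture("tnk1_like", n=120, seed=0)
config = RandomizerConfig(
    method="csmsb", voting="pooled",
    coin=CoinSpec("static", xi=0.9),  # favored arm gets probability 0.9
    alpha=0.3,  # intervention threshold for the pooled z-test
    covariates=fixture.covariates,
)

result = run_trial(fixture.stream, config, seed=2024)

print(f"patients: {len(result)}")
print(f"arm sizes: A={result.state.arm_size('A')}, B={result.state.arm_size('B')}")
ir = intervention_rate(result)
eb = expected_bias(result)
print(f"intervention rate: {ir:.3f}  (share of allocations with a biased coin)")
print(f"expected bias:     {eb:.3f}  (= IR x (xi - 0.5) = {ir * 0.4:.3f} for a static coin)")

first = next(r for r in result.records if r.intervened)
print(f"first intervention at patient {first.index}: "
      f"BD={first.bd:+.3f} favored {first.favored_arm} (prob_A={first.prob_A:.2f})")

report = end_of_trial_imbalance(result)
cols = ["covariate", "log_wmwor", "se_log", "wmw_p"]
print("\nend-of-trial imbalance (log WMW odds of arm A scoring higher):")
print(report[cols].round(3).to_string(index=False))
print("\n|log WMW odds| near 0 means the arms are well balanced on that covariate.")
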