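"""Allocation-decision logic: votes, pooling, coins, configs."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from csmsb.randomizers import (
    AllocationDecision,
    CoinSpec,
    Covariate,
    CovariateVote,
    RandomizerConfig,
    TrialState,
    coin_probability,
    covariate_vote,
    decide_allocation,
    majority_vote_decision,
    pooled_bias,
    pooled_decision,
    weighted_vote_decision,
)
from csmsb.stats import pairwise_counts, wmw_log_odds_from_u


def vote(name, direction, mag, se, significant=True, weight=1.0):
    return CovariateVote(name, direction, mag, se, 0.0, 0.0,
                         significant=significant, eligible=True, weight=weight)


class TestCoin:
    @pytest.mark.parametrize("s, x, expected", [(4, 0.05, 0.7), (16, 0.5, 1.0), (2, 0.0, 0.5)])
    def test_linear_coin(self, s, x, expected):
        assert coin_probability(CoinSpec("linear", slope=s), x) == pytest.approx(expected)

    def test_static_coin_ignores_magnitude(self):
        coin = CoinSpec("static", 0.8)
        assert coin_probability(coin, 0.0) == coin_probability(coin, 5.0) == 0.8

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CoinSpec("static", 0.5)
        with pytest.raises(ValueError):
            CoinSpec("static", 1.2)
        with pytest.raises(ValueError):
            CoinSpec("linear", slope=-1)


class TestPooledBias:
    def test_single_covariate_identity(self):
        p = pooled_bias([vote("a", "B", 0.4, 0.2)])
        assert p.bd == pytest.approx(0.4)
        assert p.se_bd == pytest.approx(0.2)

    def test_equal_and_opposite_votes_cancel(self):
        p = pooled_bias([vote("a", "B", 0.4, 0.3), vote("b", "A", 0.4, 0.3)])
        assert p.bd == pytest.approx(0.0)

    def test_three_covariate_inverse_variance_arithmetic(self):
        """BD equals the hand-computed inverse-variance weighted mean."""
        ses = (0.1, 0.2, 0.4)
        signed = (0.3, 0.3, -0.6)
        votes = [vote(f"c{i}", "B" if s > 0 else "A", abs(s), se)
                 for i, (s, se) in enumerate(zip(signed, ses))]
        p = pooled_bias(votes)
        w = [1 / se**2 for se in ses]
        assert p.bd == pytest.approx(sum(wi * si for wi, si in zip(w, signed)) / sum(w))
        assert p.se_bd**2 == pytest.approx(1.0 / sum(w))

    def test_abstainers_keep_weight_in_denominator(self):
        votes = [vote("a", "B", 0.4, 0.2), vote("b", "abstain", 0.4, 0.2)]
        p = pooled_bias(votes)
        assert p.bd == pytest.approx(0.2)  # numerator halves, denominator doubles
        assert p.n_contributing == 2

    def test_weight_rescaling_leaves_bd_and_z_invariant(self):
        votes = [vote("a", "B", 0.4, 0.2, weight=1.0), vote("b", "A", 0.1, 0.3, weight=2.0)]
        scaled = [vote("a", "B", 0.4, 0.2, weight=5.0), vote("b", "A", 0.1, 0.3, weight=10.0)]
        p, q = pooled_bias(votes), pooled_bias(scaled)
        assert p.bd == pytest.approx(q.bd)
        assert p.z == pytest.approx(q.z)

    def test_no_eligible_votes_means_no_intervention(self):
        p = pooled_bias([CovariateVote("a", "abstain", 0.0, math.nan, 0, 0, False, False)])
        assert p.bd == 0.0
        d = pooled_decision(p, 0.5, CoinSpec("static", 0.9))
        assert not d.intervened


class TestPooledDecision:
    coin = CoinSpec("static", 0.7)

    def test_intervenes_beyond_the_normal_threshold(self):
        # |BD|/SE = 2.0, alpha = 0.05: Phi(2.0) = 0.977 > 0.975
        d = pooled_decision(pooled_bias([vote("a", "B", 0.4, 0.2)]), 0.05, self.coin)
        assert d.intervened and d.favored_arm == "B"
        assert d.prob_A == pytest.approx(0.3)

    def test_zero_bd_never_intervenes(self):
        d = pooled_decision(pooled_bias([vote("a", "abstain", 0.4, 0.2)]), 0.99, self.coin)
        assert not d.intervened and d.prob_A == 0.5

    def test_negative_bd_favors_arm_a(self):
        d = pooled_decision(pooled_bias([vote("a", "A", 0.3, 0.1)]), 0.05, self.coin)
        assert d.intervened and d.favored_arm == "A"
        assert d.prob_A == pytest.approx(0.7)

    def test_linear_coin_uses_bd_magnitude(self):
        d = pooled_decision(pooled_bias([vote("a", "A", 0.3, 0.1)]), 0.05,
                            CoinSpec("linear", slope=1.0))
        assert d.prob_A == pytest.approx(0.8)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            pooled_decision(pooled_bias([vote("a", "A", 0.3, 0.1)]), 1.5, self.coin)


class TestVotingDecisions:
    coin = CoinSpec("static", 0.9)

    def test_strict_majority_wins(self):
        votes = [vote("a", "A", 0.2, 0.1), vote("b", "A", 0.2, 0.1), vote("c", "B", 0.2, 0.1)]
        d = majority_vote_decision(votes, 0.05, self.coin)
        assert d.intervened and d.favored_arm == "A" and d.prob_A == pytest.approx(0.9)

    def test_tied_votes_do_not_intervene(self):
        votes = [vote("a", "A", 0.2, 0.1), vote("b", "B", 0.2, 0.1)]
        assert not majority_vote_decision(votes, 0.05, self.coin).intervened

    def test_nonsignificant_leanings_are_ignored(self):
        votes = [vote(f"c{i}", "A", 0.2, 0.1, significant=False) for i in range(4)]
        assert not majority_vote_decision(votes, 0.05, self.coin).intervened

    def test_weighted_voting_lets_one_heavy_vote_overrule(self):
        votes = [vote("big", "B", 0.6, 0.1), vote("s1", "A", 0.2, 0.1), vote("s2", "A", 0.2, 0.1)]
        d = weighted_vote_decision(votes, 0.05, self.coin)
        assert d.intervened and d.favored_arm == "B"
        # same votes under simple majority go the other way
        assert majority_vote_decision(votes, 0.05, self.coin).favored_arm == "A"

    def test_weighted_tie_abstains(self):
        votes = [vote("a", "A", 0.3, 0.1), vote("b", "B", 0.3, 0.1)]
        assert not weighted_vote_decision(votes, 0.05, self.coin).intervened

    def test_weighted_dynamic_coin_magnitude(self):
        # x_A = 0.5, x_B = 0.1, s = 1: xi = 0.5 + 0.4 = 0.9 toward A
        votes = [vote("a", "A", 0.5, 0.1), vote("b", "B", 0.1, 0.1)]
        d = weighted_vote_decision(votes, 0.05, CoinSpec("linear", slope=1.0))
        assert d.favored_arm == "A"
        assert d.prob_A == pytest.approx(0.9)


class TestCovariateVote:
    def _state(self, a_vals, b_vals, cov):
        state = TrialState([cov])
        for v in a_vals:
            state.add({cov.name: v}, "A")
        for v in b_vals:
            state.add({cov.name: v}, "B")
        return state

    def test_numeric_vote_reduces_prospective_imbalance(self):
        cov = Covariate("x", "numeric")
        state = self._state([1, 2, 3], [4, 5, 6], cov)
        v = covariate_vote(state, cov, 6, alpha=0.05)
        assert v.direction == "A"  # high value repairs the low-valued arm
        # brute-force prospective check
        pc_a = pairwise_counts([1, 2, 3, 6], [4, 5, 6])
        pc_b = pairwise_counts([1, 2, 3], [4, 5, 6, 6])
        pa = abs(wmw_log_odds_from_u(pc_a.wins + pc_a.ties / 2, 4, 3)[0])
        pb = abs(wmw_log_odds_from_u(pc_b.wins + pc_b.ties / 2, 3, 4)[0])
        assert v.prospective_abs_A == pytest.approx(pa)
        assert v.prospective_abs_B == pytest.approx(pb)
        assert pa < pb

    def test_symmetric_value_abstains(self):
        cov = Covariate("x", "numeric")
        state = self._state([1, 2, 3], [1, 2, 3], cov)
        assert covariate_vote(state, cov, 2, alpha=0.05).direction == "abstain"

    def test_nominal_vote_uses_own_category_dummy(self):
        """Imbalance on other categories is invisible to the incoming patient."""
        cov = Covariate("occ", "nominal", categories=("ICA", "M1", "M2"))
        # ICA/M1 heavily imbalanced, M2 evenly split
        state = self._state(["ICA"] * 4 + ["M2"], ["M1"] * 4 + ["M2"], cov)
        v = covariate_vote(state, cov, "M2", alpha=0.05)
        assert v.direction == "abstain"
        assert covariate_vote(state, cov, "ICA", alpha=0.05).direction == "B"

    def test_too_few_observations_abstains(self):
        cov = Covariate("x", "numeric")
        state = self._state([1.0], [2.0, 3.0], cov)
        v = covariate_vote(state, cov, 1.5, alpha=0.05)
        assert not v.eligible and v.direction == "abstain"

    def test_missing_incoming_value_abstains(self):
        cov = Covariate("x", "numeric")
        state = self._state([1, 2, 3], [4, 5, 6], cov)
        assert not covariate_vote(state, cov, float("nan"), alpha=0.05).eligible


def test_label_symmetry_mirrors_decision(mixed_covariates):
    """Swapping the arm labels negates BD and mirrors prob_A."""
    from conftest import make_mixed_stream

    rng = np.random.default_rng(4)
    stream = make_mixed_stream(40, rng)
    cfg = RandomizerConfig("csmsb", "pooled", CoinSpec("static", 0.8), 0.4,
                           mixed_covariates)
    state = TrialState(list(mixed_covariates))
    flipped = TrialState(list(mixed_covariates))
    arms = rng.choice(["A", "B"], 39)
    for i in range(39):
        rec = stream.iloc[i].to_dict()
        state.add(rec, arms[i])
        flipped.add(rec, "B" if arms[i] == "A" else "A")
    patient = stream.iloc[39].to_dict()
    d = decide_allocation(state, patient, cfg)
    m = decide_allocation(flipped, patient, cfg)
    assert m.prob_A == pytest.approx(1.0 - d.prob_A)
    assert m.intervened == d.intervened
    if d.intervened:
        assert m.evidence.bd == pytest.approx(-d.evidence.bd)


def test_single_covariate_pooled_and_majority_agree():
    """With one covariate, the pooled rule intervenes exactly when the
    covariate's own WMW z-test is significant (and a direction exists)."""
    rng = np.random.default_rng(9)
    cov = Covariate("x", "numeric")
    coin = CoinSpec("static", 0.9)
    pooled_cfg = RandomizerConfig("csmsb", "pooled", coin, 0.2, (cov,))
    maj_cfg = RandomizerConfig("csmsb", "majority", coin, 0.2, (cov,))
    crit = sps.norm.ppf(1 - 0.2 / 2)
    checked = 0
    for _ in range(20):
        state = TrialState([cov])
        for _ in range(12):
            state.add({"x": rng.normal()}, rng.choice(["A", "B"]))
        patient = {"x": rng.normal()}
        v = covariate_vote(state, cov, patient["x"], 0.2)
        if not v.eligible or v.direction == "abstain":
            continue
        checked += 1
        dp = decide_allocation(state, patient, pooled_cfg)
        dm = decide_allocation(state, patient, maj_cfg)
        expected = abs(v.current_abs_log_imbalance / v.se_log) > crit
        assert dp.intervened == dm.intervened == expected
    assert checked > 5


class TestConfig:
    def test_yaml_round_trip_is_exact(self, mixed_covariates):
        cfg = RandomizerConfig("csmsb", "weighted", CoinSpec("linear", slope=3.7),
                               0.123456789012345, mixed_covariates, seed=42)
        assert RandomizerConfig.from_yaml(cfg.to_yaml()) == cfg
        assert RandomizerConfig.from_json(cfg.to_json()) == cfg

    def test_classic_msb_constraints(self, mixed_covariates):
        with pytest.raises(ValueError):
            RandomizerConfig("msb", "pooled", CoinSpec("static", 0.9), 0.05, mixed_covariates)
        with pytest.raises(ValueError):
            RandomizerConfig("msb", "majority", CoinSpec("linear", slope=1), 0.05, mixed_covariates)

    def test_covariate_validation(self):
        with pytest.raises(ValueError):
            Covariate("x", "numeric", weight=0.0)
        with pytest.raises(ValueError):
            Covariate("x", "nominal", categories=())
        with pytest.raises(ValueError):
            Covariate("x", "shoe_size")
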