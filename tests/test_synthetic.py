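"""Synthetic populations, counterfactual outcomes, named fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from csmsb.synthetic import (
    CounterfactualOutcomes,
    CovariateSpec,
    OutcomeModel,
    generate_covariates,
    knn_counterfactuals,
    make_trial_fixture,
    sample_outcome,
    sample_outcomes,
)

AGE = CovariateSpec("age", "numeric", median=76, q25=64, q75=81)
SEX = CovariateSpec("sex", "binary", categories=("f", "m"), probs=(0.863, 0.137))


class TestGenerateCovariates:
    def test_binary_proportions_match_at_large_n(self):
        df = generate_covariates([SEX], 10_000, seed=1)
        assert (df["sex"] == "f").mean() == pytest.approx(0.863, abs=0.02)

    def test_numeric_quartiles_match_targets(self):
        df = generate_covariates([AGE], 40_000, seed=2)
        q25, med, q75 = np.percentile(df["age"], [25, 50, 75])
        assert med == pytest.approx(76, abs=1.0)
        assert q25 == pytest.approx(64, abs=1.5)
        assert q75 == pytest.approx(81, abs=1.5)

    def test_right_skewed_target_also_matches(self):
        spec = CovariateSpec("nihss", "numeric", median=11, q25=7, q75=17)
        df = generate_covariates([spec], 40_000, seed=3)
        q25, med, q75 = np.percentile(df["nihss"], [25, 50, 75])
        assert med == pytest.approx(11, abs=0.5)
        assert q25 == pytest.approx(7, abs=0.8)
        assert q75 == pytest.approx(17, abs=0.8)

    def test_single_record_fully_populated(self):
        df = generate_covariates([AGE, SEX], 1, seed=4)
        assert len(df) == 1 and not df.isna().any().any()

    def test_seed_reproducibility(self):
        a = generate_covariates([AGE, SEX], 50, seed=5)
        b = generate_covariates([AGE, SEX], 50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="quartiles"):
            CovariateSpec("bad", "numeric", median=5, q25=7, q75=9)
        with pytest.raises(ValueError, match="categories"):
            CovariateSpec("bad", "binary", categories=(), probs=())


def _hand_knn_setup():
    """Six training patients on one numeric covariate, easy hand distances."""
    spec = CovariateSpec("x", "numeric", median=0, q25=-1, q75=1)
    train = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
    arms = np.array(["A", "A", "A", "B", "B", "B"])
    mrs = np.array([0, 1, 2, 3, 4, 5])
    return spec, train, arms, mrs


class TestKnnCounterfactuals:
    def test_k1_returns_nearest_neighbor_point_mass(self):
        spec, train, arms, mrs = _hand_knn_setup()
        query = pd.DataFrame({"x": [2.9]})
        cf = knn_counterfactuals(train, arms, mrs, query, [spec], k=1)
        assert cf.control[0, 3] == 1.0  # nearest control has mRS 3
        assert cf.treatment[0, 2] == 1.0  # nearest treated has mRS 2

    def test_exact_match_dominates(self):
        spec, train, arms, mrs = _hand_knn_setup()
        query = pd.DataFrame({"x": [3.0]})
        cf = knn_counterfactuals(train, arms, mrs, query, [spec], k=3)
        assert cf.null[0, 3] == 1.0  # zero-distance neighbor takes all weight

    def test_inverse_distance_weights_match_hand_arithmetic(self):
        spec, train, arms, mrs = _hand_knn_setup()
        query = pd.DataFrame({"x": [2.5]})
        cf = knn_counterfactuals(train, arms, mrs, query, [spec], k=3)
        # standardized scale divides by the sd of the combined 7 values;
        # inverse-distance weights are scale-free for equal raw gaps
        # null: 3 nearest of all are x = 2 (d=.5), 3 (d=.5), 1 or 4 (d=1.5)
        # sklearn breaks the distance tie deterministically toward index order
        w = np.array([1 / 0.5, 1 / 0.5, 1 / 1.5])
        w /= w.sum()
        assert cf.null[0, 2] == pytest.approx(w[0])
        assert cf.null[0, 3] == pytest.approx(w[1])
        # treatment subset: neighbors x=2 (d=.5), x=1 (d=1.5), x=0 (d=2.5)
        wt = np.array([1 / 0.5, 1 / 1.5, 1 / 2.5])
        wt /= wt.sum()
        assert cf.treatment[0, 2] == pytest.approx(wt[0])
        assert cf.treatment[0, 1] == pytest.approx(wt[1])
        assert cf.treatment[0, 0] == pytest.approx(wt[2])

    def test_uniform_weights_with_full_k_give_marginal(self):
        spec, train, arms, mrs = _hand_knn_setup()
        query = pd.DataFrame({"x": [1.7, 4.2]})
        cf = knn_counterfactuals(train, arms, mrs, query, [spec], k=3,
                                 weighting="uniform")
        # k equals each arm's size: the arm-specific marginal (1/3 each)
        np.testing.assert_allclose(cf.treatment[:, :3], 1 / 3)
        np.testing.assert_allclose(cf.control[:, 3:6], 1 / 3)

    def test_k_larger_than_subset_rejected(self):
        spec, train, arms, mrs = _hand_knn_setup()
        with pytest.raises(ValueError, match="k="):
            knn_counterfactuals(train, arms, mrs, train, [spec], k=4)

    def test_vectors_sum_to_one(self, tnk1_fixture):
        cf = tnk1_fixture.counterfactuals
        for v in (cf.treatment, cf.control, cf.null):
            np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-9)


class TestSampleOutcome:
    def test_degenerate_vector_is_deterministic(self):
        point = np.zeros((3, 7))
        point[:, 0] = 1.0
        cf = CounterfactualOutcomes(point, point.copy(), point.copy())
        draws = sample_outcome(cf, "effect", ["A", "B", "A"], seed=0)
        assert (draws == 0).all()

    def test_null_scenario_ignores_arm(self):
        rng = np.random.default_rng(0)
        vec = rng.dirichlet(np.ones(7), 50)
        cf = CounterfactualOutcomes(np.roll(vec, 1, axis=1), vec, vec)
        u = rng.random(50)
        a = sample_outcomes(cf, "null", ["A"] * 50, u)
        b = sample_outcomes(cf, "null", ["B"] * 50, u)
        np.testing.assert_array_equal(a, b)

    def test_null_draws_are_arm_independent(self):
        """Chi-square of outcome-by-arm under the null is non-significant."""
        rng = np.random.default_rng(1)
        n = 10_000
        vec = np.tile(rng.dirichlet(np.ones(7) * 3), (n, 1))
        cf = CounterfactualOutcomes(vec.copy(), vec.copy(), vec)
        arm = rng.random(n) < 0.5
        draws = sample_outcome(cf, "null", arm, seed=2)
        table = np.array([np.bincount(draws[arm], minlength=7),
                          np.bincount(draws[~arm], minlength=7)])
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.001

    def test_empirical_frequencies_match_vector(self):
        rng = np.random.default_rng(3)
        v = np.array([0.3, 0.05, 0.15, 0.1, 0.2, 0.05, 0.15])
        cf = CounterfactualOutcomes(*(np.tile(v, (20_000, 1)) for _ in range(3)))
        draws = sample_outcome(cf, "null", ["A"] * 20_000, seed=4)
        freq = np.bincount(draws, minlength=7) / 20_000
        np.testing.assert_allclose(freq, v, atol=0.01)

    def test_unknown_scenario_rejected(self):
        vec = np.full((1, 7), 1 / 7)
        cf = CounterfactualOutcomes(vec, vec.copy(), vec.copy())
        with pytest.raises(ValueError, match="scenario"):
            sample_outcome(cf, "sideways", ["A"], seed=0)


class TestFixtures:
    def test_tnk1_covariate_structure(self, tnk1_fixture):
        kinds = {c.name: c.kind for c in tnk1_fixture.covariates}
        assert kinds == {"age": "numeric", "nihss": "numeric", "occlusion": "nominal"}
        cats = {c.name: c.categories for c in tnk1_fixture.covariates}["occlusion"]
        assert len(cats) == 3

    def test_extendia_default_size(self):
        fx = make_trial_fixture("extendia_like", seed=0, k=5)
        assert len(fx) == 70

    def test_same_seed_identical_fixture(self):
        a = make_trial_fixture("tnk2_like", n=60, seed=9, k=5)
        b = make_trial_fixture("tnk2_like", n=60, seed=9, k=5)
        pd.testing.assert_frame_equal(a.stream, b.stream)
        np.testing.assert_array_equal(a.counterfactuals.null, b.counterfactuals.null)
        np.testing.assert_array_equal(a.source_mrs, b.source_mrs)

    def test_unknown_fixture_name(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_trial_fixture("phase4_like")

    def test_treatment_improves_outcomes_in_source_model(self, tnk1_fixture):
        """The counterfactual treatment vectors carry a benefit (lower mRS)."""
        cf = tnk1_fixture.counterfactuals
        mean_t = (cf.treatment * np.arange(7)).sum(axis=1).mean()
        mean_c = (cf.control * np.arange(7)).sum(axis=1).mean()
        assert mean_t < mean_c


def test_outcome_model_probabilities_shift_with_treatment():
    spec = CovariateSpec("age", "numeric", median=70, q25=60, q75=80, coef=0.5)
    model = OutcomeModel(specs=(spec,), treatment_log_or=0.8)
    stream = pd.DataFrame({"age": [70.0]})
    p_treat = model.level_probs(stream, [1])[0]
    p_ctrl = model.level_probs(stream, [0])[0]
    assert p_treat.sum() == pytest.approx(1.0)
    # cumulative odds ratio equals exp(tau) at every cutpoint
    for j in range(6):
        ct, cc = p_treat[: j + 1].sum(), p_ctrl[: j + 1].sum()
        orr = (ct / (1 - ct)) / (cc / (1 - cc))
        assert orr == pytest.approx(np.exp(0.8), rel=1e-9)
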