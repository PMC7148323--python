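import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from twasim import (
    BMIPredictor,
    get_cohort,
    SelectionWeights,
    decile_weights,
    draw_biased_sample,
    fit_bmi_predictor,
    ipw_estimated,
    ipw_known,
    population_deciles,
    random_sample_split,
    sample_reference_bmi,
    selection_probabilities,
    stage_one,
)
from twasim.cohorts import ReferenceBMISample


class TestPopulationDeciles:
    def test_equal_frequency_bins(self):
        cuts = population_deciles(np.arange(1.0, 101.0))
        assert np.all(np.diff(cuts) >= 0)
        counts = np.bincount(np.digitize(np.arange(1.0, 101.0), cuts), minlength=10)
        np.testing.assert_array_equal(counts, np.full(10, 10))

    def test_requires_ten_distinct_values(self):
        with pytest.raises(ValueError):
            population_deciles(np.repeat([1.0, 2.0, 3.0], 10))

    def test_lognormal_quantile_consistency(self, rng):
        """Empirical cuts agree with theoretical lognormal deciles."""
        x = np.exp(rng.standard_normal(100_000))
        cuts = population_deciles(x)
        theo = stats.lognorm(s=1).ppf(np.arange(1, 10) / 10)
        np.testing.assert_allclose(np.log(cuts), np.log(theo), atol=0.02)


class TestDecileWeights:
    def test_self_reference_is_uniform(self, rng):
        pop = rng.normal(28, 5, 10_000)
        cuts = population_deciles(pop)
        w = decile_weights(pop, cuts)
        np.testing.assert_allclose(w, 0.1, atol=0.01)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mass_below_first_cut(self):
        cuts = np.arange(10.0, 19.0)
        w = decile_weights(np.full(7, 5.0), cuts)
        np.testing.assert_allclose(w, [1, 0, 0, 0, 0, 0, 0, 0, 0, 0])

    def test_hand_count(self):
        cuts = np.arange(10.0, 19.0)  # deciles [., 10), [10, 11), ...
        ref = np.concatenate([np.full(5, 9.5), np.full(5, 10.5),
                              np.full(5, 11.5), np.full(5, 12.5)])
        w = decile_weights(ref, cuts)
        np.testing.assert_allclose(w, [0.25, 0.25, 0.25, 0.25, 0, 0, 0, 0, 0, 0])


class TestSelectionProbabilities:
    def test_hand_normalization(self):
        # 20 individuals, 2 per decile; all reference mass in decile 1
        pop = np.repeat(np.arange(10.0), 2) + 0.5
        cuts = np.arange(1.0, 10.0)
        w = np.zeros(10)
        w[0] = 1.0
        p = selection_probabilities(pop, w, cuts)
        np.testing.assert_allclose(np.sort(p)[-2:], [0.5, 0.5])
        assert np.count_nonzero(p) == 2

    def test_uniform_weights_give_uniform_p(self):
        pop = np.repeat(np.arange(10.0), 3) + 0.5
        cuts = np.arange(1.0, 10.0)
        p = selection_probabilities(pop, np.full(10, 0.1), cuts)
        np.testing.assert_allclose(p, 1.0 / 30, atol=1e-12)

    def test_normalization_contract(self, small_population):
        ref = sample_reference_bmi(
            get_cohort("GTEx", "women"), seed=3
        )
        sw = SelectionWeights.from_reference(small_population.bmi, ref.bmi, "GTEx")
        assert sw.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert sw.w.sum() == pytest.approx(1.0, abs=1e-9)
        # every individual in one decile shares the same probability
        dec = np.digitize(small_population.bmi, sw.decile_cuts)
        for k in range(10):
            vals = np.unique(sw.p[dec == k])
            assert vals.size <= 1

    def test_all_zero_weights_error(self):
        pop = np.linspace(1, 2, 50)
        cuts = population_deciles(pop)
        with pytest.raises(ValueError, match="zero"):
            selection_probabilities(pop, np.zeros(10), cuts)


class TestBiasedDraws:
    def test_degenerate_p(self):
        p = np.zeros(5)
        p[3] = 1.0
        s = draw_biased_sample(p, 100, seed=0)
        assert np.all(s.indices == 3)
        np.testing.assert_allclose(s.p_at_draw, 1.0)

    def test_multinomial_frequency_oracle(self, rng):
        p = rng.dirichlet(np.ones(50))
        s = draw_biased_sample(p, 1_000_000, seed=1)
        freq = np.bincount(s.indices, minlength=50) / 1e6
        se = np.sqrt(p * (1 - p) / 1e6)
        assert np.all(np.abs(freq - p) < 4 * se + 1e-9)

    def test_deterministic(self):
        p = np.full(100, 0.01)
        a = draw_biased_sample(p, 500, seed=9)
        b = draw_biased_sample(p, 500, seed=9)
        np.testing.assert_array_equal(a.indices, b.indices)


class TestRandomSplit:
    def test_sizes_disjoint_union(self):
        d1, d2 = random_sample_split(100_000, seed=5)
        assert len(d1) == 750 and len(d2) == 1500
        assert d1.scheme == d2.scheme == "random"
        combined = np.concatenate([d1.indices, d2.indices])
        assert np.unique(combined).size == 2250

    def test_insufficient_population(self):
        with pytest.raises(ValueError):
            random_sample_split(1000, 750, 1500)


class TestIPWKnown:
    def test_reciprocal(self):
        s = draw_biased_sample(np.array([0.5, 0.25, 0.25]), 3, seed=0)
        np.testing.assert_allclose(ipw_known(s), 1.0 / s.p_at_draw)
        assert np.all(np.isfinite(ipw_known(s))) and np.all(ipw_known(s) > 0)

    def test_requires_weighted_sample(self):
        d1, _ = random_sample_split(5000, 50, 100, seed=1)
        with pytest.raises(ValueError):
            ipw_known(d1)

    def test_constant_weights_reduce_to_unweighted(self, small_population):
        """Uniform selection probabilities: the IPW stage-1 fit must equal
        the unweighted fit exactly."""
        pop = small_population
        p = np.full(pop.size, 1.0 / pop.size)
        s = draw_biased_sample(p, 750, seed=2)
        w = ipw_known(s)
        fit_w = stage_one(pop.z[s.indices], pop.x[s.indices], w)
        fit_u = stage_one(pop.z[s.indices], pop.x[s.indices])
        np.testing.assert_allclose(fit_w.coef, fit_u.coef, atol=1e-10)


class TestBMIPredictor:
    def test_noiseless_linear_recovery(self, rng):
        weight = rng.uniform(50, 120, 200)
        age = rng.uniform(21, 70, 200)
        bmi = 5 + 0.3 * weight
        ref = ReferenceBMISample(
            bmi=bmi, age=age, weight=weight, height=np.sqrt(weight / bmi),
            spec=None,
        )
        fit = fit_bmi_predictor(ref)
        assert fit.intercept == pytest.approx(5.0, abs=1e-8)
        assert fit.weight == pytest.approx(0.3, abs=1e-8)
        assert fit.age == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels(self, nhanes_women):
        ref = sample_reference_bmi(nhanes_women, seed=11)
        fit = fit_bmi_predictor(ref)
        X = sm.add_constant(np.column_stack([ref.age, ref.weight]))
        sm_fit = sm.OLS(ref.bmi, X).fit()
        np.testing.assert_allclose(
            [fit.intercept, fit.age, fit.weight], sm_fit.params, atol=1e-8
        )

    def test_rank_deficiency_error(self):
        ref = ReferenceBMISample(
            bmi=np.array([20.0, 25.0, 30.0]),
            age=np.full(3, 40.0),
            weight=np.full(3, 70.0),
            height=np.full(3, 1.7),
            spec=None,
        )
        with pytest.raises(ValueError, match="rank"):
            fit_bmi_predictor(ref)

    def test_out_of_sample_r2(self, nhanes_women):
        train = sample_reference_bmi(nhanes_women, size=10_000, seed=21)
        test = sample_reference_bmi(nhanes_women, size=10_000, seed=22)
        fit = fit_bmi_predictor(train)
        pred = fit.predict(test.age, test.weight)
        r2 = 1 - np.var(test.bmi - pred) / np.var(test.bmi)
        assert 0.60 <= r2 <= 0.95


class TestIPWEstimated:
    @pytest.fixture()
    def gtex_selection(self, small_population):
        ref = sample_reference_bmi(
            get_cohort("GTEx", "women"), seed=31
        )
        return SelectionWeights.from_reference(small_population.bmi, ref.bmi, "GTEx")

    def test_perfect_predictor_reduces_to_known(self, small_population, gtex_selection):
        """A predictor that reproduces observed BMI exactly yields the known
        weights (height held fixed makes BMI exactly linear in weight)."""
        pop = small_population
        s = draw_biased_sample(gtex_selection, 750, seed=32)
        h = 1.65
        weight = pop.bmi[s.indices] * h**2
        age = np.linspace(21, 70, 750)
        predictor = BMIPredictor(intercept=0.0, age=0.0, weight=1.0 / h**2)
        west = ipw_estimated(age, weight, predictor, gtex_selection)
        np.testing.assert_allclose(west, ipw_known(s), rtol=1e-9)

    def test_same_predicted_decile_same_weight(self, gtex_selection):
        predictor = BMIPredictor(intercept=0.0, age=0.0, weight=1.0)
        cuts = gtex_selection.decile_cuts
        inside = 0.5 * (cuts[3] + cuts[4])  # two BMIs inside decile 4
        w = ipw_estimated(
            np.array([30.0, 60.0]),
            np.array([inside, inside + 1e-6]),
            predictor,
            gtex_selection,
        )
        assert w[0] == w[1]

    def test_zero_weight_decile_gets_capped_fallback(self, small_population):
        # reference occupies only the bottom decile; predictions elsewhere
        # must receive the capped (max finite) weight, not infinity
        pop = small_population
        lo = np.quantile(pop.bmi, 0.05)
        sw = SelectionWeights.from_reference(pop.bmi, np.full(50, lo), "low")
        predictor = BMIPredictor(intercept=0.0, age=0.0, weight=1.0)
        w = ipw_estimated(
            np.array([40.0, 40.0]),
            np.array([lo, np.quantile(pop.bmi, 0.95)]),
            predictor,
            sw,
        )
        assert np.isfinite(w).all()
        assert w[1] == w[0]  # fallback equals 1/min positive probability

    def test_estimated_tracks_known_weights(self, small_population, gtex_selection):
        """Estimated weights must track the known ones: predicted BMI is
        highly correlated with true BMI, most individuals land within one
        decile of their true decile, and a sizeable fraction get exactly the
        known weight.  The Spearman correlation between estimated and known
        weights is positive but modest, because the reciprocal of a
        hump-shaped decile weight profile is not monotone in BMI, so
        off-by-one decile errors can flip ranks."""
        pop = small_population
        s = draw_biased_sample(gtex_selection, 750, seed=33)
        nh = sample_reference_bmi(get_cohort("NHANES", "women"), seed=34)
        predictor = fit_bmi_predictor(nh)
        pred_bmi = predictor.predict(pop.age[s.indices], pop.weight[s.indices])
        true_bmi = pop.bmi[s.indices]
        assert np.corrcoef(pred_bmi, true_bmi)[0, 1] > 0.8
        dec_true = np.digitize(true_bmi, gtex_selection.decile_cuts)
        dec_pred = np.digitize(pred_bmi, gtex_selection.decile_cuts)
        assert np.mean(np.abs(dec_true - dec_pred) <= 1) > 0.75
        west = ipw_estimated(
            pop.age[s.indices], pop.weight[s.indices], predictor, gtex_selection
        )
        wk = ipw_known(s)
        assert np.mean(np.isclose(west, wk)) > 0.25
        assert stats.spearmanr(west, wk).statistic > 0.2


def test_monotone_targeting(small_population, rng):
    """Shifting the reference cohort's mass toward lower BMI strictly lowers
    the mean BMI of the drawn samples."""
    pop = small_population
    means = []
    for lo, hi in [(26, 34), (22, 30), (18, 26)]:
        ref = rng.uniform(lo, hi, 1000)
        sw = SelectionWeights.from_reference(pop.bmi, ref, f"u[{lo},{hi}]")
        s = draw_biased_sample(sw, 2000, seed=40)
        means.append(pop.bmi[s.indices].mean())
    assert means[0] > means[1] > means[2]
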