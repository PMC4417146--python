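import numpy as np
import pandas as pd
import pytest

import invkit as ik
from invkit.assoc import mendelian_consistent


class TestMendelian:
    @pytest.mark.parametrize("fa, mo, child, ok", [
        (0, 2, 1, True), (0, 2, 0, False), (0, 2, 2, False),
        (1, 1, 0, True), (1, 1, 1, True), (1, 1, 2, True),
        (0, 0, 0, True), (0, 0, 1, False), (2, 2, 2, True), (2, 2, 1, False),
        (0, 1, 1, True), (0, 1, 2, False), (1, 2, 0, False), (1, 2, 2, True),
    ])
    def test_transmission_table(self, fa, mo, child, ok):
        assert mendelian_consistent(fa, mo, child) is ok

    def test_uncalled_members_excluded(self):
        labels = np.array(["NN", "II", "uncalled", "NN", "NN", "NN"], dtype=object)
        ids = ["f1", "m1", "c1", "f2", "m2", "c2"]
        ped = pd.DataFrame({"child": ["c1", "c2"], "father": ["f1", "f2"],
                            "mother": ["m1", "m2"]})
        frac, per = ik.mendelian_consistency(labels, ped, sample_ids=ids)
        assert per["consistent"].notna().sum() == 1  # trio 1 dropped
        assert frac == 1.0

    def test_no_trios_errors(self):
        ped = pd.DataFrame({"child": [], "father": [], "mother": []})
        with pytest.raises(ValueError, match="no complete trios"):
            ik.mendelian_consistency(np.array(["NN"], dtype=object), ped, sample_ids=["x"])

    def test_simulated_trios_consistency(self, trio_cohort):
        gm, truth, calls = trio_cohort
        frac, _ = ik.mendelian_consistency(calls, gm.trios())
        assert frac >= 0.99


class TestConcordance:
    def test_identical_is_perfect(self):
        lab = np.array(["NN", "NI", "II"] * 10, dtype=object)
        rep = ik.concordance(lab, lab)
        assert rep.accuracy == 1.0 and rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_72_of_74(self):
        # one heterozygote miscalled twice out of 74 -> accuracy 72/74
        ref = np.array(["NN"] * 20 + ["NI"] * 34 + ["II"] * 20, dtype=object)
        called = ref.copy()
        called[20] = "NN"
        called[21] = "NN"
        rep = ik.concordance(called, ref)
        assert rep.accuracy == pytest.approx(72 / 74)
        assert rep.n_compared == 74
        assert rep.confusion.loc["NI", "NN"] == 2

    def test_matches_direct_count(self, separable_fit):
        _, fit, truth = separable_fit
        calls = ik.call_genotypes(fit, call_threshold=0.0)
        from conftest import flip_labels, oriented_accuracy
        acc, flipped = oriented_accuracy(calls.labels, truth.genotypes)
        labels = flip_labels(calls.labels) if flipped else calls.labels
        rep = ik.concordance(labels, truth.genotypes)
        assert rep.accuracy == pytest.approx(acc)

    def test_zero_overlap_errors(self):
        with pytest.raises(ValueError, match="zero overlapping"):
            ik.concordance(np.array(["uncalled"], dtype=object),
                           np.array(["NN"], dtype=object))


class TestPercentileCases:
    def test_linear_quantile_hand_computation(self):
        # 1..100 at the 5th percentile: threshold 5.95, strict-below cases 1..5
        out = ik.define_cases_percentile(np.arange(1.0, 101.0), pct=5)
        assert out.sum() == 5
        assert out[:5].all() and not out[5:].any()

    def test_zero_percentile_no_cases(self):
        out = ik.define_cases_percentile(np.arange(1.0, 101.0), pct=0)
        assert out.sum() == 0

    def test_constant_trait_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ik.define_cases_percentile(np.ones(30), pct=5)

    def test_ties_at_threshold_are_controls(self):
        # n=101 puts the 5th-percentile threshold exactly on the value 6.0;
        # the tied individual at the threshold stays a control
        x = np.arange(1.0, 102.0)
        out = ik.define_cases_percentile(x, pct=5)
        assert out.sum() == 5
        assert out[5] == 0


class TestGeneticModelTest:
    @staticmethod
    def counts_to_arrays(case_ii, case_other, ctrl_ii, ctrl_other):
        dose = np.array([2] * case_ii + [0] * case_other + [2] * ctrl_ii + [0] * ctrl_other)
        y = np.array([1] * (case_ii + case_other) + [0] * (ctrl_ii + ctrl_other))
        return dose, y

    def test_balanced_table_or_one(self):
        dose, y = self.counts_to_arrays(20, 30, 20, 30)
        res = ik.genetic_model_test(dose, y, model="recessive")
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_crude_or_matches_closed_form(self):
        dose, y = self.counts_to_arrays(30, 70, 20, 80)
        res = ik.genetic_model_test(dose, y, model="recessive")
        assert res.odds_ratio == pytest.approx((30 / 70) / (20 / 80), abs=1e-6)
        assert res.ci95_low < res.odds_ratio < res.ci95_high

    def test_codings(self):
        dose = np.array([0, 1, 2] * 40)
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=len(dose))
        for model in ("recessive", "dominant", "additive"):
            res = ik.genetic_model_test(dose, y, model=model)
            assert res.model == model and res.odds_ratio > 0

    def test_uncalled_dropped(self):
        labels = np.array(["II"] * 30 + ["NN"] * 70 + ["II"] * 20 + ["NN"] * 80
                          + ["uncalled"] * 5, dtype=object)
        y = np.array([1] * 100 + [0] * 100 + [1] * 5)
        res = ik.genetic_model_test(labels, y, model="recessive")
        assert res.n_cases == 100 and res.n_controls == 100
        assert res.odds_ratio == pytest.approx((30 / 70) / (20 / 80), abs=1e-6)

    def test_separation_flagged(self):
        dose, y = self.counts_to_arrays(50, 0, 0, 50)
        res = ik.genetic_model_test(dose, y, model="recessive")
        assert res.separation
        assert res.ci95_high == np.inf

    def test_too_few_cases_errors(self):
        dose, y = self.counts_to_arrays(2, 3, 50, 50)
        with pytest.raises(ValueError, match="cases"):
            ik.genetic_model_test(dose, y)

    def test_covariate_adjustment_runs(self):
        rng = np.random.default_rng(1)
        dose = rng.integers(0, 3, 400)
        cov = rng.normal(size=(400, 2))
        y = (rng.random(400) < 0.3).astype(int)
        res = ik.genetic_model_test(dose, y, covariates=cov, model="additive")
        assert res.covariates == ["cov1", "cov2"]


class TestStratifiedAndCombined:
    def test_single_stratum_equals_unstratified(self):
        dose = np.array([2] * 50 + [0] * 150)
        y = np.array([1] * 30 + [0] * 20 + [1] * 70 + [0] * 80)
        plain = ik.genetic_model_test(dose, y)
        strat = ik.stratified_association(dose, y, strata=np.zeros(200))
        assert len(strat) == 1
        assert strat[0].odds_ratio == pytest.approx(plain.odds_ratio, abs=1e-9)

    def test_effect_in_one_stratum(self):
        rng = np.random.default_rng(5)
        n = 4000
        strata = np.repeat([1, 2], n // 2)
        dose = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
        base = 0.15
        p = np.full(n, base)
        in1 = (strata == 1) & (dose == 2)
        p[in1] = base * 3 / (1 - base + base * 3)
        y = (rng.random(n) < p).astype(int)
        res = {r.stratum: r for r in
               ik.stratified_association(dose, y, strata=strata, model="recessive")}
        assert res["1"].odds_ratio > 1.8
        assert 0.6 < res["2"].odds_ratio < 1.5

    def test_sparse_stratum_skipped(self):
        dose = np.array([2] * 50 + [0] * 150)
        y = np.array([1] * 30 + [0] * 20 + [1] * 70 + [0] * 80)
        strata = np.array(["big"] * 195 + ["tiny"] * 5, dtype=object)
        with pytest.warns(UserWarning, match="skipped"):
            out = ik.stratified_association(dose, y, strata=strata)
        assert [r.stratum for r in out] == ["big"]

    def test_identical_studies_pool_exactly(self):
        r = ik.AssocResult(model="recessive", stratum="s", odds_ratio=2.0,
                           ci95_low=1.0, ci95_high=4.0, p_value=0.05,
                           n_cases=50, n_controls=50, covariates=[],
                           log_or=np.log(2), se=0.35)
        pooled = ik.combine_fixed_effect([r, r])
        assert pooled.odds_ratio == pytest.approx(2.0)
        assert pooled.se == pytest.approx(0.35 / np.sqrt(2))

    def test_hand_worked_two_study_pooling(self):
        # log-ORs 0.5128 (se 0.25) and 0.7419 (se 0.34): weights 16, 8.651
        b1, s1, b2, s2 = 0.5128, 0.25, 0.7419, 0.34
        w1, w2 = 1 / s1**2, 1 / s2**2
        expected = (w1 * b1 + w2 * b2) / (w1 + w2)
        mk = lambda b, s: ik.AssocResult("recessive", "x", float(np.exp(b)), 1, 10, 0.1,
                                         20, 20, [], b, s)
        pooled = ik.combine_fixed_effect([mk(b1, s1), mk(b2, s2)])
        assert pooled.log_or == pytest.approx(expected, abs=1e-12)
        assert pooled.se == pytest.approx(np.sqrt(1 / (w1 + w2)), abs=1e-12)

    def test_infinite_se_excluded(self):
        good = ik.AssocResult("recessive", "a", 2.0, 1.0, 4.0, 0.05, 20, 20, [],
                              np.log(2), 0.3)
        bad = ik.AssocResult("recessive", "b", 2.0, 0.0, np.inf, np.nan, 5, 5, [],
                             np.log(2), np.inf, separation=True)
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError, match="at least two"):
                ik.combine_fixed_effect([good, bad])


class TestPar:
    @pytest.mark.parametrize("or_, p, expected", [
        (1.0, 0.3, 0.0),
        (2.0, 0.0, 0.0),
        (2.0, 0.1, 0.1 / 1.1),
    ])
    def test_levin_formula(self, or_, p, expected):
        assert ik.population_attributable_risk(or_, p) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ik.population_attributable_risk(-1, 0.1)
        with pytest.raises(ValueError):
            ik.population_attributable_risk(2.0, 1.5)


class TestMultipleModels:
    def test_bonferroni(self):
        rng = np.random.default_rng(2)
        dose = rng.choice([0, 1, 2], size=300, p=[0.25, 0.5, 0.25])
        y = (rng.random(300) < 0.2).astype(int)
        out = ik.adjust_multiple_models(dose, y, method="bonferroni")
        assert np.all(out["p_adjusted"] >= out["p_raw"] - 1e-12)
        assert np.all(out["p_adjusted"] <= 1.0)

    def test_permutation_null_uniformish(self):
        rng = np.random.default_rng(3)
        dose = rng.choice([0, 1, 2], size=300, p=[0.25, 0.5, 0.25])
        y = (rng.random(300) < 0.2).astype(int)
        out = ik.adjust_multiple_models(dose, y, n_perm=60, seed=1, method="permutation")
        assert (out["p_adjusted"] > 0.01).all()
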