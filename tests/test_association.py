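"""Logistic score association, information for discrimination, the HLA risk
score, the case-only interaction test and the control-group correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import transcore as tc


def _null_score_and_outcome(rng, n=2_000):
    score = rng.normal(0, 1, n)
    outcome = rng.integers(0, 2, n)
    covs = rng.normal(0, 1, (n, 3))
    return score, outcome, covs


class TestInformationFormula:
    def test_zero_log_or_gives_zero(self):
        assert tc.information_for_discrimination(0.0) == 0.0

    def test_sign_invariance(self):
        assert tc.information_for_discrimination(0.23) \
            == tc.information_for_discrimination(-0.23)

    def test_sibling_risk_conversion(self):
        assert tc.total_information_from_sibling_risk(np.e) \
            == pytest.approx(1.0)


class TestFitScoreAssociation:
    def test_recovers_known_effect(self):
        rng = np.random.default_rng(0)
        n = 4_000
        score = rng.normal(0, 1, n)
        y = rng.random(n) < expit(-0.5 + 0.4 * score)
        res = tc.fit_score_association(score, y.astype(int))
        assert res.converged
        assert res.log_or == pytest.approx(0.4, abs=3 * res.se)
        assert res.info_discrimination == pytest.approx(res.log_or ** 2 / 2)

    def test_duplicated_covariate_flags_not_estimates(self):
        rng = np.random.default_rng(1)
        score, outcome, _ = _null_score_and_outcome(rng, 500)
        res = tc.fit_score_association(score, outcome,
                                       covariates=score.copy())
        assert not res.converged

    def test_separation_flagged(self):
        n = 80
        score = np.r_[np.full(40, -2.0), np.full(40, 2.0)]
        outcome = (score > 0).astype(int)
        res = tc.fit_score_association(score, outcome)
        assert not res.converged

    def test_wald_close_to_likelihood_ratio(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 2_000
        score = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(0.3 * score)).astype(int)
        res = tc.fit_score_association(score, y)
        x = sm.add_constant(score)
        full = sm.Logit(y, x).fit(disp=0)
        null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        lr_p = stats.chi2.sf(2 * (full.llf - null.llf), df=1)
        assert abs(np.log10(res.pvalue) - np.log10(lr_p)) < 1.0


class TestNullCalibration:
    def test_type_one_error_small(self):
        """Reduced-size null check; the full-size calibration lives in the
        acceptance suite."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            score, outcome, covs = _null_score_and_outcome(rng, 400)
            res = tc.fit_score_association(score, outcome, covs)
            pvals.append(res.pvalue)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert rate == pytest.approx(0.05, abs=0.05)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestPerSnpAssociation:
    def _study(self, dosages):
        n, m = dosages.shape
        variants = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(m)], "chrom": "1",
            "pos": [1_000_000 + 10_000 * i for i in range(m)],
            "effect_allele": "A", "other_allele": "G"})
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
        return tc.GenotypeMatrix(dosages.astype(float), variants, samples)

    def test_causal_snp_ranks_first(self):
        rng = np.random.default_rng(4)
        n = 3_000
        d = rng.binomial(2, 0.3, (n, 5))
        y = (rng.random(n) < expit(-0.3 + 0.6 * (d[:, 2] - 0.6))).astype(int)
        table = tc.per_snp_association(self._study(d), y)
        assert table.loc[table["pvalue"].idxmin(), "variant_id"] == "v2"

    def test_permuted_outcome_uniform_p(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.4, (500, 40))
        y = rng.permutation(np.r_[np.ones(250), np.zeros(250)]).astype(int)
        table = tc.per_snp_association(self._study(d), y)
        assert stats.kstest(table["pvalue"], "uniform").pvalue > 0.001

    def test_rare_snp_excluded(self):
        rng = np.random.default_rng(6)
        d = np.c_[rng.binomial(2, 0.003, 1_000), rng.binomial(2, 0.3, 1_000)]
        y = rng.integers(0, 2, 1_000)
        table = tc.per_snp_association(self._study(d), y)
        assert list(table["variant_id"]) == ["v1"]


class TestHLAScore:
    def _tags(self, rng, n):
        return rng.binomial(2, [0.3, 0.2, 0.4, 0.25, 0.35], size=(n, 5))

    def test_recovers_main_effect_weights(self):
        rng = np.random.default_rng(7)
        n = 6_000
        tags = self._tags(rng, n)
        truth = np.array([0.5, -0.4, 0.3, 0.0, 0.2])
        y = (rng.random(n) < expit(-0.5 + tags @ truth)).astype(int)
        model = tc.association.build_hla_score(tags, y)
        derived = model.derived_variables
        x = np.column_stack([np.ones(n), derived.to_numpy()])
        import statsmodels.api as sm
        fit = sm.Logit(y, x).fit(disp=0)
        se = fit.bse[1:6]
        got = model.weights[[f"tag{i+1}" for i in range(5)]].to_numpy()
        assert np.all(np.abs(got - truth) < 3 * se)

    def test_null_tags_give_uncorrelated_score_out_of_sample(self):
        # in-sample the fitted linear predictor overfits slightly, so the
        # null check is on held-out individuals
        rng = np.random.default_rng(8)
        n = 5_000
        est = tc.HLARiskScorer().fit(self._tags(rng, n),
                                     rng.integers(0, 2, n))
        tags_new = self._tags(rng, n)
        y_new = rng.integers(0, 2, n)
        r = np.corrcoef(est.transform(tags_new), y_new)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_constant_tag_dropped_with_refit(self):
        rng = np.random.default_rng(9)
        n = 2_000
        tags = self._tags(rng, n)
        tags[:, 3] = 1  # constant dosage column
        y = rng.integers(0, 2, n)
        model = tc.association.build_hla_score(tags, y)
        assert model.weights["tag4"] == 0.0
        assert model.derived_variables.shape[1] == 8

    def test_scorer_estimator_transform_matches_fit(self):
        rng = np.random.default_rng(10)
        tags = self._tags(rng, 1_000)
        y = rng.integers(0, 2, 1_000)
        est = tc.HLARiskScorer().fit(tags, y)
        np.testing.assert_allclose(est.transform(tags), est.model_.values)


class TestCaseOnlyInteraction:
    def test_all_control_mask_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            tc.case_only_interaction(rng.normal(size=100),
                                     rng.normal(size=100),
                                     np.zeros(100, dtype=bool))

    def test_null_under_multiplicative_model(self):
        """When trans and HLA scores act multiplicatively on odds (no
        interaction), are independent in the population and the disease is
        rare -- the stated validity conditions -- the case-only slope is null
        across replicates."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(40):
            n = 20_000
            t, h = rng.normal(0, 1, (2, n))
            y = rng.random(n) < expit(-4.0 + 0.5 * t + 0.8 * h)
            res = tc.case_only_interaction(t, h, y)
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_detects_positive_interaction(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(10):
            n = 4_000
            t, h = rng.normal(0, 1, (2, n))
            y = rng.random(n) < expit(-2.0 + 0.4 * t + 0.6 * h + 0.5 * t * h)
            res = tc.case_only_interaction(t, h, y)
            if res.pvalue < 0.05 and res.slope > 0:
                hits += 1
        assert hits >= 8


class TestScoreCorrelations:
    def test_self_correlation_flagged(self, pipe_config):
        rng = np.random.default_rng(14)
        s = rng.normal(0, 1, 200)
        scores = pd.DataFrame({"a": s, "b": rng.normal(0, 1, 200)})
        corr, flags = tc.score_correlation_matrix(
            scores, np.ones(200, dtype=bool), pipe_config)
        assert ("a", "a", 1.0) in [(x, y, round(r, 6)) for x, y, r in flags]

    def test_independent_scores_unflagged(self, pipe_config):
        rng = np.random.default_rng(15)
        n = 2_000
        scores = pd.DataFrame(rng.normal(0, 1, (n, 3)),
                              columns=["a", "b", "c"])
        corr, flags = tc.score_correlation_matrix(
            scores, np.ones(n, dtype=bool), pipe_config)
        off = [f for f in flags if f[0] != f[1]]
        assert off == []
        assert np.abs(corr.to_numpy()[~np.eye(3, dtype=bool)]).max() \
            < 3 / np.sqrt(n)

    def test_shared_loci_give_unit_correlation(self, pipe_config):
        rng = np.random.default_rng(16)
        base = rng.normal(0, 1, 300)
        scores = pd.DataFrame({"a": base, "b": -2.0 * base})
        corr, flags = tc.score_correlation_matrix(
            scores, np.ones(300, dtype=bool), pipe_config)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert any(x == "a" and y == "b" for x, y, _ in flags)
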