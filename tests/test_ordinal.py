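import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import neuromir as nm
from neuromir.ordinal import ProportionalOddsClassifier, drop_one_fits

from conftest import binary_logistic_oracle, random_binary_cohort

TERMS = "log(mir20b),apoe_e4,region,log(mir20b):apoe_e4"


class TestFit:
    def test_intercept_only_matches_observed_frequencies(self, small_cohort):
        """The cumulative-logit MLE with no predictors saturates the outcome
        margins: every fitted probability row equals the observed level
        frequencies."""
        fit = nm.fit_proportional_odds(small_cohort, nm.TermSpec([]))
        freqs = small_cohort["diagnosis"].value_counts(
            normalize=True, sort=False).to_numpy()
        np.testing.assert_allclose(fit.prob_matrix,
                                   np.tile(freqs, (len(small_cohort), 1)),
                                   atol=1e-6)

    def test_prob_matrix_rows_sum_to_one(self, small_cohort):
        fit = nm.fit_proportional_odds(small_cohort, TERMS)
        np.testing.assert_allclose(fit.prob_matrix.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert np.all((fit.prob_matrix > 0) & (fit.prob_matrix < 1))
        assert np.all(np.diff(fit.cutpoints) > 0)
        assert fit.loglik <= 0

    def test_affine_rescaling_invariance(self, small_cohort):
        """Rescaling a continuous predictor x -> (x - m)/s leaves the
        log-likelihood unchanged and multiplies its coefficient by s."""
        fit = nm.fit_proportional_odds(small_cohort, "mir20b,apoe_e4")
        scaled = small_cohort.assign(
            mir20b=(small_cohort["mir20b"] - 3.0) / 2.5)
        # shift makes some values negative; bypass the positivity check by
        # renaming the column
        scaled = scaled.rename(columns={"mir20b": "x"})
        fit2 = nm.fit_proportional_odds(scaled, "x,apoe_e4")
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
        assert fit2.coefficients["x"] == pytest.approx(
            2.5 * fit.coefficients["mir20b"], rel=1e-4)

    def test_absent_level_is_data_error(self, small_cohort):
        sub = small_cohort[small_cohort["diagnosis"] != "MCI"]
        with pytest.raises(nm.DataError):
            nm.fit_proportional_odds(sub, "log(mir20b)")

    def test_too_few_observations(self, small_cohort):
        with pytest.raises(nm.FitError):
            nm.fit_proportional_odds(small_cohort.head(4), TERMS)

    def test_binary_equivalence_with_independent_oracle(self):
        """K = 2 proportional odds is binary logistic regression; compare with
        an independently coded scipy MLE on random small datasets."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            cohort, X, y = random_binary_cohort(rng)
            fit = nm.fit_proportional_odds(cohort, "x1,x2")
            alpha, beta, ll = binary_logistic_oracle(X, y)
            assert fit.loglik == pytest.approx(ll, abs=1e-6)
            np.testing.assert_allclose(fit.coefficients.to_numpy(), beta,
                                       atol=1e-4)
            np.testing.assert_allclose(fit.cutpoints, [alpha], atol=1e-4)


class TestPredict:
    def test_closed_form_at_zero_eta(self):
        est = ProportionalOddsClassifier()
        est.cutpoints_ = np.array([-0.5, 0.5])
        est.coef_ = np.array([0.0])
        est.n_features_in_ = 1
        row = est._probabilities(np.array([[3.7]]))[0]
        np.testing.assert_allclose(
            row, [expit(-0.5), expit(0.5) - expit(-0.5), 1 - expit(0.5)],
            atol=1e-12)

    def test_limit_large_eta(self, small_cohort):
        fit = nm.fit_proportional_odds(small_cohort, "log(mir20b)")
        assert fit.coefficients["log(mir20b)"] > 0
        big = small_cohort.head(1).assign(mir20b=1e12)
        row = nm.predict_probabilities(fit, big)[0]
        np.testing.assert_allclose(row, [0.0, 0.0, 1.0], atol=1e-6)

    def test_training_data_consistency(self, small_cohort):
        fit = nm.fit_proportional_odds(small_cohort, TERMS)
        np.testing.assert_allclose(
            nm.predict_probabilities(fit, small_cohort), fit.prob_matrix,
            atol=1e-12)

    def test_missing_predictor_schema_error(self, small_cohort):
        fit = nm.fit_proportional_odds(small_cohort, TERMS)
        with pytest.raises(nm.SchemaError):
            nm.predict_probabilities(fit, small_cohort.drop(columns=["region"]))

    def test_sklearn_estimator_interface(self, small_cohort):
        """The classifier composes with sklearn tooling: get_params/set_params,
        predict over the ordered classes."""
        from sklearn.base import clone
        est = ProportionalOddsClassifier(maxiter=300)
        assert clone(est).get_params()["maxiter"] == 300
        X = np.log(small_cohort[["mir20b"]].to_numpy())
        est.fit(X, small_cohort["diagnosis"])
        assert list(est.classes_) == ["NCI", "MCI", "AD"]
        assert est.predict(X[:5]).shape == (5,)


class TestAnova:
    def test_chi2_nonnegative_and_marginality(self, small_cohort):
        tab = nm.likelihood_ratio_anova(small_cohort, TERMS)
        assert (tab["chi2"] >= 0).all()
        assert tab["error"].isna().all() or tab["error"].isnull().all()
        # dropping log(mir20b) also removes the interaction -> df = 2
        assert tab.set_index("term").loc["log(mir20b)", "df"] == 2
        assert tab.set_index("term").loc["log(mir20b):apoe_e4", "df"] == 1
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()

    def test_nested_loglik_ordering(self, small_cohort):
        full = nm.fit_proportional_odds(small_cohort, TERMS)
        for name, reduced, err in drop_one_fits(small_cohort, TERMS):
            assert err is None
            assert full.loglik >= reduced.loglik - 1e-8

    def test_duplicated_predictor_rank_error(self, small_cohort):
        dup = small_cohort.assign(mir_copy=small_cohort["mir20b"])
        with pytest.raises(nm.RankDeficiencyError):
            nm.fit_proportional_odds(dup, "mir20b,mir_copy")


def test_validate_cohort_names_offending_row(small_cohort):
    bad = small_cohort.copy()
    bad["diagnosis"] = bad["diagnosis"].astype(str)
    bad.loc[7, "diagnosis"] = "UNKNOWN"
    with pytest.raises(nm.SchemaError, match="row 7"):
        nm.validate_cohort(bad)
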