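"""Proportional-odds (cumulative-logit) ordinal regression of diagnosis severity.

The model is P(Y <= k | x) = logistic(alpha_k - x.beta) with cutpoints
alpha_1 < ... < alpha_{K-1} shared across observations, so a positive
coefficient shifts probability mass toward the worse end of the ordered
scale (NCI < MCI < AD).  Fitting is by maximum likelihood through
statsmodels' ``OrderedModel``, which uses the same sign convention and an
internal first-cutpoint-plus-log-gaps parameterization that guarantees
monotone cutpoints.

Two presentation layers are provided:

* :class:`ProportionalOddsClassifier` — a scikit-learn style estimator over
  numeric design matrices (``fit`` / ``predict_proba`` / ``predict``), usable
  inside sklearn pipelines and model selection.
* cohort-level functions (:func:`fit_proportional_odds`,
  :func:`predict_probabilities`, :func:`likelihood_ratio_anova`) that accept
  a subject table plus a :class:`~neuromir.terms.TermSpec` and handle
  encoding, validation and drop-one analysis of deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .exceptions import DataError, FitError, SchemaError
from .terms import TermSpec, build_design

#: Ordered diagnosis scale used throughout the brain-cohort analysis.
DIAGNOSIS_LEVELS = ("NCI", "MCI", "AD")

#: Default model terms: miR-20b on the log scale, APOE e4 carrier status,
#: brain region, and the miR-20b x e4 interaction.
DEFAULT_TERMS = "log(mir20b),apoe_e4,region,log(mir20b):apoe_e4"

_COHORT_COLUMNS = ("subject_id", "region", "mir20b", "apoe_e4", "age", "sex",
                   "diagnosis")


def validate_cohort(cohort: pd.DataFrame, require_all: bool = False) -> pd.DataFrame:
    """Check the cohort schema and coerce diagnosis to an ordered categorical.

    Rows whose diagnosis is not one of NCI/MCI/AD raise a
    :class:`SchemaError` naming the offending row.  With ``require_all`` the
    full column set of the cohort TSV schema must be present; otherwise only
    ``diagnosis`` is mandatory.
    """
    if require_all:
        missing = [c for c in _COHORT_COLUMNS if c not in cohort.columns]
        if missing:
            raise SchemaError(f"cohort is missing columns {missing}")
    if "diagnosis" not in cohort.columns:
        raise SchemaError("cohort has no 'diagnosis' column")
    diag = cohort["diagnosis"]
    if not isinstance(diag.dtype, pd.CategoricalDtype):
        bad = ~diag.isin(DIAGNOSIS_LEVELS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"row {row}: diagnosis {diag.iloc[row]!r} is not one of "
                f"{DIAGNOSIS_LEVELS}")
        diag = pd.Categorical(diag, categories=DIAGNOSIS_LEVELS, ordered=True)
    elif not diag.cat.ordered:
        diag = diag.cat.as_ordered()
    out = cohort.copy()
    out["diagnosis"] = diag
    if "mir20b" in out.columns and (out["mir20b"].to_numpy(dtype=float) <= 0).any():
        raise SchemaError("mir20b levels must be strictly positive")
    return out


class ProportionalOddsClassifier(ClassifierMixin, BaseEstimator):
    """Cumulative-logit ordinal classifier, P(Y <= k|x) = logistic(alpha_k - x.beta).

    Parameters
    ----------
    method : str
        Primary scipy optimizer passed to statsmodels (default ``"bfgs"``);
        an L-BFGS retry is attempted on non-convergence.
    maxiter : int
        Iteration cap for the optimizer.
    gtol : float
        Gradient max-norm convergence tolerance.

    Attributes
    ----------
    classes_ : ndarray
        The ordered outcome levels, in increasing severity.
    coef_ : ndarray of shape (n_features,)
        Slope coefficients beta (positive = shifts mass toward the top level).
    cutpoints_ : ndarray of shape (n_classes - 1,)
        Strictly increasing cutpoints alpha_k.
    coef_se_ : ndarray of shape (n_features,)
        Wald standard errors of the slopes.
    loglik_ : float
        Maximized log-likelihood.
    prob_matrix_ : ndarray of shape (n_samples, n_classes)
        Fitted category probabilities for the training rows.
    """

    def __init__(self, method: str = "bfgs", maxiter: int = 500,
                 gtol: float = 1e-8):
        self.method = method
        self.maxiter = maxiter
        self.gtol = gtol

    def fit(self, X, y):
        X = check_array(X, ensure_min_features=0, ensure_all_finite=True,
                        dtype=float)
        if isinstance(y, pd.Series):
            y = y.to_numpy() if not isinstance(y.dtype, pd.CategoricalDtype) else y
        if isinstance(getattr(y, "dtype", None), pd.CategoricalDtype):
            cats = np.asarray(y.cat.categories if isinstance(y, pd.Series)
                              else y.categories)
            codes = np.asarray(y.cat.codes if isinstance(y, pd.Series)
                               else y.codes)
        else:
            y = np.asarray(y)
            cats, codes = np.unique(y, return_inverse=True)
        if (codes < 0).any():
            raise DataError("outcome contains values outside the declared levels")
        present = np.bincount(codes, minlength=len(cats))
        if (present == 0).any():
            absent = [str(cats[i]) for i in np.flatnonzero(present == 0)]
            raise DataError(f"outcome level(s) {absent} absent from the data")
        if len(cats) < 2:
            raise DataError("need at least two outcome levels")
        n, p = X.shape
        n_params = p + len(cats) - 1
        if n <= n_params:
            raise FitError(f"n_obs={n} does not exceed parameter count {n_params}")

        exog = X if p else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(codes, exog, distr="logit")
            try:
                res = model.fit(method=self.method, maxiter=self.maxiter,
                                gtol=self.gtol, disp=False)
                converged = res.mle_retvals.get("converged", False)
            except Exception:
                res, converged = None, False
            if not converged:
                try:
                    res = model.fit(method="lbfgs", maxiter=self.maxiter,
                                    pgtol=self.gtol, disp=False)
                    converged = res.mle_retvals.get("converged", False)
                except Exception:
                    converged = False
        if not converged or not np.all(np.isfinite(res.params)):
            raise FitError(
                "proportional-odds fit did not converge (possible complete "
                "separation or degenerate design)")

        params = np.asarray(res.params, dtype=float)
        self.coef_ = params[:p]
        self.cutpoints_ = np.asarray(
            model.transform_threshold_params(params)[1:-1], dtype=float)
        self.coef_se_ = np.asarray(res.bse, dtype=float)[:p]
        self.loglik_ = float(res.llf)
        try:
            self.covariance_ = np.asarray(res.cov_params(), dtype=float)
        except Exception:  # singular Hessian: covariance is optional
            self.covariance_ = None
        self.classes_ = cats
        self.n_features_in_ = p
        self.n_obs_ = n
        self.prob_matrix_ = self._probabilities(X)
        return self

    def _probabilities(self, X: np.ndarray) -> np.ndarray:
        eta = X @ self.coef_ if X.shape[1] else np.zeros(X.shape[0])
        cum = 1.0 / (1.0 + np.exp(-(self.cutpoints_[None, :] - eta[:, None])))
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_min_features=0, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} feature columns, got {X.shape[1]}")
        return self._probabilities(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class ProportionalOddsFit:
    """A fitted cohort-level proportional-odds model.

    Bundles the estimator with the term specification and encoded design
    metadata so that deviance tables and new-data prediction can re-encode
    consistently.
    """

    estimator: ProportionalOddsClassifier
    spec: TermSpec
    design_columns: list[str]
    term_columns: dict[str, list[str]]
    levels: tuple

    @property
    def cutpoints(self) -> np.ndarray:
        return self.estimator.cutpoints_

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.estimator.coef_, index=self.design_columns)

    @property
    def coef_se(self) -> pd.Series:
        return pd.Series(self.estimator.coef_se_, index=self.design_columns)

    @property
    def loglik(self) -> float:
        return self.estimator.loglik_

    @property
    def n_obs(self) -> int:
        return self.estimator.n_obs_

    @property
    def n_params(self) -> int:
        return self.estimator.n_features_in_ + len(self.levels) - 1

    @property
    def prob_matrix(self) -> np.ndarray:
        return self.estimator.prob_matrix_

    @property
    def covariance(self):
        return self.estimator.covariance_


def _outcome(cohort: pd.DataFrame, response: str) -> pd.Series:
    if response not in cohort.columns:
        raise SchemaError(f"response column {response!r} missing")
    y = cohort[response]
    if not isinstance(y.dtype, pd.CategoricalDtype):
        cohort = validate_cohort(cohort)
        y = cohort[response]
    return y


def fit_proportional_odds(cohort: pd.DataFrame,
                          terms: TermSpec | str,
                          response: str = "diagnosis") -> ProportionalOddsFit:
    """Fit the cumulative-logit model of an ordered outcome on cohort terms."""
    if isinstance(terms, str):
        terms = TermSpec.parse(terms)
    y = _outcome(cohort, response)
    design, term_columns = build_design(cohort, terms)
    est = ProportionalOddsClassifier()
    try:
        est.fit(design.to_numpy(dtype=float).reshape(len(cohort), -1), y)
    except FitError as exc:
        raise FitError(f"model with terms {terms.names}: {exc}") from exc
    return ProportionalOddsFit(est, terms, list(design.columns), term_columns,
                               tuple(est.classes_))


def predict_probabilities(fit: ProportionalOddsFit,
                          newdata: pd.DataFrame) -> np.ndarray:
    """Predicted category probabilities for new subjects under a fitted model."""
    design, _ = build_design(newdata, fit.spec, check_rank=False)
    if list(design.columns) != fit.design_columns:
        raise SchemaError(
            f"new data encodes to columns {list(design.columns)}, model was "
            f"fitted on {fit.design_columns}")
    return fit.estimator.predict_proba(
        design.to_numpy(dtype=float).reshape(len(newdata), -1))


def drop_one_fits(cohort: pd.DataFrame, terms: TermSpec | str,
                  response: str = "diagnosis"):
    """Yield ``(term_name, reduced_fit_or_None, error_or_None)`` per model term.

    Reduced models respect marginality: dropping a main effect also removes
    every interaction involving it; interactions are removed alone.
    """
    if isinstance(terms, str):
        terms = TermSpec.parse(terms)
    for name in terms.names:
        try:
            yield name, fit_proportional_odds(cohort, terms.drop(name),
                                              response), None
        except (FitError, DataError) as exc:
            yield name, None, exc


def likelihood_ratio_anova(cohort: pd.DataFrame,
                           terms: TermSpec | str,
                           response: str = "diagnosis",
                           full_fit: ProportionalOddsFit | None = None
                           ) -> pd.DataFrame:
    """Drop-one analysis of deviance for the proportional-odds model.

    For each term the model is refitted without it (marginality respected)
    and the likelihood-ratio statistic 2*(ll_full - ll_reduced) is referred
    to chi-square with df equal to the parameter-count difference.  A term
    whose reduced model fails to fit gets an ``error`` entry; the remaining
    terms are still reported.
    """
    if isinstance(terms, str):
        terms = TermSpec.parse(terms)
    if full_fit is None:
        full_fit = fit_proportional_odds(cohort, terms, response)
    rows = []
    for name, reduced, err in drop_one_fits(cohort, terms, response):
        if err is not None:
            rows.append({"term": name, "chi2": np.nan, "df": np.nan,
                         "p": np.nan, "error": str(err)})
            continue
        chi2 = max(2.0 * (full_fit.loglik - reduced.loglik), 0.0)
        df = full_fit.n_params - reduced.n_params
        rows.append({"term": name, "chi2": chi2, "df": df,
                     "p": float(stats.chi2.sf(chi2, df)), "error": None})
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p", "error"])
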