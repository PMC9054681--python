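"""Ordinal coefficient of discrimination D and Fisher-transform partial effects.

For a fitted ordinal model with predicted probability matrix P (one row per
subject, one column per ordered level) and observed levels c_i, let p_c,i be
row i's predicted probability of its *observed* category.  The ordinal
coefficient of discrimination is

    D = mean(p_c) - mean(1 - p_c) = 2 * mean(p_c) - 1,

the mean probability credited to the truth minus the mean probability spread
over the other levels.  For a binary model with balanced classes this reduces
exactly to Tjur's coefficient of discrimination (mean fitted probability
among events minus mean among non-events).  D ranges over [-1, 1]; an
uninformative K-level model scores 2/K - 1 (e.g. -1/3 for three levels), and
worse-than-chance discrimination goes negative.

Per-effect partial D values are obtained on the Fisher-z (atanh) scale of
sqrt(D), analogously to partialling a correlation: z-transform sqrt(D) of the
full model and of the drop-one reduced model, difference, back-transform,
square.  Negative D is clamped to 0 before the square root (the transform is
undefined otherwise; worse-than-chance discrimination is treated as zero
explanatory contribution), and a negative z-difference floors the partial at
zero rather than reporting a signed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .ordinal import (ProportionalOddsFit, TermSpec, drop_one_fits,
                      fit_proportional_odds, likelihood_ratio_anova, _outcome)

_SQRT_CAP = 1.0 - 1e-12


def ordinal_tjur_d(prob_matrix, observed) -> float:
    """Ordinal coefficient of discrimination, D = 2*mean(p_c) - 1.

    Parameters
    ----------
    prob_matrix : (n, K) array
        Predicted category probabilities; every row must sum to 1 within 1e-6.
    observed : length-n sequence
        Observed outcome as 0-based column indices, or an ordered categorical
        whose codes index the columns.
    """
    P = np.asarray(prob_matrix, dtype=float)
    if P.ndim != 2:
        raise ValidationError("prob_matrix must be two-dimensional")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"probability row {bad} sums to {sums[bad]:.8f}, not 1")
    obs = observed
    if isinstance(obs, pd.Series) and isinstance(obs.dtype, pd.CategoricalDtype):
        obs = obs.cat.codes.to_numpy()
    elif isinstance(obs, pd.Categorical):
        obs = obs.codes
    obs = np.asarray(obs)
    if obs.dtype.kind not in "iu":
        raise ValidationError("observed outcomes must be integer codes or an "
                              "ordered categorical")
    if len(obs) != len(P):
        raise ValidationError("observed length does not match prob_matrix rows")
    if obs.min() < 0 or obs.max() >= P.shape[1]:
        raise ValidationError("observed codes index columns outside prob_matrix")
    p_c = P[np.arange(len(P)), obs]
    return float(2.0 * p_c.mean() - 1.0)


def partial_d(d_full: float, d_reduced: float) -> float:
    """Fisher-transform partial D of an effect.

    With c(x) = max(x, 0) and sqrt capped just below 1 to keep atanh finite:
    ``tanh(atanh(sqrt(c(d_full))) - atanh(sqrt(c(d_reduced))))**2``, floored
    at 0 when the reduced model discriminates at least as well as the full
    model.
    """
    for name, v in (("d_full", d_full), ("d_reduced", d_reduced)):
        if not -1.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [-1, 1]")
    r_full = min(np.sqrt(max(d_full, 0.0)), _SQRT_CAP)
    r_red = min(np.sqrt(max(d_reduced, 0.0)), _SQRT_CAP)
    dz = np.arctanh(r_full) - np.arctanh(r_red)
    if dz <= 0.0:
        return 0.0
    return float(np.tanh(dz) ** 2)


@dataclass
class DReport:
    """Full-model D with per-term partial and reduced-model D values."""

    d_full: float
    partials: dict[str, float] = field(default_factory=dict)
    d_reduced: dict[str, float] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": t, "D": self.partials.get(t, np.nan),
                 "D_reduced": self.d_reduced.get(t, np.nan),
                 "error": self.errors.get(t)}
                for t in list(self.partials) + list(self.errors)]
        return pd.DataFrame(rows, columns=["term", "D", "D_reduced", "error"])


def effect_d_table(cohort: pd.DataFrame, terms: TermSpec | str,
                   response: str = "diagnosis",
                   full_fit: ProportionalOddsFit | None = None) -> DReport:
    """Drop-one partial-D decomposition of a cohort model.

    Fits the full model and, for every term, the reduced model without it
    (same marginality-respecting scheme as the analysis of deviance); each
    model's D is computed on its own fitted probabilities and the partial D
    is the Fisher-z difference, back-transformed and squared.  Per-term fit
    failures are recorded without aborting the remaining terms.
    """
    if isinstance(terms, str):
        terms = TermSpec.parse(terms)
    if full_fit is None:
        full_fit = fit_proportional_odds(cohort, terms, response)
    y = _outcome(cohort, response)
    d_full = ordinal_tjur_d(full_fit.prob_matrix, y)
    report = DReport(d_full=d_full)
    for name, reduced, err in drop_one_fits(cohort, terms, response):
        if err is not None:
            report.errors[name] = str(err)
            continue
        d_red = ordinal_tjur_d(reduced.prob_matrix, y)
        report.d_reduced[name] = d_red
        report.partials[name] = partial_d(d_full, d_red)
    return report


def effect_table(cohort: pd.DataFrame, terms: TermSpec | str,
                 response: str = "diagnosis") -> pd.DataFrame:
    """Joined per-term report: chi2, df, p (analysis of deviance) and partial D.

    This is the machine-readable analogue of the study-style effect tables
    (one row per model term with its likelihood-ratio test and its share of
    the discrimination coefficient).
    """
    if isinstance(terms, str):
        terms = TermSpec.parse(terms)
    full_fit = fit_proportional_odds(cohort, terms, response)
    anova = likelihood_ratio_anova(cohort, terms, response, full_fit=full_fit)
    drep = effect_d_table(cohort, terms, response, full_fit=full_fit)
    anova = anova.drop(columns=["error"])
    anova["D"] = [drep.partials.get(t, np.nan) for t in anova["term"]]
    anova.attrs["d_full"] = drep.d_full
    return anova
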