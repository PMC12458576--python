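"""Longitudinal conversion analysis.

Builds per-year risk sets from a clinical-status panel, fits logistic
regressions of incident (annual) or cumulative conversion on baseline
predictors, and evaluates them with likelihood-ratio tests and
rank-based ROC AUC.

Risk-set rules
--------------
Annual mode, year t: subjects holding the source status who have not
yet reached the target status by year t-1 and are still under follow-up
at year t; outcome 1 iff the target status is first observed at year t.
Conversion year is the first visit showing the new status, so a
multi-year visit gap assigns the conversion to the first year it is
observed.  Subjects lost to follow-up exit the risk set after their
last visit — no unobserved conversions are imputed.

Cumulative mode, year t: converted-by-t vs never-converters still
followed at year t; year 1 therefore coincides with annual year 1.  An
``include_censored_stable`` flag instead counts every never-converter
as stable through their last visit, which reproduces the pooled
"converted-by-horizon vs stable-through-last-visit" analysis.

Predictors are standardized to zero mean / unit SD within the analysis
sample before fitting, so each odds ratio is per 1-SD increase; the
scaling record is kept on the fit for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .io_formats import StatusPanel

__all__ = [
    "RiskSet",
    "LogisticFit",
    "build_risk_sets",
    "fit_conversion",
    "or_series",
    "lr_test",
    "rank_auc",
    "roc_auc",
]


class ConversionError(ValueError):
    """Invalid input to the conversion analysis."""


@dataclass
class RiskSet:
    """Subjects at risk in one interval with their 0/1 outcomes."""

    year: int
    subjects: list[str]
    outcome: np.ndarray  # 0/1 per subject
    mode: str  # "annual" | "cumulative"

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with per-1-SD odds ratios."""

    params: pd.Series            # log-odds coefficients incl. const
    bse: pd.Series
    pvalues: pd.Series
    odds_ratios: pd.Series       # exp(beta), predictors only
    conf_int: pd.DataFrame       # 95% CI on the OR scale, predictors only
    llf: float
    n: int
    n_events: int
    scaling: pd.DataFrame        # mean/sd used to standardize each predictor
    year: int | None = None
    mode: str | None = None
    subjects: list[str] = field(default_factory=list)

    @property
    def predictor_names(self) -> list[str]:
        return [c for c in self.params.index if c != "const"]


def build_risk_sets(
    panel: StatusPanel,
    from_status: str = "MCI",
    to_status: str = "dementia",
    mode: str = "annual",
    horizon: int = 12,
    include_censored_stable: bool = False,
) -> list[RiskSet]:
    """Per-year risk sets for ``from_status`` -> ``to_status`` conversion."""
    if horizon < 1:
        raise ConversionError(f"horizon must be >= 1, got {horizon}")
    if mode not in ("annual", "cumulative"):
        raise ConversionError(f"mode must be 'annual' or 'cumulative', got {mode!r}")
    base = panel.baseline_status()
    cohort = base.index[base == from_status]
    last = panel.last_visit().reindex(cohort)
    conv = panel.first_year_with_status(to_status).reindex(cohort)

    sets: list[RiskSet] = []
    for year in range(1, horizon + 1):
        if mode == "annual":
            at_risk = cohort[
                (last.loc[cohort] >= year) & ((conv.loc[cohort].isna()) | (conv.loc[cohort] >= year))
            ]
            outcome = (conv.reindex(at_risk) == year).astype(int).to_numpy()
        else:
            converted = cohort[conv.loc[cohort].notna() & (conv.loc[cohort] <= year)]
            not_yet = conv.loc[cohort].isna() | (conv.loc[cohort] > year)
            if include_censored_stable:
                stable = cohort[not_yet]
            else:
                stable = cohort[not_yet & (last.loc[cohort] >= year)]
            at_risk = pd.Index(list(converted) + list(stable))
            outcome = np.concatenate([
                np.ones(len(converted), dtype=int),
                np.zeros(len(stable), dtype=int),
            ])
        sets.append(RiskSet(year=year, subjects=list(at_risk), outcome=outcome, mode=mode))
    return sets


def _standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ConversionError(f"constant predictor(s): {bad}")
    return (X - mean) / sd, pd.DataFrame({"mean": mean, "sd": sd})


def fit_conversion(
    risk_set: RiskSet,
    predictors: pd.DataFrame,
    standardize: bool = True,
) -> LogisticFit:
    """Logistic regression of the risk set's outcome on baseline
    predictors (columns of ``predictors``, indexed by subject_id).

    Predictors are standardized to unit SD (per-1-SD odds ratios)
    unless ``standardize=False``.  Complete separation and single-class
    outcomes raise :class:`ConversionError` with a diagnostic.
    """
    y = pd.Series(risk_set.outcome, index=risk_set.subjects, dtype=float)
    X = predictors.reindex(risk_set.subjects).astype(float)
    keep = X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    if y.nunique() < 2:
        raise ConversionError(
            f"year {risk_set.year}: single-class outcome "
            f"({int(y.sum())} events of {len(y)}) — fit not estimable"
        )
    if standardize:
        X, scaling = _standardize(X)
    else:
        scaling = pd.DataFrame({"mean": X.mean() * 0.0, "sd": X.std(ddof=1) * 0.0 + 1.0})
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise ConversionError(
                f"year {risk_set.year}: outcome perfectly separated by predictors ({exc})"
            ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConversionError(f"year {risk_set.year}: logistic fit did not converge")
    ors = np.exp(fit.params.drop("const"))
    ci = np.exp(fit.conf_int(alpha=0.05).drop(index="const"))
    ci.columns = ["lo", "hi"]
    return LogisticFit(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        odds_ratios=ors,
        conf_int=ci,
        llf=float(fit.llf),
        n=int(fit.nobs),
        n_events=int(y.sum()),
        scaling=scaling,
        year=risk_set.year,
        mode=risk_set.mode,
        subjects=list(y.index),
    )


def or_series(
    panel: StatusPanel,
    predictors: pd.DataFrame,
    mode: str = "annual",
    from_status: str = "MCI",
    to_status: str = "dementia",
    horizon: int = 12,
) -> list[LogisticFit | None]:
    """One logistic fit per follow-up year.

    Years whose risk set has a single outcome class (or no subjects)
    are reported as ``None`` — not estimable — rather than dropped
    silently, so the returned list always has ``horizon`` entries.
    """
    sets = build_risk_sets(panel, from_status=from_status, to_status=to_status,
                           mode=mode, horizon=horizon)
    fits: list[LogisticFit | None] = []
    for rs in sets:
        try:
            fits.append(fit_conversion(rs, predictors))
        except ConversionError:
            fits.append(None)
    return fits


def lr_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair of logistic fits.

    Returns (chi2, df, p).  The reduced model's predictors must be a
    subset of the full model's and both must be fitted on the same
    rows.
    """
    full_terms = set(full.predictor_names)
    red_terms = set(reduced.predictor_names)
    if not red_terms <= full_terms:
        raise ConversionError(
            f"models not nested: reduced has extra terms {sorted(red_terms - full_terms)}"
        )
    if full.n != reduced.n or set(full.subjects) != set(reduced.subjects):
        raise ConversionError("models fitted on different rows; LR test invalid")
    df = len(full_terms) - len(red_terms)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(st.chi2.sf(chi2, df))
    return chi2, df, p


def rank_auc(score: np.ndarray | pd.Series, outcome: np.ndarray | pd.Series) -> float:
    """Rank-based ROC AUC: probability that a random event outranks a
    random non-event, ties counted half (Mann-Whitney form)."""
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    n1 = int(outcome.sum())
    n0 = int(len(outcome) - n1)
    if n1 == 0 or n0 == 0:
        raise ConversionError("AUC undefined: only one outcome class present")
    ranks = st.rankdata(score)
    auc = (ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc)


def roc_auc(fit: LogisticFit, risk_set: RiskSet, predictors: pd.DataFrame) -> float:
    """AUC of a fitted model's predicted probabilities on a risk set."""
    y = pd.Series(risk_set.outcome, index=risk_set.subjects, dtype=float)
    X = predictors.reindex(risk_set.subjects).astype(float)
    keep = X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    Xs = (X - fit.scaling["mean"]) / fit.scaling["sd"]
    Xc = sm.add_constant(Xs, has_constant="add")[fit.params.index]
    eta = Xc.to_numpy() @ fit.params.to_numpy()
    prob = 1.0 / (1.0 + np.exp(-eta))
    return rank_auc(prob, y.to_numpy())
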