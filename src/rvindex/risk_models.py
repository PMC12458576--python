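"""Cross-sectional hypothesis tests on RVI scores.

Covers the three analyses run on healthy cohorts: the carrier vs
non-carrier contrast on RVI (Student's pooled-variance t-test with
Cohen's d), the linear model

    RVI ~ b_e4 * E4 + b_fcvrs * FCVRS + b_int * E4xFCVRS  (+ intercept)

probing whether cardiovascular burden loads on the disease pattern
differently in APOE-e4 carriers, and Fisher r-to-z comparison of the
per-genotype FCVRS-RVI correlations.  All p-values are two-sided; no
multiple-testing correction is applied in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .io_formats import EffectSizeBlueprint

__all__ = [
    "GroupContrast",
    "Model1Fit",
    "CorrelationComparison",
    "carrier_contrast",
    "fit_model1",
    "corr_and_compare",
    "pattern_correlation",
]


class RiskModelError(ValueError):
    """Invalid input to a cross-sectional test."""


@dataclass
class GroupContrast:
    """Two-sample contrast: group 1 minus group 0."""

    t: float
    p: float
    cohens_d: float
    n1: int
    n2: int


@dataclass
class Model1Fit:
    """OLS of RVI on carrier status, FCVRS and their interaction."""

    beta_e4: float
    beta_fcvrs: float
    beta_interaction: float
    se_e4: float
    se_fcvrs: float
    se_interaction: float
    t_e4: float
    t_fcvrs: float
    t_interaction: float
    p_e4: float
    p_fcvrs: float
    p_interaction: float
    F: float
    p_overall: float
    n: int

    def ci_interaction(self, alpha: float = 0.05) -> tuple[float, float]:
        df = self.n - 4
        half = st.t.ppf(1 - alpha / 2, df) * self.se_interaction
        return self.beta_interaction - half, self.beta_interaction + half


@dataclass
class CorrelationComparison:
    """Fisher r-to-z test for the difference of two independent
    Pearson correlations (group 1 minus group 2)."""

    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float
    p_r1: float = float("nan")
    p_r2: float = float("nan")


def carrier_contrast(
    rvi: pd.Series | np.ndarray,
    carrier: pd.Series | np.ndarray,
    welch: bool = False,
) -> GroupContrast:
    """Carrier (1) vs non-carrier (0) contrast on a score.

    Pooled-variance Student's t by default; Cohen's d is the mean
    difference over the pooled SD, so sign(d) == sign(t) and a positive
    d means carriers score higher.
    """
    rvi = np.asarray(rvi, dtype=float)
    carrier = np.asarray(carrier)
    x1 = rvi[carrier == 1]
    x0 = rvi[carrier == 0]
    if len(x1) < 2 or len(x0) < 2:
        raise RiskModelError(
            f"need >= 2 subjects per group (carriers={len(x1)}, noncarriers={len(x0)})"
        )
    t, p = st.ttest_ind(x1, x0, equal_var=not welch)
    n1, n2 = len(x1), len(x0)
    sp = np.sqrt(((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x0, ddof=1)) / (n1 + n2 - 2))
    d = (np.mean(x1) - np.mean(x0)) / sp
    return GroupContrast(t=float(t), p=float(p), cohens_d=float(d), n1=n1, n2=n2)


def fit_model1(
    rvi: pd.Series | np.ndarray,
    e4: pd.Series | np.ndarray,
    fcvrs: pd.Series | np.ndarray,
) -> Model1Fit:
    """Fit RVI ~ E4 + FCVRS + E4xFCVRS with intercept (complete cases).

    The overall F tests all three slopes against the intercept-only
    model.  A constant predictor is rejected by name rather than fitted.
    """
    df = pd.DataFrame({
        "rvi": np.asarray(rvi, dtype=float),
        "e4": np.asarray(e4, dtype=float),
        "fcvrs": np.asarray(fcvrs, dtype=float),
    }).dropna()
    if len(df) <= 10:
        raise RiskModelError(f"need n > 10 complete cases, got {len(df)}")
    for name in ("e4", "fcvrs"):
        if df[name].nunique() < 2:
            raise RiskModelError(f"constant predictor: {name}")
    X = pd.DataFrame({
        "e4": df["e4"],
        "fcvrs": df["fcvrs"],
        "e4_x_fcvrs": df["e4"] * df["fcvrs"],
    })
    if X["e4_x_fcvrs"].nunique() < 2:
        raise RiskModelError("constant predictor: e4_x_fcvrs")
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(df["rvi"], X).fit()
    return Model1Fit(
        beta_e4=float(fit.params["e4"]),
        beta_fcvrs=float(fit.params["fcvrs"]),
        beta_interaction=float(fit.params["e4_x_fcvrs"]),
        se_e4=float(fit.bse["e4"]),
        se_fcvrs=float(fit.bse["fcvrs"]),
        se_interaction=float(fit.bse["e4_x_fcvrs"]),
        t_e4=float(fit.tvalues["e4"]),
        t_fcvrs=float(fit.tvalues["fcvrs"]),
        t_interaction=float(fit.tvalues["e4_x_fcvrs"]),
        p_e4=float(fit.pvalues["e4"]),
        p_fcvrs=float(fit.pvalues["fcvrs"]),
        p_interaction=float(fit.pvalues["e4_x_fcvrs"]),
        F=float(fit.fvalue),
        p_overall=float(fit.f_pvalue),
        n=int(fit.nobs),
    )


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """z and two-sided p for the difference of two independent Pearson
    correlations: z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))."""
    if n1 <= 3 or n2 <= 3:
        raise RiskModelError(f"Fisher comparison needs n > 3 per group (got {n1}, {n2})")
    if r1 == r2:
        return 0.0, 1.0
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * st.norm.sf(abs(z))
    return float(z), float(p)


def corr_and_compare(
    rvi: pd.Series | np.ndarray,
    fcvrs: pd.Series | np.ndarray,
    carrier: pd.Series | np.ndarray,
) -> CorrelationComparison:
    """Per-genotype Pearson correlation of FCVRS with RVI, and the
    Fisher r-to-z test of their difference (carriers minus
    non-carriers).  Complete cases within each group; each group needs
    at least 4 subjects."""
    df = pd.DataFrame({
        "rvi": np.asarray(rvi, dtype=float),
        "fcvrs": np.asarray(fcvrs, dtype=float),
        "carrier": np.asarray(carrier),
    }).dropna()
    g1 = df[df["carrier"] == 1]
    g0 = df[df["carrier"] == 0]
    if len(g1) <= 3 or len(g0) <= 3:
        raise RiskModelError(
            f"need > 3 complete cases per group (carriers={len(g1)}, noncarriers={len(g0)})"
        )
    r1, p_r1 = st.pearsonr(g1["fcvrs"], g1["rvi"])
    r2, p_r2 = st.pearsonr(g0["fcvrs"], g0["rvi"])
    z, p = fisher_compare(float(r1), len(g1), float(r2), len(g0))
    return CorrelationComparison(
        r1=float(r1), n1=len(g1), r2=float(r2), n2=len(g0),
        z=z, p=p, p_r1=float(p_r1), p_r2=float(p_r2),
    )


def pattern_correlation(
    blueprint_a: EffectSizeBlueprint,
    blueprint_b: EffectSizeBlueprint,
) -> tuple[float, float]:
    """Pearson correlation of two blueprints' d vectors over their
    region intersection (aligned by region_id)."""
    da = blueprint_a.d_series()
    db = blueprint_b.d_series()
    common = da.index.intersection(db.index)
    if len(common) < 4:
        raise RiskModelError(f"region intersection too small ({len(common)} < 4)")
    r, p = st.pearsonr(da.reindex(common), db.reindex(common))
    return float(r), float(p)
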