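"""Case-control effect-size blueprints.

Per-region Cohen's d values are derived from a covariate-adjusted
ordinary-least-squares fit

    measure ~ diagnosis + age + sex + age:sex + ICV

with diagnosis coded case = 1, control = 0, followed by a t-to-d
conversion of the diagnosis t-statistic:

    d = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df))

where df is the residual degrees of freedom of the adjusted regression.
With equal group sizes and no covariates this reduces to the familiar
2t/sqrt(df).  Under this coding d < 0 means cases have lower values —
the typical direction for cortical thickness and gray-matter volume in
neurodegeneration — which makes the RVI sign convention coherent
(positive RVI = disease-like).

The d values are used downstream as similarity weights, not as
significance claims, so no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import EffectSizeBlueprint, PhenotypeTable

__all__ = ["RegionModelResult", "fit_region_model", "t_to_d", "build_blueprint"]


class EffectSizeError(ValueError):
    """Region model could not be fitted."""


@dataclass
class RegionModelResult:
    """Diagnosis contrast for one region from the adjusted regression."""

    region_id: str
    t_diag: float
    df_resid: int
    n_case: int
    n_control: int
    d: float


def t_to_d(t: float, n1: int, n2: int, df: int) -> float:
    """Convert a two-group contrast t-statistic into Cohen's d.

    ``n1`` and ``n2`` are the group sizes and ``df`` the residual
    degrees of freedom of the (possibly covariate-adjusted) model the
    t came from.
    """
    if n1 < 2 or n2 < 2:
        raise EffectSizeError(f"need >= 2 subjects per group, got n1={n1}, n2={n2}")
    if df <= 0:
        raise EffectSizeError(f"residual df must be positive, got {df}")
    return float(t) * (n1 + n2) / (math.sqrt(n1 * n2) * math.sqrt(df))


def _design_matrix(table: PhenotypeTable, diagnosis: pd.Series) -> pd.DataFrame:
    cov = table.data
    for c in ("age", "sex", "icv"):
        if c not in cov.columns:
            raise EffectSizeError(f"covariate column {c!r} required for the adjusted fit")
    X = pd.DataFrame(
        {
            "diagnosis": diagnosis.reindex(cov.index).astype(float),
            "age": cov["age"].astype(float),
            "sex": cov["sex"].astype(float),
            "age_x_sex": cov["age"].astype(float) * cov["sex"].astype(float),
            "icv": cov["icv"].astype(float),
        },
        index=cov.index,
    )
    return sm.add_constant(X, has_constant="add")


def fit_region_model(
    table: PhenotypeTable,
    region: str,
    diagnosis: pd.Series,
) -> RegionModelResult:
    """OLS diagnosis contrast for one region, adjusted for age, sex,
    their interaction, and intracranial volume.

    ``diagnosis`` is 0/1 per subject (case = 1).  Rows with a missing
    measure, covariate, or label are dropped as complete-case.
    """
    if region not in table.regions:
        raise EffectSizeError(f"unknown region {region!r}")
    X = _design_matrix(table, diagnosis)
    y = table.data[region].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    diag = X["diagnosis"]
    n_case = int((diag == 1).sum())
    n_control = int((diag == 0).sum())
    if n_case < 2 or n_control < 2:
        raise EffectSizeError(
            f"{region}: need >= 2 subjects per diagnosis group "
            f"(got {n_case} cases, {n_control} controls)"
        )
    if float(np.var(y)) == 0.0:
        raise EffectSizeError(f"{region}: zero-variance measure")
    # name the collinear term rather than silently dropping rank
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for col in [c for c in X.columns if c != "const"]:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank:
                raise EffectSizeError(f"{region}: singular design, collinear term {col!r}")
        raise EffectSizeError(f"{region}: singular design matrix")
    fit = sm.OLS(y, X).fit()
    t = float(fit.tvalues["diagnosis"])
    df = int(fit.df_resid)
    return RegionModelResult(
        region_id=region,
        t_diag=t,
        df_resid=df,
        n_case=n_case,
        n_control=n_control,
        d=t_to_d(t, n_case, n_control, df),
    )


def build_blueprint(
    table: PhenotypeTable,
    diagnosis: pd.Series,
    modality_map: dict[str, str],
    study: pd.Series | None = None,
) -> EffectSizeBlueprint:
    """Fit every region and assemble the per-region d values into a
    blueprint, in table column order.

    ``modality_map`` assigns each region its modality tag.  ``study``
    optionally adds a between-dataset covariate to every fit (pooled
    concatenation is the default).  If any region fit fails, no
    blueprint is emitted and the error lists all failures.
    """
    missing_tags = [r for r in table.regions if r not in modality_map]
    if missing_tags:
        raise EffectSizeError(f"regions without a modality tag: {missing_tags}")
    work = table
    if study is not None:
        data = table.data.copy()
        data["_study"] = pd.Categorical(study.reindex(data.index)).codes.astype(float)
        work = PhenotypeTable(data=data, regions=list(table.regions),
                              covariates=table.covariates + ["_study"])
    rows, failures = [], []
    for region in table.regions:
        try:
            res = _fit_with_optional_study(work, region, diagnosis, study is not None)
        except EffectSizeError as exc:
            failures.append(str(exc))
            continue
        rows.append({"region_id": region, "modality": modality_map[region], "d": res.d})
    if failures:
        raise EffectSizeError(
            "blueprint not emitted; region fits failed:\n" + "\n".join(failures)
        )
    return EffectSizeBlueprint(pd.DataFrame(rows))


def _fit_with_optional_study(
    table: PhenotypeTable, region: str, diagnosis: pd.Series, with_study: bool
) -> RegionModelResult:
    if not with_study:
        return fit_region_model(table, region, diagnosis)
    X = _design_matrix(table, diagnosis)
    X["_study"] = table.data["_study"]
    y = table.data[region].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    n_case = int((X["diagnosis"] == 1).sum())
    n_control = int((X["diagnosis"] == 0).sum())
    if n_case < 2 or n_control < 2:
        raise EffectSizeError(f"{region}: need >= 2 subjects per diagnosis group")
    fit = sm.OLS(y, X).fit()
    t = float(fit.tvalues["diagnosis"])
    df = int(fit.df_resid)
    return RegionModelResult(region, t, df, n_case, n_control, t_to_d(t, n_case, n_control, df))
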