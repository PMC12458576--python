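"""Framingham general cardiovascular risk score (FCVRS).

Sex-specific point-based score predicting 10-year risk of a first major
cardiovascular event (myocardial infarction, stroke, cardiovascular
death and related outcomes) from age, total and HDL cholesterol,
systolic blood pressure (treated vs untreated), current smoking and
diabetes.  This is the point-table form of the general-CVD profile of
D'Agostino et al. (Circulation 2008); the point and risk tables ship as
versioned CSV data files under ``rvindex/data`` so they can be audited
or substituted without touching logic.

Units: age in years, lipids in mg/dL, pressure in mmHg.  Lipid values
recorded in mmol/L must be converted at the I/O boundary
(:func:`mmol_to_mgdl`).  No imputation happens here: a missing field is
an error for a single-subject call and an explicit missingness flag for
the batch call.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["CvRiskInput", "CvRiskScore", "fcvrs", "fcvrs_batch", "mmol_to_mgdl"]

_CHOL_MGDL_PER_MMOL = 38.67  # molar mass conversion for cholesterol

FCVRS_FIELDS = (
    "age", "sex", "total_cholesterol", "hdl_cholesterol",
    "systolic_bp", "bp_treated", "smoker", "diabetic",
)


class FraminghamError(ValueError):
    """Invalid or incomplete FCVRS input."""


@dataclass(frozen=True)
class CvRiskInput:
    """Clinical covariates for one subject (sex: 0 = female, 1 = male)."""

    age: float
    sex: int
    total_cholesterol: float
    hdl_cholesterol: float
    systolic_bp: float
    bp_treated: int
    smoker: int
    diabetic: int


@dataclass(frozen=True)
class CvRiskScore:
    points: int
    risk_10yr: float  # fraction in (0, 1)


def mmol_to_mgdl(value_mmol: float) -> float:
    """Convert a cholesterol concentration from mmol/L to mg/dL."""
    return value_mmol * _CHOL_MGDL_PER_MMOL


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("rvindex.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


_POINTS: pd.DataFrame | None = None
_RISK: pd.DataFrame | None = None


def _tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    global _POINTS, _RISK
    if _POINTS is None:
        _POINTS = _load_table("framingham_points.csv")
        _POINTS["lower"] = pd.to_numeric(_POINTS["lower"])
        _POINTS["upper"] = pd.to_numeric(_POINTS["upper"])
    if _RISK is None:
        _RISK = _load_table("framingham_risk.csv")
    return _POINTS, _RISK


def _band_points(tab: pd.DataFrame, sex: str, factor: str, value: float) -> int:
    # bands are printed with integer edges (e.g. 35-44, 45-49); a value of
    # 44.5 belongs to the 35-44 band, so the upper edge is exclusive at +1
    rows = tab[(tab["sex"] == sex) & (tab["factor"] == factor)]
    hit = rows[(rows["lower"] <= value) & (value < rows["upper"] + 1)]
    if len(hit) != 1:
        raise FraminghamError(f"value {value!r} outside the {factor} bands for {sex}")
    return int(hit["points"].iloc[0])


def fcvrs(inp: CvRiskInput) -> CvRiskScore:
    """Sex-specific FCVRS point total and mapped 10-year risk.

    Raises :class:`FraminghamError` naming the field if any input is
    missing (NaN) or out of range; age must lie in [20, 100].
    """
    for f in FCVRS_FIELDS:
        v = getattr(inp, f)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise FraminghamError(f"missing field {f!r}")
    if not (20 <= inp.age <= 100):
        raise FraminghamError(f"age {inp.age} outside [20, 100]")
    if inp.total_cholesterol <= 0 or inp.hdl_cholesterol <= 0 or inp.systolic_bp <= 0:
        raise FraminghamError("lipids and pressure must be positive")
    if inp.sex not in (0, 1):
        raise FraminghamError(f"sex must be 0 (female) or 1 (male), got {inp.sex}")

    points_tab, risk_tab = _tables()
    sex = "male" if inp.sex == 1 else "female"
    # ages below the youngest band score as the youngest band
    age = min(max(inp.age, 30.0), 120.0)
    total = _band_points(points_tab, sex, "age", age)
    total += _band_points(points_tab, sex, "total_cholesterol", inp.total_cholesterol)
    total += _band_points(points_tab, sex, "hdl_cholesterol", inp.hdl_cholesterol)
    bp_factor = "sbp_treated" if inp.bp_treated else "sbp_untreated"
    total += _band_points(points_tab, sex, bp_factor, inp.systolic_bp)
    if inp.smoker:
        total += _band_points(points_tab, sex, "smoker", 1)
    if inp.diabetic:
        total += _band_points(points_tab, sex, "diabetic", 1)

    rows = risk_tab[risk_tab["sex"] == sex].sort_values("points")
    clipped = int(np.clip(total, rows["points"].min(), rows["points"].max()))
    risk_pct = float(rows.loc[rows["points"] == clipped, "risk_pct"].iloc[0])
    return CvRiskScore(points=int(total), risk_10yr=risk_pct / 100.0)


def _band_points_vec(tab: pd.DataFrame, sex: str, factor: str, values: np.ndarray) -> np.ndarray:
    rows = tab[(tab["sex"] == sex) & (tab["factor"] == factor)]
    out = np.full(len(values), np.nan)
    for _, band in rows.iterrows():
        mask = (values >= band["lower"]) & (values < band["upper"] + 1)
        out[mask] = band["points"]
    return out


def fcvrs_batch(covariates: pd.DataFrame) -> pd.DataFrame:
    """Score every subject in a covariate table (vectorized over the
    same band tables as :func:`fcvrs`).

    Returns a DataFrame indexed like ``covariates`` with columns
    ``points`` (float, NaN when incomplete), ``risk_10yr`` and
    ``missing`` (bool flag).  Missingness is data at the batch level,
    not an error.
    """
    needed = [f for f in FCVRS_FIELDS if f not in covariates.columns]
    if needed:
        raise FraminghamError(f"covariate table lacks columns: {needed}")
    points_tab, risk_tab = _tables()
    n = len(covariates)
    complete = covariates[list(FCVRS_FIELDS)].notna().all(axis=1).to_numpy()
    points = np.full(n, np.nan)
    risk = np.full(n, np.nan)
    sex_col = covariates["sex"].to_numpy()
    for sex_code, sex in ((0, "female"), (1, "male")):
        m = complete & (sex_col == sex_code)
        if not m.any():
            continue
        sub = covariates.loc[m]
        age = np.clip(sub["age"].to_numpy(dtype=float), 30.0, 120.0)
        total = _band_points_vec(points_tab, sex, "age", age)
        total += _band_points_vec(points_tab, sex, "total_cholesterol",
                                  sub["total_cholesterol"].to_numpy(dtype=float))
        total += _band_points_vec(points_tab, sex, "hdl_cholesterol",
                                  sub["hdl_cholesterol"].to_numpy(dtype=float))
        sbp = sub["systolic_bp"].to_numpy(dtype=float)
        treated = sub["bp_treated"].to_numpy() == 1
        bp = np.where(treated,
                      _band_points_vec(points_tab, sex, "sbp_treated", sbp),
                      _band_points_vec(points_tab, sex, "sbp_untreated", sbp))
        total += bp
        total += np.where(sub["smoker"].to_numpy() == 1,
                          _band_points(points_tab, sex, "smoker", 1), 0)
        total += np.where(sub["diabetic"].to_numpy() == 1,
                          _band_points(points_tab, sex, "diabetic", 1), 0)
        rows = risk_tab[risk_tab["sex"] == sex].set_index("points")["risk_pct"]
        clipped = np.clip(total, rows.index.min(), rows.index.max()).astype(int)
        points[m] = total
        risk[m] = rows.reindex(clipped).to_numpy() / 100.0
    return pd.DataFrame(
        {"points": points, "risk_10yr": risk, "missing": ~complete},
        index=covariates.index,
    )
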