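"""Synthetic cohorts with the statistical structure the analyses assume.

Generates cross-sectional phenotype tables and longitudinal status
panels so every analysis module can be exercised — and its estimators
validated against stored ground truth — without any data download.

Generative model
----------------
For subject j and region i with blueprint effect size d_i, population
mean m_i and SD s_i, the raw measure is

    x_ij = m_i + s_i * ( a*(age_j - age_mean)/10 + b*sex_j
                         + c*(icv_j - icv_mean)/icv_sd
                         + L_j * d_i + eps_ij )

where ``L_j = delta*carrier_j + gamma*carrier_j*fcvrs_z_j`` is the
subject's disease-pattern loading (carriers express the deficit
pattern, more so with higher cardiovascular burden) and eps is Gaussian
noise with SD ``noise_sd``, optionally equicorrelated across regions.
Because d_i < 0 where the disease lowers a measure, positive loading
moves the subject in the disease direction and yields a positive RVI.

Conversion times are drawn year-by-year from a logistic hazard in the
standardized latent pattern score and baseline age; dropout is an
independent per-year Bernoulli.  Every latent quantity (loading, latent
RVI, conversion probability inputs) is returned alongside the
observables as oracle ground truth.

The packaged 64-region blueprint (33 cortical thickness, 7 subcortical
volume, 24 white-matter regions) ships in
``data/ad_blueprint_synthetic.csv``; its d values are synthetic,
plausible-magnitude stand-ins for a meta-analytic table, not estimates
from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from . import framingham
from .io_formats import EffectSizeBlueprint, PhenotypeTable, StatusPanel

__all__ = [
    "CohortSpec",
    "bundled_ad_blueprint",
    "generate_cross_sectional",
    "generate_longitudinal",
]

#: Per-modality population mean / SD for raw measures (mm, mm^3, FA).
DEFAULT_REGION_STATS = {
    "cortical_thickness": (2.5, 0.15),
    "subcortical_volume": (4000.0, 400.0),
    "white_matter": (0.45, 0.03),
}


class CohortError(ValueError):
    """Invalid cohort specification."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic population.

    Defaults emulate a healthy middle-aged-to-older replication-style
    cohort: mean age 64 (SD 7.5), ~27% APOE-e4 carrier prevalence,
    carrier pattern loading ``delta`` = 0.3 SD with an extra
    ``gamma`` = 0.15 SD per SD of FCVRS in carriers only, and a
    conversion hazard of about 6%/year at the mean with a per-SD
    odds ratio of 1.8 on the latent pattern score over a 12-year
    horizon.
    """

    n_subjects: int = 500
    seed: int = 0
    # covariate distributions
    age_mean: float = 64.0
    age_sd: float = 7.5
    age_range: tuple[float, float] = (45.0, 85.0)
    p_male: float = 0.5
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    carrier_prevalence: float = 0.27
    # covariate effects on raw measures, in region-SD units
    age_slope_per_decade: float = -0.2
    sex_effect: float = 0.1
    icv_effect: float = 0.3
    # disease-pattern expression
    delta: float = 0.3          # loading in carriers, SD units
    gamma: float = 0.15         # extra loading per SD of FCVRS, carriers only
    noise_sd: float = 1.0
    equicorrelation: float = 0.0
    # conversion model
    hazard_intercept: float = -2.75   # logit of ~6%/year at the mean
    log_or_rvi: float = float(np.log(1.8))  # per SD of latent pattern score
    log_or_age: float = 0.2           # per SD of baseline age
    horizon: int = 12
    dropout_rate: float = 0.03        # per-year loss to follow-up

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise CohortError("n_subjects must be >= 2")
        if not (0 < self.carrier_prevalence < 1):
            raise CohortError("carrier_prevalence must be in (0, 1)")
        if self.noise_sd < 0:
            raise CohortError("noise_sd must be >= 0")
        if not (0 <= self.equicorrelation < 1):
            raise CohortError("equicorrelation must be in [0, 1)")


def bundled_ad_blueprint() -> EffectSizeBlueprint:
    """The packaged synthetic 64-region AD blueprint (33/7/24 split)."""
    with resources.files("rvindex.data").joinpath("ad_blueprint_synthetic.csv").open("rb") as fh:
        return EffectSizeBlueprint(pd.read_csv(fh))


def _draw_clinical(rng: np.random.Generator, n: int, age: np.ndarray, sex: np.ndarray) -> pd.DataFrame:
    """Plausible cardiovascular covariates (mg/dL, mmHg)."""
    tc = np.clip(rng.normal(200, 35, n), 110, 360)
    hdl = np.clip(rng.normal(58 - 8 * sex, 13, n), 25, 110)
    sbp = np.clip(rng.normal(118 + 0.35 * (age - 50), 14, n), 90, 210)
    treated = rng.random(n) < np.clip(0.05 + 0.006 * (age - 45), 0, 0.6)
    smoker = rng.random(n) < 0.15
    diabetic = rng.random(n) < np.clip(0.03 + 0.003 * (age - 45), 0, 0.35)
    return pd.DataFrame({
        "total_cholesterol": np.round(tc, 1),
        "hdl_cholesterol": np.round(hdl, 1),
        "systolic_bp": np.round(sbp, 1),
        "bp_treated": treated.astype(int),
        "smoker": smoker.astype(int),
        "diabetic": diabetic.astype(int),
    })


def generate_cross_sectional(
    spec: CohortSpec,
    blueprint: EffectSizeBlueprint,
    seed: int | None = None,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Simulate a hemisphere-averaged phenotype table plus ground truth.

    Returns ``(table, truth)`` where ``truth`` is indexed by subject_id
    with columns ``loading`` (true pattern expression, SD units),
    ``latent_rvi`` (noiseless normalized dot product implied by the
    loading), ``fcvrs_points`` and ``fcvrs_z``.  The table carries
    every covariate the downstream modules need (age, sex, icv,
    apoe4_carrier, the FCVRS clinical fields and the computed
    ``fcvrs`` points).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    ids = [f"S{i:05d}" for i in range(n)]

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), *spec.age_range)
    sex = (rng.random(n) < spec.p_male).astype(int)
    icv = rng.normal(spec.icv_mean, spec.icv_sd, n)
    carrier = (rng.random(n) < spec.carrier_prevalence).astype(int)
    clinical = _draw_clinical(rng, n, age, sex)

    cov = pd.DataFrame({"age": np.round(age, 1), "sex": sex,
                        "icv": np.round(icv, 0), "apoe4_carrier": carrier},
                       index=pd.Index(ids, name="subject_id"))
    cov = pd.concat([cov, clinical.set_index(cov.index)], axis=1)
    fc = framingham.fcvrs_batch(cov)
    cov["fcvrs"] = fc["points"]
    fcvrs_z = (fc["points"] - fc["points"].mean()) / fc["points"].std(ddof=1)

    loading = spec.delta * carrier + spec.gamma * carrier * fcvrs_z.to_numpy()

    d = blueprint.d_series()
    regions = list(d.index)
    stats = blueprint.table.set_index("region_id")["modality"].map(DEFAULT_REGION_STATS)
    means = np.array([stats[r][0] for r in regions])
    sds = np.array([stats[r][1] for r in regions])

    rho = spec.equicorrelation
    eps = rng.standard_normal((n, len(regions)))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        eps = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
    eps *= spec.noise_sd

    std_units = (
        spec.age_slope_per_decade * ((age - spec.age_mean) / 10.0)[:, None]
        + spec.sex_effect * sex[:, None]
        + spec.icv_effect * ((icv - spec.icv_mean) / spec.icv_sd)[:, None]
        + loading[:, None] * d.to_numpy()[None, :]
        + eps
    )
    values = means[None, :] + sds[None, :] * std_units
    pheno = pd.DataFrame(values, index=cov.index, columns=regions)

    table = PhenotypeTable(
        data=pd.concat([pheno, cov], axis=1),
        regions=regions,
        covariates=list(cov.columns),
    )
    truth = pd.DataFrame({
        "loading": loading,
        "latent_rvi": loading * float(np.mean(d.to_numpy() ** 2)),
        "carrier": carrier,
        "fcvrs_points": fc["points"].to_numpy(),
        "fcvrs_z": fcvrs_z.to_numpy(),
        "age": age,
    }, index=cov.index)
    return table, truth


def generate_longitudinal(
    spec: CohortSpec,
    truth: pd.DataFrame,
    seed: int | None = None,
    baseline_status: str = "MCI",
) -> StatusPanel:
    """Simulate yearly clinical follow-up driven by the latent score.

    Each year while a subject is event-free and still followed, a
    conversion to dementia is drawn from a logistic hazard in the
    standardized latent pattern score and baseline age; dropout
    (loss to follow-up) is an independent per-year draw.  Statuses are
    monotone (dementia is absorbing) and every subject has a year-0
    visit at ``baseline_status``.
    """
    if baseline_status not in ("CN", "MCI"):
        raise CohortError(f"baseline_status must be CN or MCI, got {baseline_status!r}")
    rng = np.random.default_rng((spec.seed + 1) if seed is None else seed)
    latent = truth["latent_rvi"].to_numpy(dtype=float)
    lsd = latent.std(ddof=1)
    latent_z = (latent - latent.mean()) / lsd if lsd > 0 else np.zeros_like(latent)
    age = truth["age"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / age.std(ddof=1)
    eta = spec.hazard_intercept + spec.log_or_rvi * latent_z + spec.log_or_age * age_z
    p_conv = 1.0 / (1.0 + np.exp(-eta))

    rows: list[dict] = []
    for j, sid in enumerate(truth.index):
        rows.append({"subject_id": sid, "visit_year": 0, "status": baseline_status})
        status = baseline_status
        for year in range(1, spec.horizon + 1):
            if rng.random() < spec.dropout_rate:
                break
            if status != "dementia" and rng.random() < p_conv[j]:
                status = "dementia"
            rows.append({"subject_id": sid, "visit_year": year, "status": status})
    return StatusPanel(pd.DataFrame(rows))
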