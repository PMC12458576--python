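"""Periodic-MRI screening simulation.

Asks how much predictive value a pattern-similarity score retains when
scans are repeated every 1, 3 or 5 years instead of once at baseline.
The trajectory model is deliberately simple and fully parameterized:

* each subject starts at a latent score drawn from a Gaussian;
* conversion times are drawn year-by-year from a logistic hazard in the
  baseline latent score;
* the latent score drifts linearly in everyone, and converters
  additionally accelerate during the final ``accel_years`` before their
  conversion (neurodegeneration speeds up as the event approaches);
* an observed scan is the latent value plus Gaussian measurement noise,
  available only at scheduled visit years.

Staleness is the phenomenon of interest: with positive pre-conversion
drift, a recent scan separates imminent converters from stable subjects
better than an old one, so AUC(annual) >= AUC(triennial) >=
AUC(quinquennial), and the predictive value of a single baseline scan
decays with the prediction gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conversion import rank_auc

__all__ = [
    "ScreeningConfig",
    "Trajectories",
    "ScreeningResult",
    "simulate_trajectories",
    "evaluate_screening",
    "baseline_auc_decay",
]


class ScreeningError(ValueError):
    """Invalid screening configuration or evaluation input."""


@dataclass
class ScreeningConfig:
    """Trajectory and evaluation parameters.

    ``drift`` is the common annual latent increase (score units/year);
    ``accel`` is the extra annual increase converters show during the
    final ``accel_years`` before conversion; ``noise_sd`` is the
    measurement noise of one scan.  The hazard intercept gives roughly
    a 5%/year conversion rate at the mean latent score, with
    ``log_or_latent`` per-SD log-odds on the baseline score.
    """

    n_subjects: int = 500
    horizon_years: int = 10
    interval_years: int = 1
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    drift: float = 0.05
    accel: float = 0.45
    accel_years: int = 3
    noise_sd: float = 0.5
    hazard_intercept: float = -3.0
    log_or_latent: float = float(np.log(1.8))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_years > self.horizon_years:
            raise ScreeningError("interval must not exceed the horizon")
        if self.interval_years < 1:
            raise ScreeningError("interval must be >= 1 year")
        if self.noise_sd < 0:
            raise ScreeningError("noise SD must be >= 0")


@dataclass
class Trajectories:
    """Latent and observed scores on a yearly grid.

    ``latent`` and ``observed`` are (n_subjects, horizon+1) arrays
    indexed by calendar year 0..horizon; ``observed`` is NaN at years
    without a scheduled scan.  ``conversion_year`` is NaN for subjects
    who do not convert within the horizon.
    """

    latent: np.ndarray
    observed: np.ndarray
    conversion_year: np.ndarray
    scan_years: np.ndarray
    config: ScreeningConfig


@dataclass
class ScreeningResult:
    interval_years: int
    auc_recent_scan: float       # most-recent-scan AUC over the horizon
    auc_baseline_scan: float     # single baseline scan, same pairs
    n_converters: int
    n_stable: int


def simulate_trajectories(config: ScreeningConfig, seed: int | None = None) -> Trajectories:
    """Draw latent trajectories, conversion times and scheduled scans."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, h = config.n_subjects, config.horizon_years
    latent0 = rng.normal(config.latent_mean, config.latent_sd, n)
    z0 = (latent0 - config.latent_mean) / config.latent_sd
    p_year = 1.0 / (1.0 + np.exp(-(config.hazard_intercept + config.log_or_latent * z0)))

    conversion = np.full(n, np.nan)
    draws = rng.random((n, h))
    for year in range(1, h + 1):
        new = np.isnan(conversion) & (draws[:, year - 1] < p_year)
        conversion[new] = year

    years = np.arange(h + 1)
    latent = latent0[:, None] + config.drift * years[None, :]
    # converters accelerate in the accel window before their event
    for j in np.flatnonzero(~np.isnan(conversion)):
        t_conv = conversion[j]
        start = max(0.0, t_conv - config.accel_years)
        extra = np.clip(years - start, 0.0, t_conv - start)
        latent[j] += config.accel * extra

    scan_years = np.arange(0, h + 1, config.interval_years)
    observed = np.full_like(latent, np.nan)
    noise = rng.normal(0.0, config.noise_sd, (n, len(scan_years)))
    observed[:, scan_years] = latent[:, scan_years] + noise
    return Trajectories(latent=latent, observed=observed,
                        conversion_year=conversion, scan_years=scan_years,
                        config=config)


def _most_recent_scan(traj: Trajectories, year: int) -> np.ndarray:
    """Latest observed scan at or before ``year`` for every subject."""
    usable = traj.scan_years[traj.scan_years <= year]
    if len(usable) == 0:
        raise ScreeningError(f"no scans available by year {year}")
    last = usable.max()
    return traj.observed[:, last]


def evaluate_screening(traj: Trajectories, interval: int | None = None) -> ScreeningResult:
    """Pooled time-dependent AUC of a rolling re-scan program.

    For each event year t, converters at t are paired against subjects
    still event-free at t; both are scored with their most recent scan
    strictly before t (no older than the interval by construction).
    Pooling the (score, outcome) pairs across event years gives the
    program-level AUC; scoring the same pairs with the baseline scan
    gives the single-scan comparator.
    """
    cfg = traj.config
    interval = cfg.interval_years if interval is None else interval
    conv = traj.conversion_year
    scores_recent: list[np.ndarray] = []
    scores_base: list[np.ndarray] = []
    outcomes: list[np.ndarray] = []
    for year in range(1, cfg.horizon_years + 1):
        events = conv == year
        at_risk = np.isnan(conv) | (conv >= year)
        if not events.any():
            continue
        recent = _most_recent_scan(traj, year - 1)
        keep = at_risk & ~np.isnan(recent)
        scores_recent.append(recent[keep])
        scores_base.append(traj.observed[keep, 0])
        outcomes.append(events[keep].astype(int))
    if not outcomes:
        raise ScreeningError("no conversions within the horizon; AUC undefined")
    score_r = np.concatenate(scores_recent)
    score_b = np.concatenate(scores_base)
    y = np.concatenate(outcomes)
    return ScreeningResult(
        interval_years=interval,
        auc_recent_scan=rank_auc(score_r, y),
        auc_baseline_scan=rank_auc(score_b, y),
        n_converters=int(np.sum(~np.isnan(conv))),
        n_stable=int(np.sum(np.isnan(conv))),
    )


def baseline_auc_decay(traj: Trajectories) -> dict[int, float]:
    """AUC of the single baseline scan for predicting incident
    conversion at each gap year (converters at year t vs subjects still
    event-free at t).  Years with no events are omitted."""
    conv = traj.conversion_year
    base = traj.observed[:, 0]
    out: dict[int, float] = {}
    for year in range(1, traj.config.horizon_years + 1):
        events = conv == year
        at_risk = np.isnan(conv) | (conv >= year)
        if not events.any() or not (at_risk & ~events).any():
            continue
        keep = at_risk
        out[year] = rank_auc(base[keep], events[keep].astype(int))
    return out
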