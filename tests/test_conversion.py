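import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from rvindex.conversion import (
    ConversionError,
    build_risk_sets,
    fit_conversion,
    lr_test,
    or_series,
    rank_auc,
    roc_auc,
)
from rvindex.io_formats import StatusPanel


def _panel(rows):
    return StatusPanel(pd.DataFrame(rows, columns=["subject_id", "visit_year", "status"]))


def _sim_cohort(n=600, beta=0.6, seed=0, horizon=6, dropout=0.0, p0=0.08):
    """Yearly logistic conversion driven by a known per-SD slope."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    xz = (x - x.mean()) / x.std(ddof=1)
    alpha = np.log(p0 / (1 - p0))
    p = 1 / (1 + np.exp(-(alpha + beta * xz)))
    rows = []
    for j in range(n):
        sid = f"S{j}"
        rows.append((sid, 0, "MCI"))
        status = "MCI"
        for year in range(1, horizon + 1):
            if dropout and rng.random() < dropout:
                break
            if status == "MCI" and rng.random() < p[j]:
                status = "dementia"
            rows.append((sid, year, status))
    panel = _panel(rows)
    X = pd.DataFrame({"score": x}, index=pd.Index([f"S{j}" for j in range(n)],
                                                  name="subject_id"))
    return panel, X


class TestBuildRiskSets:
    def test_hand_enumerated_toy_panel(self, toy_panel):
        sets = build_risk_sets(toy_panel, mode="annual", horizon=3)
        y2 = sets[1]
        assert y2.year == 2
        assert set(y2.subjects) == {"conv", "stable"}  # dropout exited after year 1
        out = dict(zip(y2.subjects, y2.outcome))
        assert out == {"conv": 1, "stable": 0}
        y1 = sets[0]
        assert set(y1.subjects) == {"conv", "stable", "drop"}
        assert y1.n_events == 0

    def test_converter_is_event_in_exactly_one_annual_set(self, toy_panel):
        sets = build_risk_sets(toy_panel, mode="annual", horizon=12)
        events = [rs for rs in sets if "conv" in rs.subjects
                  and rs.outcome[rs.subjects.index("conv")] == 1]
        assert len(events) == 1 and events[0].year == 2
        # and exits the risk set afterwards
        assert all("conv" not in rs.subjects for rs in sets if rs.year > 2)

    def test_nobody_converts_all_outcomes_zero(self):
        rows = [(s, y, "MCI") for s in ("A", "B") for y in range(4)]
        sets = build_risk_sets(_panel(rows), horizon=3)
        assert all(rs.n_events == 0 for rs in sets)

    def test_everyone_converts_year1_leaves_year2_empty(self):
        rows = []
        for s in ("A", "B"):
            rows += [(s, 0, "MCI"), (s, 1, "dementia"), (s, 2, "dementia")]
        sets = build_risk_sets(_panel(rows), horizon=2)
        assert sets[0].n_events == 2
        assert sets[1].n == 0

    def test_accounting_conserves_subjects(self):
        panel, _ = _sim_cohort(n=300, beta=0.5, seed=4, horizon=8, dropout=0.05)
        sets = build_risk_sets(panel, mode="annual", horizon=8)
        last = panel.last_visit()
        for t in range(len(sets) - 1):
            at_risk_t = set(sets[t].subjects)
            incident = {s for s, o in zip(sets[t].subjects, sets[t].outcome) if o == 1}
            censored = {s for s in at_risk_t - incident if last[s] == sets[t].year}
            assert set(sets[t + 1].subjects) == at_risk_t - incident - censored

    def test_cumulative_year1_equals_annual_year1(self, toy_panel):
        a = build_risk_sets(toy_panel, mode="annual", horizon=1)[0]
        c = build_risk_sets(toy_panel, mode="cumulative", horizon=1)[0]
        assert sorted(a.subjects) == sorted(c.subjects)
        assert dict(zip(a.subjects, a.outcome)) == dict(zip(c.subjects, c.outcome))

    def test_multiyear_gap_assigns_first_observed_year(self):
        rows = [("A", 0, "MCI"), ("A", 5, "dementia"), ("B", 0, "MCI"),
                ("B", 5, "MCI")]
        sets = build_risk_sets(_panel(rows), mode="annual", horizon=5)
        y5 = sets[4]
        assert dict(zip(y5.subjects, y5.outcome))["A"] == 1

    def test_bad_horizon_rejected(self, toy_panel):
        with pytest.raises(ConversionError, match="horizon"):
            build_risk_sets(toy_panel, horizon=0)


class TestFitConversion:
    def test_known_slope_recovered(self):
        # average the point estimate over replicates: mean log-OR within
        # Monte-Carlo error of the generating slope
        betas = []
        for seed in range(12):
            panel, X = _sim_cohort(n=1200, beta=0.6, seed=seed, horizon=1, p0=0.15)
            rs = build_risk_sets(panel, horizon=1)[0]
            betas.append(np.log(fit_conversion(rs, X).odds_ratios["score"]))
        assert np.mean(betas) == pytest.approx(0.6, abs=0.06)

    def test_or_is_per_sd_and_ci_brackets_or(self):
        panel, X = _sim_cohort(n=800, beta=0.5, seed=2, horizon=1, p0=0.2)
        rs = build_risk_sets(panel, horizon=1)[0]
        fit = fit_conversion(rs, X)
        orv = fit.odds_ratios["score"]
        lo, hi = fit.conf_int.loc["score"]
        assert lo < orv < hi and orv > 0
        assert fit.scaling.loc["score", "sd"] == pytest.approx(
            X.loc[fit.subjects, "score"].std(ddof=1), rel=1e-9)

    def test_row_duplication_leaves_point_estimate_unchanged(self):
        panel, X = _sim_cohort(n=300, beta=0.5, seed=3, horizon=1, p0=0.2)
        rs = build_risk_sets(panel, horizon=1)[0]
        fit = fit_conversion(rs, X)
        rs2 = type(rs)(year=1, subjects=rs.subjects * 2,
                       outcome=np.r_[rs.outcome, rs.outcome], mode="annual")
        fit_raw = fit_conversion(rs, X, standardize=False)
        fit2 = fit_conversion(rs2, X, standardize=False)
        assert fit2.params["score"] == pytest.approx(fit_raw.params["score"], rel=1e-6)
        # standardized ORs agree up to the finite-sample ddof change in the SD
        fit2_std = fit_conversion(rs2, X)
        assert fit2_std.odds_ratios["score"] == pytest.approx(
            fit.odds_ratios["score"], rel=1e-3)

    def test_single_class_risk_set_rejected(self):
        rows = [("A", 0, "MCI"), ("A", 1, "MCI"), ("B", 0, "MCI"), ("B", 1, "MCI")]
        rs = build_risk_sets(_panel(rows), horizon=1)[0]
        X = pd.DataFrame({"score": [0.1, 0.2]}, index=pd.Index(["A", "B"], name="subject_id"))
        with pytest.raises(ConversionError, match="single-class"):
            fit_conversion(rs, X)

    def test_separation_detected(self):
        rows = []
        for j in range(40):
            sid = f"S{j}"
            rows += [(sid, 0, "MCI"), (sid, 1, "dementia" if j < 20 else "MCI")]
        rs = build_risk_sets(_panel(rows), horizon=1)[0]
        X = pd.DataFrame({"score": np.r_[np.ones(20), np.zeros(20)] * 5},
                         index=pd.Index([f"S{j}" for j in range(40)], name="subject_id"))
        with pytest.raises(ConversionError, match="separat"):
            fit_conversion(rs, X)

    def test_matches_irls_oracle_on_small_fixture(self):
        panel, X = _sim_cohort(n=120, beta=0.8, seed=5, horizon=1, p0=0.3)
        rs = build_risk_sets(panel, horizon=1)[0]
        fit = fit_conversion(rs, X, standardize=False)
        # hand-rolled iteratively reweighted least squares
        y = rs.outcome.astype(float)
        x = X.loc[rs.subjects, "score"].to_numpy()
        Xd = np.column_stack([np.ones_like(x), x])
        beta = np.zeros(2)
        for _ in range(60):
            mu = 1 / (1 + np.exp(-Xd @ beta))
            W = mu * (1 - mu)
            grad = Xd.T @ (y - mu)
            H = Xd.T @ (Xd * W[:, None])
            beta = beta + np.linalg.solve(H, grad)
        assert fit.params["score"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-8)


class TestOrSeries:
    def test_single_class_years_reported_not_dropped(self):
        rows = []
        for j in range(30):
            sid = f"S{j}"
            rows += [(sid, 0, "MCI"), (sid, 1, "MCI"),
                     (sid, 2, "dementia" if j < 10 else "MCI")]
        panel = _panel(rows)
        X = pd.DataFrame({"score": np.random.default_rng(0).standard_normal(30)},
                         index=pd.Index([f"S{j}" for j in range(30)], name="subject_id"))
        fits = or_series(panel, X, horizon=2)
        assert len(fits) == 2
        assert fits[0] is None          # no events in year 1
        assert fits[1] is not None

    def test_cumulative_year1_fit_equals_annual_year1_fit(self):
        panel, X = _sim_cohort(n=500, beta=0.5, seed=6, horizon=3, p0=0.2)
        fa = or_series(panel, X, mode="annual", horizon=1)[0]
        fc = or_series(panel, X, mode="cumulative", horizon=1)[0]
        assert fa.odds_ratios["score"] == pytest.approx(fc.odds_ratios["score"], rel=1e-9)

    def test_attenuating_hazard_gives_declining_or(self):
        # slope halves every year: fitted annual ORs should decline
        rng = np.random.default_rng(7)
        n, horizon = 4000, 4
        x = rng.standard_normal(n)
        rows = []
        for j in range(n):
            sid = f"S{j}"
            rows.append((sid, 0, "MCI"))
            status = "MCI"
            for year in range(1, horizon + 1):
                beta = 1.2 * 0.5 ** (year - 1)
                p = 1 / (1 + np.exp(-(-2.0 + beta * x[j])))
                if status == "MCI" and rng.random() < p:
                    status = "dementia"
                rows.append((sid, year, status))
        X = pd.DataFrame({"score": x}, index=pd.Index([f"S{j}" for j in range(n)],
                                                      name="subject_id"))
        fits = or_series(_panel(rows), X, horizon=horizon)
        ors = [f.odds_ratios["score"] for f in fits if f is not None]
        assert len(ors) == horizon
        assert ors[0] > ors[-1]
        assert ors[0] == max(ors)


class TestLrTest:
    def _fits(self, seed=0):
        panel, X = _sim_cohort(n=700, beta=0.6, seed=seed, horizon=1, p0=0.2)
        rng = np.random.default_rng(seed + 1)
        X2 = X.assign(noise=rng.standard_normal(len(X)))
        rs = build_risk_sets(panel, horizon=1)[0]
        return fit_conversion(rs, X2), fit_conversion(rs, X)

    def test_identical_models_give_chi2_zero_p_one(self):
        full, _ = self._fits()
        chi2, df, p = lr_test(full, full)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_adding_predictor_never_decreases_llf(self):
        full, reduced = self._fits(seed=2)
        assert full.llf >= reduced.llf - 1e-9
        chi2, df, p = lr_test(full, reduced)
        assert df == 1 and chi2 >= 0 and 0 < p <= 1

    def test_useless_predictor_chi2_is_chi2_1(self):
        chis = [lr_test(*self._fits(seed=s)) [0] for s in range(200)]
        assert abs(np.mean(chis) - 1.0) < 0.25   # E[chi2_1] = 1

    def test_non_nested_rejected(self):
        panel, X = _sim_cohort(n=300, beta=0.5, seed=9, horizon=1, p0=0.2)
        rs = build_risk_sets(panel, horizon=1)[0]
        fit_a = fit_conversion(rs, X.rename(columns={"score": "a"}))
        fit_b = fit_conversion(rs, X.rename(columns={"score": "b"}))
        with pytest.raises(ConversionError, match="nested"):
            lr_test(fit_a, fit_b)


class TestAuc:
    def test_perfect_separation_gives_one(self):
        score = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        assert rank_auc(score, y) == 1.0

    def test_brute_force_pair_count_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            score = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            pos, neg = score[y == 1], score[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert rank_auc(score, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(21)
        for _ in range(10):
            score = rng.standard_normal(150)
            y = (rng.random(150) < 0.35).astype(int)
            assert rank_auc(score, y) == pytest.approx(roc_auc_score(y, score))

    def test_single_class_rejected(self):
        with pytest.raises(ConversionError, match="one outcome class"):
            rank_auc(np.arange(5.0), np.ones(5))

    def test_roc_auc_monotone_transform_invariant(self):
        panel, X = _sim_cohort(n=500, beta=0.8, seed=13, horizon=1, p0=0.2)
        rs = build_risk_sets(panel, horizon=1)[0]
        fit = fit_conversion(rs, X)
        auc_prob = roc_auc(fit, rs, X)
        auc_raw = rank_auc(X.loc[rs.subjects, "score"], rs.outcome)
        assert auc_prob == pytest.approx(auc_raw, abs=1e-12)
        assert auc_prob > 0.5
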