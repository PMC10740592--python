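"""Diel/lunar covariates, hourly rates, and the hurdle-model parts."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from kelptrack import movement as mv

LAT, LON = 32.85, -117.27


def coas_from_offsets(offsets_xy, start="2021-03-02 10:00", tag="A"):
    """Ten-minute COA rows from a list of (x, y) positions."""
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "tag_id": tag,
        "interval_start": [t0 + pd.Timedelta(minutes=10 * i)
                           for i in range(len(offsets_xy))],
        "x": [p[0] for p in offsets_xy],
        "y": [p[1] for p in offsets_xy],
        "n_detections": 3, "n_receivers": 1,
    })


def simulate_records(beta, sigma_alpha, n_ind, n_per, seed, kind="binary",
                     sigma_e=300.0):
    """Movement-rate records with known diel effects (dawn reference)."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_ind):
        alpha = rng.normal(0, sigma_alpha)
        diel = rng.choice(mv.DIEL_LEVELS, n_per)
        eta = (beta["(Intercept)"] + alpha
               + np.select([diel == lev for lev in mv.DIEL_LEVELS[1:]],
                           [beta[f"diel[{lev}]"] for lev in mv.DIEL_LEVELS[1:]],
                           0.0))
        if kind == "binary":
            moved = (rng.random(n_per) < expit(eta)).astype(int)
            rate = moved * 100.0
        else:
            rate = eta + rng.normal(0, sigma_e, n_per)
            moved = (rate > 0).astype(int)
        frames.append(pd.DataFrame({
            "tag_id": f"F{i}", "hour_start": pd.Timestamp("2021-03-01"),
            "rate": rate, "moved": moved, "diel": diel, "lunar": "new",
            "month": 3}))
    return pd.concat(frames, ignore_index=True)


class TestDielPeriod:
    def test_noon_is_day_midnight_is_night(self):
        tz = "America/Los_Angeles"
        assert mv.diel_period(pd.Timestamp("2021-06-21 12:30", tz=tz),
                              LAT, LON) == "day"
        assert mv.diel_period(pd.Timestamp("2021-06-21 00:00", tz=tz),
                              LAT, LON) == "night"

    def test_partition_over_a_day_no_gaps(self):
        times = pd.Series(pd.date_range("2021-03-20 00:00", periods=24 * 12,
                                        freq="5min", tz="America/Los_Angeles"))
        labels = mv.diel_period_series(times, LAT, LON)
        assert set(labels) == {"dawn", "day", "dusk", "night"}
        # contiguous blocks through the day: night..dawn..day..dusk..night
        changes = labels[labels.shift() != labels]
        assert list(changes) == ["night", "dawn", "day", "dusk", "night"]

    def test_polar_latitudes_rejected(self):
        with pytest.raises(ValueError):
            mv.diel_period(pd.Timestamp("2021-06-21 12:00", tz="UTC"), 70.0, 0.0)

    def test_scalar_and_series_agree(self):
        t = pd.Timestamp("2021-09-10 06:15", tz="America/Los_Angeles")
        assert mv.diel_period(t, LAT, LON) == \
            mv.diel_period_series(pd.Series([t]), LAT, LON).iloc[0]


class TestLunarPhase:
    ANCHOR = pd.Timestamp("2000-01-06 18:14", tz="UTC")

    def test_anchor_epoch_is_new(self):
        assert mv.lunar_phase(self.ANCHOR) == "new"

    def test_half_cycle_is_full(self):
        assert mv.lunar_phase(self.ANCHOR + pd.Timedelta(days=14.765)) == "full"

    def test_full_cycle_back_to_new(self):
        assert mv.lunar_phase(self.ANCHOR + pd.Timedelta(days=29.53)) == "new"

    def test_quarter_cycle_waxing_three_quarters_waning(self):
        q = 29.530588 / 4
        assert mv.lunar_phase(self.ANCHOR + pd.Timedelta(days=q)) == "waxing"
        assert mv.lunar_phase(self.ANCHOR + pd.Timedelta(days=3 * q)) == "waning"


class TestHourlyRates:
    def test_six_identical_coas_give_zero_rate(self):
        coas = coas_from_offsets([(5.0, 5.0)] * 6)
        out = mv.hourly_movement_rates(coas, LAT, LON)
        assert len(out) == 1
        assert out["rate"].iloc[0] == 0.0
        assert out["moved"].iloc[0] == 0

    def test_colinear_steps_sum_distances(self):
        coas = coas_from_offsets([(100.0 * i, 0.0) for i in range(6)])
        out = mv.hourly_movement_rates(coas, LAT, LON)
        assert out["rate"].iloc[0] == pytest.approx(500.0)
        assert out["moved"].iloc[0] == 1

    def test_incomplete_hour_emits_nothing(self):
        coas = coas_from_offsets([(0.0, 0.0)] * 5)
        assert mv.hourly_movement_rates(coas, LAT, LON).empty

    def test_row_order_invariance(self):
        coas = coas_from_offsets([(100.0 * i, 50.0 * i) for i in range(6)])
        shuffled = coas.sample(frac=1, random_state=1)
        a = mv.hourly_movement_rates(coas, LAT, LON)
        b = mv.hourly_movement_rates(shuffled, LAT, LON)
        pd.testing.assert_frame_equal(a, b)

    def test_covariates_derived_not_supplied(self):
        coas = coas_from_offsets([(0.0, 0.0)] * 6, start="2021-07-10 12:00")
        out = mv.hourly_movement_rates(coas, LAT, LON)
        assert out["diel"].iloc[0] == "day"
        assert out["month"].iloc[0] == 7


class TestBinaryPart:
    def test_intercept_only_balanced_data_near_zero(self):
        rng = np.random.default_rng(0)
        rec = simulate_records({"(Intercept)": 0.0, "diel[day]": 0.0,
                                "diel[dusk]": 0.0, "diel[night]": 0.0},
                               0.0, 4, 500, seed=1)
        rec["moved"] = rng.permutation(np.repeat([0, 1], len(rec) // 2))
        fit = mv.fit_binary_part(rec, include_diel=False, include_lunar=False,
                                 include_month=False)
        assert abs(fit.params[0]) < 0.1

    def test_pooled_logit_oracle_at_sigma_zero(self):
        import statsmodels.api as sm

        beta = {"(Intercept)": 0.8, "diel[day]": 0.4, "diel[dusk]": -0.3,
                "diel[night]": -0.4}
        rec = simulate_records(beta, 0.0, 5, 1200, seed=3)
        fit = mv.fit_binary_part(rec, include_lunar=False, include_month=False)
        X, _ = mv.build_design(rec, include_lunar=False, include_month=False)
        oracle = sm.Logit(rec["moved"].to_numpy(), X).fit(disp=0)
        assert np.allclose(fit.params, oracle.params, rtol=1e-3)

    def test_single_seed_recovery_within_four_se(self):
        beta = {"(Intercept)": 0.8, "diel[day]": 0.4, "diel[dusk]": -0.3,
                "diel[night]": -0.4}
        rec = simulate_records(beta, 0.5, 5, 3000, seed=11)
        fit = mv.fit_binary_part(rec, include_lunar=False, include_month=False)
        truth = np.array([beta[n] for n in fit.names])
        assert np.all(np.abs(fit.params - truth) < 4 * fit.se)
        assert fit.sigma > 0

    def test_degenerate_level_warns(self):
        rec = simulate_records({"(Intercept)": 0.0, "diel[day]": 0.0,
                                "diel[dusk]": 0.0, "diel[night]": 0.0},
                               0.0, 2, 50, seed=5)
        rec.loc[rec["diel"] == "dusk", "moved"] = 1
        with pytest.warns(UserWarning, match="dusk"):
            try:
                mv.fit_binary_part(rec, include_lunar=False,
                                   include_month=False)
            except Exception:
                pass


class TestPositivePart:
    def _balanced_records(self, beta, sigma_e, n_ind, seed):
        """Identical covariate block per individual: GLS = OLS exactly."""
        rng = np.random.default_rng(seed)
        block = np.repeat(mv.DIEL_LEVELS, 50)
        frames = []
        for i in range(n_ind):
            eta = (beta["(Intercept)"]
                   + np.select([block == lev for lev in mv.DIEL_LEVELS[1:]],
                               [beta[f"diel[{lev}]"]
                                for lev in mv.DIEL_LEVELS[1:]], 0.0))
            rate = eta + rng.normal(0, sigma_e, len(block))
            frames.append(pd.DataFrame({
                "tag_id": f"F{i}", "hour_start": pd.Timestamp("2021-03-01"),
                "rate": np.abs(rate) + 1.0, "moved": 1, "diel": block,
                "lunar": "new", "month": 3}))
        return pd.concat(frames, ignore_index=True)

    def test_ols_oracle_on_balanced_design(self):
        beta = {"(Intercept)": 640.0, "diel[day]": 12.0, "diel[dusk]": 5.0,
                "diel[night]": -78.0}
        rec = self._balanced_records(beta, 100.0, 4, seed=2)
        fit = mv.fit_positive_part(rec, include_lunar=False,
                                   include_month=False)
        X, _ = mv.build_design(rec, include_lunar=False, include_month=False)
        ols = np.linalg.lstsq(X, rec["rate"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.params, ols, rtol=1e-6)

    def test_shift_equivariance(self):
        beta = {"(Intercept)": 640.0, "diel[day]": 12.0, "diel[dusk]": 5.0,
                "diel[night]": -78.0}
        rec = self._balanced_records(beta, 100.0, 4, seed=4)
        shifted = rec.assign(rate=rec["rate"] + 500.0)
        f0 = mv.fit_positive_part(rec, include_lunar=False, include_month=False)
        f1 = mv.fit_positive_part(shifted, include_lunar=False,
                                  include_month=False)
        assert f1.params[0] - f0.params[0] == pytest.approx(500.0, abs=1e-6)
        assert np.allclose(f1.params[1:], f0.params[1:], atol=1e-6)

    def test_single_seed_recovery(self):
        beta = {"(Intercept)": 640.0, "diel[day]": 12.0, "diel[dusk]": 5.0,
                "diel[night]": -78.0}
        rec = simulate_records(beta, 50.0, 5, 2000, seed=6, kind="linear")
        rec["rate"] = np.maximum(rec["rate"], 1.0)  # keep positives
        fit = mv.fit_positive_part(rec, include_lunar=False,
                                   include_month=False)
        truth = np.array([beta[n] for n in fit.names])
        assert np.all(np.abs(fit.params - truth) < 4 * fit.se)


class TestPseudoR2:
    def test_null_model_marginal_zero(self):
        rec = simulate_records({"(Intercept)": 0.3, "diel[day]": 0.0,
                                "diel[dusk]": 0.0, "diel[night]": 0.0},
                               0.0, 3, 400, seed=7)
        fit = mv.fit_binary_part(rec, include_diel=False, include_lunar=False,
                                 include_month=False)
        marginal, conditional = mv.pseudo_r2(fit)
        assert marginal == pytest.approx(0.0, abs=1e-12)
        assert conditional >= marginal

    def test_conditional_at_least_marginal(self):
        beta = {"(Intercept)": 0.8, "diel[day]": 0.4, "diel[dusk]": -0.3,
                "diel[night]": -0.4}
        for seed in range(3):
            rec = simulate_records(beta, 0.5, 5, 800, seed=seed)
            fit = mv.fit_binary_part(rec, include_lunar=False,
                                     include_month=False)
            marginal, conditional = mv.pseudo_r2(fit)
            assert conditional >= marginal >= 0.0

    def test_linear_variance_decomposition_oracle(self):
        beta = {"(Intercept)": 640.0, "diel[day]": 12.0, "diel[dusk]": 5.0,
                "diel[night]": -78.0}
        rec = simulate_records(beta, 50.0, 5, 1000, seed=9, kind="linear")
        rec["rate"] = np.maximum(rec["rate"], 1.0)
        fit = mv.fit_positive_part(rec, include_lunar=False,
                                   include_month=False)
        marginal, conditional = mv.pseudo_r2(fit)
        # independent recomputation from the variance components
        vf = np.var(fit.linpred_fixed, ddof=1)
        denom = vf + fit.sigma_alpha ** 2 + fit.sigma_e ** 2
        assert marginal == pytest.approx(vf / denom, abs=1e-6)
        assert conditional == pytest.approx(
            (vf + fit.sigma_alpha ** 2) / denom, abs=1e-6)


def test_hurdle_decomposition_lossless():
    beta = {"(Intercept)": 0.5, "diel[day]": 0.4, "diel[dusk]": -0.3,
            "diel[night]": -0.4}
    rec = simulate_records(beta, 0.3, 4, 500, seed=10)
    rec.loc[rec["moved"] == 1, "rate"] = np.abs(
        np.random.default_rng(0).normal(600, 200, (rec["moved"] == 1).sum())) + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = mv.fit_hurdle(rec, include_lunar=False, include_month=False)
    n_zero = (rec["rate"] == 0).sum()
    n_pos = (rec["rate"] > 0).sum()
    assert n_zero + n_pos == len(rec)
    assert fit.positive.n_obs == n_pos
    assert fit.binary.n_obs == len(rec)
    report = mv.format_hurdle_report(fit)
    assert "Binary part" in report and "Positive part" in report
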