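"""Synthetic cohort generator: determinism, hazard-model recovery,
missingness injection and the baseline summary table."""

import numpy as np
import pandas as pd
import pytest

from conftest import simple_covs
from graftree.cohort import (
    Cohort,
    CovariateSpec,
    HazardModelSpec,
    MARSpec,
    calibrate_baseline_rate,
    default_covariates,
    default_hazard,
    generate_cohort,
    inject_missingness,
    round_half_away,
    summarize_cohort,
)
from graftree.metrics import concordance_index, km_estimator


class TestGenerate:
    def test_deterministic(self):
        covs = simple_covs()
        hz = HazardModelSpec(baseline_rate=0.003, dropout_rate=0.002)
        a = generate_cohort(500, covs, hz, seed=3)
        b = generate_cohort(500, covs, hz, seed=3)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        c = generate_cohort(500, covs, hz, seed=4)
        assert not a.to_frame().equals(c.to_frame())

    def test_no_signal_concordance_near_half(self):
        hz = HazardModelSpec(baseline_rate=0.004, admin_censor_time=200.0,
                             admin_censor_min=30.0)
        c = generate_cohort(1000, simple_covs(), hz, seed=1)
        score = c.data["level"].to_numpy()  # arbitrary covariate-based risk
        assert abs(concordance_index(c.time, c.event, score) - 0.5) < 0.03

    def test_no_censoring_all_events(self):
        hz = HazardModelSpec(baseline_rate=0.01, admin_censor_time=1e9,
                             admin_censor_min=1e9 - 1, dropout_rate=0.0)
        c = generate_cohort(300, simple_covs(), hz, seed=5)
        assert c.event.all()

    def test_cox_recovers_injected_log_hr(self):
        from graftree.linear import fit_cox

        covs = [CovariateSpec(name="flag", kind="binary", p=0.5)]
        hz = HazardModelSpec(baseline_rate=0.003, log_hr_effects={"flag": np.log(4.27)},
                             admin_censor_time=180.0, admin_censor_min=20.0,
                             dropout_rate=0.002)
        c = generate_cohort(3000, covs, hz, seed=21)
        assert 0.2 < c.event.mean() < 0.8  # mixed censoring, not degenerate
        fit = fit_cox(c)
        beta, se = fit.coef_[0], fit.se_[0]
        assert abs(beta - np.log(4.27)) < 2 * se

    def test_validation_errors_name_field(self):
        with pytest.raises(ValueError, match="n"):
            generate_cohort(1, simple_covs(), HazardModelSpec(baseline_rate=0.01), 0)
        with pytest.raises(ValueError, match="baseline_rate"):
            HazardModelSpec(baseline_rate=0.0)
        with pytest.raises(ValueError, match="missing_rate"):
            CovariateSpec(name="x", kind="binary", p=0.5, missing_rate=1.2)
        with pytest.raises(ValueError, match="frequencies"):
            CovariateSpec(name="x", kind="categorical",
                          categories=("a", "b"), frequencies=(0.6, 0.6))

    def test_event_rate_calibration(self):
        covs = default_covariates()
        hz = calibrate_baseline_rate(covs, default_hazard(), 0.098,
                                     n_pilot=8000, seed=5)
        c = generate_cohort(3117, covs, hz, seed=9)
        assert abs(c.event.mean() - 0.098) < 0.015

    def test_km_matches_exponential_closed_form(self):
        """Zero-effect, zero-censoring cohort: KM tracks exp(-rate*t)."""
        rate = 0.01
        hz = HazardModelSpec(baseline_rate=rate, admin_censor_time=1e9,
                             admin_censor_min=1e9 - 1)
        c = generate_cohort(4000, simple_covs(), hz, seed=13)
        km = km_estimator(c.time, c.event)
        for q in np.arange(0.1, 1.0, 0.1):
            t_q = -np.log(q) / rate  # true survivor deciles
            assert km(t_q) == pytest.approx(q, abs=0.025)


class TestMissingness:
    def test_zero_rates_identity(self):
        covs = simple_covs()
        c = generate_cohort(200, covs, HazardModelSpec(baseline_rate=0.01), seed=2)
        out = inject_missingness(c, covs, "mcar", seed=3)
        pd.testing.assert_frame_equal(out.to_frame(), c.to_frame())

    def test_dsa_like_column_masked_fraction(self):
        covs = [CovariateSpec(name="dsa", kind="binary", p=0.04, missing_rate=0.81)]
        c = generate_cohort(3117, covs, HazardModelSpec(baseline_rate=0.01), seed=4)
        out = inject_missingness(c, covs, "mcar", seed=5)
        assert 2440 <= int(out.mask["dsa"].sum()) <= 2610  # binomial interval

    def test_empirical_rates_near_spec(self):
        covs = default_covariates()
        c = generate_cohort(2000, covs, default_hazard(), seed=6)
        out = inject_missingness(c, covs, "mcar", seed=7)
        frac = out.mask.mean()
        for cv in covs:
            assert abs(frac[cv.name] - cv.missing_rate) <= 0.03

    def test_mar_on_event_raises_event_rows_rate(self):
        covs = [CovariateSpec(name="lab", kind="continuous", mean=0, sd=1,
                              missing_rate=0.2)]
        hz = HazardModelSpec(baseline_rate=0.01, admin_censor_time=150.0,
                             admin_censor_min=20.0)
        c = generate_cohort(4000, covs, hz, seed=8)
        out = inject_missingness(c, covs, MARSpec(on="event", delta=0.3), seed=9)
        m = out.mask["lab"].to_numpy()
        assert m[c.event == 1].mean() > m[c.event == 0].mean()

    def test_time_event_never_masked(self):
        covs = [CovariateSpec(name="time_months", kind="continuous", mean=0, sd=1,
                              missing_rate=0.5)]
        c = generate_cohort(100, simple_covs(), HazardModelSpec(baseline_rate=0.01), 0)
        with pytest.raises(ValueError, match="reserved"):
            inject_missingness(c, covs, "mcar", 0)


class TestSummary:
    @staticmethod
    def _crafted_cohort():
        """3,117 rows with exactly 304 events of whom 201 male."""
        n, n_ev = 3117, 304
        event = np.zeros(n, dtype=int)
        event[:n_ev] = 1
        male = np.zeros(n, dtype=int)
        male[:201] = 1  # events
        male[n_ev:n_ev + 1655] = 1  # non-events
        age = np.full(n, 42.0)
        data = pd.DataFrame({"male": male, "age": age})
        return Cohort(data, np.full(n, 85.0), event)

    def test_overall_event_percent(self):
        s = summarize_cohort(self._crafted_cohort())
        row = s[(s.covariate == "event") & (s.group == "all")].iloc[0]
        assert row["count"] == 304
        assert row["percent"] == 9.8

    def test_male_percent_in_event_group(self):
        s = summarize_cohort(self._crafted_cohort(), group_by_event=True)
        row = s[(s.covariate == "male") & (s.level == "1") & (s.group == "event")].iloc[0]
        assert row["count"] == 201
        assert row["percent"] == 66.1

    def test_categorical_percentages_sum_to_100(self):
        covs = default_covariates()
        c = generate_cohort(800, covs, default_hazard(), seed=3)
        s = summarize_cohort(c, group_by_event=False)
        cat = s[(s.covariate == "esrd_cause") & (s.group == "all")]
        assert cat["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(66.05) == 66.1
        assert round_half_away(9.75) == 9.8
        assert round_half_away(-1.25) == -1.3


class TestIO:
    def test_csv_roundtrip_with_missing(self, tmp_path):
        covs = default_covariates()
        c = generate_cohort(120, covs, default_hazard(), seed=10)
        c = inject_missingness(c, covs, "mcar", seed=11)
        path = tmp_path / "cohort.csv"
        c.to_csv(path)
        back = Cohort.read_csv(path)
        assert back.n == c.n
        assert (back.mask.sum() == c.mask.sum()).all()
        np.testing.assert_allclose(back.time, c.time)
        np.testing.assert_array_equal(back.event, c.event)
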