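"""Age standardization, exposure prevalence, and trend extrapolation."""

import numpy as np
import pandas as pd
import pytest

from dietburden import exposure as exp
from dietburden import synthetic as syn
from dietburden.config import FactorDefinition


def _records(rows):
    df = pd.DataFrame(rows, columns=["person_id", "sex", "age_group", "year", "grams_per_day"])
    df["factor"] = "f"
    return df


def _fdef(direction="risk_increasing", low=0.0, high=30.0, unit=50.0, sites=("stomach",)):
    return FactorDefinition(
        name="f", direction=direction, optimal_low=low, optimal_high=high,
        unit_g_per_day=unit, sites=sites,
    )


STD2 = pd.DataFrame({"age_group": ["20-24", "25-29"], "weight": [0.25, 0.75]})


class TestSummarizeIntake:
    def test_equal_age_means_passthrough(self):
        rec = _records([(0, "male", "20-24", 2010, 7.0), (1, "male", "25-29", 2010, 7.0)])
        s = exp.summarize_intake(rec, "f", STD2)
        assert s["std_mean"].iloc[0] == pytest.approx(7.0)

    def test_hand_weighted_mean(self):
        """Means 10 and 30 under weights 0.25/0.75 standardize to 25."""
        rec = _records([(0, "male", "20-24", 2010, 10.0), (1, "male", "25-29", 2010, 30.0)])
        s = exp.summarize_intake(rec, "f", STD2)
        assert s["std_mean"].iloc[0] == pytest.approx(25.0)
        assert s["crude_mean"].iloc[0] == pytest.approx(20.0)

    def test_standardized_mean_is_convex_combination(self, truth, std_pop):
        rec = syn.generate_intake_survey(truth, [2010], 2000, seed=21)
        s, age_means = exp.summarize_intake(
            rec, "red_meat", std_pop, return_age_means=True
        )
        for row in s.itertuples(index=False):
            m = age_means.loc[
                (age_means["sex"] == row.sex) & (age_means["year"] == row.year), "mean"
            ]
            assert m.min() - 1e-9 <= row.std_mean <= m.max() + 1e-9

    def test_duplication_invariance(self):
        rec = _records([(0, "male", "20-24", 2010, 10.0), (1, "male", "25-29", 2010, 30.0)])
        doubled = pd.concat([rec, rec], ignore_index=True)
        a = exp.summarize_intake(rec, "f", STD2)
        b = exp.summarize_intake(doubled, "f", STD2)
        assert a["std_mean"].iloc[0] == pytest.approx(b["std_mean"].iloc[0])

    def test_missing_age_group_in_standard_errors(self):
        rec = _records([(0, "male", "85+", 2010, 10.0)])
        with pytest.raises(ValueError, match="absent from the standard"):
            exp.summarize_intake(rec, "f", STD2)

    def test_recovers_truth_at_large_n(self, std_pop):
        """Standardized mean within 3 SE of the generator's configured mean."""
        ft = syn.FactorTruth(
            name="f", mean={"male": 60.0, "female": 60.0},
            slope={"male": 0.0, "female": 0.0}, sigma_log=0.7,
        )
        t = syn.SyntheticTruth(factors={"f": ft}, betas={})
        rec = syn.generate_intake_survey(t, [2010], 100_000, seed=22)
        s = exp.summarize_intake(rec, "f", std_pop)
        g = rec["grams_per_day"]
        se = g.std() / np.sqrt(len(g) / 2)  # per-sex stratum size
        for row in s.itertuples(index=False):
            assert abs(row.std_mean - 60.0) < 3 * se


class TestPrevalence:
    def test_all_above_bound_gives_p1(self):
        rec = _records([(i, "male", "20-24", 2010, 100.0 + i) for i in range(5)])
        out = exp.prevalence_outside_optimal(rec, _fdef(high=30.0), STD2)
        assert out["P"].iloc[0] == pytest.approx(1.0)

    def test_no_exposed_gives_p0_dose0(self):
        fd = _fdef(direction="risk_decreasing", low=10.0, high=None)
        rec = _records([(i, "male", "20-24", 2010, 50.0) for i in range(5)])
        out = exp.prevalence_outside_optimal(rec, fd, STD2)
        assert out["P"].iloc[0] == 0.0
        assert out["dose_g"].iloc[0] == 0.0

    def test_gap_dose_is_mean_excess_beyond_bound(self):
        rec = _records([(0, "male", "20-24", 2010, 50.0), (1, "male", "20-24", 2010, 70.0)])
        out = exp.prevalence_outside_optimal(rec, _fdef(high=30.0), STD2)
        assert out["dose_g"].iloc[0] == pytest.approx(30.0)  # mean of 20 and 40

    def test_mean_dose_basis_uses_intake_among_exposed(self):
        rec = _records([(0, "male", "20-24", 2010, 50.0), (1, "male", "20-24", 2010, 70.0),
                        (2, "male", "20-24", 2010, 10.0)])
        out = exp.prevalence_outside_optimal(rec, _fdef(high=30.0), STD2, dose_basis="mean")
        assert out["dose_g"].iloc[0] == pytest.approx(60.0)

    def test_monotone_in_bound(self, survey_records, std_pop):
        """Raising a risk factor's high bound never increases P."""
        prev = None
        for high in (5.0, 20.0, 60.0, 150.0):
            fd = FactorDefinition(
                name="red_meat", direction="risk_increasing", optimal_low=0.0,
                optimal_high=high, unit_g_per_day=120.0, sites=("colorectal",),
            )
            out = exp.prevalence_outside_optimal(survey_records, fd, std_pop)
            p = out["P"].to_numpy()
            if prev is not None:
                assert (p <= prev + 1e-12).all()
            prev = p

    def test_matches_analytic_tail(self, std_pop):
        """Standardized P within 3 binomial SEs of the mixture tail probability."""
        ft = syn.FactorTruth(
            name="f", mean={"male": 50.0, "female": 50.0},
            slope={"male": 0.0, "female": 0.0}, sigma_log=0.8,
            zero_prob={"male": 0.3, "female": 0.3},
        )
        t = syn.SyntheticTruth(factors={"f": ft}, betas={})
        n = 100_000
        rec = syn.generate_intake_survey(t, [2010], n, seed=23)
        fd = _fdef(high=40.0)
        out = exp.prevalence_outside_optimal(rec, fd, std_pop)
        p_star = ft.tail_probability("male", 2010, 40.0, "above")
        se = np.sqrt(p_star * (1 - p_star) / (n / 2))
        for row in out.itertuples(index=False):
            assert abs(row.P - p_star) < 3 * se


class TestTrend:
    def test_exact_linear_series_predicts_exactly(self):
        years = np.arange(2001, 2010)
        vals = 2.0 * years + 3.0
        fit = exp.fit_trend_and_extrapolate(years, vals, [2000, 2030])
        assert fit["predictions"] == pytest.approx([2.0 * 2000 + 3, 2.0 * 2030 + 3])

    def test_constant_series_predicts_constant(self):
        fit = exp.fit_trend_and_extrapolate([2001, 2005, 2010], [4.0, 4.0, 4.0], [2030])
        assert fit["predictions"][0] == pytest.approx(4.0)
        assert fit["slope"] == pytest.approx(0.0)

    def test_noisy_linear_slope_within_3se(self):
        rng = np.random.default_rng(24)
        years = np.arange(2001, 2016)
        vals = 1.5 * years - 2950 + rng.normal(0, 0.8, len(years))
        fit = exp.fit_trend_and_extrapolate(years, vals, [2030])
        assert abs(fit["slope"] - 1.5) < 3 * fit["slope_se"]

    def test_single_year_errors(self):
        with pytest.raises(ValueError):
            exp.fit_trend_and_extrapolate([2010, 2010], [1.0, 2.0], [2020])

    def test_prevalence_clamped_to_unit_interval(self):
        fit = exp.fit_trend_and_extrapolate(
            [2001, 2005], [0.9, 0.99], [2030], clamp=(0.0, 1.0)
        )
        assert fit["predictions"][0] == 1.0


class TestPrevalenceSeries:
    def test_grid_sources(self, survey_records, std_pop, factors):
        fd = next(f for f in factors if f.name == "red_meat")
        series = exp.build_prevalence_series(
            survey_records, fd, std_pop, [2000, 2005, 2010, 2015, 2030]
        )
        src = series.set_index(["sex", "year"])["source"]
        assert src.loc[("male", 2000)] == "extrapolated"  # before first wave (2001)
        assert src.loc[("male", 2005)] == "observed"
        assert src.loc[("male", 2010)] == "observed"
        assert src.loc[("male", 2030)] == "extrapolated"
        assert ((series["P"] >= 0) & (series["P"] <= 1)).all()
        assert (series["dose_g"] >= 0).all()

    def test_interpolated_year(self, truth, std_pop, factors):
        rec = syn.generate_intake_survey(truth, [2001, 2009], 800, seed=25)
        fd = next(f for f in factors if f.name == "red_meat")
        series = exp.build_prevalence_series(rec, fd, std_pop, [2005])
        assert (series["source"] == "interpolated").all()
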