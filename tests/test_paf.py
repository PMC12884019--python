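"""Levin PAF, latency mapping, attributable cases, burden aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietburden import paf as paf_mod
from dietburden.config import FactorDefinition, ScenarioConfig
from dietburden.paf import (
    aggregate,
    aggregate_from_components,
    attributable_cases,
    latency_lookup,
    levin_paf,
)
from oracles import levin_paf_oracle


class TestLevin:
    @pytest.mark.parametrize(
        "P,beta,dose,expected",
        [
            (0.0, 0.5, 3.0, 0.0),        # no exposed => no attributable burden
            (0.4, 0.0, 3.0, 0.0),        # null RR => no attributable burden
            (1.0, math.log(2.0), 1.0, 0.5),  # RR 2 in everyone => half attributable
        ],
    )
    def test_reference_points(self, P, beta, dose, expected):
        assert levin_paf(P, beta, dose) == pytest.approx(expected)

    def test_matches_direct_transcription(self):
        """Oracle equivalence on 1,000 random (P, beta, dose) triples to 1e-12."""
        rng = np.random.default_rng(41)
        for _ in range(1000):
            P = rng.uniform(0, 1)
            beta = rng.uniform(-0.5, 1.0)
            dose = rng.uniform(0, 5)
            if P * math.expm1(beta * dose) <= -1:
                continue
            assert levin_paf(P, beta, dose) == pytest.approx(
                levin_paf_oracle(P, beta, dose), abs=1e-12
            )

    @given(
        st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 5.0)
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity(self, P, beta, dose):
        v = levin_paf(P, beta, dose)
        assert 0 <= v < 1
        eps = 1e-6
        assert levin_paf(min(P + eps, 1.0), beta, dose) >= v
        assert levin_paf(P, beta + eps, dose) > v
        assert levin_paf(P, beta, dose + eps) > v

    def test_saturates_to_one(self):
        assert levin_paf(1.0, 10.0, 10.0) == pytest.approx(1.0, abs=1e-6)

    def test_small_beta_linearization(self):
        """PAF ~ P*beta*dose to second order for beta*dose < 1e-4."""
        for P in (0.2, 0.7, 1.0):
            for bd in (1e-5, 5e-5, 1e-4):
                approx = P * bd
                assert levin_paf(P, bd, 1.0) == pytest.approx(approx, rel=2e-4)

    def test_missigned_beta_raises(self):
        with pytest.raises(ValueError, match="mis-signed|risk direction"):
            levin_paf(1.0, -10.0, 5.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            levin_paf(1.2, 0.1, 1.0)
        with pytest.raises(ValueError):
            levin_paf(0.5, 0.1, -1.0)


class TestLatency:
    @pytest.fixture()
    def series(self):
        return pd.DataFrame(
            {"factor": "f", "sex": "male", "year": [2000, 2005, 2010, 2015, 2020],
             "P": [0.5, 0.4, 0.3, 0.2, 0.1], "dose_g": 10.0, "n_effective": 100}
        )

    def test_table_footnote_mapping(self, series):
        """Burden years 2015-2030 at 15-y latency consume 2000/2005/2010/2015."""
        for target, source in [(2015, 2000), (2020, 2005), (2025, 2010), (2030, 2015)]:
            rows = latency_lookup(target, 15, series)
            assert set(rows["year"]) == {source}

    def test_zero_latency_identity(self, series):
        assert set(latency_lookup(2020, 0, series)["year"]) == {2020}

    def test_twenty_year_latency(self, series):
        assert set(latency_lookup(2030, 20, series)["year"]) == {2010}

    def test_missing_exposure_year_errors(self, series):
        with pytest.raises(KeyError):
            latency_lookup(2010, 15, series)  # would need 1995


class TestAttributableCases:
    def test_values(self):
        assert attributable_cases(0.0, 100) == 0.0
        assert attributable_cases(0.5, 100) == pytest.approx(50.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            attributable_cases(0.5, -1)


class TestAggregateFromComponents:
    def test_single_component_passthrough(self):
        t = aggregate_from_components({"only": 50.0}, 1000.0)
        total = t.loc[t["key"] == "total"].iloc[0]
        assert total["paf"] == pytest.approx(0.05)

    def test_published_ratio_identity(self):
        """14,973 attributable over 246,436 incident cases is 6.08%."""
        t = aggregate_from_components({"all_dietary": 14_973.0}, 246_436.0)
        assert round(100 * t.loc[t["key"] == "total", "paf"].iloc[0], 2) == 6.08


def _mini_inputs():
    """One risk factor / one protective factor on two sites, one year."""
    factors = (
        FactorDefinition(name="risk_f", direction="risk_increasing", optimal_low=0.0,
                         optimal_high=10.0, unit_g_per_day=50.0, sites=("stomach",)),
        FactorDefinition(name="prot_f", direction="risk_decreasing", optimal_low=100.0,
                         unit_g_per_day=100.0, sites=("stomach", "colorectal")),
    )
    cells = pd.DataFrame(
        [
            # factor, site, sex, year, outcome, exp_year, P, n, dose_u, beta, paf, count, ac
            ("risk_f", "stomach", "male", 2020, "incidence", 2005, 0.8, 500, 1.0, 0.1, None, 1000.0, None),
            ("prot_f", "stomach", "male", 2020, "incidence", 2005, 0.5, 500, 0.5, 0.2, None, 1000.0, None),
            ("prot_f", "colorectal", "male", 2020, "incidence", 2005, 0.5, 500, 0.5, 0.2, None, 2000.0, None),
        ],
        columns=paf_mod.CELL_COLUMNS,
    )
    cells["paf"] = levin_paf(cells["P"], cells["beta"], cells["dose_units"])
    cells["ac"] = cells["paf"] * cells["count"]
    counts = pd.DataFrame(
        [
            ("stomach", "male", 2020, "incidence", 1000),
            ("colorectal", "male", 2020, "incidence", 2000),
            ("other", "male", 2020, "incidence", 7000),
        ],
        columns=["site", "sex", "year", "outcome", "count"],
    )
    return factors, cells, counts


class TestAggregate:
    def test_ac_first_identities(self):
        factors, cells, counts = _mini_inputs()
        burden = aggregate(cells, counts, factors)
        # every row: PAF * denominator == AC
        assert np.allclose(burden["paf"] * burden["denominator"], burden["ac"])
        # group AC equals sum of member ACs
        all_row = burden.loc[
            (burden["level"] == "factor_group") & (burden["key"] == "all_dietary")
            & (burden["sex"] == "male")
        ].iloc[0]
        assert all_row["ac"] == pytest.approx(cells["ac"].sum())
        assert all_row["denominator"] == 10_000

    def test_single_factor_single_site_group_equals_cell(self):
        factors, cells, counts = _mini_inputs()
        one = cells.iloc[[0]]
        burden = aggregate(one, counts, factors)
        site_row = burden.loc[(burden["level"] == "site") & (burden["key"] == "stomach")].iloc[0]
        assert site_row["paf"] == pytest.approx(one["paf"].iloc[0])

    def test_site_ac_capped_at_site_count(self, caplog):
        factors, cells, counts = _mini_inputs()
        cells = cells.copy()
        cells.loc[:, "ac"] = [900.0, 800.0, 10.0]  # stomach members sum to 1700 > 1000
        with caplog.at_level("WARNING"):
            burden = aggregate(cells, counts, factors)
        stomach = burden.loc[
            (burden["level"] == "site") & (burden["key"] == "stomach") & (burden["sex"] == "male")
        ].iloc[0]
        assert stomach["ac"] == 1000.0
        assert "capping" in caplog.text

    def test_sex_combined_is_ac_sum_not_paf_average(self, truth, factors):
        """The 'all' row divides summed ACs by the combined denominator."""
        fs, cells, counts = _mini_inputs()
        cells2 = cells.copy()
        cells2["sex"] = "female"
        counts2 = counts.copy()
        counts2["sex"] = "female"
        counts2["count"] = counts2["count"] * 3  # asymmetric denominators
        burden = aggregate(
            pd.concat([cells, cells2], ignore_index=True),
            pd.concat([counts, counts2], ignore_index=True),
            fs,
        )
        row = burden.loc[
            (burden["level"] == "factor_group") & (burden["key"] == "all_dietary")
            & (burden["sex"] == "all")
        ].iloc[0]
        assert row["ac"] == pytest.approx(2 * cells["ac"].sum())
        assert row["denominator"] == 40_000
        paf_m = burden.loc[
            (burden["level"] == "factor_group") & (burden["key"] == "all_dietary")
            & (burden["sex"] == "male"), "paf"].iloc[0]
        paf_f = burden.loc[
            (burden["level"] == "factor_group") & (burden["key"] == "all_dietary")
            & (burden["sex"] == "female"), "paf"].iloc[0]
        assert row["paf"] != pytest.approx((paf_m + paf_f) / 2)

    def test_missing_denominator_errors(self):
        factors, cells, counts = _mini_inputs()
        with pytest.raises(KeyError):
            aggregate(cells, counts.loc[counts["site"] != "colorectal"], factors)


class TestEndToEndIdentity:
    def test_pipeline_paf_equals_direct_formula(self, small_scenario):
        """With known P, beta, dose the cell PAF is Eq-style exact (1e-12)."""
        from dietburden.meta import PooledRR

        fd = FactorDefinition(
            name="risk_f", direction="risk_increasing", optimal_low=0.0,
            optimal_high=10.0, unit_g_per_day=50.0, sites=("stomach",),
        )
        sc = ScenarioConfig(latency=15, target_years=(2020,), factors=(fd,))
        prev = pd.DataFrame(
            {"factor": "risk_f", "sex": ["male"], "year": [2005], "P": [0.63],
             "dose_g": [42.0], "n_effective": [1000]}
        )
        pooled = {
            ("risk_f", "stomach", o): PooledRR(
                factor="risk_f", site="stomach", sex="combined", outcome=o,
                region="korean", beta=0.21, se=0.03, k=3, Q=0.1, q_pvalue=0.9,
                i2=0.0, tau2=0.0, unit_g_per_day=50.0,
            )
            for o in ("incidence", "mortality")
        }
        counts = pd.DataFrame(
            [("stomach", "male", 2020, "incidence", 5000),
             ("stomach", "male", 2020, "mortality", 1500)],
            columns=["site", "sex", "year", "outcome", "count"],
        )
        cells = paf_mod.compute_cells(prev, pooled, [fd], counts, sc)
        expected = levin_paf_oracle(0.63, 0.21, 42.0 / 50.0)
        assert cells["paf"].to_numpy() == pytest.approx([expected] * 2, abs=1e-12)
        assert cells.loc[cells["outcome"] == "incidence", "ac"].iloc[0] == pytest.approx(
            expected * 5000, abs=1e-9
        )
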