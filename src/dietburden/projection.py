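"""Projected cancer counts and future-year burden tables.

Published national projections of cancer cases and deaths are the
preferred denominators for future years and are read verbatim when
supplied.  When absent, a simple trend fallback fits log-linear trends to
historical rates (count / population per stratum) and multiplies the
projected rate by the projected population — adequate for synthetic
end-to-end runs, not a substitute for demographic cohort-component
projection.  Burden computation for future years is otherwise identical:
pooled RRs held fixed, exposure lagged by the latency (so at a 15-year
latency the 2025/2030 burden uses the observed 2010/2015 exposure).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import FactorDefinition, ScenarioConfig
from .meta import PooledRR
from . import paf as paf_mod

logger = logging.getLogger(__name__)

_KEYS = ["site", "sex", "outcome"]


def project_counts(
    observed_counts: pd.DataFrame,
    target_years: Sequence[int],
    population: Optional[pd.DataFrame] = None,
    projected_population: Optional[pd.DataFrame] = None,
    external_counts: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Counts for future years: external projections or a rate-trend fallback.

    ``external_counts`` (site, sex, year, outcome, count) is returned
    verbatim for the requested years when it covers them.  The fallback
    requires >= 3 observed years plus population tables for the observed
    and target years; it fits OLS on log(rate) per (site, sex, outcome)
    stratum and applies the projected rate to the projected population.
    Zero-rate strata stay zero; projected counts are non-negative by
    construction of the log-linear form.
    """
    target_years = sorted(set(int(y) for y in target_years))
    if external_counts is not None:
        ext = external_counts.loc[external_counts["year"].isin(target_years)]
        missing = set(target_years) - set(ext["year"].unique())
        if missing:
            raise ValueError(f"external projections missing years {sorted(missing)}")
        return ext.reset_index(drop=True)

    obs_years = sorted(observed_counts["year"].unique())
    if len(obs_years) < 3:
        raise ValueError(
            "rate-trend fallback needs >= 3 observed years "
            "(or supply external projected counts)"
        )
    if population is None or projected_population is None:
        raise ValueError("fallback projection needs observed and projected population")
    pop = population.groupby(["sex", "year"])["population"].sum()
    proj_pop = projected_population.groupby(["sex", "year"])["population"].sum()

    rows = []
    for key, grp in observed_counts.groupby(_KEYS):
        site, sex, outcome = key
        grp = grp.sort_values("year")
        yrs = grp["year"].to_numpy(dtype=float)
        rates = grp["count"].to_numpy(dtype=float) / np.array(
            [pop.loc[(sex, int(y))] for y in yrs]
        )
        if np.all(rates <= 0):
            pred_rates = {y: 0.0 for y in target_years}
        else:
            # log-linear trend; exact for constant-growth rates
            safe = np.clip(rates, 1e-300, None)
            res = stats.linregress(yrs, np.log(safe))
            pred_rates = {
                y: float(np.exp(res.intercept + res.slope * y)) for y in target_years
            }
        for y in target_years:
            n = proj_pop.loc[(sex, y)]
            rows.append(
                {
                    "site": site,
                    "sex": sex,
                    "year": y,
                    "outcome": outcome,
                    "count": max(0.0, pred_rates[y] * n),
                }
            )
    return pd.DataFrame(rows)


def project_paf(
    scenario: ScenarioConfig,
    prevalence: pd.DataFrame,
    pooled: Mapping[tuple[str, str, str], PooledRR],
    factors: Sequence[FactorDefinition],
    projected_counts: pd.DataFrame,
    target_years: Sequence[int] = (2025, 2030),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Burden table for projection years: same machinery, fixed RRs.

    Returns (cells, burden).  The pooled RRs are used exactly as fitted —
    RR stability across projection years is an assumption, not a refit.
    """
    cells = paf_mod.compute_cells(
        prevalence, pooled, factors, projected_counts, scenario,
        target_years=target_years,
    )
    burden = paf_mod.aggregate(cells, projected_counts, factors)
    return cells, burden
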