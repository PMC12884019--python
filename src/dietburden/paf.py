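"""Dose-modified Levin population-attributable fractions and burden tables.

The attributable fraction for one factor-site cell is

    PAF = P (e^{beta * dose} - 1) / (P (e^{beta * dose} - 1) + 1)

where P is the prevalence of intake outside the optimal range, dose is how
far (in the factor's unit increments) the exposed group sits from the
optimal bound, and beta is the pooled log-RR per unit increment.  For
protective factors the exposed group is the low-intake group and the
risk-direction beta is the negated pooled beta (log of the inverse
protective RR), so the excess-risk term stays non-negative.

Burden is computed AC-first: attributable cases per cell are summed within
a grouping (factor, direction group, site, everything) and the group PAF
is the summed AC over the group's denominator count — never an average of
cell PAFs.  Exposure is lagged by the latency: burden in year Y uses the
exposure state of year Y - L.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import FactorDefinition, ScenarioConfig
from .meta import PooledRR

logger = logging.getLogger(__name__)

#: column order of the per-cell PAF table
CELL_COLUMNS = [
    "factor", "site", "sex", "year", "outcome",
    "exposure_year", "P", "n_effective", "dose_units", "beta", "paf",
    "count", "ac",
]


def levin_paf(P, beta, dose):
    """Dose-modified Levin attributable fraction; vectorised.

    ``dose`` is expressed in the same unit increments as ``beta``.  Raises
    if the excess-risk term P*(e^{beta*dose}-1) falls to -1 or below,
    which can only happen with a mis-signed beta.
    """
    P = np.asarray(P, dtype=float)
    beta = np.asarray(beta, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("P must lie in [0, 1]")
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    x = P * np.expm1(beta * dose)
    if np.any(x <= -1):
        raise ValueError(
            "excess-risk term <= -1; the beta passed to levin_paf must be "
            "oriented in the risk direction (negate pooled protective betas)"
        )
    out = x / (x + 1.0)
    return float(out) if out.ndim == 0 else out


def latency_lookup(
    target_year: int, latency: int, prevalence_series: pd.DataFrame
) -> pd.DataFrame:
    """Exposure state driving burden in ``target_year`` under the latency lag.

    Returns the prevalence rows of year ``target_year - latency`` (e.g.
    burden years 2015/2020/2025/2030 at a 15-year latency consume exposure
    years 2000/2005/2010/2015).
    """
    exposure_year = target_year - latency
    rows = prevalence_series.loc[prevalence_series["year"] == exposure_year]
    if rows.empty:
        raise KeyError(
            f"no prevalence available for exposure year {exposure_year} "
            f"(target {target_year}, latency {latency})"
        )
    return rows


def attributable_cases(paf, count):
    """AC = PAF x count; carried unrounded (round only at reporting time)."""
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be >= 0")
    return paf * count


def risk_direction_beta(pooled: PooledRR, fdef: FactorDefinition) -> float:
    """Beta oriented so the exposed group carries the excess risk.

    Risk-increasing factors use the pooled beta as-is; protective factors
    use the negated pooled beta (log of the inverse protective RR) applied
    to the intake deficit of the low-intake group.
    """
    return pooled.beta if fdef.direction == "risk_increasing" else -pooled.beta


def compute_cells(
    prevalence: pd.DataFrame,
    pooled: Mapping[tuple[str, str, str], PooledRR],
    factors: Sequence[FactorDefinition],
    counts: pd.DataFrame,
    scenario: ScenarioConfig,
    target_years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-(factor, site, sex, year, outcome) PAF and attributable cases.

    ``prevalence`` holds the exposure series (factor, sex, year, P, dose_g,
    n_effective); ``pooled`` maps (factor, site, outcome) to a PooledRR;
    ``counts`` holds site/sex/year/outcome registry counts for the burden
    years.  The exposure year is target year minus latency.
    """
    years = list(target_years if target_years is not None else scenario.target_years)
    cnt = counts.set_index(["site", "sex", "year", "outcome"])["count"]
    rows = []
    for fdef in factors:
        prev_f = prevalence.loc[prevalence["factor"] == fdef.name]
        if prev_f.empty:
            raise KeyError(f"no prevalence series for factor {fdef.name!r}")
        for year in years:
            lagged = latency_lookup(year, scenario.latency, prev_f)
            for site in fdef.sites:
                for outcome in ("incidence", "mortality"):
                    p = pooled.get((fdef.name, site, outcome))
                    if p is None:
                        raise KeyError(
                            f"no pooled RR for {fdef.name}/{site}/{outcome}"
                        )
                    beta = risk_direction_beta(p, fdef)
                    for sex_row in lagged.itertuples(index=False):
                        key = (site, sex_row.sex, year, outcome)
                        if key not in cnt.index:
                            raise KeyError(f"missing count for {key}")
                        dose_units = sex_row.dose_g / fdef.unit_g_per_day
                        paf = levin_paf(sex_row.P, beta, dose_units)
                        count = float(cnt.loc[key])
                        rows.append(
                            {
                                "factor": fdef.name,
                                "site": site,
                                "sex": sex_row.sex,
                                "year": year,
                                "outcome": outcome,
                                "exposure_year": year - scenario.latency,
                                "P": sex_row.P,
                                "n_effective": float(
                                    getattr(sex_row, "n_effective", np.nan)
                                ),
                                "dose_units": dose_units,
                                "beta": beta,
                                "paf": paf,
                                "count": count,
                                "ac": attributable_cases(paf, count),
                            }
                        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def _denominators(counts: pd.DataFrame) -> pd.Series:
    """Total cancer counts by (sex incl. 'all', year, outcome)."""
    by_sex = counts.groupby(["sex", "year", "outcome"])["count"].sum()
    all_sex = counts.groupby(["year", "outcome"])["count"].sum()
    frames = [by_sex]
    frames.append(
        pd.concat({"all": all_sex}, names=["sex"])
    )
    return pd.concat(frames)


def aggregate(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    factors: Sequence[FactorDefinition],
) -> pd.DataFrame:
    """Burden table: AC-first aggregation to factor, group, site and total rows.

    Emits, for each (sex in {male, female, all}, year, outcome):

    * one row per factor (level ``factor``), denominator = all cancers;
    * direction-group rows ``risk_increasing`` / ``risk_decreasing`` and the
      ``all_dietary`` row (level ``factor_group``), same denominator;
    * one row per diet-linked site plus ``all_cancers`` (level ``site``),
      denominator = that site's (or the total) count, with the site AC
      capped at the site count (logged) under the independence assumption.

    Each output row records the member-cell indices of ``cells`` in the
    ``_cell_idx`` column so Monte Carlo resampling can re-aggregate
    coherently; the column is dropped when tables are written out.
    """
    direction = {f.name: f.direction for f in factors}
    denom = _denominators(counts)
    site_cnt = counts.set_index(["site", "sex", "year", "outcome"])["count"]
    site_cnt_all = counts.groupby(["site", "year", "outcome"])["count"].sum()

    rows = []

    def _emit(level, key, sex, year, outcome, idx, denominator, cap=None):
        ac = float(cells.loc[idx, "ac"].sum())
        if cap is not None and ac > cap:
            logger.warning(
                "summed AC %.1f exceeds the %s count %.0f for %s/%s/%s; capping",
                ac, key, cap, sex, year, outcome,
            )
            ac = float(cap)
        if denominator <= 0:
            raise ValueError(f"missing/zero denominator for {key}/{sex}/{year}/{outcome}")
        rows.append(
            {
                "level": level,
                "key": key,
                "sex": sex,
                "year": year,
                "outcome": outcome,
                "ac": ac,
                "denominator": float(denominator),
                "paf": ac / float(denominator),
                "_cell_idx": tuple(idx),
            }
        )

    sexes_present = sorted(cells["sex"].unique())
    for (year, outcome), sub in cells.groupby(["year", "outcome"]):
        for sex in sexes_present + ["all"]:
            ss = sub if sex == "all" else sub.loc[sub["sex"] == sex]
            if ss.empty:
                continue
            total = denom.loc[(sex, year, outcome)]
            # factor rows
            for fname, grp in ss.groupby("factor"):
                _emit("factor", fname, sex, year, outcome, grp.index, total)
            # direction groups and the all-dietary row
            for dname in ("risk_increasing", "risk_decreasing"):
                members = ss.loc[ss["factor"].map(direction) == dname]
                if not members.empty:
                    _emit("factor_group", dname, sex, year, outcome, members.index, total)
            _emit("factor_group", "all_dietary", sex, year, outcome, ss.index, total)
            # site rows
            for site, grp in ss.groupby("site"):
                if sex == "all":
                    d = site_cnt_all.loc[(site, year, outcome)]
                else:
                    d = site_cnt.loc[(site, sex, year, outcome)]
                _emit("site", site, sex, year, outcome, grp.index, d, cap=d)
            _emit("site", "all_cancers", sex, year, outcome, ss.index, total, cap=total)
    return pd.DataFrame(rows)


def aggregate_from_components(
    component_acs: Mapping[str, float], denominator: float
) -> pd.DataFrame:
    """Two-step aggregation from already-summed attributable cases.

    The AC-first identity in its barest form: member ACs are summed and the
    group PAF is total AC / denominator.  Useful for recomputing published
    group PAFs from their printed AC components.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    total_ac = float(sum(component_acs.values()))
    rows = [
        {"key": k, "ac": float(v), "denominator": float(denominator),
         "paf": float(v) / float(denominator)}
        for k, v in component_acs.items()
    ]
    rows.append(
        {"key": "total", "ac": total_ac, "denominator": float(denominator),
         "paf": total_ac / float(denominator)}
    )
    return pd.DataFrame(rows)
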