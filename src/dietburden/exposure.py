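"""Age-standardized intake summaries and exposure prevalence.

Intakes from single-day recalls are summarised per factor, sex and survey
year; means and prevalences are directly age-standardized to a fixed
standard population.  Exposure is defined against a factor's optimal
range: above the upper bound for risk-increasing foods, below the lower
bound for protective ones.  A linear (OLS) trend bridges unsurveyed years:
back-cast to 2000, interpolation between waves, and forecast to 2030, with
prevalence clamped to [0, 1] and intakes to >= 0.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import FactorDefinition

logger = logging.getLogger(__name__)


def _standard_weights(standard_population: pd.DataFrame) -> pd.Series:
    w = standard_population.set_index("age_group")["weight"].astype(float)
    total = w.sum()
    if not total > 0:
        raise ValueError("standard-population weights must sum to > 0")
    return w / total


def _check_age_coverage(records: pd.DataFrame, weights: pd.Series) -> None:
    missing = set(records["age_group"].unique()) - set(weights.index)
    if missing:
        raise ValueError(
            f"age groups present in records but absent from the standard "
            f"population: {sorted(missing)}"
        )


def summarize_intake(
    records: pd.DataFrame,
    factor: str,
    standard_population: pd.DataFrame,
    return_age_means: bool = False,
):
    """Crude and age-standardized mean intake per sex and survey year.

    The standardized mean is the convex combination sum_g w_g * mean_g of
    age-group means under the (renormalised) standard weights; age groups
    absent from a stratum simply contribute their weight to renormalisation.
    """
    sub = records.loc[records["factor"] == factor]
    if sub.empty:
        raise KeyError(f"no records for factor {factor!r}")
    weights = _standard_weights(standard_population)
    _check_age_coverage(sub, weights)

    age_means = (
        sub.groupby(["sex", "year", "age_group"], observed=True)["grams_per_day"]
        .mean()
        .rename("mean")
        .reset_index()
    )
    rows = []
    for (sex, year), grp in age_means.groupby(["sex", "year"]):
        w = weights.loc[grp["age_group"]].to_numpy()
        std_mean = float(np.average(grp["mean"].to_numpy(), weights=w))
        crude = float(
            sub.loc[(sub["sex"] == sex) & (sub["year"] == year), "grams_per_day"].mean()
        )
        rows.append(
            {
                "factor": factor,
                "sex": sex,
                "year": int(year),
                "crude_mean": crude,
                "std_mean": std_mean,
            }
        )
    summary = pd.DataFrame(rows).sort_values(["sex", "year"]).reset_index(drop=True)
    if return_age_means:
        return summary, age_means
    return summary


def _exposed_mask(g: pd.Series, fdef: FactorDefinition) -> pd.Series:
    if fdef.direction == "risk_increasing":
        return g > fdef.exposure_bound
    return g < fdef.exposure_bound


def prevalence_outside_optimal(
    records: pd.DataFrame,
    fdef: FactorDefinition,
    standard_population: pd.DataFrame,
    dose_basis: str = "gap",
) -> pd.DataFrame:
    """Age-standardized prevalence of suboptimal intake, with its dose.

    P is the standardized proportion of individuals beyond the factor's
    optimal bound.  The dose accompanying P is, under the default ``gap``
    basis, the standardized mean absolute gap between intake and the bound
    *among exposed individuals*; under the literal ``mean`` basis it is the
    standardized mean intake among the exposed.  Strata with no exposed
    individuals report P = 0 and dose = 0.
    """
    if dose_basis not in ("gap", "mean"):
        raise ValueError("dose_basis must be 'gap' or 'mean'")
    sub = records.loc[records["factor"] == fdef.name].copy()
    if sub.empty:
        raise KeyError(f"no records for factor {fdef.name!r}")
    weights = _standard_weights(standard_population)
    _check_age_coverage(sub, weights)

    bound = fdef.exposure_bound
    sub["exposed"] = _exposed_mask(sub["grams_per_day"], fdef)
    if dose_basis == "gap":
        sub["dose_contrib"] = (sub["grams_per_day"] - bound).abs()
    else:
        sub["dose_contrib"] = sub["grams_per_day"]

    rows = []
    for (sex, year), grp in sub.groupby(["sex", "year"]):
        by_age = grp.groupby("age_group", observed=True).agg(
            p=("exposed", "mean"), n=("exposed", "size")
        )
        exp_only = (
            grp.loc[grp["exposed"]]
            .groupby("age_group", observed=True)["dose_contrib"]
            .mean()
        )
        by_age["dose"] = exp_only.reindex(by_age.index).fillna(0.0)
        w = weights.loc[by_age.index].to_numpy()
        w = w / w.sum()
        p_std = float(np.dot(w, by_age["p"].to_numpy()))
        # exposure-weighted standardized dose among the exposed
        pw = w * by_age["p"].to_numpy()
        dose = float(np.dot(pw, by_age["dose"].to_numpy()) / pw.sum()) if pw.sum() > 0 else 0.0
        rows.append(
            {
                "factor": fdef.name,
                "sex": sex,
                "year": int(year),
                "P": p_std,
                "dose_g": dose,
                "n_effective": int(by_age["n"].sum()),
            }
        )
    return pd.DataFrame(rows).sort_values(["sex", "year"]).reset_index(drop=True)


def fit_trend_and_extrapolate(
    years: Sequence[float],
    values: Sequence[float],
    target_years: Sequence[float],
    clamp: Optional[tuple[float, float]] = None,
) -> dict:
    """OLS linear trend on calendar year with prediction at target years.

    Returns predictions plus the fitted slope and its standard error.
    Predictions are clamped to ``clamp`` when given (e.g. (0, 1) for a
    prevalence, (0, inf) for an intake).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("need >= 2 distinct observed years to fit a trend")
    res = stats.linregress(years, values)
    pred = res.intercept + res.slope * np.asarray(target_years, dtype=float)
    if clamp is not None:
        pred = np.clip(pred, clamp[0], clamp[1])
    return {
        "predictions": pred,
        "slope": float(res.slope),
        "slope_se": float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        "intercept": float(res.intercept),
    }


def build_prevalence_series(
    records: pd.DataFrame,
    fdef: FactorDefinition,
    standard_population: pd.DataFrame,
    grid_years: Iterable[int],
    dose_basis: str = "gap",
) -> pd.DataFrame:
    """Exposure prevalence and dose on a year grid, per sex.

    Observed survey years are used directly; years inside the observed
    range are linearly interpolated; years outside it (the 2000 back-cast
    and any forecast) come from the OLS trend, clamped to valid ranges.
    Extrapolation beyond the observed range is flagged in the ``source``
    column and logged (relevant e.g. for factors with short survey series).
    """
    observed = prevalence_outside_optimal(
        records, fdef, standard_population, dose_basis=dose_basis
    )
    grid_years = sorted(set(int(y) for y in grid_years))
    frames = []
    for sex, grp in observed.groupby("sex"):
        grp = grp.sort_values("year")
        yrs = grp["year"].to_numpy(dtype=float)
        lo, hi = yrs.min(), yrs.max()
        need_extrap = [y for y in grid_years if y < lo or y > hi]
        if need_extrap:
            logger.info(
                "factor %s (%s): extrapolating beyond observed range %d-%d for %s",
                fdef.name, sex, int(lo), int(hi), need_extrap,
            )
            p_fit = fit_trend_and_extrapolate(yrs, grp["P"], need_extrap, clamp=(0.0, 1.0))
            d_fit = fit_trend_and_extrapolate(
                yrs, grp["dose_g"], need_extrap, clamp=(0.0, np.inf)
            )
            p_ext = dict(zip(need_extrap, p_fit["predictions"]))
            d_ext = dict(zip(need_extrap, d_fit["predictions"]))
        else:
            p_ext, d_ext = {}, {}
        n_typical = int(round(grp["n_effective"].mean()))
        for y in grid_years:
            if y in set(grp["year"]):
                row = grp.loc[grp["year"] == y].iloc[0]
                P, dose, n, src = row["P"], row["dose_g"], int(row["n_effective"]), "observed"
            elif lo <= y <= hi:
                P = float(np.interp(y, yrs, grp["P"]))
                dose = float(np.interp(y, yrs, grp["dose_g"]))
                n, src = n_typical, "interpolated"
            else:
                P, dose = float(p_ext[y]), float(d_ext[y])
                n, src = n_typical, "extrapolated"
            frames.append(
                {
                    "factor": fdef.name,
                    "sex": sex,
                    "year": y,
                    "P": P,
                    "dose_g": dose,
                    "n_effective": n,
                    "source": src,
                }
            )
    return pd.DataFrame(frames).sort_values(["sex", "year"]).reset_index(drop=True)
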