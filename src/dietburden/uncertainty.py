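"""Monte Carlo percentile confidence intervals for PAFs and burden tables.

Per repetition, each pooled log-RR is redrawn from Normal(beta, se) and
each exposure prevalence from a Beta distribution with matching mean and
effective sample size (prevalence held fixed when no sample size backs
it, or when only the relative risks are to vary).  The Levin formula is
re-evaluated cell by cell and the burden table re-aggregated *jointly*
per repetition, so group intervals are coherent with their members under
the cross-factor independence assumption.  Intervals are the 2.5th and
97.5th percentiles of 10,000 repetitions by default.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import FactorDefinition, McSettings
from .meta import PooledRR
from .paf import levin_paf

logger = logging.getLogger(__name__)

_STREAM_MC = 404


def _draw_prevalence(rng, P: float, n_effective: Optional[float], reps: int):
    """Beta draws with mean P and effective sample size n; degenerate cases fixed."""
    if (
        n_effective is None
        or not np.isfinite(n_effective)
        or n_effective <= 0
        or P <= 0.0
        or P >= 1.0
    ):
        return np.full(reps, P)
    a = P * n_effective
    b = (1.0 - P) * n_effective
    return rng.beta(a, b, size=reps)


def mc_interval(
    P: float,
    beta: float,
    dose: float,
    se_beta: float,
    n_effective: Optional[float] = None,
    settings: Optional[McSettings] = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte Carlo percentile CI for a single-cell Levin PAF.

    ``dose`` is in unit increments (matching beta).  With ``se_beta = 0``
    and no prevalence sampling the interval collapses to the point
    estimate.  Fewer than 100 repetitions triggers a warning (the
    percentile estimates are unstable).
    """
    settings = settings or McSettings()
    if se_beta < 0:
        raise ValueError("se_beta must be >= 0")
    if settings.reps < 100:
        warnings.warn("fewer than 100 Monte Carlo reps: interval is unstable")
    rng = np.random.default_rng([seed, _STREAM_MC])
    beta_draws = rng.normal(beta, se_beta, size=settings.reps) if se_beta > 0 else np.full(settings.reps, beta)
    if settings.vary == "rr_and_prevalence":
        p_draws = _draw_prevalence(rng, P, n_effective, settings.reps)
    else:
        p_draws = np.full(settings.reps, P)
    pafs = levin_paf(p_draws, beta_draws, np.full(settings.reps, dose))
    lo, hi = np.percentile(pafs, settings.percentiles)
    return float(lo), float(hi)


def mc_burden_intervals(
    cells: pd.DataFrame,
    burden: pd.DataFrame,
    pooled: Mapping[tuple[str, str, str], PooledRR],
    factors: Sequence[FactorDefinition],
    settings: Optional[McSettings] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Joint Monte Carlo intervals for every burden-table row.

    One repetition perturbs the full vector at once: one beta draw per
    pooled effect (shared by all cells using it) and one prevalence draw
    per (factor, sex, exposure year) stratum (shared across the sites and
    outcomes that stratum feeds), then re-runs Levin and the AC-first
    aggregation.  Returns ``burden`` with paf_low/paf_high/ac_low/ac_high.
    """
    settings = settings or McSettings()
    rng = np.random.default_rng([seed, _STREAM_MC])
    reps = settings.reps
    fdefs = {f.name: f for f in factors}
    n_cells = len(cells)

    # group cells by shared pooled effect and by shared prevalence stratum
    beta_keys = list(dict.fromkeys(
        (r.factor, r.site, r.outcome) for r in cells.itertuples(index=False)
    ))
    beta_idx = {k: i for i, k in enumerate(beta_keys)}
    prev_keys = list(dict.fromkeys(
        (r.factor, r.sex, r.exposure_year) for r in cells.itertuples(index=False)
    ))
    prev_idx = {k: i for i, k in enumerate(prev_keys)}

    beta_draws = np.empty((reps, len(beta_keys)))
    for k, j in beta_idx.items():
        p = pooled[k]
        sign = 1.0 if fdefs[k[0]].direction == "risk_increasing" else -1.0
        if p.se > 0:
            beta_draws[:, j] = sign * rng.normal(p.beta, p.se, size=reps)
        else:
            beta_draws[:, j] = sign * p.beta

    prev_draws = np.empty((reps, len(prev_keys)))
    # prevalence sampling needs an effective sample size; cells without an
    # n_effective column fall back to fixed P
    n_eff_col = "n_effective" in cells.columns
    for k, j in prev_idx.items():
        sub = cells.loc[
            (cells["factor"] == k[0])
            & (cells["sex"] == k[1])
            & (cells["exposure_year"] == k[2])
        ]
        P = float(sub["P"].iloc[0])
        n_eff = float(sub["n_effective"].iloc[0]) if n_eff_col else None
        if settings.vary == "rr_and_prevalence":
            prev_draws[:, j] = _draw_prevalence(rng, P, n_eff, reps)
        else:
            prev_draws[:, j] = P

    # per-cell matrices
    b_col = np.array([beta_idx[(r.factor, r.site, r.outcome)] for r in cells.itertuples(index=False)])
    p_col = np.array([prev_idx[(r.factor, r.sex, r.exposure_year)] for r in cells.itertuples(index=False)])
    dose = cells["dose_units"].to_numpy()
    count = cells["count"].to_numpy()

    paf_mat = levin_paf(prev_draws[:, p_col], beta_draws[:, b_col], dose[None, :])
    ac_mat = paf_mat * count[None, :]

    pos = {idx: j for j, idx in enumerate(cells.index)}
    lo_q, hi_q = settings.percentiles
    out = burden.copy()
    member_idx = burden["_cell_idx"].tolist()
    denominators = burden["denominator"].to_numpy(dtype=float)
    levels = burden["level"].tolist()
    paf_lo = np.empty(len(burden))
    paf_hi = np.empty(len(burden))
    ac_lo = np.empty(len(burden))
    ac_hi = np.empty(len(burden))
    for i in range(len(burden)):
        cols = [pos[j] for j in member_idx[i]]
        ac_rep = ac_mat[:, cols].sum(axis=1)
        if levels[i] == "site":
            np.minimum(ac_rep, denominators[i], out=ac_rep)
        lo, hi = np.percentile(ac_rep, [lo_q, hi_q])
        ac_lo[i], ac_hi[i] = lo, hi
        paf_lo[i], paf_hi[i] = lo / denominators[i], hi / denominators[i]
    out["ac_low"] = ac_lo
    out["ac_high"] = ac_hi
    out["paf_low"] = paf_lo
    out["paf_high"] = paf_hi
    return out


def delta_interval(P: float, beta: float, dose: float, se_beta: float) -> tuple[float, float]:
    """Analytic (delta-method) CI on the PAF; internal cross-check only.

    Propagates se_beta through the Levin formula via d(PAF)/d(beta) at the
    point estimate; prevalence uncertainty is ignored.
    """
    x = P * np.expm1(beta * dose)
    paf = x / (x + 1)
    dpaf_dbeta = P * dose * np.exp(beta * dose) / (x + 1) ** 2
    half = 1.96 * abs(dpaf_dbeta) * se_beta
    return float(paf - half), float(paf + half)
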