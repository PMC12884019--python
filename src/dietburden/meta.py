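"""Random-effects dose-response meta-analysis.

Study-level relative risks per unit increment of intake are pooled with
the DerSimonian-Laird moment estimator.  Because a log-linear
dose-response is assumed, a study reported per u_s g/day rescales to the
target unit u by beta' = beta * u / u_s (and likewise its SE), so pooling
and rescaling commute.  Heterogeneity is summarised by Cochran's Q and
I^2 = max(0, 100 * (Q - (k-1)) / Q); sets failing the screening rule
(Q p-value < 0.05 or I^2 > 50%) are pruned by iterative leave-one-out
removal of the study whose exclusion most reduces I^2, stopping at k = 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = 1.96  # the conventional normal quantile used for reported 95% CIs


@dataclass(frozen=True)
class StudyEffect:
    """One study's dose-response relative risk per its own unit increment."""

    study_id: str
    rr: float
    ci_low: float
    ci_high: float
    unit_g_per_day: float
    design: str = "cohort"
    region: str = "korean"
    sex: str = "combined"
    factor: str = ""
    site: str = ""
    outcome: str = "incidence"

    def __post_init__(self) -> None:
        if min(self.rr, self.ci_low, self.ci_high) <= 0:
            raise ValueError(f"{self.study_id}: RR and CI bounds must be > 0")
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError(f"{self.study_id}: CI must bracket the RR")
        if self.unit_g_per_day <= 0:
            raise ValueError(f"{self.study_id}: unit increment must be > 0")
        if self.ci_high > self.ci_low and self.se <= 0:
            raise ValueError(f"{self.study_id}: derived SE must be > 0")

    @property
    def beta(self) -> float:
        return math.log(self.rr)

    @property
    def se(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * Z95)


@dataclass(frozen=True)
class PooledRR:
    """A pooled per-unit log-RR with heterogeneity diagnostics."""

    factor: str
    site: str
    sex: str
    outcome: str
    region: str
    beta: float
    se: float
    k: int
    Q: float
    q_pvalue: float
    i2: float
    tau2: float
    unit_g_per_day: float
    excluded: tuple[str, ...] = field(default_factory=tuple)

    @property
    def rr(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


def rescale_effect(effect: StudyEffect, target_unit: float) -> StudyEffect:
    """Rescale a study to a different unit increment (log-linearity).

    RR per u_s becomes RR**(u/u_s) per u; equivalently beta and se scale
    by u/u_s, and the CI is recomputed from the scaled beta and se.
    """
    if target_unit <= 0:
        raise ValueError("target_unit must be > 0")
    f = target_unit / effect.unit_g_per_day
    b, s = effect.beta * f, effect.se * f
    return replace(
        effect,
        rr=math.exp(b),
        ci_low=math.exp(b - Z95 * s),
        ci_high=math.exp(b + Z95 * s),
        unit_g_per_day=target_unit,
    )


def _dl_moments(betas: np.ndarray, ses: np.ndarray) -> dict:
    w = 1.0 / ses**2
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - beta_fe) ** 2))
    k = len(betas)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    q_p = float(stats.chi2.sf(Q, k - 1)) if k > 1 else 1.0
    i2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
    return {"beta": beta, "se": se, "Q": Q, "q_pvalue": q_p, "i2": i2, "tau2": tau2}


def pool_dersimonian_laird(
    effects: Sequence[StudyEffect],
    target_unit: float,
    excluded: Iterable[str] = (),
) -> PooledRR:
    """DerSimonian-Laird random-effects pooling at a common unit increment.

    A single study passes through with its own beta and SE (tau^2 set to
    0, Q = 0) and a logged warning, so downstream attributable-fraction
    computation always has an estimate.
    """
    if not effects:
        raise ValueError("no effects to pool")
    scaled = [rescale_effect(e, target_unit) for e in effects]
    first = scaled[0]
    betas = np.array([e.beta for e in scaled])
    ses = np.array([e.se for e in scaled])
    if len(scaled) == 1:
        logger.warning("single-study passthrough for %s/%s", first.factor, first.site)
        m = {"beta": float(betas[0]), "se": float(ses[0]), "Q": 0.0,
             "q_pvalue": 1.0, "i2": 0.0, "tau2": 0.0}
    else:
        m = _dl_moments(betas, ses)
    return PooledRR(
        factor=first.factor,
        site=first.site,
        sex="combined" if len({e.sex for e in scaled}) > 1 else first.sex,
        outcome=first.outcome,
        region=first.region,
        unit_g_per_day=target_unit,
        k=len(scaled),
        excluded=tuple(excluded),
        **m,
    )


def apply_heterogeneity_rule(
    effects: Sequence[StudyEffect],
    target_unit: float,
    threshold_i2: float = 50.0,
    threshold_p: float = 0.05,
) -> tuple[list[StudyEffect], list[str]]:
    """Iterative leave-one-out screening of heterogeneous study sets.

    While the pooled set is heterogeneous (Q p-value < threshold_p or
    I^2 > threshold_i2) and more than two studies remain, remove the one
    study whose exclusion minimises the remaining I^2 (ties broken by the
    lower remaining Q, then study id).  A two-study set that is still
    heterogeneous is returned unchanged with a warning.
    """
    if len(effects) < 2:
        raise ValueError("need >= 2 effects to screen for heterogeneity")
    retained = list(effects)
    removed: list[str] = []
    while True:
        pooled = pool_dersimonian_laird(retained, target_unit)
        bad = pooled.q_pvalue < threshold_p or pooled.i2 > threshold_i2
        if not bad:
            break
        if len(retained) <= 2:
            logger.warning(
                "heterogeneity rule unsatisfiable at k=2 for %s/%s (I2=%.1f, p=%.3g)",
                pooled.factor, pooled.site, pooled.i2, pooled.q_pvalue,
            )
            break
        candidates = []
        for i, e in enumerate(retained):
            rest = retained[:i] + retained[i + 1:]
            p = pool_dersimonian_laird(rest, target_unit)
            candidates.append((p.i2, p.Q, e.study_id, i))
        candidates.sort()
        _, _, sid, idx = candidates[0]
        removed.append(sid)
        retained.pop(idx)
    return retained, removed


def pool_with_screening(
    effects: Sequence[StudyEffect],
    target_unit: float,
    threshold_i2: float = 50.0,
    threshold_p: float = 0.05,
) -> PooledRR:
    """Heterogeneity screening followed by DL pooling of the retained set."""
    if len(effects) == 1:
        return pool_dersimonian_laird(effects, target_unit)
    retained, removed = apply_heterogeneity_rule(
        effects, target_unit, threshold_i2=threshold_i2, threshold_p=threshold_p
    )
    return pool_dersimonian_laird(retained, target_unit, excluded=removed)


def effects_from_frame(df: pd.DataFrame) -> list[StudyEffect]:
    """Parse a study-effect table (the CSV schema) into StudyEffect objects."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            StudyEffect(
                study_id=str(row.study_id),
                rr=float(row.rr),
                ci_low=float(row.ci_low),
                ci_high=float(row.ci_high),
                unit_g_per_day=float(row.unit_g_per_day),
                design=str(getattr(row, "design", "cohort")),
                region=str(getattr(row, "region", "korean")),
                sex=str(getattr(row, "sex", "combined")),
                factor=str(getattr(row, "factor", "")),
                site=str(getattr(row, "site", "")),
                outcome=str(getattr(row, "outcome", "incidence")),
            )
        )
    return out


def pooled_to_frame(pooled: Iterable[PooledRR]) -> pd.DataFrame:
    """Serialise pooled results (with diagnostics and exclusion audit)."""
    rows = []
    for p in pooled:
        rows.append(
            {
                "factor": p.factor,
                "site": p.site,
                "sex": p.sex,
                "outcome": p.outcome,
                "region": p.region,
                "unit_g_per_day": p.unit_g_per_day,
                "beta": p.beta,
                "se": p.se,
                "rr": p.rr,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "k": p.k,
                "Q": p.Q,
                "q_pvalue": p.q_pvalue,
                "i2": p.i2,
                "tau2": p.tau2,
                "excluded_studies": ";".join(p.excluded),
            }
        )
    return pd.DataFrame(rows)
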