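"""The model/results surface tying the pipeline stages together.

``DietaryBurdenModel`` is constructed from the four data inputs —
individual-level single-day intake records, study-level dose-response
effects, registry cancer counts, and a standard population for direct age
standardization — plus a scenario configuration.  ``fit()`` runs the full
chain: exposure prevalence with trend back-cast/forecast, heterogeneity-
screened DerSimonian-Laird pooling, latency-lagged Levin PAFs, AC-first
aggregation, and joint Monte Carlo intervals.  The returned
``DietaryBurdenResults`` carries the burden table with uncertainty, the
per-cell detail, the pooled relative risks with diagnostics, and a
``summary()`` in the style of a registry report.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import exposure as exposure_mod
from . import meta as meta_mod
from . import paf as paf_mod
from . import projection as projection_mod
from . import report as report_mod
from . import uncertainty as uncertainty_mod
from .config import ScenarioConfig
from .meta import PooledRR

logger = logging.getLogger(__name__)


class DietaryBurdenModel:
    """Comparative risk assessment of diet-attributable cancer burden.

    Parameters
    ----------
    intake_records
        Single-day intake table (person_id, sex, age_group, year, factor,
        grams_per_day), e.g. from :mod:`dietburden.synthetic` or a national
        24-hour-recall survey export.
    study_effects
        Study-level dose-response RRs (study_id, design, region, sex,
        factor, site, outcome, rr, ci_low, ci_high, unit_g_per_day).
    cancer_counts
        Registry counts (site, sex, year, outcome, count) for the observed
        burden years.
    standard_population
        Age-group weights (age_group, weight) for direct standardization.
    scenario
        :class:`ScenarioConfig`; defaults to the main-analysis scenario.
    projected_counts, population, projected_population
        Denominators for future burden years: externally projected counts
        are used verbatim; otherwise a rate-trend fallback needs the
        observed and projected population tables.
    """

    def __init__(
        self,
        intake_records: pd.DataFrame,
        study_effects: pd.DataFrame,
        cancer_counts: pd.DataFrame,
        standard_population: pd.DataFrame,
        scenario: Optional[ScenarioConfig] = None,
        projected_counts: Optional[pd.DataFrame] = None,
        population: Optional[pd.DataFrame] = None,
        projected_population: Optional[pd.DataFrame] = None,
    ) -> None:
        self.intake_records = intake_records
        self.study_effects = study_effects
        self.cancer_counts = cancer_counts
        self.standard_population = standard_population
        self.scenario = scenario or ScenarioConfig()
        self.projected_counts = projected_counts
        self.population = population
        self.projected_population = projected_population

    @classmethod
    def from_csv(
        cls,
        intake_path: str,
        effects_path: str,
        counts_path: str,
        standard_population_path: str,
        scenario: Optional[ScenarioConfig] = None,
        projected_counts_path: Optional[str] = None,
    ) -> "DietaryBurdenModel":
        proj = (
            pd.read_csv(projected_counts_path)
            if projected_counts_path is not None
            else None
        )
        return cls(
            intake_records=pd.read_csv(intake_path),
            study_effects=pd.read_csv(effects_path),
            cancer_counts=pd.read_csv(counts_path),
            standard_population=pd.read_csv(standard_population_path),
            scenario=scenario,
            projected_counts=proj,
        )

    # ------------------------------------------------------------------ fit

    def _exposure_years(self, scenario: ScenarioConfig) -> list[int]:
        return sorted({y - scenario.latency for y in scenario.target_years})

    def build_prevalence(self, scenario: Optional[ScenarioConfig] = None) -> pd.DataFrame:
        scenario = scenario or self.scenario
        years = self._exposure_years(scenario)
        frames = [
            exposure_mod.build_prevalence_series(
                self.intake_records,
                fdef,
                self.standard_population,
                years,
                dose_basis=scenario.dose_basis,
            )
            for fdef in scenario.factors
        ]
        return pd.concat(frames, ignore_index=True)

    def pool_relative_risks(
        self, scenario: Optional[ScenarioConfig] = None, rr_region: Optional[str] = None
    ) -> dict[tuple[str, str, str], PooledRR]:
        """Heterogeneity-screened pooled RR per (factor, site, outcome).

        Composite-RR factors are pooled once per outcome over all their
        studies and the pooled estimate is shared across the linked sites.
        """
        scenario = scenario or self.scenario
        region = rr_region or scenario.rr_region
        df = self.study_effects
        df = df.loc[df["region"] == region]
        pooled: dict[tuple[str, str, str], PooledRR] = {}
        for fdef in scenario.factors:
            for outcome in ("incidence", "mortality"):
                if fdef.composite_rr:
                    sub = df.loc[
                        (df["factor"] == fdef.name) & (df["outcome"] == outcome)
                    ]
                    if sub.empty:
                        raise KeyError(
                            f"no {region} studies for {fdef.name}/{outcome}"
                        )
                    effects = meta_mod.effects_from_frame(sub)
                    p = meta_mod.pool_with_screening(
                        effects,
                        fdef.unit_g_per_day,
                        threshold_i2=scenario.heterogeneity_i2_threshold,
                        threshold_p=scenario.heterogeneity_p_threshold,
                    )
                    for site in fdef.sites:
                        pooled[(fdef.name, site, outcome)] = p
                else:
                    for site in fdef.sites:
                        sub = df.loc[
                            (df["factor"] == fdef.name)
                            & (df["site"] == site)
                            & (df["outcome"] == outcome)
                        ]
                        if sub.empty:
                            raise KeyError(
                                f"no {region} studies for {fdef.name}/{site}/{outcome}"
                            )
                        effects = meta_mod.effects_from_frame(sub)
                        pooled[(fdef.name, site, outcome)] = meta_mod.pool_with_screening(
                            effects,
                            fdef.unit_g_per_day,
                            threshold_i2=scenario.heterogeneity_i2_threshold,
                            threshold_p=scenario.heterogeneity_p_threshold,
                        )
        return pooled

    def _counts_for_targets(self, scenario: ScenarioConfig) -> pd.DataFrame:
        observed_years = set(self.cancer_counts["year"].unique())
        targets = list(scenario.target_years)
        have = [y for y in targets if y in observed_years]
        need = [y for y in targets if y not in observed_years]
        frames = [self.cancer_counts.loc[self.cancer_counts["year"].isin(have)]]
        if need:
            frames.append(
                projection_mod.project_counts(
                    self.cancer_counts,
                    need,
                    population=self.population,
                    projected_population=self.projected_population,
                    external_counts=self.projected_counts,
                )
            )
        return pd.concat(frames, ignore_index=True)

    def fit(
        self,
        seed: Optional[int] = None,
        reps: Optional[int] = None,
        rr_region: Optional[str] = None,
    ) -> "DietaryBurdenResults":
        scenario = self.scenario
        seed = scenario.seed if seed is None else seed
        mc = scenario.mc if reps is None else scenario.mc.model_copy(update={"reps": reps})

        prevalence = self.build_prevalence(scenario)
        pooled = self.pool_relative_risks(scenario, rr_region=rr_region)
        counts = self._counts_for_targets(scenario)
        cells = paf_mod.compute_cells(
            prevalence, pooled, scenario.factors, counts, scenario
        )
        burden = paf_mod.aggregate(cells, counts, scenario.factors)
        burden = uncertainty_mod.mc_burden_intervals(
            cells, burden, pooled, scenario.factors, settings=mc, seed=seed
        )
        return DietaryBurdenResults(
            model=self,
            scenario=scenario,
            rr_region=rr_region or scenario.rr_region,
            seed=seed,
            prevalence=prevalence,
            pooled=pooled,
            counts=counts,
            cells=cells,
            burden=burden,
        )

    def fit_sensitivity(
        self, regions: Sequence[str] = ("korean", "asian", "global"),
        seed: Optional[int] = None, reps: Optional[int] = None,
    ) -> dict[str, "DietaryBurdenResults"]:
        """Refit under each RR source region (the sensitivity analysis)."""
        return {r: self.fit(seed=seed, reps=reps, rr_region=r) for r in regions}


class DietaryBurdenResults:
    """Fitted diet-attributable burden with uncertainty and diagnostics."""

    def __init__(
        self,
        model: DietaryBurdenModel,
        scenario: ScenarioConfig,
        rr_region: str,
        seed: int,
        prevalence: pd.DataFrame,
        pooled: Mapping[tuple[str, str, str], PooledRR],
        counts: pd.DataFrame,
        cells: pd.DataFrame,
        burden: pd.DataFrame,
    ) -> None:
        self.model = model
        self.scenario = scenario
        self.rr_region = rr_region
        self.seed = seed
        self.prevalence = prevalence
        self.pooled = pooled
        self.counts = counts
        self.cells = cells
        self.burden = burden

    @property
    def pooled_frame(self) -> pd.DataFrame:
        return meta_mod.pooled_to_frame(self.pooled.values()).drop_duplicates()

    def factor_table(self) -> pd.DataFrame:
        return report_mod.factor_table(self.burden)

    def site_table(self) -> pd.DataFrame:
        return report_mod.site_table(self.burden)

    def paf(self, key: str, year: int, outcome: str = "incidence", sex: str = "all") -> float:
        """Point-estimate PAF (fraction) for a factor, group or site row."""
        b = self.burden
        row = b.loc[
            (b["key"] == key) & (b["year"] == year)
            & (b["outcome"] == outcome) & (b["sex"] == sex)
        ]
        if row.empty:
            raise KeyError(f"no burden row for {key}/{year}/{outcome}/{sex}")
        return float(row["paf"].iloc[0])

    def to_csv(self, outdir: str, burden_by_region=None) -> dict:
        """Write report tables and the run manifest to ``outdir``."""
        return report_mod.render_report(
            self.burden, self.scenario, outdir, self.seed,
            burden_by_region=burden_by_region,
        )

    def summary(self) -> str:
        """Registry-report style text summary of the fitted burden."""
        lines = [
            "Diet-attributable cancer burden",
            "=" * 64,
            f"RR source: {self.rr_region}   latency: {self.scenario.latency} y   "
            f"dose basis: {self.scenario.dose_basis}   "
            f"MC reps: {self.scenario.mc.reps}   seed: {self.seed}",
            "",
        ]
        b = self.burden
        for outcome in ("incidence", "mortality"):
            lines.append(f"{outcome.capitalize()} (both sexes)")
            lines.append(
                f"  {'group/factor':<22}" + "".join(f"{y:>18}" for y in self.scenario.target_years)
            )
            sub = b.loc[
                (b["outcome"] == outcome) & (b["sex"] == "all")
                & b["level"].isin(["factor", "factor_group"])
            ]
            order = [f.name for f in self.scenario.factors] + [
                "risk_increasing", "risk_decreasing", "all_dietary",
            ]
            for key in order:
                rows = sub.loc[sub["key"] == key].set_index("year")
                if rows.empty:
                    continue
                cellstr = []
                for y in self.scenario.target_years:
                    if y in rows.index:
                        r = rows.loc[y]
                        cellstr.append(
                            f"{100 * r['paf']:.2f}% ({report_mod.round_half_up(r['ac']):,})".rjust(18)
                        )
                    else:
                        cellstr.append(f"{'—':>18}")
                lines.append(f"  {key:<22}" + "".join(cellstr))
            lines.append("")
        lines.append(
            "PAF percentages with attributable cases in parentheses; rows are "
            "AC-first aggregates over factor-site cells."
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<DietaryBurdenResults region={self.rr_region!r} "
            f"years={tuple(self.scenario.target_years)} rows={len(self.burden)}>"
        )
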