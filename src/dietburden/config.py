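"""Scenario and factor-definition configuration.

Everything the burden estimate depends on that is a modelling choice rather
than data — optimal intake ranges, unit increments for the dose-response
relative risks, the latency lag, the relative-risk region, the Monte Carlo
settings — lives in one validated configuration object so that a run is
fully described by (config, seed, input files).
"""

from __future__ import annotations

import hashlib
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

Direction = Literal["risk_increasing", "risk_decreasing"]
Region = Literal["korean", "asian", "global"]
Outcome = Literal["incidence", "mortality"]

#: ICD-10 ranges backing each modelled cancer-site label.  "aerodigestive"
#: is the residual upper-aerodigestive + lung group reported alongside the
#: named sites (lip/oral cavity/pharynx C00-C10, other digestive C12-C15,
#: respiratory C30-C34) excluding nasopharynx, stomach and colorectum.
SITE_ICD_CODES: dict[str, tuple[str, ...]] = {
    "nasopharynx": ("C11",),
    "stomach": ("C16",),
    "colorectal": ("C18", "C19", "C20"),
    "aerodigestive": ("C00-C10", "C12-C15", "C30-C34"),
}

SEXES = ("male", "female")


class FactorDefinition(BaseModel):
    """One dietary factor and its link(s) to cancer sites.

    ``direction`` decides what counts as exposed: for a risk-increasing
    factor exposure is intake above ``optimal_high``; for a risk-decreasing
    (protective) factor it is intake below ``optimal_low``.  ``unit_g_per_day``
    is the increment the pooled log-RR refers to.  ``composite_rr`` marks
    factors whose studies report a single dose-response across a composite
    outcome; the one pooled RR is then applied to every linked site.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    direction: Direction
    optimal_low: Optional[float] = None
    optimal_high: Optional[float] = None
    unit_g_per_day: float = Field(gt=0)
    sites: tuple[str, ...]
    episodic: bool = False
    composite_rr: bool = False

    @model_validator(mode="after")
    def _check_bounds(self) -> "FactorDefinition":
        if self.direction == "risk_increasing" and self.optimal_high is None:
            raise ValueError(
                f"risk-increasing factor {self.name!r} needs an optimal_high bound"
            )
        if self.direction == "risk_decreasing" and self.optimal_low is None:
            raise ValueError(
                f"risk-decreasing factor {self.name!r} needs an optimal_low bound"
            )
        if (
            self.optimal_low is not None
            and self.optimal_high is not None
            and self.optimal_low > self.optimal_high
        ):
            raise ValueError(f"factor {self.name!r}: optimal_low > optimal_high")
        if not self.sites:
            raise ValueError(f"factor {self.name!r} has no linked cancer sites")
        return self

    @property
    def exposure_bound(self) -> float:
        """The optimal-range bound that separates exposed from unexposed."""
        if self.direction == "risk_increasing":
            assert self.optimal_high is not None
            return self.optimal_high
        assert self.optimal_low is not None
        return self.optimal_low


def default_factors() -> tuple[FactorDefinition, ...]:
    """The six dietary factors and their seven cancer-site links.

    Optimal ranges follow the GBD 2017 theoretical-minimum-risk exposure
    levels where published (dietary fiber 19-28 g/day, non-starchy
    vegetables and fruits 490-730 g/day, red meat up to ~27 g/day,
    processed meat up to ~4 g/day); for salted vegetables and salted fish,
    which have no GBD TMREL, the thresholds are set at typical global
    average intakes (10 and 5 g/day).  Unit increments match the increments
    the dose-response literature reports on (red meat per 120 g/day,
    processed meat per 50 g/day, salted fish per 20 g/day, fiber per
    10 g/day, vegetables/fruits per 100 g/day, salted vegetables per
    40 g/day ~ one serving).
    """
    return (
        FactorDefinition(
            name="red_meat",
            direction="risk_increasing",
            optimal_low=18.0,
            optimal_high=27.0,
            unit_g_per_day=120.0,
            sites=("colorectal",),
        ),
        FactorDefinition(
            name="processed_meat",
            direction="risk_increasing",
            optimal_low=0.0,
            optimal_high=4.0,
            unit_g_per_day=50.0,
            sites=("colorectal",),
            episodic=True,
        ),
        FactorDefinition(
            name="salted_vegetables",
            direction="risk_increasing",
            optimal_low=0.0,
            optimal_high=10.0,
            unit_g_per_day=40.0,
            sites=("stomach",),
        ),
        FactorDefinition(
            name="salted_fish",
            direction="risk_increasing",
            optimal_low=0.0,
            optimal_high=5.0,
            unit_g_per_day=20.0,
            sites=("nasopharynx", "stomach"),
            episodic=True,
        ),
        FactorDefinition(
            name="dietary_fiber",
            direction="risk_decreasing",
            optimal_low=19.0,
            optimal_high=28.0,
            unit_g_per_day=10.0,
            sites=("colorectal",),
        ),
        FactorDefinition(
            name="vegetables_fruits",
            direction="risk_decreasing",
            optimal_low=490.0,
            optimal_high=730.0,
            unit_g_per_day=100.0,
            sites=("colorectal", "stomach", "aerodigestive"),
            composite_rr=True,
        ),
    )


#: The canonical factor -> site links (a composite link counts once).
CANONICAL_LINKS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("red_meat", ("colorectal",)),
    ("processed_meat", ("colorectal",)),
    ("salted_vegetables", ("stomach",)),
    ("salted_fish", ("nasopharynx",)),
    ("salted_fish", ("stomach",)),
    ("dietary_fiber", ("colorectal",)),
    ("vegetables_fruits", ("colorectal", "stomach", "aerodigestive")),
)


class McSettings(BaseModel):
    """Monte Carlo settings for percentile confidence intervals."""

    model_config = ConfigDict(extra="forbid")

    reps: int = Field(default=10_000, ge=1)
    percentiles: tuple[float, float] = (2.5, 97.5)
    vary: Literal["rr", "rr_and_prevalence"] = "rr_and_prevalence"

    @model_validator(mode="after")
    def _check_percentiles(self) -> "McSettings":
        lo, hi = self.percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        return self


class ScenarioConfig(BaseModel):
    """A fully resolved analysis scenario.

    Defaults reproduce the main analysis: 15-year latency, Korean pooled
    RRs, gap dose basis, burden years 2015-2030 on a 5-year grid, 10,000
    Monte Carlo repetitions.
    """

    model_config = ConfigDict(extra="forbid")

    latency: int = Field(default=15, ge=0)
    rr_region: Region = "korean"
    dose_basis: Literal["gap", "mean"] = "gap"
    target_years: tuple[int, ...] = (2015, 2020, 2025, 2030)
    mc: McSettings = Field(default_factory=McSettings)
    seed: int = 0
    factors: tuple[FactorDefinition, ...] = Field(default_factory=default_factors)
    heterogeneity_i2_threshold: float = 50.0
    heterogeneity_p_threshold: float = 0.05

    def factor(self, name: str) -> FactorDefinition:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")

    def config_hash(self) -> str:
        """Stable hash of the scenario for run manifests."""
        canonical = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_canonical_links(factors: Sequence[FactorDefinition]) -> None:
    """Check that a factor list realises the seven canonical factor-site links."""
    have = {(f.name, tuple(sorted(f.sites))) for f in factors}
    need: set[tuple[str, tuple[str, ...]]] = set()
    for name, sites in CANONICAL_LINKS:
        if len(sites) > 1:
            need.add((name, tuple(sorted(sites))))
    # single-site links: the site must appear among the factor's sites
    by_name: dict[str, set[str]] = {}
    for f in factors:
        by_name.setdefault(f.name, set()).update(f.sites)
    missing = []
    for name, sites in CANONICAL_LINKS:
        if len(sites) == 1:
            if name not in by_name or sites[0] not in by_name[name]:
                missing.append(f"{name} -> {sites[0]}")
        else:
            if (name, tuple(sorted(sites))) not in have:
                missing.append(f"{name} -> {'+'.join(sites)}")
    if missing:
        raise ValueError(
            "factor configuration is missing canonical links: " + "; ".join(missing)
        )


def load_scenario(path: str, strict: bool = True) -> ScenarioConfig:
    """Load and validate a YAML scenario file.

    Unknown keys are rejected.  With ``strict`` (default) the factor list
    must realise the seven canonical factor-site links; pass
    ``strict=False`` for reduced synthetic scenarios.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = ScenarioConfig.model_validate(raw)
    if strict:
        validate_canonical_links(scenario.factors)
    return scenario
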