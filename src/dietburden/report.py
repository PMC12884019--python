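"""Report assembly: published-table layouts, site shares, run manifest.

Burden tables are reshaped into the three canonical layouts — factor by
year, diet-linked site by year, and the RR-source sensitivity comparison —
plus the site-share breakdown (each site's attributable cases as a
percentage of all diet-attributable cases, by sex).  PAFs are reported as
percentages to 2 decimals and attributable cases as integers (half-up),
matching registry-report precision; full precision is kept internally.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .config import ScenarioConfig

__version__ = "0.1.0"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def format_paf_pct(paf: float) -> float:
    """PAF as a percentage rounded to 2 decimals."""
    return round(100.0 * paf, 2)


def _drop_internal(df: pd.DataFrame) -> pd.DataFrame:
    return df.drop(columns=[c for c in df.columns if c.startswith("_")])


def _tidy(df: pd.DataFrame) -> pd.DataFrame:
    out = _drop_internal(df).copy()
    out["paf_pct"] = out["paf"].map(format_paf_pct)
    out["ac_rounded"] = out["ac"].map(round_half_up)
    for c in ("paf_low", "paf_high"):
        if c in out.columns:
            out[c.replace("paf", "paf_pct")] = out[c].map(format_paf_pct)
    return out


def factor_table(burden: pd.DataFrame) -> pd.DataFrame:
    """Factor x year layout (factor and direction-group rows, sex = all)."""
    sub = burden.loc[
        burden["level"].isin(["factor", "factor_group"]) & (burden["sex"] == "all")
    ]
    return _tidy(sub).sort_values(["outcome", "level", "key", "year"]).reset_index(drop=True)


def site_table(burden: pd.DataFrame) -> pd.DataFrame:
    """Diet-linked site x year layout (sex = all)."""
    sub = burden.loc[(burden["level"] == "site") & (burden["sex"] == "all")]
    return _tidy(sub).sort_values(["outcome", "key", "year"]).reset_index(drop=True)


def sensitivity_table(
    burden_by_region: Mapping[str, pd.DataFrame], year: int
) -> pd.DataFrame:
    """RR-source sensitivity layout: direction groups x sex, one burden year."""
    frames = []
    for region, burden in burden_by_region.items():
        sub = burden.loc[
            (burden["level"] == "factor_group") & (burden["year"] == year)
        ].copy()
        sub.insert(0, "rr_region", region)
        frames.append(_tidy(sub))
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["outcome", "rr_region", "key", "sex"])
        .reset_index(drop=True)
    )


def site_shares(burden: pd.DataFrame, year: int) -> pd.DataFrame:
    """Each site's share (%) of all diet-attributable cases, by sex and outcome."""
    sites = burden.loc[
        (burden["level"] == "site")
        & (burden["key"] != "all_cancers")
        & (burden["year"] == year)
    ]
    rows = []
    for (sex, outcome), grp in sites.groupby(["sex", "outcome"]):
        total = grp["ac"].sum()
        for r in grp.itertuples(index=False):
            rows.append(
                {
                    "sex": sex,
                    "outcome": outcome,
                    "year": year,
                    "site": r.key,
                    "ac": r.ac,
                    "share_pct": round(100.0 * r.ac / total, 2) if total > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def check_ratio_identity(table: pd.DataFrame, tol: float = 1.0) -> None:
    """Assert AC / denominator = PAF within rounding for every row."""
    bad = (table["paf"] * table["denominator"] - table["ac"]).abs() >= tol
    if bad.any():
        raise AssertionError(
            f"{int(bad.sum())} rows violate the AC/denominator = PAF identity"
        )


def render_report(
    burden: pd.DataFrame,
    scenario: ScenarioConfig,
    outdir: str | Path,
    seed: int,
    burden_by_region: Optional[Mapping[str, pd.DataFrame]] = None,
    share_year: int = 2020,
) -> dict[str, Path]:
    """Write the report CSVs and a run manifest; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    check_ratio_identity(burden)
    written: dict[str, Path] = {}

    tables = {
        "burden_by_factor.csv": factor_table(burden),
        "burden_by_site.csv": site_table(burden),
    }
    if share_year in set(burden["year"]):
        tables["site_shares.csv"] = site_shares(burden, share_year)
    if burden_by_region:
        tables["sensitivity_rr_region.csv"] = sensitivity_table(
            burden_by_region, share_year
        )
    tables["burden_full.csv"] = _tidy(burden)
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False)
        written[name] = path

    manifest = {
        "seed": seed,
        "config_hash": scenario.config_hash(),
        "version": __version__,
        "latency": scenario.latency,
        "rr_region": scenario.rr_region,
        "dose_basis": scenario.dose_basis,
        "mc_reps": scenario.mc.reps,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written["manifest.json"] = mpath
    return written
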