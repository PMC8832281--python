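"""Bundled reference tables.

Three small plain-text tables ship with the package so pattern deduction,
distance summaries and heterosis summaries can be exercised without any
genotype data:

* a registry of 30 commercially deployed three-line indica hybrid rice
  combinations with the genetic cluster of each parent and the parental
  identity-by-state genetic distance;
* mid-/better-parent heterosis estimates (with significance flags and
  parental GD) for 38 F1 hybrids from a 3 CMS-female x 14-male RCBD trial,
  across six earliness and yield traits;
* the per-chromosome SNP counts of the 10,268-marker rice genotyping panel.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_commercial_hybrids",
    "load_f1_heterosis",
    "load_panel_chromosome_counts",
]

_EARLINESS_TRAITS = ("days_to_heading", "plant_height", "panicles_per_plant")
_YIELD_TRAITS = ("grains_per_panicle", "thousand_grain_weight", "grain_yield_per_plant")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("heteropat.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_commercial_hybrids() -> pd.DataFrame:
    """Registry of 30 commercial hybrids with parental clusters and GD.

    Columns: female, female_code, female_cluster, male, male_code,
    male_cluster, hybrid, gd.
    """
    return _read("commercial_hybrids.csv")


def load_f1_heterosis(tidy: bool = True) -> pd.DataFrame:
    """Heterosis estimates for the 38 trial F1 hybrids.

    With ``tidy=True`` (default) returns one row per hybrid x trait with
    columns (cross_code, hybrid, female_code, male_code, trait, mph,
    mph_sig, bph, bph_sig, gd); otherwise the two wide per-trait-group
    tables concatenated column-wise.
    """
    early = _read("f1_heterosis_earliness.csv")
    yield_ = _read("f1_heterosis_yield.csv")
    if not tidy:
        merged = early.merge(
            yield_.drop(columns=["hybrid", "gd"]), on="cross_code", validate="1:1"
        )
        return merged
    rows = []
    for df, traits in ((early, _EARLINESS_TRAITS), (yield_, _YIELD_TRAITS)):
        for _, row in df.iterrows():
            female_code, male_code = [s.strip() for s in row["cross_code"].split("x")]
            for t in traits:
                rows.append(
                    {
                        "cross_code": row["cross_code"],
                        "hybrid": row["hybrid"],
                        "female_code": female_code,
                        "male_code": male_code,
                        "trait": t,
                        "mph": row[f"{t}_mph"],
                        "mph_sig": row[f"{t}_mph_sig"],
                        "bph": row[f"{t}_bph"],
                        "bph_sig": row[f"{t}_bph_sig"],
                        "gd": row["gd"],
                    }
                )
    return pd.DataFrame(rows)


def load_panel_chromosome_counts() -> pd.Series:
    """Per-chromosome SNP counts of the reference 10K panel."""
    df = _read("panel_chromosome_counts.csv")
    return df.set_index("chromosome")["n_snps"]
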