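"""RCBD trial analysis: ANOVA, mid-/better-parent heterosis, summaries.

Mid-parent heterosis MPH = 100 (F1 - MP) / MP with MP the parental average;
better-parent heterosis (heterobeltiosis) BPH = 100 (F1 - BP) / BP, where
the better parent is the lower-mean parent for traits whose favorable
direction is "low" (earliness, short stature) and the higher-mean parent
otherwise. Significance uses t-tests on line means with the RCBD pooled
error mean square: SE(F1 - MP) = sqrt(3 EMS / 2r), SE(F1 - BP) =
sqrt(2 EMS / r), on the error degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialData",
    "AnovaRow",
    "rcbd_anova",
    "heterosis",
    "heterosis_summary",
    "TRAIT_DIRECTIONS",
]

# favorable direction per trait: earliness and short stature favor "low",
# yield components favor "high"
TRAIT_DIRECTIONS: dict[str, str] = {
    "days_to_heading": "low",
    "plant_height": "low",
    "panicles_per_plant": "high",
    "grains_per_panicle": "high",
    "thousand_grain_weight": "high",
    "grain_yield_per_plant": "high",
}


@dataclass
class TrialData:
    """Tidy trial observations plus per-trait metadata.

    observations: columns (entry, role, block, trait, value) with role in
    {parent, F1}; traits: columns (trait, direction) with direction in
    {low, high}.
    """

    observations: pd.DataFrame
    traits: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"entry", "role", "block", "trait", "value"}
        missing = need - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if not np.isfinite(self.observations["value"]).all():
            raise ValueError("observations contain non-finite values")
        if not {"trait", "direction"} <= set(self.traits.columns):
            raise ValueError("traits table needs columns (trait, direction)")

    def direction(self, trait: str) -> str:
        row = self.traits.loc[self.traits["trait"] == trait, "direction"]
        if row.empty:
            return TRAIT_DIRECTIONS.get(trait, "high")
        return str(row.iloc[0])

    def entry_means(self, trait: str) -> pd.Series:
        obs = self.observations[self.observations["trait"] == trait]
        return obs.groupby("entry")["value"].mean()

    def write(self, path) -> None:
        self.observations.to_csv(path, index=False)

    @classmethod
    def read(cls, path, traits: pd.DataFrame | None = None) -> "TrialData":
        obs = pd.read_csv(path)
        if traits is None:
            names = sorted(obs["trait"].unique())
            traits = pd.DataFrame(
                {"trait": names, "direction": [TRAIT_DIRECTIONS.get(t, "high") for t in names]}
            )
        return cls(observations=obs, traits=traits)


@dataclass
class AnovaRow:
    """One trait's RCBD ANOVA: mean squares, F ratio, CV%."""

    trait: str
    df_genotype: int
    df_block: int
    df_error: int
    ss_genotype: float
    ss_block: float
    ss_error: float
    gms: float
    bms: float
    ems: float
    f_ratio: float
    p_value: float
    cv_pct: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _check_balanced(obs: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = obs[obs["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    counts = sub.groupby(["entry", "block"]).size()
    if (counts != 1).any():
        raise ValueError(
            f"trait {trait!r} is not a balanced complete block design "
            "(each entry must appear exactly once per block)"
        )
    entries = sub["entry"].nunique()
    blocks = sub["block"].nunique()
    if len(sub) != entries * blocks:
        raise ValueError(
            f"trait {trait!r}: incomplete entry x block grid (not a balanced RCBD)"
        )
    if entries < 2 or blocks < 2:
        raise ValueError("RCBD ANOVA needs >= 2 entries and >= 2 blocks")
    return sub


def rcbd_anova(t: TrialData, trait: str) -> AnovaRow:
    """Partition SS into blocks + genotypes + error for one trait.

    Fits ``value ~ C(block) + C(entry)`` by OLS and reads the sequential
    ANOVA table (the design is balanced, so the partition is exact).
    A zero error mean square yields an infinite F with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = _check_balanced(t.observations, trait)
    model = smf.ols("value ~ C(block) + C(entry)", data=sub).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on ems == 0
        table = sm.stats.anova_lm(model, typ=1)
    ss_block = float(table.loc["C(block)", "sum_sq"])
    ss_geno = float(table.loc["C(entry)", "sum_sq"])
    ss_err = float(table.loc["Residual", "sum_sq"])
    # snap pure floating-point residue in any SS component to an exact zero
    ss_total = ss_block + ss_geno + ss_err
    tol = 1e-10 * max(1.0, ss_total)
    ss_block, ss_geno, ss_err = (
        0.0 if ss <= tol else ss for ss in (ss_block, ss_geno, ss_err)
    )
    df_block = int(table.loc["C(block)", "df"])
    df_geno = int(table.loc["C(entry)", "df"])
    df_err = int(table.loc["Residual", "df"])
    gms = ss_geno / df_geno
    bms = ss_block / df_block
    ems = ss_err / df_err
    if ems > 0:
        f = gms / ems
        p = float(stats.f.sf(f, df_geno, df_err))
    else:
        f = math.inf if gms > 0 else 0.0
        p = 0.0 if gms > 0 else 1.0
        warnings.warn(
            f"trait {trait!r}: error mean square is 0; F ratio reported as {f}",
            RuntimeWarning,
            stacklevel=2,
        )
    grand = float(sub["value"].mean())
    cv = 100.0 * math.sqrt(ems) / grand if grand != 0 else float("nan")
    return AnovaRow(
        trait=trait,
        df_genotype=df_geno, df_block=df_block, df_error=df_err,
        ss_genotype=ss_geno, ss_block=ss_block, ss_error=ss_err,
        gms=gms, bms=bms, ems=ems, f_ratio=f, p_value=p, cv_pct=cv,
    )


def _sig_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def heterosis(
    t: TrialData,
    crosses: list[tuple[str, str, str]],
    gd=None,
) -> pd.DataFrame:
    """Mid- and better-parent heterosis for (F1, P1, P2) crosses, all traits.

    Returns one row per cross x trait with entry means, MPH/BPH percentages,
    t-based significance flags (on the trial-wide RCBD EMS) and the parental
    genetic distance when ``gd`` (a DistanceMatrix or mapping) resolves the
    parent pair; unresolvable pairs get a missing GD with a warning.
    """
    records = []
    trait_names = list(t.traits["trait"])
    for trait in trait_names:
        an = rcbd_anova(t, trait)
        means = t.entry_means(trait)
        r = t.observations.loc[t.observations["trait"] == trait, "block"].nunique()
        se_mph = math.sqrt(3.0 * an.ems / (2.0 * r))
        se_bph = math.sqrt(2.0 * an.ems / r)
        direction = t.direction(trait)
        for f1, p1, p2 in crosses:
            for entry in (f1, p1, p2):
                if entry not in means.index:
                    raise ValueError(f"entry {entry!r} absent from trial for trait {trait!r}")
            f1m, p1m, p2m = means[f1], means[p1], means[p2]
            mp = 0.5 * (p1m + p2m)
            bp = min(p1m, p2m) if direction == "low" else max(p1m, p2m)
            mph = 100.0 * (f1m - mp) / mp
            bph = 100.0 * (f1m - bp) / bp
            if se_mph > 0:
                t_mph = (f1m - mp) / se_mph
                p_mph = 2.0 * float(stats.t.sf(abs(t_mph), an.df_error))
            else:
                t_mph = math.inf if f1m != mp else 0.0
                p_mph = 0.0 if f1m != mp else 1.0
            if se_bph > 0:
                t_bph = (f1m - bp) / se_bph
                p_bph = 2.0 * float(stats.t.sf(abs(t_bph), an.df_error))
            else:
                t_bph = math.inf if f1m != bp else 0.0
                p_bph = 0.0 if f1m != bp else 1.0
            gd_val = float("nan")
            if gd is not None:
                try:
                    if hasattr(gd, "get") and not isinstance(gd, dict):
                        gd_val = gd.get(p1, p2)
                    else:
                        gd_val = gd.get((p1, p2), gd.get((p2, p1), float("nan")))
                except KeyError:
                    warnings.warn(
                        f"parents ({p1!r}, {p2!r}) absent from distance matrix; GD missing",
                        RuntimeWarning,
                        stacklevel=2,
                    )
            records.append(
                {
                    "cross": f1, "female": p1, "male": p2, "trait": trait,
                    "direction": direction,
                    "f1_mean": f1m, "p1_mean": p1m, "p2_mean": p2m,
                    "midparent": mp, "better_parent": bp,
                    "mph": mph, "bph": bph,
                    "mph_t": t_mph, "mph_p": p_mph, "mph_sig": _sig_flag(p_mph),
                    "bph_t": t_bph, "bph_p": p_bph, "bph_sig": _sig_flag(p_bph),
                    "gd": gd_val,
                }
            )
    return pd.DataFrame(records)


def heterosis_summary(records: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Per-trait mean / min / max of MPH, BPH and GD, rounded for reporting."""
    if records.empty:
        raise ValueError("no heterosis records to summarize")
    rows = []
    for trait, sub in records.groupby("trait", sort=False):
        for stat, fn in (("mean", np.nanmean), ("min", np.nanmin), ("max", np.nanmax)):
            rows.append(
                {
                    "trait": trait, "statistic": stat,
                    "mph": round(float(fn(sub["mph"])), decimals),
                    "bph": round(float(fn(sub["bph"])), decimals),
                    "gd": round(float(fn(sub["gd"])), decimals)
                    if sub["gd"].notna().any() else float("nan"),
                }
            )
    return pd.DataFrame(rows)
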