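"""Heterotic-pattern deduction and the genetic-distance/heterosis link.

A heterotic pattern is an (unordered, by default) pair of genetic clusters
whose inter-cluster crosses have already produced successful hybrids. The
deduction cross-references a hybrid registry (female, male per hybrid) with
per-parent cluster assignments, attaches each pair's IBS genetic distance,
and summarizes GD per pattern. The GD-heterosis relationship is quantified
by a Pearson correlation / least-squares slope per trait and heterosis kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from heteropat.popgen import DistanceMatrix
from heteropat.structure import UNASSIGNED

__all__ = [
    "CorrelationResult",
    "deduce_patterns",
    "gd_heterosis_correlation",
    "nominate_crosses",
]


def _resolve_cluster(parent: str, row: pd.Series, side: str, assignments) -> str | None:
    if assignments is not None:
        return assignments.get(parent)
    col = f"{side}_cluster"
    return row[col] if col in row.index else None


def _resolve_gd(row: pd.Series, gd) -> float:
    if gd is None:
        return float(row["gd"]) if "gd" in row.index else float("nan")
    a, b = row["female"], row["male"]
    try:
        if isinstance(gd, DistanceMatrix):
            return gd.get(a, b)
        return float(gd.get((a, b), gd.get((b, a), float("nan"))))
    except KeyError:
        return float("nan")


def deduce_patterns(
    registry: pd.DataFrame,
    assignments: pd.Series | dict | None = None,
    gd=None,
    ordered: bool = False,
) -> pd.DataFrame:
    """Group registry hybrids into cluster-pair heterotic patterns.

    Cluster labels come from ``assignments`` (mapping parent id -> cluster)
    when given, else from the registry's own ``female_cluster`` /
    ``male_cluster`` columns. Patterns are unordered cluster pairs by
    default (``ordered=True`` keeps female-cluster first). Entries whose
    parents share a cluster are kept and flagged ``within_group``; entries
    with an UNASSIGNED parent are grouped under their own label. Entries
    whose parents cannot be resolved are skipped with a warning.

    Returns one row per pattern: (pattern, cluster_a, cluster_b, n_hybrids,
    gd_min, gd_mean, gd_max, hybrids, within_group, unassigned).
    """
    if isinstance(assignments, pd.Series):
        assignments = assignments.to_dict()
    buckets: dict[tuple, dict] = {}
    for _, row in registry.iterrows():
        cf = _resolve_cluster(row["female"], row, "female", assignments)
        cm = _resolve_cluster(row["male"], row, "male", assignments)
        if cf is None or cm is None:
            warnings.warn(
                f"hybrid {row.get('hybrid', '?')!r}: parent without cluster label; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        unassigned = UNASSIGNED in (cf, cm)
        pair = (cf, cm) if ordered else tuple(sorted((str(cf), str(cm))))
        b = buckets.setdefault(
            pair,
            {"hybrids": [], "gds": [], "unassigned": unassigned},
        )
        b["hybrids"].append(row.get("hybrid", f"{row['female']} x {row['male']}"))
        b["gds"].append(_resolve_gd(row, gd))

    rows = []
    for (ca, cb), b in buckets.items():
        gds = np.asarray(b["gds"], dtype=float)
        has_gd = np.isfinite(gds).any()
        rows.append(
            {
                "pattern": f"{ca} x {cb}",
                "cluster_a": ca,
                "cluster_b": cb,
                "n_hybrids": len(b["hybrids"]),
                "gd_min": float(np.nanmin(gds)) if has_gd else float("nan"),
                "gd_mean": float(np.nanmean(gds)) if has_gd else float("nan"),
                "gd_max": float(np.nanmax(gds)) if has_gd else float("nan"),
                # sorted so the output is invariant to registry row order
                "hybrids": ";".join(sorted(map(str, b["hybrids"]))),
                "within_group": ca == cb,
                "unassigned": b["unassigned"],
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(
            ["n_hybrids", "pattern"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return out


@dataclass
class CorrelationResult:
    """Pearson correlation of heterosis against parental genetic distance."""

    trait: str
    kind: str
    n: int
    r: float
    slope: float
    p_value: float


def gd_heterosis_correlation(
    records: pd.DataFrame, trait: str, kind: str = "MPH"
) -> CorrelationResult:
    """Pearson r, least-squares slope and two-sided p for GD vs heterosis.

    ``records`` is a tidy heterosis table with columns (trait, gd, mph/bph).
    Zero variance in either column yields NaN r with a warning.
    """
    col = kind.lower()
    if col not in ("mph", "bph"):
        raise ValueError("kind must be 'MPH' or 'BPH'")
    sub = records[(records["trait"] == trait)].dropna(subset=["gd", col])
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 records with GD for trait {trait!r}; have {n}")
    x = sub["gd"].to_numpy(float)
    y = sub[col].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            f"zero variance in GD or {kind} for trait {trait!r}; r undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return CorrelationResult(trait, kind, n, float("nan"), float("nan"), float("nan"))
    fit = stats.linregress(x, y)
    return CorrelationResult(
        trait=trait, kind=kind, n=n,
        r=float(fit.rvalue), slope=float(fit.slope), p_value=float(fit.pvalue),
    )


def nominate_crosses(
    assignments: pd.Series | dict,
    gd: DistanceMatrix,
    gd_range: tuple[float, float] = (0.193, 0.359),
    meta: pd.DataFrame | None = None,
    female_types: tuple[str, ...] | None = None,
    male_types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Between-cluster parent pairs whose GD lies inside ``gd_range``.

    Optionally restricts candidates by breeding-line type (``meta`` must
    then carry sample_id and line_type). Pairs are ranked by GD descending.
    An empty result is an empty table, not an error.
    """
    if isinstance(assignments, pd.Series):
        assignments = assignments.to_dict()
    lo, hi = gd_range
    line_type = None
    if meta is not None:
        m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
        line_type = m["line_type"]

    def allowed(s: str, types: tuple[str, ...] | None) -> bool:
        if types is None:
            return True
        if line_type is None or s not in line_type.index:
            return False
        return line_type.loc[s] in types

    samples = [s for s in gd.sample_ids if s in assignments]
    rows = []
    directed = female_types is not None or male_types is not None
    for i, a in enumerate(samples):
        ca = assignments[a]
        partners = samples if directed else samples[i + 1 :]
        for b in partners:
            if a == b:
                continue
            cb = assignments[b]
            if ca == cb or UNASSIGNED in (ca, cb):
                continue
            if not (allowed(a, female_types) and allowed(b, male_types)):
                continue
            val = gd.get(a, b)
            if lo <= val <= hi:
                rows.append(
                    {
                        "female": a, "male": b,
                        "female_cluster": ca, "male_cluster": cb,
                        "gd": val,
                    }
                )
    out = pd.DataFrame(rows, columns=["female", "male", "female_cluster", "male_cluster", "gd"])
    return out.sort_values("gd", ascending=False, kind="stable").reset_index(drop=True)
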