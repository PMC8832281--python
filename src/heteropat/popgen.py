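"""Identity-by-state distances and gene-diversity / divergence statistics.

The IBS similarity between two diploid genotypes at a locus is the fraction
of shared alleles: identical homozygotes score 1, a heterozygote against any
genotype sharing one allele scores 0.5, opposite homozygotes score 0. In
dosage coding this is ``1 - |a - b| / 2``. Distances are ``1 - similarity``
averaged over pairwise-complete loci (both calls non-missing).

Gene diversity follows Nei: per-locus per-group expected heterozygosity
``2p(1-p)``; Hs is the mean over loci, Ht uses the pooled all-sample
frequency, ``Gst = (Ht - Hs_bar) / Ht`` with the unweighted group mean
Hs_bar, and G'st is Hedrick's standardized measure
``Gst (k-1+Hs_bar) / ((k-1)(1-Hs_bar))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from heteropat.genotypes import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "DiversityTable",
    "ibs_distance",
    "gene_diversity",
    "distance_summary",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named samples."""

    sample_ids: list[str]
    values: np.ndarray
    n_loci_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def get(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "sample_a": self.sample_ids[i],
                        "sample_b": self.sample_ids[j],
                        "distance": self.values[i, j],
                        "n_loci": int(self.n_loci_used[i, j]) if self.n_loci_used is not None else None,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_square_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sample_ids=[str(s) for s in df.index], values=df.to_numpy(dtype=float))


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 - IBS similarity with pairwise-complete locus averaging.

    A pair with zero shared non-missing loci gets a missing (NaN) distance
    with a warning. The diagonal is exactly 0.
    """
    X = g.dosage
    valid = (X != MISSING)
    V = valid.astype(np.float64)
    G = [((X == k) & valid).astype(np.float64) for k in (0, 1, 2)]

    n_shared = V @ V.T
    # total |a-b| over shared loci via one-hot cross-products
    diff = (
        G[0] @ G[1].T + G[1] @ G[0].T
        + G[1] @ G[2].T + G[2] @ G[1].T
        + 2.0 * (G[0] @ G[2].T + G[2] @ G[0].T)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_shared > 0, (diff / 2.0) / n_shared, np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        warnings.warn(
            "some sample pairs share no non-missing loci; their distance is missing",
            RuntimeWarning,
            stacklevel=2,
        )
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        sample_ids=list(g.sample_ids),
        values=d,
        n_loci_used=n_shared.astype(np.int64),
    )


@dataclass
class DiversityTable:
    """Per-group diversity plus pooled divergence statistics.

    ``table`` has one row per group with columns label, n, n_alleles (the
    2 x n reporting convention), n_polymorphic (segregating loci) and hs.
    ``gst``/``gpst`` are NaN when fewer than two groups are present.
    """

    table: pd.DataFrame
    ht: float
    gst: float
    gpst: float
    k: int

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["ht"] = self.ht
        df["gst"] = self.gst
        df["gpst"] = self.gpst
        return df


def _group_freqs(g: GenotypeMatrix, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = g.dosage[members, :]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return p, n_called


def gene_diversity(
    g: GenotypeMatrix,
    groups: pd.Series | dict | np.ndarray,
    weighted: bool = False,
) -> DiversityTable:
    """Nei gene diversity per group and Gst / Hedrick's G'st across groups.

    groups maps each sample id to a group label (or is an array aligned with
    ``g.sample_ids``). Hs_bar is the unweighted mean of group Hs by default;
    ``weighted=True`` weights by sample size.
    """
    if isinstance(groups, dict):
        labels = np.array([groups[s] for s in g.sample_ids], dtype=object)
    elif isinstance(groups, pd.Series):
        labels = np.array([groups.loc[s] for s in g.sample_ids], dtype=object)
    else:
        labels = np.asarray(groups, dtype=object)
        if len(labels) != g.n_samples:
            raise ValueError("groups array length must match sample count")

    uniq = list(pd.unique(labels))
    rows = []
    hs_list = []
    for lab in uniq:
        members = np.flatnonzero(labels == lab)
        p, n_called = _group_freqs(g, members)
        if (n_called == 0).all():
            raise ValueError(f"group {lab!r} has zero non-missing calls at all loci")
        h_locus = 2.0 * p * (1.0 - p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hs = float(np.nanmean(h_locus))
        n_poly = int(np.nansum((p > 0) & (p < 1)))
        rows.append(
            {
                "label": lab,
                "n": int(len(members)),
                "n_alleles": int(2 * len(members)),
                "n_polymorphic": n_poly,
                "hs": hs,
            }
        )
        hs_list.append((hs, len(members)))

    p_pool, _ = _group_freqs(g, np.arange(g.n_samples))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ht = float(np.nanmean(2.0 * p_pool * (1.0 - p_pool)))

    k = len(uniq)
    if k < 2 or ht == 0.0:
        gst = gpst = float("nan")
    else:
        if weighted:
            w = np.array([n for _, n in hs_list], dtype=float)
            hs_bar = float(np.average([h for h, _ in hs_list], weights=w))
        else:
            hs_bar = float(np.mean([h for h, _ in hs_list]))
        gst = (ht - hs_bar) / ht
        gpst = gst * (k - 1 + hs_bar) / ((k - 1) * (1.0 - hs_bar)) if hs_bar < 1.0 else float("nan")
    return DiversityTable(table=pd.DataFrame(rows), ht=ht, gst=gst, gpst=gpst, k=k)


def distance_summary(
    d: DistanceMatrix,
    pairs: list[tuple[str, str]] | None = None,
    decimals: int = 3,
) -> tuple[float, float, float]:
    """(min, max, mean) of the requested pairs, or all off-diagonal entries."""
    if pairs is None:
        iu = np.triu_indices(len(d.sample_ids), k=1)
        vals = d.values[iu]
    else:
        vals = np.array([d.get(a, b) for a, b in pairs], dtype=float)
    if vals.size == 0:
        raise ValueError("no pairs to summarize")
    return (
        round(float(np.nanmin(vals)), decimals),
        round(float(np.nanmax(vals)), decimals),
        round(float(np.nanmean(vals)), decimals),
    )
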