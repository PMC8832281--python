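"""Genotype panel container, VCF I/O, variant filtering and panel summaries.

Genotypes are stored as alt-allele dosage (0, 1, 2) with ``-1`` marking a
missing call, one row per sample and one column per locus. Filtering follows
the usual chip-panel QC chain: per-call masking on genotype quality and read
depth, then locus-level biallelic / call-rate / minor-allele-frequency
filters, with each dropped locus attributed to the first filter it fails.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

LINE_TYPES = ("inbred", "maintainer", "restorer", "TGMS", "unknown")
ECOTYPES = ("Indica", "Japonica", "unknown")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class EmptyPanelError(ValueError):
    """Raised when filtering removes every locus."""


@dataclass
class GenotypeMatrix:
    """Samples x loci alt-dosage matrix with locus annotations.

    Attributes
    ----------
    sample_ids : list of str
    chrom, pos, ref : per-locus arrays (1-based positions, sorted within
        each chromosome)
    alt : per-locus tuple of alternate alleles; more than one entry flags a
        multi-allelic record
    dosage : int8 array of shape (n_samples, n_loci) in {-1, 0, 1, 2}
    gq, dp : optional per-call genotype quality / read depth arrays
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list[tuple[str, ...]]
    dosage: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.pos)
        if self.dosage.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != (n_samples={n}, n_loci={m})"
            )
        if len(self.alt) != m or len(self.chrom) != m or len(self.ref) != m:
            raise ValueError("locus annotation arrays have inconsistent lengths")
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        for chrom in pd.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {chrom}")
        for arr_name in ("gq", "dp"):
            arr = getattr(self, arr_name)
            if arr is not None and np.asarray(arr).shape != (n, m):
                raise ValueError(f"{arr_name} shape must match dosage")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    @property
    def is_biallelic(self) -> np.ndarray:
        return np.array([len(a) == 1 for a in self.alt], dtype=bool)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of non-missing calls."""
        return self.called().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-locus alt-allele frequency from non-missing calls (NaN if none)."""
        called = self.called()
        n_called = called.sum(axis=0)
        alt_count = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=[self.alt[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            gq=None if self.gq is None else self.gq[:, idx].copy(),
            dp=None if self.dp is None else self.dp[:, idx].copy(),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=list(self.alt),
            dosage=self.dosage[idx, :].copy(),
            gq=None if self.gq is None else self.gq[idx, :].copy(),
            dp=None if self.dp is None else self.dp[idx, :].copy(),
        )


@dataclass
class QCReport:
    """Filter accounting plus panel summary statistics.

    The accounting invariant ``loci_out + sum(removals) == loci_in`` holds
    because every dropped locus is attributed to the first filter it fails.
    """

    loci_in: int = 0
    loci_out: int = 0
    removed_non_biallelic: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    calls_masked: int = 0
    samples_in: int = 0
    samples_out: int = 0
    per_chromosome: dict = field(default_factory=dict)
    mean_maf: float = float("nan")
    het_proportion: float = float("nan")
    mean_spacing_kb: float = float("nan")
    missing_sites: int = 0
    genome_size_bp: int | None = None

    def check(self) -> None:
        removed = (
            self.removed_non_biallelic + self.removed_call_rate + self.removed_maf
        )
        if self.loci_out + removed != self.loci_in:
            raise AssertionError("QC accounting does not sum")
        if min(self.loci_in, self.loci_out, self.removed_non_biallelic,
               self.removed_call_rate, self.removed_maf) < 0:
            raise AssertionError("negative QC counts")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("loci_in", self.loci_in),
            ("loci_out", self.loci_out),
            ("removed_non_biallelic", self.removed_non_biallelic),
            ("removed_call_rate", self.removed_call_rate),
            ("removed_maf", self.removed_maf),
            ("calls_masked", self.calls_masked),
            ("samples_in", self.samples_in),
            ("samples_out", self.samples_out),
            ("mean_maf", self.mean_maf),
            ("het_proportion", self.het_proportion),
            ("mean_spacing_kb", self.mean_spacing_kb),
            ("missing_sites", self.missing_sites),
        ]
        rows += [(f"chr{c}_n_snps", n) for c, n in self.per_chromosome.items()]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required; GQ/DP used when present).

    Diploid GT is mapped to alt dosage; ``./.`` becomes missing. Records with
    more than one ALT allele are retained and flagged via
    :attr:`GenotypeMatrix.is_biallelic`.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    chrom, pos, ref, alt, dosages = [], [], [], [], []
    gqs, dps = [], []
    has_gq = has_dp = False
    record_no = 0
    try:
        for v in vcf:
            record_no += 1
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(tuple(v.ALT) if v.ALT else ("",))
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            gt = np.asarray(v.gt_types, dtype=np.int8)
            dosages.append(np.where(gt == 3, MISSING, gt))
            def _fmt(field: str, dtype):
                try:
                    arr = v.format(field)
                except KeyError:
                    arr = None
                if arr is None:
                    return np.full(len(samples), -1, dtype=dtype), False
                flat = np.asarray(arr, dtype=dtype).reshape(len(samples), -1)[:, 0]
                return flat, bool(np.any(flat >= 0))

            gq, seen = _fmt("GQ", np.float32)
            gqs.append(gq)
            has_gq = has_gq or seen
            dp, seen = _fmt("DP", np.int32)
            dps.append(dp)
            has_dp = has_dp or seen
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record #{record_no} in {path}: {exc}") from exc

    if not dosages:
        raise VcfParseError(f"no variant records in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=alt,
        dosage=np.stack(dosages, axis=1),
        gq=np.stack(gqs, axis=1) if has_gq else None,
        dp=np.stack(dps, axis=1) if has_dp else None,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    g: GenotypeMatrix,
    path: str | Path,
    gq_fill: int | None = None,
    dp_fill: int | None = None,
) -> None:
    """Write a VCF v4.2 with GT (and GQ/DP if carried or filled with constants)."""
    gq = g.gq
    dp = g.dp
    if gq is None and gq_fill is not None:
        gq = np.full(g.dosage.shape, gq_fill, dtype=np.float32)
    if dp is None and dp_fill is not None:
        dp = np.full(g.dosage.shape, dp_fill, dtype=np.int32)
    fmt = "GT" + (":GQ" if gq is not None else "") + (":DP" if dp is not None else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heteropat\n")
        for chrom in pd.unique(g.chrom):
            length = int(g.pos[g.chrom == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j in range(g.n_loci):
            cells = []
            for i in range(g.n_samples):
                cell = _GT_STR[int(g.dosage[i, j])]
                if gq is not None:
                    cell += f":{int(gq[i, j])}"
                if dp is not None:
                    cell += f":{int(dp[i, j])}"
                cells.append(cell)
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t.\t{g.ref[j]}\t{','.join(g.alt[j])}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def apply_filters(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.80,
    gq_min: float = 20.0,
    dp_min: float = 5.0,
    sample_call_rate_min: float | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the panel QC chain and report per-filter removal counts.

    Order: per-call GQ/DP masking (when those fields exist), then drop
    non-biallelic loci, then loci with call rate < ``call_rate_min``, then
    loci whose MAF (on non-missing calls) is <= ``maf_min`` (strictly greater
    retained). An optional sample-level call-rate filter is applied before
    the locus filters; it is off by default.
    """
    if g.n_loci == 0:
        raise EmptyPanelError("input panel has no loci")
    report = QCReport(loci_in=g.n_loci, samples_in=g.n_samples)

    dosage = g.dosage.copy()
    called_before = dosage != MISSING
    if g.gq is not None:
        dosage[(g.gq < gq_min) & (g.gq >= 0)] = MISSING
    if g.dp is not None:
        dosage[(g.dp < dp_min) & (g.dp >= 0)] = MISSING
    report.calls_masked = int((called_before & (dosage == MISSING)).sum())
    g = GenotypeMatrix(
        sample_ids=list(g.sample_ids), chrom=g.chrom, pos=g.pos, ref=g.ref,
        alt=list(g.alt), dosage=dosage,
    )

    if sample_call_rate_min is not None:
        keep = (g.dosage != MISSING).mean(axis=1) >= sample_call_rate_min
        g = g.subset_samples(keep)
        if g.n_samples == 0:
            raise EmptyPanelError("sample call-rate filter removed every sample")
    report.samples_out = g.n_samples

    biallelic = g.is_biallelic
    report.removed_non_biallelic = int((~biallelic).sum())

    call_ok = g.call_rate() >= call_rate_min
    report.removed_call_rate = int((biallelic & ~call_ok).sum())

    with np.errstate(invalid="ignore"):
        maf_ok = g.maf() > maf_min
    maf_ok = np.nan_to_num(maf_ok, nan=False).astype(bool)
    report.removed_maf = int((biallelic & call_ok & ~maf_ok).sum())

    keep = biallelic & call_ok & maf_ok
    report.loci_out = int(keep.sum())
    report.check()
    if report.loci_out == 0:
        raise EmptyPanelError("all loci removed: empty panel after filtering")
    return g.subset_loci(keep), report


def _truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals."""
    return math.floor(x * 100.0) / 100.0


def mean_spacing_kb(n_loci: int, genome_size_bp: int = 350_000_000) -> float:
    """Mean physical spacing between markers in Kb, truncated to 2 decimals."""
    return _truncate2(genome_size_bp / n_loci / 1000.0)


def summarize_panel(
    g: GenotypeMatrix, genome_size_bp: int = 350_000_000
) -> QCReport:
    """Panel summary: per-chromosome counts, mean MAF, heterozygosity, spacing."""
    report = QCReport(
        loci_in=g.n_loci, loci_out=g.n_loci,
        samples_in=g.n_samples, samples_out=g.n_samples,
        genome_size_bp=genome_size_bp,
    )
    chroms, counts = np.unique(g.chrom.astype(str), return_counts=True)
    report.per_chromosome = dict(zip(chroms.tolist(), counts.tolist()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        report.mean_maf = float(np.nanmean(g.maf()))
    called = g.called()
    n_called = called.sum()
    report.het_proportion = float((g.dosage == 1).sum() / n_called) if n_called else float("nan")
    report.missing_sites = int((called.sum(axis=0) == 0).sum())
    report.mean_spacing_kb = mean_spacing_kb(g.n_loci, genome_size_bp)
    return report


def read_sample_info(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata table (sample_id, ecotype, origin, line_type...)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("sample metadata needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return df


def write_sample_info(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
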