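"""Synthetic genotype panels and RCBD trials with known ground truth.

The panel generator draws subpopulation allele frequencies from the
Balding-Nichols beta model, so a single parameter controls Fst-like
divergence between subpopulations; an excess-homozygosity step emulates the
near-complete inbreeding of rice breeding lines (maintainers, restorers,
inbreds), whose realized heterozygous-call proportion is pushed toward a
target value. The trial generator inverts the mid-parent heterosis formula:
F1 true means are set so each cross attains its target MPH exactly, and
plot observations add block effects and normal error, so downstream
estimators can be checked against an exact truth table.

Defaults emulate the study conditions this package reconstructs: a
359-sample indica/japonica panel in six subpopulations typed at 10,268 loci
on 12 chromosomes with ~1.5% heterozygous calls and no missing data, and a
trial of 3 CMS females x 14 males in 3 complete blocks scored for six
earliness/yield traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heteropat.genotypes import MISSING, GenotypeMatrix
from heteropat.trials import TrialData

__all__ = [
    "SimPanelSpec",
    "SimTrialSpec",
    "PanelSim",
    "TrialSim",
    "simulate_panel",
    "simulate_trial",
    "DEFAULT_TRAITS",
]


class SpecError(ValueError):
    """Invalid simulation specification; message names the offending field."""


# Six printed cluster sizes of the 359-line panel, with the 6 unassigned
# lines folded into the smallest group to keep n = 359.
_DEFAULT_SUBPOP_SIZES = (161, 31, 75, 41, 15, 36)

_DEFAULT_ORIGINS = ("Guangdong", "Zhejiang", "Yunnan", "Fujian", "Heilongjiang", "Guangxi")


@dataclass
class SimPanelSpec:
    """Parameters of the Balding-Nichols panel simulator.

    fst is the divergence parameter F of the beta model
    Beta(p(1-F)/F, (1-p)(1-F)/F); het_inflation is the target proportion of
    heterozygous calls after the excess-homozygosity adjustment (0.0152
    matches a panel dominated by inbred lines); frac_multiallelic and
    frac_low_maf plant known QC-failing loci so filter accounting can be
    tested against simulator bookkeeping.
    """

    n_subpops: int = 6
    samples_per_subpop: tuple[int, ...] = _DEFAULT_SUBPOP_SIZES
    n_loci: int = 10_268
    n_chromosomes: int = 12
    chrom_length_bp: int = 29_000_000
    fst: float = 0.3
    # calibrated so the MAF>0.05-filtered panel has mean MAF ~= 0.22 under F=0.3
    ancestral_maf_range: tuple[float, float] = (0.02, 0.35)
    missing_rate: float = 0.0
    het_inflation: float = 0.0152
    frac_multiallelic: float = 0.0
    frac_low_maf: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subpops < 1:
            raise SpecError("n_subpops must be >= 1")
        if len(self.samples_per_subpop) != self.n_subpops:
            raise SpecError("samples_per_subpop length must equal n_subpops")
        if sum(self.samples_per_subpop) < 2:
            raise SpecError("samples_per_subpop must sum to >= 2")
        if self.n_loci < self.n_chromosomes:
            raise SpecError("n_loci must be >= n_chromosomes")
        if not 0.0 < self.fst < 1.0:
            raise SpecError("fst must lie in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SpecError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("missing_rate", "het_inflation", "frac_multiallelic", "frac_low_maf"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SpecError(f"{name} must lie in [0, 1)")
        if self.chrom_length_bp < self.n_loci:
            raise SpecError("chrom_length_bp too small for n_loci")


@dataclass
class PanelSim:
    """Simulated panel: genotypes, sample metadata and planting bookkeeping."""

    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    ancestral_freq: np.ndarray
    subpop_freq: np.ndarray
    planted_multiallelic: np.ndarray
    planted_low_maf: np.ndarray


def simulate_panel(spec: SimPanelSpec) -> PanelSim:
    """Draw a structured biallelic dosage panel under the Balding-Nichols model.

    Loci are spread over ``n_chromosomes`` chromosomes with sorted 1-based
    positions drawn uniformly without replacement. Each heterozygote is
    replaced, with probability ``1 - het_inflation / (2 p (1-p))`` (clamped
    to [0, 1]), by the homozygote of one of its own alleles chosen uniformly,
    which leaves the expected allele frequency unchanged while deflating
    heterozygosity. Missing calls are masked uniformly at ``missing_rate``.
    Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(sum(spec.samples_per_subpop))
    m = spec.n_loci

    # chromosome assignment: as even as possible, positions sorted per chrom
    base, extra = divmod(m, spec.n_chromosomes)
    chrom_sizes = [base + (1 if c < extra else 0) for c in range(spec.n_chromosomes)]
    chrom = np.concatenate(
        [np.full(sz, str(c + 1), dtype=object) for c, sz in enumerate(chrom_sizes)]
    )
    pos = np.concatenate(
        [
            np.sort(rng.choice(spec.chrom_length_bp, size=sz, replace=False)) + 1
            for sz in chrom_sizes
        ]
    ).astype(np.int64)

    lo, hi = spec.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    # randomly orient which allele is minor so alt freq spans (0, 1)
    flip = rng.random(m) < 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)

    F = spec.fst
    shape_a = p_anc * (1.0 - F) / F
    shape_b = (1.0 - p_anc) * (1.0 - F) / F
    p_sub = rng.beta(
        np.broadcast_to(shape_a, (spec.n_subpops, m)),
        np.broadcast_to(shape_b, (spec.n_subpops, m)),
    )
    p_sub = np.clip(p_sub, 1e-9, 1.0 - 1e-9)

    subpop_of = np.repeat(np.arange(spec.n_subpops), spec.samples_per_subpop)
    p_cell = p_sub[subpop_of, :]  # (n, m)
    dosage = rng.binomial(2, p_cell).astype(np.int8)

    # excess homozygosity: duplicate one allele of a heterozygote
    het = dosage == 1
    if het.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            keep_prob = np.clip(spec.het_inflation / (2.0 * p_cell * (1.0 - p_cell)), 0.0, 1.0)
        replace_mask = het & (rng.random((n, m)) >= keep_prob)
        new_hom = 2 * rng.integers(0, 2, size=(n, m), dtype=np.int8)
        dosage = np.where(replace_mask, new_hom, dosage).astype(np.int8)

    alt: list[tuple[str, ...]] = [("T",)] * m
    ref = np.full(m, "A", dtype=object)

    # plant QC-failing loci (disjoint index sets), recorded for bookkeeping
    n_multi = int(round(spec.frac_multiallelic * m))
    n_lowmaf = int(round(spec.frac_low_maf * m))
    planted = rng.choice(m, size=n_multi + n_lowmaf, replace=False) if n_multi + n_lowmaf else np.array([], dtype=int)
    idx_multi = np.sort(planted[:n_multi])
    idx_lowmaf = np.sort(planted[n_multi:])
    for j in idx_multi:
        alt[j] = ("T", "G")
    for j in idx_lowmaf:
        # exactly one het carrier -> alt freq 1/(2n) <= 0.05, call rate 1
        col = np.zeros(n, dtype=np.int8)
        col[rng.integers(0, n)] = 1
        dosage[:, j] = col

    if spec.missing_rate > 0:
        dosage[rng.random((n, m)) < spec.missing_rate] = MISSING

    width = len(str(n))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    origins = [_DEFAULT_ORIGINS[k % len(_DEFAULT_ORIGINS)] for k in subpop_of]
    ecotype = ["Japonica" if k == 4 and spec.n_subpops >= 5 else "Indica" for k in subpop_of]
    line_type = rng.choice(
        ["inbred", "maintainer", "restorer", "TGMS", "unknown"],
        size=n,
        p=np.array([183, 53, 120, 1, 2]) / 359.0,
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subpop": [f"P{k + 1}" for k in subpop_of],
            "ecotype": ecotype,
            "origin": origins,
            "line_type": line_type,
        }
    )

    g = GenotypeMatrix(
        sample_ids=sample_ids, chrom=chrom, pos=pos, ref=ref, alt=alt, dosage=dosage
    )
    return PanelSim(
        genotypes=g,
        samples=samples,
        ancestral_freq=p_anc,
        subpop_freq=p_sub,
        planted_multiallelic=idx_multi,
        planted_low_maf=idx_lowmaf,
    )


# trait name -> (favorable direction, parent-mean range, plot error SD)
DEFAULT_TRAITS: dict[str, tuple[str, tuple[float, float], float]] = {
    "days_to_heading": ("low", (76.0, 102.0), 1.06),
    "plant_height": ("low", (88.0, 131.0), 2.32),
    "panicles_per_plant": ("high", (4.3, 11.0), 0.66),
    "grains_per_panicle": ("high", (30.0, 174.0), 13.26),
    "thousand_grain_weight": ("high", (20.9, 32.0), 0.28),
    "grain_yield_per_plant": ("high", (9.5, 40.4), 1.72),
}

_DEFAULT_FEMALES = ("TianfengA", "TaifengA", "Guang8A")
_DEFAULT_MALES = (
    "Guang122", "Huanghuazhan-1", "Huazhan", "Minghui63", "Wushansimiao",
    "Huanghuazhan", "Minhui3301", "Chenghui727", "Yahui2115", "Gui99",
    "Yuexiangzhan", "Yuenongsimiao", "Fuhui676", "Ce64",
)


@dataclass
class SimTrialSpec:
    """Parameters of the RCBD trial simulator.

    target_mph is either a single percentage applied to every cross x trait,
    or a mapping {(female, male, trait): pct}. Alternatively, when ``gd`` is
    supplied (a mapping or DistanceMatrix of parental genetic distances) and
    ``mph_gd_slope`` is set, targets are sampled as
    ``target_mph + mph_gd_slope * GD + N(0, mph_noise_sd^2)``, linking
    heterosis to parental divergence.
    """

    females: tuple[str, ...] = _DEFAULT_FEMALES
    males: tuple[str, ...] = _DEFAULT_MALES
    traits: dict[str, str] = field(
        default_factory=lambda: {t: d for t, (d, _, _) in DEFAULT_TRAITS.items()}
    )
    n_blocks: int = 3
    parent_mean_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {t: r for t, (_, r, _) in DEFAULT_TRAITS.items()}
    )
    target_mph: float | dict = 0.0
    mph_gd_slope: float | None = None
    mph_noise_sd: float = 0.0
    gd: object | None = None
    error_sd: float | dict[str, float] = field(
        default_factory=lambda: {t: s for t, (_, _, s) in DEFAULT_TRAITS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 2:
            raise SpecError("n_blocks must be >= 2")
        if not self.females or not self.males:
            raise SpecError("females and males must be non-empty")
        for t in self.traits:
            if self.traits[t] not in ("low", "high"):
                raise SpecError(f"traits[{t}] direction must be 'low' or 'high'")
            if t not in self.parent_mean_ranges:
                raise SpecError(f"parent_mean_ranges missing trait {t}")
        sds = self.error_sd.values() if isinstance(self.error_sd, dict) else [self.error_sd]
        if any(s < 0 for s in sds):
            raise SpecError("error_sd must be >= 0")


@dataclass
class TrialSim:
    """Simulated trial plus its ground-truth heterosis table."""

    trial: TrialData
    truth: pd.DataFrame


def _lookup_gd(gd: object, a: str, b: str) -> float:
    if gd is None:
        raise SpecError("gd must be provided when mph_gd_slope is set")
    if hasattr(gd, "get"):
        try:
            return float(gd.get((a, b), gd.get((b, a))))  # type: ignore[arg-type]
        except TypeError:
            pass
    return float(gd.get(a, b))  # DistanceMatrix-style


def simulate_trial(spec: SimTrialSpec) -> TrialSim:
    """Generate a balanced RCBD trial whose true MPH per cross is known.

    Parent true means are drawn uniformly from ``parent_mean_ranges``; the F1
    true mean is ``midparent * (1 + target_mph/100)``, so the generated cross
    attains exactly its target MPH at the true-mean level. Observations are
    ``true mean + block effect + N(0, error_sd^2)`` with block effects drawn
    N(0, (error_sd/2)^2), one observation per entry x block.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    parents = list(dict.fromkeys(list(spec.females) + list(spec.males)))
    traits = list(spec.traits)

    def err_sd(t: str) -> float:
        return float(spec.error_sd[t]) if isinstance(spec.error_sd, dict) else float(spec.error_sd)

    parent_means = {
        (p, t): rng.uniform(*spec.parent_mean_ranges[t]) for p in parents for t in traits
    }

    crosses = [(f, m) for f in spec.females for m in spec.males]
    for f, m in crosses:
        if f not in parents or m not in parents:  # pragma: no cover - by construction
            raise SpecError(f"cross ({f}, {m}) references unknown parent")

    def target(f: str, m: str, t: str) -> float:
        if spec.mph_gd_slope is not None:
            base = float(spec.target_mph) if not isinstance(spec.target_mph, dict) else 0.0
            return (
                base
                + spec.mph_gd_slope * _lookup_gd(spec.gd, f, m)
                + (rng.normal(0.0, spec.mph_noise_sd) if spec.mph_noise_sd > 0 else 0.0)
            )
        if isinstance(spec.target_mph, dict):
            try:
                return float(spec.target_mph[(f, m, t)])
            except KeyError as exc:
                raise SpecError(f"target_mph missing entry for {(f, m, t)}") from exc
        return float(spec.target_mph)

    truth_rows = []
    true_means: dict[tuple[str, str], float] = {}
    for f, m in crosses:
        for t in traits:
            p1, p2 = parent_means[(f, t)], parent_means[(m, t)]
            mp = 0.5 * (p1 + p2)
            tgt = target(f, m, t)
            f1 = mp * (1.0 + tgt / 100.0)
            direction = spec.traits[t]
            bp = min(p1, p2) if direction == "low" else max(p1, p2)
            entry = f"{f} x {m}"
            true_means[(entry, t)] = f1
            truth_rows.append(
                {
                    "f1": entry, "female": f, "male": m, "trait": t,
                    "direction": direction,
                    "p1_mean": p1, "p2_mean": p2, "midparent": mp,
                    "better_parent": bp, "f1_mean": f1,
                    "mph_true": tgt, "bph_true": 100.0 * (f1 - bp) / bp,
                }
            )
    for p in parents:
        for t in traits:
            true_means[(p, t)] = parent_means[(p, t)]

    entries = [(p, "parent") for p in parents] + [(f"{f} x {m}", "F1") for f, m in crosses]
    obs_rows = []
    for t in traits:
        sd = err_sd(t)
        block_eff = rng.normal(0.0, sd / 2.0, size=spec.n_blocks) if sd > 0 else np.zeros(spec.n_blocks)
        for b in range(spec.n_blocks):
            for entry, role in entries:
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                obs_rows.append(
                    {
                        "entry": entry, "role": role, "block": f"B{b + 1}",
                        "trait": t, "value": true_means[(entry, t)] + block_eff[b] + noise,
                    }
                )

    trial = TrialData(
        observations=pd.DataFrame(obs_rows),
        traits=pd.DataFrame(
            {"trait": traits, "direction": [spec.traits[t] for t in traits]}
        ),
    )
    return TrialSim(trial=trial, truth=pd.DataFrame(truth_rows))
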