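"""Depletion QC: read classification, class tables, efficiency, correlation.

Uniquely mapped reads are binned into annotation classes with a fixed
priority ladder (targeted rRNA > non-targeted rRNA spacer > mitochondrial
rRNA > other mito > exon > intron > intergenic); a read overlapping two
classes takes the higher-priority one. From the class tables the module
derives the two-way rRNA / non-rRNA rollup (all rRNAs encoded in nuclear
and mitochondrial genomes count as rRNA), depletion efficiency from
untreated-vs-depleted rRNA proportions, and Pearson correlations of log10
transcript counts between libraries, stratified by small-RNA biotype and
probe-homolog status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from sdrna.formats import (
    MT_RRNA_LABELS,
    RRNA_ROLLUP_LABELS,
    TARGETED_RRNA_LABELS,
    AlignedRead,
    Region,
    RegionLabel,
)

#: Classification priority: lower rank wins when a read overlaps two classes.
_PRIORITY = {
    RegionLabel.rRNA_18S: 0,
    RegionLabel.rRNA_28S: 0,
    RegionLabel.rRNA_5_8S: 0,
    RegionLabel.rRNA_nontargeted: 1,
    RegionLabel.mt_12S: 2,
    RegionLabel.mt_16S: 2,
    RegionLabel.mt_other: 3,
    RegionLabel.exon: 4,
    RegionLabel.intron: 5,
    RegionLabel.intergenic: 6,
}

SMALL_RNA_BIOTYPES = frozenset({"snoRNA", "snRNA", "scRNA", "miRNA"})


class QCError(ValueError):
    """Invalid QC input (zero unique reads, too few shared genes, ...)."""


class RegionAnnotation:
    """Interval index over labeled regions, one tree per contig."""

    def __init__(self, regions: list[Region]):
        self.regions = list(regions)
        self._trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            self._trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, r)
        self.unknown_contig_reads = 0  # warning counter

    @property
    def contigs(self) -> set[str]:
        return set(self._trees)

    def classify(self, read: AlignedRead) -> RegionLabel:
        """Class of one read: highest-priority label with >=1 base overlap."""
        tree = self._trees.get(read.contig)
        if tree is None:
            self.unknown_contig_reads += 1
            return RegionLabel.intergenic
        overlaps = tree.overlap(read.pos, read.end)
        if not overlaps:
            return RegionLabel.intergenic
        return min((iv.data.label for iv in overlaps), key=_PRIORITY.__getitem__)


def classify_read(read: AlignedRead, annotation: RegionAnnotation) -> RegionLabel:
    """Bin one uniquely mapped read (see :meth:`RegionAnnotation.classify`)."""
    return annotation.classify(read)


@dataclass
class ClassCounts:
    """Per-class read tallies over uniquely mapped reads."""

    counts: dict[RegionLabel, int]
    total_unique: int

    @property
    def proportions(self) -> dict[RegionLabel, float]:
        return {label: n / self.total_unique for label, n in self.counts.items()}

    def rollup_rrna(self) -> tuple[float, float]:
        """(rRNA fraction, non-rRNA fraction): nuclear + mito rRNA vs rest."""
        rrna = sum(self.counts.get(label, 0) for label in RRNA_ROLLUP_LABELS)
        return rrna / self.total_unique, 1.0 - rrna / self.total_unique


def percent(fraction: float, decimals: int = 1) -> float:
    """Half-up percentage for display (raw fractions stay untouched)."""
    q = Decimal(10) ** -decimals
    # repr() gives the shortest faithful decimal, so 5.65 stays 5.65 rather
    # than its slightly-low binary expansion, and half-up behaves as printed
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def class_table(reads: list[AlignedRead], annotation: RegionAnnotation) -> ClassCounts:
    """Tally unique reads per class; order of reads is irrelevant."""
    unique = [r for r in reads if r.unique]
    if not unique:
        raise QCError("zero unique reads")
    counts: dict[RegionLabel, int] = {label: 0 for label in RegionLabel}
    for read in unique:
        counts[annotation.classify(read)] += 1
    return ClassCounts(counts=counts, total_unique=len(unique))


@dataclass(frozen=True)
class EfficiencyResult:
    f_untreated: float
    f_depleted: float
    efficiency: float
    method: str


def depletion_efficiency(f_u: float, f_d: float, method: str = "odds") -> EfficiencyResult:
    """Fraction of targeted RNA removed, from before/after read proportions.

    ``odds`` (default) normalizes by odds ratios,
    ``E = 1 - [f_d/(1-f_d)] / [f_u/(1-f_u)]``, which is compositionally
    correct: removing targeted reads inflates every non-target proportion,
    so raw fractions understate depletion. ``naive`` is ``1 - f_d/f_u`` for
    comparison.
    """
    if not (0 < f_u < 1):
        raise QCError(f"untreated targeted fraction must be in (0, 1), got {f_u}")
    if not (0 <= f_d < 1):
        raise QCError(f"depleted targeted fraction must be in [0, 1), got {f_d}")
    if method == "odds":
        eff = 1.0 - (f_d / (1.0 - f_d)) / (f_u / (1.0 - f_u))
    elif method == "naive":
        eff = 1.0 - f_d / f_u
    else:
        raise QCError(f"unknown efficiency method {method!r}")
    return EfficiencyResult(f_untreated=f_u, f_depleted=f_d, efficiency=eff, method=method)


@dataclass
class CorrelationResult:
    """Pearson R of log10 counts plus per-stratum breakdown."""

    r: float
    n_genes: int
    strata: dict[str, tuple[float, int]]  # stratum -> (R, n); R is nan for n < 3
    points: pd.DataFrame = field(repr=False)  # gene_id, log10_a, log10_b, residual, strata

    def outliers(self, n: int = 10) -> pd.DataFrame:
        """Genes farthest from the identity line."""
        return self.points.reindex(
            self.points["residual"].abs().sort_values(ascending=False).index
        ).head(n)


def _stratum(row: pd.Series) -> str:
    if row.get("biotype") in SMALL_RNA_BIOTYPES:
        return "small_RNA"
    flag = row.get("homolog_flag")
    if flag in ("SDRNA", "SDRNA2-only"):
        return f"homolog_{flag}"
    return "other"


def transcript_correlation(lib_a: pd.DataFrame, lib_b: pd.DataFrame) -> CorrelationResult:
    """Pearson R on log10 counts over genes nonzero in both libraries.

    Inputs are count tables (gene_id, count, biotype, homolog_flag). Genes
    with zero reads in either library are excluded (log10 requires it).
    Residuals from the identity line (log10 a - log10 b) support outlier
    listing; strata are small-RNA biotypes and probe-homolog flags.
    """
    merged = lib_a.merge(lib_b, on="gene_id", suffixes=("_a", "_b"))
    merged = merged[(merged["count_a"] > 0) & (merged["count_b"] > 0)].copy()
    if len(merged) < 3:
        raise QCError(f"only {len(merged)} genes with nonzero counts in both libraries")
    merged["log10_a"] = np.log10(merged["count_a"])
    merged["log10_b"] = np.log10(merged["count_b"])
    merged["residual"] = merged["log10_a"] - merged["log10_b"]
    none_col = pd.Series([None] * len(merged), index=merged.index)
    biotype = next(
        (merged[c] for c in ("biotype_a", "biotype") if c in merged.columns), none_col
    )
    homolog = next(
        (merged[c] for c in ("homolog_flag_a", "homolog_flag") if c in merged.columns),
        none_col,
    )
    merged["stratum"] = [
        _stratum(pd.Series({"biotype": b, "homolog_flag": h}))
        for b, h in zip(biotype, homolog)
    ]
    if float(merged["log10_a"].std()) == 0.0 or float(merged["log10_b"].std()) == 0.0:
        r = 1.0 if np.allclose(merged["residual"], merged["residual"].iloc[0]) else float("nan")
    else:
        r = float(stats.pearsonr(merged["log10_a"], merged["log10_b"]).statistic)
    strata: dict[str, tuple[float, int]] = {}
    for name, sub in merged.groupby("stratum"):
        if len(sub) >= 3 and sub["log10_a"].std() > 0 and sub["log10_b"].std() > 0:
            strata[name] = (
                float(stats.pearsonr(sub["log10_a"], sub["log10_b"]).statistic),
                len(sub),
            )
        else:
            strata[name] = (float("nan"), len(sub))
    cols = ["gene_id", "log10_a", "log10_b", "residual", "stratum"]
    return CorrelationResult(r=r, n_genes=len(merged), strata=strata, points=merged[cols])


#: Broad RNA classes of the read-distribution profile. Here "rRNA" means the
#: nuclear rRNA transcript only; mitochondrial reads (including 12S/16S)
#: form their own "Mito" class.
PROFILE_CLASSES = ("rRNA", "Mito", "exon", "intron", "intergenic")

_PROFILE_MAP = {
    **{label: "rRNA" for label in TARGETED_RRNA_LABELS},
    RegionLabel.rRNA_nontargeted: "rRNA",
    **{label: "Mito" for label in MT_RRNA_LABELS},
    RegionLabel.mt_other: "Mito",
    RegionLabel.exon: "exon",
    RegionLabel.intron: "intron",
    RegionLabel.intergenic: "intergenic",
}


def exon_intron_intergenic_profile(
    reads: list[AlignedRead], annotation: RegionAnnotation
) -> dict[str, float]:
    """Proportions of unique reads over {rRNA, Mito, exon, intron, intergenic}."""
    table = class_table(reads, annotation)
    profile = {cls: 0.0 for cls in PROFILE_CLASSES}
    for label, n in table.counts.items():
        profile[_PROFILE_MAP[label]] += n / table.total_unique
    return profile


def class_proportion_row(
    counts: ClassCounts, library_id: str, tissue: str, method: str
) -> dict[str, object]:
    """One library's row of the class-proportion report (percentages, 0.1%)."""
    f_rrna, f_other = counts.rollup_rrna()
    return {
        "library_id": library_id,
        "tissue": tissue,
        "depletion_method": method,
        "non_rRNA_percent": percent(f_other),
        "rRNA_percent": percent(f_rrna),
    }
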