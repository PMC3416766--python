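"""Synthetic references and FFPE-like read sets with known truth.

The generator emulates the structure the depletion experiments run on:

* a pseudo-rRNA contig carrying the 18S, 5.8S and 28S regions of the single
  long rRNA transcript, separated by non-targeted spacers;
* a pseudo-mitochondrial contig with embedded 12S and 16S rRNA regions;
* protein-coding genes with alternating exon/intron blocks on a genomic
  contig, with per-gene log-normal abundances.

Reads are emitted with truth alignments (position is known by
construction), so the classifier and efficiency estimator can be tested
hermetically without an external mapper; all simulated reads are uniquely
mapped by construction. Depletion acts on fragments before sampling reads:
a fragment from a targeted region survives with probability ``1 - e``.

Default library composition follows an untreated FFPE library in which
rRNA accounts for 60.5% of uniquely mapped reads, with short (mean 60 nt)
gamma-distributed fragments; fresh-frozen settings use longer fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sdrna.formats import (
    AlignedRead,
    Region,
    RegionLabel,
    SequenceRecord,
    write_alignments_tsv,
)

_BASES = np.array(list("ACGT"))

#: Region lengths that reproduce the canonical probe tilings (an 18S of
#: 1976 nt tiles into 24 80-mers + one 56-mer, and so on).
DEFAULT_SIZES = {
    "spacer": 1000,
    "18S": 1976,
    "5.8S": 157,
    "28S": 5025,
    "mt_lead": 648,
    "12S": 954,
    "16S": 1559,
    "mt_tail": 1000,
    "n_genes": 50,
    "exons_per_gene": 3,
    "exon_len": 200,
    "intron_len": 500,
    "intergenic_gap": 300,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    Class fractions are expected proportions of emitted fragments before
    depletion; the remainder after rRNA/mito/intergenic classes is drawn
    from genes. ``depletion_efficiency`` removes targeted-region fragments
    (nuclear 18S/5.8S/28S and, for the SDRNA2 panel, 12S/16S) with
    probability ``e`` each.
    """

    seed: int = 0
    n_reads: int = 200_000
    frac_rRNA_targeted: float = 0.55
    frac_rRNA_nontargeted: float = 0.030
    frac_mito: float = 0.025  # mitochondrial rRNA (12S + 16S)
    frac_mt_other: float = 0.005
    frac_intergenic: float = 0.02
    abundance_sigma: float = 1.2  # log-normal spread of gene abundances
    intron_retention: float = 0.6  # FFPE-like: most gene fragments intronic
    fragment_mean: float = 60.0  # FFPE-like; fresh-frozen libraries ~200
    fragment_shape: float = 6.0  # gamma shape; scale = mean / shape
    depletion_efficiency: float = 0.0
    panel: str = "SDRNA2"
    read_len: int = 50

    def __post_init__(self) -> None:
        fracs = (
            self.frac_rRNA_targeted,
            self.frac_rRNA_nontargeted,
            self.frac_mito,
            self.frac_mt_other,
            self.frac_intergenic,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must be in [0,1] and sum to <= 1")
        if not 0 <= self.depletion_efficiency <= 1:
            raise ValueError("depletion efficiency must be in [0, 1]")
        if self.panel not in ("SDRNA1", "SDRNA2"):
            raise ValueError(f"unknown panel {self.panel!r}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_reference(
    seed: int, sizes: dict | None = None
) -> tuple[list[SequenceRecord], list[Region]]:
    """Build the synthetic genome and its annotation, deterministic in seed.

    Returns (contigs, regions). Contigs: ``chrR`` (rRNA repeating unit),
    ``chrM`` (mitochondrion), ``chrG`` (genes). Intergenic stretches carry
    no region — the classifier's fallback class covers them.
    """
    sz = dict(DEFAULT_SIZES)
    if sizes:
        unknown = set(sizes) - set(sz)
        if unknown:
            raise ValueError(f"unknown size keys {sorted(unknown)}")
        sz.update(sizes)
    rng = np.random.default_rng(seed)
    regions: list[Region] = []

    # chrR: spacer | 18S | spacer | 5.8S | spacer | 28S | spacer
    layout = [
        (RegionLabel.rRNA_nontargeted, sz["spacer"]),
        (RegionLabel.rRNA_18S, sz["18S"]),
        (RegionLabel.rRNA_nontargeted, sz["spacer"]),
        (RegionLabel.rRNA_5_8S, sz["5.8S"]),
        (RegionLabel.rRNA_nontargeted, sz["spacer"]),
        (RegionLabel.rRNA_28S, sz["28S"]),
        (RegionLabel.rRNA_nontargeted, sz["spacer"]),
    ]
    pos = 0
    for label, length in layout:
        regions.append(Region("chrR", pos, pos + length, label))
        pos += length
    chr_r = SequenceRecord("chrR", _random_seq(rng, pos), "synthetic rRNA repeating unit")

    # chrM: other | 12S | 16S | other (12S and 16S are adjacent, as in mtDNA)
    layout = [
        (RegionLabel.mt_other, sz["mt_lead"]),
        (RegionLabel.mt_12S, sz["12S"]),
        (RegionLabel.mt_16S, sz["16S"]),
        (RegionLabel.mt_other, sz["mt_tail"]),
    ]
    pos = 0
    for label, length in layout:
        regions.append(Region("chrM", pos, pos + length, label))
        pos += length
    chr_m = SequenceRecord("chrM", _random_seq(rng, pos), "synthetic mitochondrial contig")

    # chrG: [gap] exon intron exon intron exon [gap] per gene
    pos = 0
    for g in range(sz["n_genes"]):
        gene_id = f"gene_{g + 1:04d}"
        pos += sz["intergenic_gap"]
        for b in range(sz["exons_per_gene"]):
            regions.append(Region("chrG", pos, pos + sz["exon_len"], RegionLabel.exon, gene_id))
            pos += sz["exon_len"]
            if b < sz["exons_per_gene"] - 1:
                regions.append(
                    Region("chrG", pos, pos + sz["intron_len"], RegionLabel.intron, gene_id)
                )
                pos += sz["intron_len"]
    pos += sz["intergenic_gap"]
    chr_g = SequenceRecord("chrG", _random_seq(rng, pos), "synthetic gene-bearing contig")

    return [chr_r, chr_m, chr_g], regions


@dataclass
class SimulatedLibrary:
    """One simulated library: reads, truth labels and gene abundances."""

    reads: list[AlignedRead]
    truth: pd.DataFrame = field(repr=False)  # read_id, true_class, gene_id
    gene_abundance: pd.DataFrame = field(repr=False)  # gene_id, weight
    config: SimConfig

    def write(self, aln_path: str | Path, truth_path: str | Path) -> None:
        write_alignments_tsv(self.reads, aln_path)
        self.truth.to_csv(truth_path, sep="\t", index=False)

    def fastq_records(self, contigs: list[SequenceRecord]):
        """Yield Biopython FASTQ records with sequences cut from the contigs."""
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord as BioRecord

        by_id = {c.id: c.sequence for c in contigs}
        for read in self.reads:
            seq = by_id[read.contig][read.pos : read.end]
            rec = BioRecord(Seq(seq), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec


def _targeted_labels(panel: str) -> set[RegionLabel]:
    labels = {RegionLabel.rRNA_18S, RegionLabel.rRNA_28S}
    if panel == "SDRNA2":
        labels |= {RegionLabel.rRNA_5_8S, RegionLabel.mt_12S, RegionLabel.mt_16S}
    return labels


def simulate_library(
    reference: tuple[list[SequenceRecord], list[Region]], config: SimConfig
) -> SimulatedLibrary:
    """Draw fragments per class proportions, deplete, and emit reads.

    ``config.n_reads`` fragments are drawn; fragments from regions targeted
    by the configured panel survive with probability ``1 - e``, so the
    emitted library is smaller than ``n_reads`` whenever ``e > 0`` —
    exactly how depletion changes a library's composition. Fragments are
    placed fully inside their source region whenever the region is long
    enough, so truth labels and classifier output coincide away from the
    (rare) clipped-fragment case.
    """
    if config.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    contigs, regions = reference
    rng = np.random.default_rng(config.seed)

    by_label: dict[RegionLabel, list[Region]] = {}
    for r in regions:
        by_label.setdefault(r.label, []).append(r)

    genes = sorted({r.gene_id for r in regions if r.gene_id})
    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(genes))
    gene_abundance = pd.DataFrame({"gene_id": genes, "weight": weights / weights.sum()})

    frac_gene = 1.0 - (
        config.frac_rRNA_targeted
        + config.frac_rRNA_nontargeted
        + config.frac_mito
        + config.frac_mt_other
        + config.frac_intergenic
    )
    class_names = ["rRNA_targeted", "rRNA_nontargeted", "mt_rRNA", "mt_other", "intergenic", "gene"]
    class_probs = np.array(
        [
            config.frac_rRNA_targeted,
            config.frac_rRNA_nontargeted,
            config.frac_mito,
            config.frac_mt_other,
            config.frac_intergenic,
            frac_gene,
        ]
    )
    class_probs = class_probs / class_probs.sum()

    targeted = _targeted_labels(config.panel)
    scale = config.fragment_mean / config.fragment_shape

    draws = rng.choice(len(class_names), size=config.n_reads, p=class_probs)
    frag_lens = np.maximum(
        20, rng.gamma(config.fragment_shape, scale, size=config.n_reads).astype(int)
    )
    survival = rng.random(config.n_reads)

    # region pools per simulation class, weighted by length
    pools: dict[str, tuple[list[Region], np.ndarray]] = {}
    for name, labels in (
        ("rRNA_targeted", [RegionLabel.rRNA_18S, RegionLabel.rRNA_5_8S, RegionLabel.rRNA_28S]),
        ("rRNA_nontargeted", [RegionLabel.rRNA_nontargeted]),
        ("mt_rRNA", [RegionLabel.mt_12S, RegionLabel.mt_16S]),
        ("mt_other", [RegionLabel.mt_other]),
    ):
        pool = [r for lbl in labels for r in by_label.get(lbl, [])]
        lens = np.array([len(r) for r in pool], dtype=float)
        pools[name] = (pool, lens / lens.sum()) if pool else ([], np.array([]))

    gene_blocks: dict[str, dict[str, list[Region]]] = {}
    for r in regions:
        if r.gene_id:
            gene_blocks.setdefault(r.gene_id, {"exon": [], "intron": []})[r.label.value].append(r)

    chr_g_len = next(len(c.sequence) for c in contigs if c.id == "chrG")
    gene_spans = [(r.start, r.end) for r in regions if r.contig == "chrG"]
    gene_lo = min(s for s, _ in gene_spans) if gene_spans else 0
    gene_hi = max(e for _, e in gene_spans) if gene_spans else 0

    reads: list[AlignedRead] = []
    truth_rows: list[tuple[str, str, str]] = []
    gene_idx = rng.choice(
        len(genes), size=config.n_reads, p=gene_abundance["weight"].to_numpy()
    )
    intronic = rng.random(config.n_reads) < config.intron_retention
    u_region = rng.random(config.n_reads)
    u_pos = rng.random(config.n_reads)

    for k in range(config.n_reads):
        cls = class_names[draws[k]]
        frag = int(frag_lens[k])
        if cls == "gene":
            gene = genes[gene_idx[k]]
            blocks = gene_blocks[gene]
            kind = "intron" if intronic[k] and blocks["intron"] else "exon"
            pool = blocks[kind]
            region = pool[int(u_region[k] * len(pool)) % len(pool)]
            true_class = RegionLabel.intron if kind == "intron" else RegionLabel.exon
            gene_label = gene
        elif cls == "intergenic":
            # place outside gene bodies: the flanks of chrG
            left = gene_lo
            right = chr_g_len - gene_hi
            if u_region[k] * (left + right) < left:
                region = Region("chrG", 0, max(gene_lo, 21), RegionLabel.intergenic)
            else:
                region = Region("chrG", gene_hi, chr_g_len, RegionLabel.intergenic)
            true_class = RegionLabel.intergenic
            gene_label = ""
        else:
            pool, probs = pools[cls]
            region = pool[np.searchsorted(np.cumsum(probs), u_region[k], side="right").clip(0, len(pool) - 1)]
            true_class = region.label
            gene_label = ""

        if true_class in targeted and survival[k] < config.depletion_efficiency:
            continue

        frag = min(frag, len(region))
        start = region.start + int(u_pos[k] * (len(region) - frag + 1))
        read_len = min(config.read_len, frag)
        read_id = f"read_{k + 1:07d}"
        reads.append(AlignedRead(read_id, region.contig, start, read_len, unique=True))
        truth_rows.append((read_id, true_class.value, gene_label))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "true_class", "gene_id"])
    return SimulatedLibrary(reads=reads, truth=truth, gene_abundance=gene_abundance, config=config)


def simulate_replicates(
    config: SimConfig,
    n_genes: int = 5000,
    depth: int = 1_000_000,
    small_rna_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two technical-replicate count tables from one gene-abundance vector.

    Both replicates are independent multinomial draws of ``depth`` reads
    from the same log-normal abundance profile, which is what technical
    replication of a sequencing library measures. A fraction of genes is
    tagged with small-RNA biotypes for stratified correlation plots.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n_genes)
    p = weights / weights.sum()
    biotypes = np.where(
        rng.random(n_genes) < small_rna_fraction,
        rng.choice(["snoRNA", "snRNA", "scRNA", "miRNA"], size=n_genes),
        "other",
    )

    def table(counts: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": genes,
                "count": counts,
                "biotype": biotypes,
                "homolog_flag": "none",
            }
        )

    a = rng.multinomial(depth, p)
    b = rng.multinomial(depth, p)
    return table(a), table(b)
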