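"""File formats and shared coordinate conventions.

Every interval inside the toolkit is 0-based, half-open ``[start, end)``.
The only 1-based boundary is SAM, and pysam converts it on the way in.

FASTA and FASTQ go through Biopython, SAM through pysam, BED and TSV tables
through pandas; this module only layers the toolkit's validation and domain
types on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Malformed input file (bad FASTA header, illegal character, bad table)."""


VALID_ALPHABET = frozenset("ACGTN")

#: Default MAPQ threshold below which a SAM read is not considered unique.
DEFAULT_MIN_MAPQ = 10


class RegionLabel(str, Enum):
    """Closed vocabulary of annotation classes used for read binning."""

    rRNA_18S = "rRNA_18S"
    rRNA_28S = "rRNA_28S"
    rRNA_5_8S = "rRNA_5_8S"
    rRNA_nontargeted = "rRNA_nontargeted"
    mt_12S = "mt_12S"
    mt_16S = "mt_16S"
    mt_other = "mt_other"
    exon = "exon"
    intron = "intron"
    intergenic = "intergenic"

    def __str__(self) -> str:  # BED name column
        return self.value


#: Nuclear rRNA regions covered by depletion probes.
TARGETED_RRNA_LABELS = (RegionLabel.rRNA_18S, RegionLabel.rRNA_28S, RegionLabel.rRNA_5_8S)
#: Mitochondrial rRNA regions (targeted by the SDRNA2 panel).
MT_RRNA_LABELS = (RegionLabel.mt_12S, RegionLabel.mt_16S)
#: Everything counted in the two-way "rRNA" rollup: all rRNAs encoded in
#: both the nuclear and mitochondrial genomes.
RRNA_ROLLUP_LABELS = TARGETED_RRNA_LABELS + (RegionLabel.rRNA_nontargeted,) + MT_RRNA_LABELS


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase ACGTN)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r} (alphabet is ACGTN)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Region:
    """A labeled interval on a contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    label: RegionLabel
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.contig}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to what classification needs."""

    read_id: str
    contig: str
    pos: int  # 0-based leftmost
    length: int  # span on the reference, bases
    unique: bool

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"read {self.read_id!r}: length must be >= 1")
        if self.pos < 0:
            raise ValueError(f"read {self.read_id!r}: negative position")

    @property
    def end(self) -> int:
        return self.pos + self.length


def _normalize_sequence(raw: str) -> str:
    # RNA targets are handled as DNA throughout: uppercase, U -> T.
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercased and U is converted to T. An empty file yields
    an empty list. Malformed headers or characters outside ACGTN(U) raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected FASTA header starting with '>'")
            break
    records: list[SequenceRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # SeqIO warns on oddities we validate ourselves
        parsed = list(SeqIO.parse(str(path), "fasta"))
    for rec in parsed:
        seq = _normalize_sequence(str(rec.seq))
        bad = set(seq) - VALID_ALPHABET
        if bad:
            lineno = _find_bad_line(lines, rec.id, bad)
            raise FormatError(
                f"{path}:{lineno}: record {rec.id!r} contains illegal characters {sorted(bad)!r}"
            )
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def _find_bad_line(lines: Sequence[str], rec_id: str, bad: set[str]) -> int:
    in_record = False
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == rec_id if line[1:].split() else False
        elif in_record and (set(_normalize_sequence(line.strip())) & bad):
            return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Alignments


def read_alignments(
    path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    dialect: str = "sam",
) -> list[AlignedRead]:
    """Read alignments from SAM or a 5-column TSV.

    Unmapped records are dropped. Uniqueness of mapping:

    * ``sam`` — unique iff the NH tag is absent or 1 AND MAPQ >= ``min_mapq``
      (single-hit semantics; threshold configurable to match any mapper).
    * ``tsv`` — columns ``read_id contig pos length unique``, with an
      explicit 0/1 unique column; ``min_mapq`` is ignored.
    """
    if dialect == "sam":
        return _read_sam(path, min_mapq)
    if dialect == "tsv":
        return _read_alignment_tsv(path)
    raise ValueError(f"unknown alignment dialect {dialect!r} (expected 'sam' or 'tsv')")


def _read_sam(path: str | Path, min_mapq: int) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            unique = (nh <= 1) and (rec.mapping_quality >= min_mapq)
            length = rec.reference_length or rec.query_length or len(rec.query_sequence or "")
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    pos=rec.reference_start,
                    length=length,
                    unique=unique,
                )
            )
    return reads


_ALN_COLUMNS = ["read_id", "contig", "pos", "length", "unique"]


def _read_alignment_tsv(path: str | Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=_ALN_COLUMNS, comment="#")
    if df.empty:
        return []
    if (df["pos"] < 0).any():
        bad = df.index[df["pos"] < 0][0]
        raise FormatError(f"{path}: negative coordinate at row {bad + 1}")
    return [
        AlignedRead(
            read_id=str(r.read_id),
            contig=str(r.contig),
            pos=int(r.pos),
            length=int(r.length),
            unique=bool(int(r.unique)),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignments_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write the 5-column whitespace alignment table (truth-table dialect)."""
    df = pd.DataFrame(
        [(r.read_id, r.contig, r.pos, r.length, int(r.unique)) for r in reads],
        columns=_ALN_COLUMNS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED6; the name column carries ``label[;gene_id]``."""
    rows = []
    for r in regions:
        name = r.label.value if r.gene_id is None else f"{r.label.value};{r.gene_id}"
        rows.append((r.contig, r.start, r.end, name, 0, "+"))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> list[Region]:
    """Read a BED6 file back into regions, sorted by (contig, start).

    Duplicate identical rows are deduplicated with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 4:
        raise FormatError(f"{path}: BED needs at least 4 columns (found {df.shape[1]})")
    seen: set[tuple] = set()
    regions: list[Region] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        contig, start, end, name = str(row[0]), int(row[1]), int(row[2]), str(row[3])
        label_str, _, gene_id = name.partition(";")
        try:
            label = RegionLabel(label_str)
        except ValueError as exc:
            raise FormatError(f"{path}:{idx}: unknown region label {label_str!r}") from exc
        key = (contig, start, end, label_str, gene_id)
        if key in seen:
            warnings.warn(f"{path}:{idx}: duplicate region {key}, deduplicated", stacklevel=2)
            continue
        seen.add(key)
        regions.append(Region(contig, start, end, label, gene_id or None))
    regions.sort(key=lambda r: (r.contig, r.start, r.end, r.label.value, r.gene_id or ""))
    return regions


# ---------------------------------------------------------------------------
# Count tables

_COUNT_COLUMNS = ["gene_id", "count", "biotype", "homolog_flag"]


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-transcript count table (gene_id, count, biotype, homolog_flag)."""
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"count table missing columns {missing}")
    df[_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-transcript count table written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: count table missing columns {missing}")
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df
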