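"""Adapter trimming and fixed end trimming of short reads.

Because library fragments (especially from FFPE RNA) are often shorter than
the read length, reads frequently run into the 3' sequencing adapter. The
trimmer tests the full adapter first, then shortens it one base at a time,
matching each prefix against the read's 3' end under a length-dependent
mismatch allowance; the longest matching prefix is removed. A separate
fixed trim removes a constant number of bases from each end (a policy
constant derived from one's own data, not hard-coded — e.g. 6 from the 5'
end and 8 from the 3' end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord


def default_mismatch_allowance(k: int) -> int:
    """~10% mismatch tolerance: floor(k/10) mismatches for a k-base match."""
    return k // 10


@dataclass
class TrimPolicy:
    """Adapter plus end-trim settings for one library."""

    adapter: str
    k_min: int = 5
    mismatch_allowance: Callable[[int], int] = field(default=default_mismatch_allowance)
    fixed_5p: int = 0
    fixed_3p: int = 0

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")


def trim_adapter(read: str, policy: TrimPolicy) -> tuple[str, int]:
    """Remove the longest adapter prefix matching the read's 3' end.

    For k from len(adapter) down to ``policy.k_min``, the adapter prefix of
    length k is compared (Hamming) against the read suffix of length k; the
    first success trims k bases. Returns (trimmed read, bases trimmed).
    """
    if not read:
        raise ValueError("empty read")
    adapter = policy.adapter
    for k in range(min(len(adapter), len(read)), policy.k_min - 1, -1):
        suffix = read[-k:]
        prefix = adapter[:k]
        mismatches = sum(a != b for a, b in zip(suffix, prefix))
        if mismatches <= policy.mismatch_allowance(k):
            return read[:-k], k
    return read, 0


def trim_fixed(read: str, n5: int, n3: int) -> str | None:
    """Keep bases [n5, len-n3); return None if the read is too short."""
    if n5 < 0 or n3 < 0:
        raise ValueError("fixed trim lengths must be non-negative")
    if len(read) <= n5 + n3:
        return None
    return read[n5 : len(read) - n3] if n3 else read[n5:]


@dataclass
class TrimStats:
    """Per-file trimming tallies, serializable to a JSON log."""

    total: int = 0
    adapter_trimmed: int = 0
    bases_trimmed: int = 0
    dropped_short: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def trim_record(rec: SeqRecord, policy: TrimPolicy) -> tuple[SeqRecord | None, int]:
    """Adapter-trim then fixed-trim one FASTQ record (qualities kept in sync).

    Order is fixed: the adapter is located on the original 3' end first,
    then the constant end trims are applied to what remains.
    """
    seq = str(rec.seq)
    trimmed, k = trim_adapter(seq, policy)
    kept = trim_fixed(trimmed, policy.fixed_5p, policy.fixed_3p)
    if kept is None:
        return None, k
    start = policy.fixed_5p
    end = start + len(kept)
    return rec[start:end], k


def trim_fastq(
    records: Iterable[SeqRecord], policy: TrimPolicy, stats: TrimStats | None = None
) -> Iterator[SeqRecord]:
    """Trim a FASTQ record stream, dropping reads that become too short."""
    stats = stats if stats is not None else TrimStats()
    for rec in records:
        stats.total += 1
        out, k = trim_record(rec, policy)
        if k:
            stats.adapter_trimmed += 1
            stats.bases_trimmed += k
        if out is None:
            stats.dropped_short += 1
            continue
        yield out


def trim_fastq_file(
    in_path: str | Path,
    out_path: str | Path,
    policy: TrimPolicy,
    log_path: str | Path | None = None,
) -> TrimStats:
    """Trim a FASTQ file on disk; optionally write a JSON statistics log."""
    stats = TrimStats()
    with open(out_path, "w") as out:
        SeqIO.write(trim_fastq(SeqIO.parse(str(in_path), "fastq"), policy, stats), out, "fastq")
    if log_path is not None:
        stats.to_json(log_path)
    return stats
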