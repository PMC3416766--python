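"""Tiled antisense probe panels for RNase H depletion.

Probes are short (default 39-80 nt) antisense DNA oligos tiled
non-overlapping, end to end, across the full length of each target RNA so
that RNase H can digest RNA:DNA hybrids along the whole molecule — including
fragmented FFPE-derived molecules that hybridize to only part of the panel.

Two panel versions are built in:

* ``SDRNA1`` — 18S + 28S rRNA probes, pooled at 0.5 µM per probe.
* ``SDRNA2`` — the SDRNA1 probes plus 5.8S rRNA and mitochondrial 12S/16S
  rRNA probes at 0.05 µM per probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from sdrna.formats import VALID_ALPHABET, SequenceRecord, write_fasta

DEFAULT_MAX_LEN = 80
DEFAULT_MIN_LEN = 39

#: Per-probe pool concentrations (µM) by concentration group.
CONC_UM = {"A": 0.5, "B": 0.05}


class DesignError(ValueError):
    """Invalid probe-design input (target too short, duplicate names, ...)."""


class TargetClass(str, Enum):
    nuclear_rRNA = "nuclear_rRNA"
    mito_rRNA = "mito_rRNA"


@dataclass(frozen=True)
class TargetSpec:
    """One RNA species targeted for depletion.

    ``conc_group`` "A" pools at 0.5 µM per probe (18S/28S), "B" at 0.05 µM
    per probe (5.8S/12S/16S).
    """

    name: str
    sequence: str
    target_class: TargetClass = TargetClass.nuclear_rRNA
    conc_group: str = "A"

    def __post_init__(self) -> None:
        if self.conc_group not in CONC_UM:
            raise DesignError(f"unknown concentration group {self.conc_group!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Probe:
    """An antisense oligo covering target[start:end] on the sense strand."""

    id: str
    target_name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise DesignError(f"probe {self.id}: interval/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        gc = sum(self.sequence.count(b) for b in "GC")
        return 100.0 * gc / len(self.sequence)


@dataclass
class ProbePanel:
    """A versioned probe set with per-probe molar concentrations."""

    version: str
    probes: list[Probe]
    conc_per_probe: dict[str, float] = field(default_factory=dict)

    @property
    def total_conc(self) -> float:
        """Pool total in µM (sum of per-probe concentrations)."""
        return sum(self.conc_per_probe.values())

    def __len__(self) -> int:
        return len(self.probes)


def antisense(seq: str) -> str:
    """Reverse complement of a DNA string (the antisense probe sequence)."""
    bad = set(seq.upper()) - VALID_ALPHABET
    if bad:
        raise DesignError(f"illegal characters {sorted(bad)!r} in sequence")
    return str(Seq(seq.upper()).reverse_complement())


def tile_target(
    target: TargetSpec | str,
    max_len: int = DEFAULT_MAX_LEN,
    min_len: int = DEFAULT_MIN_LEN,
    policy: str = "greedy",
) -> list[tuple[int, int]]:
    """Tile non-overlapping probe intervals across a target sequence.

    ``greedy`` lays consecutive ``max_len`` windows from position 0 and adds
    one trailing remainder probe if the leftover is at least ``min_len``
    (e.g. a 954-nt target gives eleven 80-mers and one 74-mer). A leftover
    shorter than ``min_len`` would leave a synthesizable gap, so such targets
    fall back to the ``balanced`` policy: ``ceil(L / max_len)`` probes whose
    lengths differ by at most one and jointly cover the whole target.

    Returns sorted (start, end) intervals, 0-based half-open on the target
    sense strand.
    """
    seq = target.sequence if isinstance(target, TargetSpec) else target
    L = len(seq)
    if not (1 <= min_len <= max_len):
        raise DesignError(f"invalid probe length bounds [{min_len}, {max_len}]")
    if L < min_len:
        raise DesignError(f"target of length {L} is shorter than min probe length {min_len}")
    if policy not in ("greedy", "balanced"):
        raise DesignError(f"unknown tiling policy {policy!r}")

    if policy == "greedy":
        n_full, remainder = divmod(L, max_len)
        if remainder == 0 or remainder >= min_len:
            intervals = [(i * max_len, (i + 1) * max_len) for i in range(n_full)]
            if remainder:
                intervals.append((n_full * max_len, L))
            return intervals
        # short remainder: fall through to balanced so coverage stays complete

    n = -(-L // max_len)  # ceil
    base, extra = divmod(L, n)
    if base < min_len:
        raise DesignError(
            f"cannot tile length {L} with {n} probes of at least {min_len} nt"
        )
    intervals = []
    pos = 0
    for i in range(n):
        length = base + (1 if i < extra else 0)
        intervals.append((pos, pos + length))
        pos += length
    return intervals


def design_probes(
    target: TargetSpec,
    max_len: int = DEFAULT_MAX_LEN,
    min_len: int = DEFAULT_MIN_LEN,
    policy: str = "greedy",
) -> list[Probe]:
    """Tile a target and emit antisense probes ordered 5'→3' on the sense strand.

    Probe ids are deterministic: ``<target>_<ordinal>``, 1-based.
    """
    intervals = tile_target(target, max_len=max_len, min_len=min_len, policy=policy)
    return [
        Probe(
            id=f"{target.name}_{i}",
            target_name=target.name,
            start=start,
            end=end,
            sequence=antisense(target.sequence[start:end]),
        )
        for i, (start, end) in enumerate(intervals, start=1)
    ]


def build_panel(
    targets: list[TargetSpec],
    version: str = "custom",
    max_len: int = DEFAULT_MAX_LEN,
    min_len: int = DEFAULT_MIN_LEN,
    policy: str = "greedy",
) -> ProbePanel:
    """Assemble a probe panel from target specs.

    Probes are concatenated in target order, each target tiled 5'→3'.
    Per-probe concentrations come from each target's concentration group.
    """
    if not targets:
        raise DesignError("empty target list")
    names = [t.name for t in targets]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate target names in {names}")
    probes: list[Probe] = []
    conc: dict[str, float] = {}
    for target in targets:
        for probe in design_probes(target, max_len=max_len, min_len=min_len, policy=policy):
            probes.append(probe)
            conc[probe.id] = CONC_UM[target.conc_group]
    return ProbePanel(version=version, probes=probes, conc_per_probe=conc)


def standard_targets(sequences: dict[str, str]) -> list[TargetSpec]:
    """Build the canonical SDRNA target specs from named sequences.

    Expects keys among {"18S", "28S", "5.8S", "12S", "16S"}; 18S/28S get
    concentration group A (0.5 µM), the rest group B (0.05 µM).
    """
    group = {"18S": "A", "28S": "A", "5.8S": "B", "12S": "B", "16S": "B"}
    cls = {
        "18S": TargetClass.nuclear_rRNA,
        "28S": TargetClass.nuclear_rRNA,
        "5.8S": TargetClass.nuclear_rRNA,
        "12S": TargetClass.mito_rRNA,
        "16S": TargetClass.mito_rRNA,
    }
    unknown = set(sequences) - set(group)
    if unknown:
        raise DesignError(f"unknown standard target names {sorted(unknown)}")
    order = [n for n in ("18S", "28S", "5.8S", "12S", "16S") if n in sequences]
    return [
        TargetSpec(name=n, sequence=sequences[n], target_class=cls[n], conc_group=group[n])
        for n in order
    ]


def panel_report(panel: ProbePanel) -> pd.DataFrame:
    """Per-probe summary: id, target, coordinates, length, GC%, concentration.

    Deterministic given the panel — identical inputs give a byte-identical
    table — so it doubles as the pool recipe.
    """
    rows = [
        {
            "probe_id": p.id,
            "target": p.target_name,
            "start": p.start,
            "end": p.end,
            "length": len(p),
            "gc_percent": round(p.gc_percent, 2),
            "conc_uM": panel.conc_per_probe.get(p.id, float("nan")),
            "sequence": p.sequence,
        }
        for p in panel.probes
    ]
    return pd.DataFrame(rows)


def probe_counts(panel: ProbePanel) -> dict[str, int]:
    """Number of probes per target."""
    counts: dict[str, int] = {}
    for p in panel.probes:
        counts[p.target_name] = counts.get(p.target_name, 0) + 1
    return counts


def write_panel(panel: ProbePanel, fasta_path: str | Path, recipe_path: str | Path) -> None:
    """Write probe FASTA (antisense sequences) and the pool-recipe TSV."""
    records = [
        SequenceRecord(
            id=p.id,
            sequence=p.sequence,
            description=f"{p.target_name}:{p.start}-{p.end} antisense",
        )
        for p in panel.probes
    ]
    write_fasta(records, fasta_path)
    panel_report(panel).to_csv(recipe_path, sep="\t", index=False)
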