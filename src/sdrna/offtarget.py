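"""Off-target screening of depletion probes by local alignment.

Each probe is aligned against every transcript on both strands with
blastn-style scoring (match +2, mismatch -3, gap existence 5, gap extension
2, word size 11) and genes reaching at least 50% nucleotide identity with a
probe are flagged as potential off-targets. Identity is probe-centric:
identities divided by probe length, not by alignment length, so short local
hits cannot inflate the fraction.

The aligner is an exact Smith-Waterman dynamic program with affine gaps
(a gap of length k costs ``gap_open + k * gap_extend``, the NCBI
convention). A word-seeded fast path skips transcripts that share no exact
``word_size``-mer with the probe; on seeded transcripts the full DP runs,
so seeded scores equal exhaustive scores whenever a seed exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from sdrna.formats import SequenceRecord
from sdrna.probe_design import ProbePanel, antisense

#: Targets shared by both panel versions; probes against anything else are
#: considered SDRNA2-only when aggregating homolog flags.
SDRNA1_TARGETS = frozenset({"18S", "28S"})

DEFAULT_SCORE_FLOOR = 20


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring (defaults follow low-stringency blastn)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5  # gap existence cost (positive)
    gap_extend: int = 2  # per-base extension cost (positive)
    word_size: int = 11

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a probe against one subject sequence."""

    probe_id: str
    subject_id: str
    score: int
    aln_len: int
    identities: int
    identity_frac_probe: float
    probe_span: tuple[int, int]  # 0-based half-open on the probe
    subject_span: tuple[int, int]  # 0-based half-open on the subject + strand
    strand: str  # "+" or "-"


_STOP, _DIAG, _LEFT, _UP = 0, 1, 2, 3


def _smith_waterman(query: str, subject: str, sc: ScoringScheme):
    """Affine-gap local DP. Returns (score, q_span, s_span, aln_len, identities).

    Ties are broken toward longer alignments, then smaller subject start.
    """
    n, m = len(query), len(subject)
    neg = -(10**9)
    open_cost = sc.gap_open + sc.gap_extend  # first gapped base
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in query (left)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in subject (up)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    e_ext = np.zeros((n + 1, m + 1), dtype=bool)  # E came from E (extension)
    f_ext = np.zeros((n + 1, m + 1), dtype=bool)

    best = 0
    ends: list[tuple[int, int]] = []
    q = query
    s = subject
    for i in range(1, n + 1):
        qi = q[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fp = F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - open_cost, Ei[j - 1] - sc.gap_extend)
            f = max(Hp[j] - open_cost, Fp[j] - sc.gap_extend)
            sub = sc.match if qi == s[j - 1] else sc.mismatch
            d = Hp[j - 1] + sub
            h = max(0, d, e, f)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > 0:
                if h == d:
                    ptr[i, j] = _DIAG
                elif h == e:
                    ptr[i, j] = _LEFT
                else:
                    ptr[i, j] = _UP
            e_ext[i, j] = e == Ei[j - 1] - sc.gap_extend and e != Hi[j - 1] - open_cost
            f_ext[i, j] = f == Fp[j] - sc.gap_extend and f != Hp[j] - open_cost
            if h > best:
                best = h
                ends = [(i, j)]
            elif h == best and h > 0:
                ends.append((i, j))

    if best == 0:
        return 0, (0, 0), (0, 0), 0, 0

    candidates = []
    for end_i, end_j in ends:
        tb = _traceback(query, subject, ptr, e_ext, f_ext, end_i, end_j)
        candidates.append(tb)
    # longer alignment first, then smaller subject start
    candidates.sort(key=lambda t: (-t[2], t[1][0]))
    q_span, s_span, aln_len, identities = candidates[0]
    return best, q_span, s_span, aln_len, identities


def _traceback(query, subject, ptr, e_ext, f_ext, i, j):
    aln_len = 0
    identities = 0
    end_i, end_j = i, j
    state = "H"
    while True:
        if state == "H":
            p = ptr[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                aln_len += 1
                if query[i - 1] == subject[j - 1]:
                    identities += 1
                i -= 1
                j -= 1
            elif p == _LEFT:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aln_len += 1
            came_ext = e_ext[i, j]
            j -= 1
            if not came_ext:
                state = "H"
        else:  # F
            aln_len += 1
            came_ext = f_ext[i, j]
            i -= 1
            if not came_ext:
                state = "H"
    return (i, end_i), (j, end_j), aln_len, identities


def _word_hits(query: str, subject: str, word_size: int) -> bool:
    if len(query) < word_size or len(subject) < word_size:
        return False
    words = {query[k : k + word_size] for k in range(len(query) - word_size + 1)}
    return any(subject[k : k + word_size] in words for k in range(len(subject) - word_size + 1))


def local_align(
    query: str,
    subject: str,
    scoring: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    method: str = "dp",
) -> AlignmentHit:
    """Best affine-gap local alignment of query vs subject, both strands.

    ``method="dp"`` is the exhaustive dynamic program; ``method="seeded"``
    first requires an exact shared word of ``scoring.word_size`` bases on a
    strand and returns a zero hit for unseeded strands. Ties between strands
    go to the plus strand.
    """
    sc = scoring or ScoringScheme()
    if not query or not subject:
        raise ValueError("empty sequence")
    if method not in ("dp", "seeded"):
        raise ValueError(f"unknown alignment method {method!r}")

    best = None
    for strand, subj in (("+", subject), ("-", antisense(subject))):
        if method == "seeded" and not _word_hits(query, subj, sc.word_size):
            continue
        score, q_span, s_span, aln_len, identities = _smith_waterman(query, subj, sc)
        if strand == "-" and aln_len:
            # report subject coordinates on the forward strand
            s_span = (len(subject) - s_span[1], len(subject) - s_span[0])
        hit = AlignmentHit(
            probe_id=query_id,
            subject_id=subject_id,
            score=score,
            aln_len=aln_len,
            identities=identities,
            identity_frac_probe=identities / len(query),
            probe_span=q_span,
            subject_span=s_span,
            strand=strand,
        )
        if (
            best is None
            or hit.score > best.score
            or (hit.score == best.score and hit.aln_len > best.aln_len)
            or (
                hit.score == best.score
                and hit.aln_len == best.aln_len
                and hit.subject_span[0] < best.subject_span[0]
            )
        ):
            best = hit
    if best is None:  # no seed on either strand
        best = AlignmentHit(query_id, subject_id, 0, 0, 0, 0.0, (0, 0), (0, 0), "+")
    return best


def screen_panel(
    panel: ProbePanel,
    transcriptome: Iterable[SequenceRecord],
    threshold: float = 0.5,
    scoring: ScoringScheme | None = None,
    method: str = "seeded",
    score_floor: int = DEFAULT_SCORE_FLOOR,
) -> pd.DataFrame:
    """Screen every probe against every transcript; flag >=threshold identity.

    Returns the hit table (one row per probe x transcript with a reported
    hit) with columns probe_id, gene_id, score, aln_len, identities,
    identity_frac, strand, flagged. Hits below ``score_floor`` are dropped
    before identity filtering (the low-stringency raw-score gate).
    """
    transcripts = list(transcriptome)
    if not panel.probes:
        raise ValueError("empty panel")
    if not transcripts:
        raise ValueError("empty transcriptome")
    sc = scoring or ScoringScheme()
    rows = []
    for probe in panel.probes:
        for tx in transcripts:
            hit = local_align(
                probe.sequence,
                tx.sequence,
                sc,
                query_id=probe.id,
                subject_id=tx.id,
                method=method,
            )
            if hit.score < score_floor:
                continue
            rows.append(
                {
                    "probe_id": probe.id,
                    "gene_id": tx.id,
                    "score": hit.score,
                    "aln_len": hit.aln_len,
                    "identities": hit.identities,
                    "identity_frac": hit.identity_frac_probe,
                    "strand": hit.strand,
                    "flagged": hit.identity_frac_probe >= threshold,
                    "probe_target": probe.target_name,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "gene_id",
            "score",
            "aln_len",
            "identities",
            "identity_frac",
            "strand",
            "flagged",
            "probe_target",
        ],
    )


def homolog_flags(hits: pd.DataFrame, sdrna1_targets: frozenset[str] = SDRNA1_TARGETS) -> pd.DataFrame:
    """Aggregate flagged hits to per-gene homolog-version flags.

    A gene homologous to any probe of an SDRNA1 target (18S/28S by default)
    is flagged ``SDRNA``; genes homologous only to the additional SDRNA2
    probes (5.8S/12S/16S) are flagged ``SDRNA2-only`` — mirroring the black
    vs red scatter-plot annotations of depletion-library comparisons.
    """
    flagged = hits[hits["flagged"]]
    rows = []
    for gene, sub in flagged.groupby("gene_id"):
        shared = any(t in sdrna1_targets for t in sub["probe_target"])
        rows.append(
            {
                "gene_id": gene,
                "homolog_flag": "SDRNA" if shared else "SDRNA2-only",
                "n_probes": sub["probe_id"].nunique(),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "homolog_flag", "n_probes"])


def probe_gene_map(hits: pd.DataFrame) -> dict[str, list[str]]:
    """Flagged probe -> sorted gene list."""
    flagged = hits[hits["flagged"]]
    return {
        probe: sorted(sub["gene_id"].unique()) for probe, sub in flagged.groupby("probe_id")
    }
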