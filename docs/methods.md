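# Methods

## Problem setting

Ribosomal RNA can account for the large majority of a total-RNA sequencing
library — archival FFPE (formalin-fixed, paraffin-embedded) tissue RNA is
both heavily rRNA-dominated and too fragmented for polyA+ selection. One
effective remedy is hybridization of tiled antisense DNA oligos across the
abundant species, digestion of the RNA:DNA hybrids with RNase H, and
removal of the probes with DNase I. Because the probes tile the full length
of each target, even short fragments form digestible hybrids. This package
implements the computational side of that workflow: panel design,
off-target screening, read preparation, depletion QC, and a truth-labelled
simulator that makes the whole pipeline testable offline.

## Probe tiling

`probe_design.tile_target` lays non-overlapping windows 5'→3' along the
target sense strand and emits their reverse complements as probes.

* **greedy** (default): consecutive `max_len` windows from position 0, plus
  one trailing remainder probe if the leftover is at least `min_len`. This
  reproduces the canonical panel arithmetic: a 1976-nt 18S gives 24 80-mers
  + one 56-mer; 5025-nt 28S gives 62 + one 65-mer; 954-nt 12S gives 11 +
  one 74-mer; 1559-nt 16S gives 19 + one 39-mer. SDRNA1 (18S+28S) is 88
  probes; SDRNA2 adds 5.8S/12S/16S for 122.
* **balanced**: `ceil(L / max_len)` windows whose lengths differ by at most
  one. A greedy leftover shorter than `min_len` falls back to balanced
  rather than leaving part of the target uncovered, because depletion
  depends on hybrid formation across the entire molecule. (The historical
  5.8S design — two 78-mers on a 157-nt target — corresponds to the
  balanced layout up to one base; both policies are exposed.)

Defaults: `max_len = 80`, `min_len = 39` (the shortest probe ever
synthesized in the reference panels; more conservative bounds can be set
per call). Pool concentrations: group A targets (18S, 28S) at 0.5 µM per
probe, group B (5.8S, 12S, 16S) at 0.05 µM; the SDRNA1 pool therefore
totals 88 × 0.5 = 44 µM. Probe ids (`<target>_<ordinal>`), ordering and the
recipe table are deterministic, so a rebuilt panel is byte-identical.

## Off-target screening

Probes are screened against a transcriptome with an exact Smith–Waterman
local alignment under blastn-style low-stringency scoring: match +2,
mismatch −3, affine gaps costing `5 + 2k` for length `k` (NCBI
existence/extension convention), both subject strands searched, ties broken
toward longer alignments and then smaller subject start. A word-seeded fast
path (word size 11) skips transcripts sharing no exact 11-mer with the
probe; seeded transcripts get the full DP, so seeded and exhaustive scores
agree whenever a seed exists. Unseeded best alignments are necessarily weak
(well below the flagging level under these gap costs), which the test suite
checks empirically.

Design choices, where the convention is genuinely open:

* **Identity denominator.** "50% nucleotide identity" is computed as
  identities ÷ probe length, not ÷ alignment length — a probe-centric risk
  measure that a short high-identity local hit cannot inflate.
* **No E-values.** The low-stringency behaviour is realized as a raw-score
  floor (default 20) before identity filtering; Karlin–Altschul calibration
  would add complexity without changing which genes cross the 50% rule.
* **Low-complexity masking** is available as an explicit upstream concern
  and deliberately off by default so toy tests are reproducible.

Flagged genes are aggregated to per-gene homolog flags: `SDRNA` if the gene
is homologous to any 18S/28S probe (present in both panel versions),
`SDRNA2-only` if only to the added 5.8S/12S/16S probes. The flag file feeds
the correlation strata in `qc`.

## Read preparation

`read_prep.trim_adapter` tests the full adapter first and shortens it one
base at a time, comparing each prefix against the read's 3' end under a
Hamming mismatch allowance; the longest admissible prefix is removed. The
allowance is a function of match length, default `floor(k/10)` (~10%
tolerance, the common choice for 3'-adapter trimmers) with `k_min = 5`.
Fixed end trimming (`trim_fixed`) removes constants from both ends —
datasets dominated by short fragments have used 6 bases 5' and 8 bases 3' —
and drops reads that would become empty, counting them. Order is fixed:
adapter first, then fixed ends; qualities are sliced identically.

## Read classification and QC

Uniquely mapped reads (SAM: NH tag absent-or-1 and MAPQ ≥ 10 by default;
TSV truth tables: explicit flag) are binned by ≥1-base overlap with a
region annotation under a fixed priority ladder:

targeted rRNA (18S/28S/5.8S) > non-targeted rRNA spacer > mt 12S/16S >
other mito > exon > intron > intergenic.

A read straddling two classes takes the higher-priority one; reads on
unannotated contigs fall to intergenic with a warning counter. Two rollups
are derived: the two-way table treats all nuclear **and** mitochondrial
rRNAs as "rRNA"; the five-class profile (rRNA / Mito / exon / intron /
intergenic) keeps the mitochondrial genome as its own class. Per-subregion
tallies are always retained, so either spacer convention can be read off.
Display percentages are rounded half-up to 0.1% (so a printed row may sum
to 100.1%); raw fractions are kept internally.

**Depletion efficiency.** Read proportions are compositional: removing
targeted reads inflates every other class's share, so the naive
`1 − f_d/f_u` understates nothing but behaves poorly when `f_u` is large.
The default estimator normalizes by odds,

    E = 1 − [f_d/(1−f_d)] / [f_u/(1−f_u)],

which recovers the true per-fragment survival probability exactly when
depletion is an independent thinning of targeted fragments (the simulator's
model, and the test suite verifies recovery within ±0.01 at 2×10⁵ reads).
On an archival untreated/depleted pair with rRNA at 60.5% and 1.9%, E =
98.7%; both estimators are exposed (`--efficiency {odds,naive}`).

**Correlation.** Cross-library reproducibility is Pearson R on log10 read
counts over genes with nonzero counts in **both** libraries (pairwise
exclusion is the only rule that permits log10 on both axes). Per-stratum R
is reported for small-RNA biotypes (sno/sn/sc/mi) and probe-homolog flags,
with identity-line residuals for outlier listing.

## Simulator

`simulate.make_reference` builds a three-contig genome, deterministic in
the seed: `chrR` with 18S/5.8S/28S regions separated by non-targeted
spacers (default subregion lengths 1976/157/5025, i.e. the sizes whose
tilings reproduce the canonical probe counts); `chrM` with adjacent
12S/16S regions (954/1559 nt) flanked by other mitochondrial sequence; and
`chrG` with mRNA genes of alternating exon/intron blocks.

`simulate_library` draws fragments from a categorical class distribution,
places each fully inside a length-weighted region of its class, applies
depletion as an independent Bernoulli thinning of fragments from
panel-targeted regions (survival `1 − e`), and emits one uniquely mapped
read per surviving fragment with a truth alignment — no external mapper is
involved, keeping tests hermetic. Gene-derived fragments pick a gene from a
log-normal abundance profile (σ = 1.2) and an intron with probability
`intron_retention`.

Defaults are the untreated-FFPE condition: combined rRNA 60.5% of reads
(targeted 0.55, spacer 0.030, mt-rRNA 0.025 — the split across subclasses
is a modelling choice, as published tables report only the rollup),
short gamma fragments (mean 60 nt, shape 6) for FFPE versus mean 200 nt
for fresh-frozen-like settings, read length 50, intron retention 0.6.

What the simulator does **not** model: sequencing errors, mapper artifacts
and multireads (all reads are unique by construction), boundary-straddling
fragments (fragments are clipped into their source region, which is why
truth recovery is ~100% rather than merely ≥99.9%), positional coverage
bias, and any mechanistic account of why FFPE libraries are intron-rich —
`intron_retention` is a free parameter. Passing tests therefore validate
the algorithms and their statistical behaviour under the stated model, not
performance on real libraries, which additionally depends on the mapper,
annotation release and chemistry.

## Problem sizes and numerical conventions

Simulation-based checks use 2×10⁵ reads (binomial 3σ on a 94.4% class is
±0.3 percentage points, the tolerance the recovery tests assert) and the
full-scale canonical target lengths; alignment equivalence tests use
queries ≤80 nt against subjects ≤500 nt, where exhaustive DP is cheap.
Ties in the aligner prefer longer alignments, then smaller subject start,
then the plus strand. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; nothing in any random stream depends on
hashing or locale, so outputs are reproducible across platforms.

## Known limitations

* The seeded screening path can miss alignments that lack an exact shared
  11-mer; under the scoring above such alignments cannot reach 50% identity
  for probes ≥39 nt in practice, but the guarantee is empirical, not proven.
* The panel builder treats target sequences as given and never fetches or
  validates accessions; record lengths in public databases may differ from
  the canonical panel arithmetic.
* Efficiency estimation assumes depletion is an independent thinning of
  targeted fragments; saturation or probe-competition effects in the real
  chemistry are out of scope.
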