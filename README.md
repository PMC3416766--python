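# sdrna

Probe-panel design and library QC for **selective depletion of abundant
RNA** — the RNase H–based removal of ribosomal and mitochondrial rRNA from
RNA-seq libraries, including libraries made from highly fragmented archival
FFPE tissue RNA.

rRNA can make up the bulk of a total-RNA library, and the fragmented RNA in
formalin-fixed, paraffin-embedded specimens rules out polyA+ selection. The
depletion strategy this package supports instead tiles short antisense DNA
oligos end-to-end across each abundant target, digests the resulting
RNA:DNA hybrids with RNase H, and removes the probes with DNase I. The
package covers everything computational around that protocol:

* **`sdrna.probe_design`** — tile non-overlapping antisense probes
  (39–80 nt) across target RNAs and assemble versioned pools. The built-in
  conventions reproduce the canonical two-version design: SDRNA1 = 88
  probes against 18S+28S rRNA at 0.5 µM each (44 µM pool); SDRNA2 = those
  plus 5.8S and mitochondrial 12S/16S probes at 0.05 µM each (122 probes).
* **`sdrna.offtarget`** — exact affine-gap Smith–Waterman screening of
  probes against a transcriptome under low-stringency blastn scoring
  (+2/−3, gap `5 + 2k`, word size 11), flagging genes with ≥50% nucleotide
  identity to a probe.
* **`sdrna.read_prep`** — 3' adapter trimming (adapter shortened one base
  at a time, matched against the read end with a length-dependent mismatch
  allowance) plus fixed end trimming.
* **`sdrna.qc`** — classification of uniquely mapped reads into
  rRNA / mito / exon / intron / intergenic classes, two-way rRNA rollups,
  depletion efficiency from before/after proportions, and Pearson R of
  log10 transcript counts between libraries with biotype/homolog strata.
* **`sdrna.simulate`** — a deterministic synthetic genome (rRNA repeating
  unit, mitochondrial contig, intron-containing genes) and FFPE-like read
  sets with truth labels, so the full pipeline runs hermetically.

The depletion-efficiency statistic uses odds-ratio normalization, which is
exact for independent thinning of targeted fragments:

E = 1 − [f_d/(1−f_d)] / [f_u/(1−f_u)]

where f_u and f_d are the targeted-RNA read fractions in the untreated and
depleted libraries. See `docs/methods.md` for the model, conventions and
limitations.

## Worked example

Design the full five-target panel from a targets FASTA, simulate an
untreated FFPE-like library, and QC it:

```sh
$ sdrna design --targets targets.fa --panel SDRNA2 \
      --out-fasta probes.fa --out-recipe recipe.tsv
122 probes, pool total 45.7 uM

$ sdrna simulate --seed 7 --out-dir sim --n-reads 200000
emitted 200000 reads into sim

$ sdrna qc --alignments sim/alignments.tsv --dialect tsv --bed sim/annotation.bed
unique reads: 200000
rRNA: 60.4%  non-rRNA: 39.6%

$ sdrna qc --untreated-rrna 0.605 --depleted-rrna 0.019
depletion efficiency (odds): 98.7%
```

The 122 probes are the 88 SDRNA1 probes (25 against 18S, 63 against 28S,
0.5 µM each) plus 2 + 12 + 20 probes against 5.8S/12S/16S at 0.05 µM,
giving the 45.7 µM pool total. The simulated library was configured with an
untreated-FFPE composition (combined rRNA 60.5%), and the classifier
reports 60.4% — within binomial noise at 2×10⁵ reads. Feeding the
untreated (60.5%) and depleted (1.9%) rRNA proportions to the efficiency
estimator shows that depletion removed 98.7% of the targeted RNA.

The recipe TSV is the pool sheet (probe id, target window, length, GC%,
µM, antisense sequence):

```text
probe_id  target  start  end  length  gc_percent  conc_uM  sequence
18S_1     18S     0      80   80      55.0        0.5      GCATACGGG...
18S_2     18S     80     160  80      50.0        0.5      GTACAGCAG...
```

The same operations are importable: `probe_design.build_panel`,
`offtarget.screen_panel`, `qc.class_table`, `qc.depletion_efficiency`,
`simulate.simulate_library`, etc.

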