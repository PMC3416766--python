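import math

import numpy as np
import pandas as pd
import pytest

from sdrna.formats import AlignedRead, Region, RegionLabel
from sdrna.qc import (
    QCError,
    RegionAnnotation,
    class_table,
    classify_read,
    depletion_efficiency,
    exon_intron_intergenic_profile,
    percent,
    transcript_correlation,
)


@pytest.fixture
def annotation():
    return RegionAnnotation(
        [
            Region("chrR", 0, 1000, RegionLabel.rRNA_18S),
            Region("chrR", 1000, 2000, RegionLabel.rRNA_nontargeted),
            Region("chrM", 0, 500, RegionLabel.mt_12S),
            Region("chrM", 500, 900, RegionLabel.mt_other),
            Region("chrG", 0, 200, RegionLabel.exon, "g1"),
            Region("chrG", 200, 700, RegionLabel.intron, "g1"),
            Region("chrG", 700, 900, RegionLabel.exon, "g1"),
        ]
    )


def _read(contig, pos, length=50, read_id="r", unique=True):
    return AlignedRead(read_id, contig, pos, length, unique)


class TestClassifyRead:
    def test_read_inside_18s(self, annotation):
        assert classify_read(_read("chrR", 100), annotation) == RegionLabel.rRNA_18S

    def test_read_inside_intron(self, annotation):
        assert classify_read(_read("chrG", 300), annotation) == RegionLabel.intron

    def test_boundary_straddler_takes_higher_priority_class(self, annotation):
        # spans the 18S / non-targeted boundary at 1000
        assert classify_read(_read("chrR", 990), annotation) == RegionLabel.rRNA_18S
        # spans mt rRNA / mt_other: mt rRNA wins
        assert classify_read(_read("chrM", 480), annotation) == RegionLabel.mt_12S
        # spans exon / intron: exon wins
        assert classify_read(_read("chrG", 180), annotation) == RegionLabel.exon

    def test_unannotated_position_is_intergenic(self, annotation):
        assert classify_read(_read("chrG", 2000), annotation) == RegionLabel.intergenic

    def test_unknown_contig_is_intergenic_and_counted(self, annotation):
        before = annotation.unknown_contig_reads
        assert classify_read(_read("chrX", 0), annotation) == RegionLabel.intergenic
        assert annotation.unknown_contig_reads == before + 1


class TestClassTable:
    def test_constructed_rollup_percentages(self, annotation):
        """944 rRNA-class + 56 other unique reads give 94.4% / 5.6%."""
        reads = [_read("chrR", 10, read_id=f"a{i}") for i in range(900)]
        reads += [_read("chrM", 10, read_id=f"b{i}") for i in range(44)]  # mt rRNA counts
        reads += [_read("chrG", 10, read_id=f"c{i}") for i in range(56)]
        table = class_table(reads, annotation)
        f_rrna, f_other = table.rollup_rrna()
        assert percent(f_rrna) == 94.4 and percent(f_other) == 5.6
        assert table.total_unique == 1000

    def test_single_class_is_100_percent(self, annotation):
        table = class_table([_read("chrG", 10, read_id=str(i)) for i in range(5)], annotation)
        assert table.proportions[RegionLabel.exon] == 1.0

    def test_order_invariance(self, annotation, rng):
        reads = [_read("chrR", 10, read_id=f"a{i}") for i in range(20)]
        reads += [_read("chrG", 300, read_id=f"b{i}") for i in range(30)]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert class_table(reads, annotation).counts == class_table(shuffled, annotation).counts

    def test_nonunique_reads_excluded_and_zero_unique_fails(self, annotation):
        reads = [_read("chrR", 1, unique=False, read_id=str(i)) for i in range(3)]
        with pytest.raises(QCError, match="zero unique"):
            class_table(reads, annotation)

    def test_counts_partition_unique_reads(self, annotation, rng):
        reads = [
            _read(
                rng.choice(["chrR", "chrM", "chrG"]),
                int(rng.integers(0, 1500)),
                read_id=str(i),
            )
            for i in range(200)
        ]
        table = class_table(reads, annotation)
        assert sum(table.counts.values()) == table.total_unique == 200
        assert math.isclose(sum(table.proportions.values()), 1.0, abs_tol=1e-9)


class TestDepletionEfficiency:
    def test_odds_ratio_on_archival_library_pair(self):
        # untreated 60.5% rRNA vs depleted 1.9%
        res = depletion_efficiency(0.605, 0.019)
        assert res.efficiency == pytest.approx(0.9874, abs=5e-4)
        assert res.efficiency >= 0.98

    def test_odds_ratio_on_intact_library_pair(self):
        res = depletion_efficiency(0.944, 0.062)
        assert res.efficiency == pytest.approx(0.9961, abs=5e-4)

    def test_no_change_means_zero_efficiency(self):
        assert depletion_efficiency(0.3, 0.3).efficiency == pytest.approx(0.0)

    def test_naive_variant(self):
        assert depletion_efficiency(0.6, 0.06, method="naive").efficiency == pytest.approx(0.9)

    @pytest.mark.parametrize("f_u, f_d", [(0.0, 0.1), (1.0, 0.1), (0.5, 1.0), (0.5, -0.1)])
    def test_degenerate_fractions_rejected(self, f_u, f_d):
        with pytest.raises(QCError):
            depletion_efficiency(f_u, f_d)


def _counts(values, biotype=None, homolog=None):
    n = len(values)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "count": values,
            "biotype": biotype or ["other"] * n,
            "homolog_flag": homolog or ["none"] * n,
        }
    )


class TestTranscriptCorrelation:
    def test_identical_libraries_give_r_one(self):
        lib = _counts([10, 100, 1000, 55, 7])
        assert transcript_correlation(lib, lib).r == pytest.approx(1.0)

    def test_scaling_is_a_log_shift(self):
        a = _counts([10, 100, 1000, 55, 7])
        b = a.copy()
        b["count"] = 10 * b["count"]
        assert transcript_correlation(a, b).r == pytest.approx(1.0)

    def test_five_gene_worked_example_matches_hand_pearson(self):
        xs = [12, 340, 56, 7800, 91]
        ys = [15, 290, 70, 8100, 60]
        a, b = _counts(xs), _counts(ys)
        # closed-form Pearson on the log10 values, computed independently
        lx = [math.log10(v) for v in xs]
        ly = [math.log10(v) for v in ys]
        n = len(lx)
        mx, my = sum(lx) / n, sum(ly) / n
        cov = sum((x - mx) * (y - my) for x, y in zip(lx, ly))
        vx = sum((x - mx) ** 2 for x in lx)
        vy = sum((y - my) ** 2 for y in ly)
        expected = cov / math.sqrt(vx * vy)
        assert transcript_correlation(a, b).r == pytest.approx(expected, abs=1e-12)

    def test_zero_count_genes_dropped_pairwise(self):
        a = _counts([10, 0, 30, 40, 50])
        b = _counts([10, 20, 0, 40, 50])
        result = transcript_correlation(a, b)
        assert result.n_genes == 3  # g0, g3, g4

    def test_strata_and_outliers(self):
        a = _counts(
            [10, 100, 1000, 50, 60, 70],
            biotype=["snoRNA", "miRNA", "other", "other", "other", "other"],
            homolog=["none", "none", "SDRNA", "none", "none", "none"],
        )
        b = a.copy()
        b.loc[2, "count"] = 10_000  # push one gene off the identity line
        result = transcript_correlation(a, b)
        assert set(result.strata) <= {"small_RNA", "homolog_SDRNA", "other"}
        assert result.outliers(1)["gene_id"].iloc[0] == "g2"
        assert -1.0 <= result.r <= 1.0

    def test_fewer_than_three_shared_genes_fails(self):
        a = _counts([5, 0, 0])
        b = _counts([5, 1, 1])
        with pytest.raises(QCError, match="nonzero"):
            transcript_correlation(a, b)


class TestProfile:
    def test_all_exonic_reads(self, annotation):
        reads = [_read("chrG", 10, read_id=str(i)) for i in range(10)]
        profile = exon_intron_intergenic_profile(reads, annotation)
        assert profile["exon"] == 1.0

    def test_constructed_mixture_recovered(self, annotation):
        reads = [_read("chrG", 10, read_id=f"e{i}") for i in range(48)]
        reads += [_read("chrG", 300, read_id=f"i{i}") for i in range(36)]
        reads += [_read("chrG", 2000, read_id=f"x{i}") for i in range(16)]
        profile = exon_intron_intergenic_profile(reads, annotation)
        assert profile["exon"] == pytest.approx(0.48)
        assert profile["intron"] == pytest.approx(0.36)
        assert profile["intergenic"] == pytest.approx(0.16)

    def test_proportions_sum_to_one(self, annotation, rng):
        reads = [
            _read(rng.choice(["chrR", "chrM", "chrG"]), int(rng.integers(0, 1500)), read_id=str(i))
            for i in range(100)
        ]
        profile = exon_intron_intergenic_profile(reads, annotation)
        assert sum(profile.values()) == pytest.approx(1.0)


class TestPercent:
    def test_half_up_rounding(self):
        assert percent(0.0565) == 5.7  # 5.65 rounds half-up, not to even
        assert percent(0.944) == 94.4
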