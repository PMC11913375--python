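"""Intron extraction and junction counting."""

import random

import pandas as pd
import pysam
import pytest

from intronret.annotation import (
    AnnotationError,
    count_junctions,
    count_junctions_in_file,
    extract_introns,
    filter_low_coverage,
)

from conftest import counts_row, make_intron, write_sam
from oracles import brute_force_counts


class TestExtractIntrons:
    def test_plus_strand_gap_coordinates(self, toy_gtf):
        introns = {i.intron_id: i for i in extract_introns(toy_gtf)}
        ia = introns["gA.i1"]
        assert (ia.start, ia.end, ia.length, ia.strand) == (100, 150, 50, "+")

    def test_minus_strand_index_runs_from_transcript_five_prime(self, toy_gtf):
        introns = {i.intron_id: i for i in extract_introns(toy_gtf)}
        # highest-coordinate gap (GTF 251..300) is the 5'-most intron on '-'
        assert (introns["gB.i1"].start, introns["gB.i1"].end) == (250, 300)
        assert (introns["gB.i2"].start, introns["gB.i2"].end) == (100, 150)

    def test_single_exon_transcript_yields_no_introns(self, tmp_path):
        p = tmp_path / "single.gtf"
        p.write_text('chr1\tt\texon\t1\t500\t.\t+\t.\tgene_id "g"; transcript_id "g.t1";\n')
        assert extract_introns(p) == []

    def test_duplicate_intron_across_transcripts_deduplicated(self, tmp_path):
        lines = []
        for tx in ("t1", "t2"):
            for s, e in ((1, 100), (151, 250)):
                lines.append(
                    f'chr1\tt\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g"; transcript_id "g.{tx}";'
                )
        p = tmp_path / "dup.gtf"
        p.write_text("\n".join(lines) + "\n")
        assert len(extract_introns(p)) == 1

    def test_malformed_gtf_raises(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tonly\tthree\n")
        with pytest.raises(AnnotationError):
            extract_introns(p)


class TestCountJunctions:
    CHROMS = {"chr1": 10_000}
    INTRON = [make_intron("gA.i1", "chr1", 100, 150)]

    def count_one(self, tmp_path, reads, introns=None, min_anchor=5):
        sam = write_sam(tmp_path / "t.sam", self.CHROMS, reads)
        counts, _ = count_junctions_in_file(sam, introns or self.INTRON, min_anchor)
        return counts

    def test_exact_gap_scores_eejr(self, tmp_path):
        counts = self.count_one(tmp_path, [("r1", "chr1", 50, "50M50N50M")])
        assert counts[0] == [1, 0, 0]

    def test_contiguous_read_over_donor_scores_eijr(self, tmp_path):
        # 40 nt exonic + 60 nt intronic across the donor at 100
        counts = self.count_one(tmp_path, [("r1", "chr1", 60, "100M")])
        assert counts[0] == [0, 1, 0]

    def test_contiguous_read_over_acceptor_scores_iejr(self, tmp_path):
        counts = self.count_one(tmp_path, [("r1", "chr1", 130, "100M")])
        assert counts[0] == [0, 0, 1]

    def test_short_anchor_scores_nothing(self, tmp_path):
        reads = [
            ("gap_short_flank", "chr1", 96, "4M50N50M"),  # left anchor 4 < 5
            ("window_partial", "chr1", 97, "6M"),  # does not reach 100+5
        ]
        counts = self.count_one(tmp_path, reads)
        assert counts[0] == [0, 0, 0]

    def test_gap_match_excludes_boundary_counts_for_same_intron(self, tmp_path):
        # gap matches the intron; its blocks also touch the windows of no
        # other junction type for this intron
        counts = self.count_one(tmp_path, [("r1", "chr1", 50, "50M50N50M")])
        assert counts[0][1] == 0 and counts[0][2] == 0

    def test_secondary_and_unmapped_ignored(self, tmp_path):
        reads = [
            ("sec", "chr1", 50, "50M50N50M", 256),
            ("sup", "chr1", 50, "50M50N50M", 2048),
            ("unmapped", "chr1", 50, "50M50N50M", 4),
        ]
        counts = self.count_one(tmp_path, reads)
        assert counts[0] == [0, 0, 0]

    def test_unsupported_cigar_skipped_and_tallied(self, tmp_path):
        sam = write_sam(tmp_path / "t.sam", self.CHROMS, [("r1", "chr1", 50, "50M2P48M")])
        counts, skipped = count_junctions_in_file(sam, self.INTRON, 5)
        assert counts[0] == [0, 0, 0]
        assert skipped["unsupported_cigar"] == 1

    @staticmethod
    def _random_instance(tmp_path, seed, n_reads=200):
        rng = random.Random(seed)
        introns = [
            make_intron(f"g{k}.i1", "chr1", s, s + rng.randint(20, 120))
            for k, s in enumerate(sorted(rng.sample(range(200, 4000, 40), 5)))
        ]
        reads = []
        for r in range(n_reads):
            pos = rng.randint(0, 4500)
            if rng.random() < 0.5:
                intr = rng.choice(introns)
                a = rng.randint(1, 99)
                reads.append((f"r{r}", "chr1", intr.start - a, f"{a}M{intr.length}N{100 - a}M"))
            else:
                reads.append((f"r{r}", "chr1", pos, "100M"))
        return write_sam(tmp_path / f"rand{seed}.sam", {"chr1": 10_000}, reads), introns

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, tmp_path, seed):
        sam, introns = self._random_instance(tmp_path, seed)
        counts, _ = count_junctions_in_file(sam, introns, 5)
        oracle = brute_force_counts(sam, introns, 5)
        assert {i.intron_id: c for i, c in zip(introns, counts)} == oracle

    def test_invariant_under_read_order_and_bam_encoding(self, tmp_path):
        sam, introns = self._random_instance(tmp_path, 99)
        counts, _ = count_junctions_in_file(sam, introns, 5)
        # shuffled copy
        with pysam.AlignmentFile(str(sam)) as af:
            header = af.header.to_dict()
            records = list(af.fetch(until_eof=True))
        random.Random(1).shuffle(records)
        shuffled = tmp_path / "shuffled.sam"
        with pysam.AlignmentFile(str(shuffled), "w", header=header) as out:
            for r in records:
                out.write(r)
        counts2, _ = count_junctions_in_file(shuffled, introns, 5)
        assert counts == counts2
        # BAM encoding of the same records
        bam = tmp_path / "same.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
            for r in records:
                out.write(r)
        counts3, _ = count_junctions_in_file(bam, introns, 5)
        assert counts == counts3


class TestFilterLowCoverage:
    @staticmethod
    def _frame(wt_total, kd_total):
        rows = [
            counts_row("i1", "WT_1", "WT", 1, wt_total, 0, 0),
            counts_row("i1", "KD_1", "KD", 1, kd_total, 0, 0),
        ]
        return pd.DataFrame(rows)

    def test_one_condition_below_threshold_drops(self):
        kept, dropped = filter_low_coverage(self._frame(9, 50), 10)
        assert kept == set() and dropped == {"i1"}

    def test_boundary_total_is_kept(self):
        kept, dropped = filter_low_coverage(self._frame(10, 10), 10)
        assert kept == {"i1"} and dropped == set()

    def test_absent_intron_reported_dropped(self):
        kept, dropped = filter_low_coverage(self._frame(50, 50), 10, all_introns=["i1", "i2"])
        assert kept == {"i1"} and dropped == {"i2"}


def test_count_junctions_sample_table(tmp_path):
    introns = [make_intron("gA.i1", "chr1", 100, 150)]
    p1 = write_sam(tmp_path / "s1.sam", {"chr1": 10_000}, [("r", "chr1", 50, "50M50N50M")])
    p2 = write_sam(tmp_path / "s2.sam", {"chr1": 10_000}, [("r", "chr1", 60, "100M")])
    sheet = pd.DataFrame(
        {
            "sample_id": ["WT_1", "KD_1"],
            "condition": ["WT", "KD"],
            "replicate": [1, 1],
            "path": [str(p1), str(p2)],
        }
    )
    counts = count_junctions(sheet, introns)
    by = counts.set_index("sample_id")
    assert by.loc["WT_1", ["eejr", "eijr", "iejr"]].tolist() == [1, 0, 0]
    assert by.loc["KD_1", ["eejr", "eijr", "iejr"]].tolist() == [0, 1, 0]
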