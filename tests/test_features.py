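"""Splice-site windows, logo matrices, Fisher tests, signatures, U5 pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronret._util import revcomp
from intronret.features import (
    SignatureGroup,
    assign_signature_group,
    build_matrix,
    diff_matrix,
    extract_site_windows,
    group_irs_curves,
    position_fisher,
    u5_pairing_score,
)

from conftest import make_intron
from oracles import fisher_two_sided

BASES = "ACGT"


@pytest.fixture(scope="module")
def toy_seq():
    rng = np.random.default_rng(42)
    return {"chrT": "".join(rng.choice(list(BASES), size=400))}


class TestExtractSiteWindows:
    def test_plus_strand_windows_are_direct_slices(self, toy_seq):
        intron = make_intron("g.i1", "chrT", 100, 150, "+")
        w = extract_site_windows(toy_seq, [intron]).iloc[0]
        seq = toy_seq["chrT"]
        assert w["five_prime_window"] == seq[97:106]
        assert w["three_prime_window"] == seq[144:151]
        assert w["last3_exon"] == seq[97:100]
        assert w["first1_exon3"] == seq[150]

    def test_minus_strand_windows_are_reverse_complements(self, toy_seq):
        intron = make_intron("g.i1", "chrT", 100, 150, "-")
        w = extract_site_windows(toy_seq, [intron]).iloc[0]
        seq = toy_seq["chrT"]
        # donor is at the genomic end on '-': 3 exonic nt right of 150,
        # 6 intronic nt left of it, read back on the minus strand
        assert w["five_prime_window"] == revcomp(seq[144:153])
        assert w["three_prime_window"] == revcomp(seq[99:106])
        assert w["last3_exon"] == revcomp(seq[150:153])
        assert w["first1_exon3"] == revcomp(seq[99])

    def test_short_intron_sets_overlap_flag(self, toy_seq):
        intron = make_intron("g.i1", "chrT", 100, 108, "+")  # 8 nt < 6 + 6
        w = extract_site_windows(toy_seq, [intron]).iloc[0]
        assert bool(w["intronic_overlap"])

    def test_contig_edge_intron_dropped(self, toy_seq):
        intron = make_intron("g.i1", "chrT", 1, 60, "+")  # 3 exonic nt missing
        assert extract_site_windows(toy_seq, [intron]).empty

    def test_missing_chromosome_named(self, toy_seq):
        intron = make_intron("g.i1", "chrMISSING", 100, 150, "+")
        with pytest.raises(KeyError, match="chrMISSING"):
            extract_site_windows(toy_seq, [intron])


class TestBuildMatrix:
    def test_pure_column_has_two_bits(self):
        pm = build_matrix(["A", "A", "A", "A"])
        assert pm.information[0] == pytest.approx(2.0)
        assert pm.probabilities[0].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_uniform_column_has_zero_bits(self):
        pm = build_matrix(["A", "C", "G", "T"])
        assert pm.information[0] == pytest.approx(0.0)

    def test_mixed_column_closed_form(self):
        pm = build_matrix(["A", "A", "A", "C"])
        expected = 2 + 0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)
        assert pm.information[0] == pytest.approx(expected)

    def test_ambiguous_bases_excluded_from_column(self):
        pm = build_matrix(["AN", "AA", "AA", "AA"])
        assert pm.n_ambiguous == 1
        assert pm.counts[1].sum() == 3
        assert pm.probabilities[1, 0] == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_matrix(["AA", "A"])


class TestDiffMatrix:
    def test_identical_matrices_have_zero_divergence(self):
        p = build_matrix(["ACGT", "ACGT"])
        assert diff_matrix(p, p)["jsd_bits"].abs().max() == pytest.approx(0.0)

    def test_disjoint_columns_reach_one_bit(self):
        d = diff_matrix(build_matrix(["A"] * 6), build_matrix(["C"] * 6))
        assert d["jsd_bits"].iloc[0] == pytest.approx(1.0)

    def test_half_split_against_pure_closed_form(self):
        d = diff_matrix(build_matrix(["A", "C"]), build_matrix(["A", "A"]))
        assert d["jsd_bits"].iloc[0] == pytest.approx(0.311278, abs=1e-5)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            diff_matrix(build_matrix(["AA"]), build_matrix(["A"]))


class TestPositionFisher:
    def test_small_table_two_sided_p(self):
        a = ["A"] * 3 + ["C"]
        b = ["A"] + ["C"] * 3
        odds, p, table = position_fisher(a, b, 0, "A")
        assert table == ((3, 1), (1, 3))
        assert p == pytest.approx(0.485714, abs=1e-5)

    def test_identical_composition_is_null(self):
        odds, p, _ = position_fisher(["A", "C"], ["A", "C"], 0, "A")
        assert p == pytest.approx(1.0) and odds == pytest.approx(1.0)

    def test_fully_separated_table(self):
        _, p, _ = position_fisher(["A"] * 5, ["C"] * 5, 0, "A")
        assert p == pytest.approx(2 / 252, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = ["A" if x else "C" for x in rng.random(12) < 0.7]
        b = ["A" if x else "C" for x in rng.random(9) < 0.3]
        _, p, table = position_fisher(a, b, 0, "A")
        assert p == pytest.approx(fisher_two_sided(table), rel=1e-9)


class TestSignatureGroups:
    @pytest.mark.parametrize(
        "last3,first1,expected",
        [
            ("AAG", "G", SignatureGroup.AAG_G),
            ("AAG", "A", SignatureGroup.AAG_H),
            ("TTC", "A", SignatureGroup.BBH_H),  # U5-weak exonic context
            ("AAA", "G", SignatureGroup.NNN_N),
            ("AAG", "N", SignatureGroup.NNN_N),  # ambiguous base
            ("UUC", "A", SignatureGroup.BBH_H),  # RNA alphabet accepted
        ],
    )
    def test_examples(self, last3, first1, expected):
        assert assign_signature_group(last3, first1) is expected

    def test_groups_partition_all_contexts(self):
        counts = {g: 0 for g in SignatureGroup}
        for last3 in itertools.product(BASES, repeat=3):
            for first1 in BASES:
                counts[assign_signature_group("".join(last3), first1)] += 1
        assert sum(counts.values()) == 256
        # AAG-G: 1 context; AAG-H: 3; BBH-H: 3*3*3*3 = 81 minus none (AAG not in BBH)
        assert counts[SignatureGroup.AAG_G] == 1
        assert counts[SignatureGroup.AAG_H] == 3
        assert counts[SignatureGroup.BBH_H] == 81


class TestU5Pairing:
    @pytest.mark.parametrize(
        "exon,register,expected",
        [
            ("AAG", "CUU", 3),  # the strongly recognised wild-type register
            ("UUC", "CUU", 0),  # weak context against wild-type loop1
            ("UUC", "GAA", 3),  # rescued by the mutant GAA register
            ("AAG", "GAA", 0),
            ("TTC", "GAA", 3),  # DNA alphabet equivalent
        ],
    )
    def test_register_scores(self, exon, register, expected):
        assert u5_pairing_score(exon, register) == expected

    def test_wobble_only_counts_when_enabled(self):
        # G against U (antiparallel register position) pairs only as wobble
        assert u5_pairing_score("GAG", "CUU") == 2
        assert u5_pairing_score("GAG", "CUU", allow_wobble=True) == 3

    @given(st.text(alphabet="ACGU", min_size=3, max_size=3))
    @settings(max_examples=64, deadline=None)
    def test_reverse_complement_register_always_pairs_fully(self, exon):
        rc = revcomp(exon.replace("U", "T"))
        assert u5_pairing_score(exon, rc) == 3

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            u5_pairing_score("AAGG", "CUU")


class TestGroupIrsCurves:
    def test_ecdf_points(self):
        ecdf = group_irs_curves({"g": [1, 2, 2, 3]})
        assert ecdf["value"].tolist() == [1, 2, 3]
        assert ecdf["cum_frac"].tolist() == pytest.approx([0.25, 0.75, 1.0])

    def test_single_value_single_step(self):
        ecdf = group_irs_curves({"g": [5.0]})
        assert ecdf["cum_frac"].tolist() == [1.0]

    def test_stochastic_dominance_orders_curves(self):
        ecdf = group_irs_curves({"low": [1, 2, 3], "high": [4, 5, 6]})
        grid = np.linspace(0, 7, 50)

        def at(group, x):
            sub = ecdf[ecdf["group"] == group]
            below = sub[sub["value"] <= x]
            return 0.0 if below.empty else below["cum_frac"].iloc[-1]

        assert all(at("low", x) >= at("high", x) for x in grid)

    def test_empty_group_omitted(self):
        ecdf = group_irs_curves({"a": [1.0], "b": []})
        assert set(ecdf["group"]) == {"a"}
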