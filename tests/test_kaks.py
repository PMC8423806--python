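import itertools
import math

import numpy as np
import pytest

from hsp70evo.kaks import (CodonAlignment, backtranslate, clade_pool,
                           filter_saturated, jukes_cantor, ng86_pairwise,
                           ng86_site_counts, pairwise_kaks_matrix,
                           strip_terminal_stop, validate_cds)
from hsp70evo.seqio import CodingRecord, MultipleAlignment, ProteinRecord

from oracles import SENSE, oracle_ng86, oracle_site_counts


def codon_aln(rows: dict[str, list[str]]) -> CodonAlignment:
    return CodonAlignment(list(rows), list(rows.values()))


class TestValidateCds:
    def test_matching_pair_with_terminal_stop_ok(self):
        rep = validate_cds(ProteinRecord(id="x", sequence="MK"),
                           CodingRecord(id="x", cds="ATGAAATAA"))
        assert rep.ok

    def test_single_extra_nucleotide_is_a_frame_shift(self):
        rep = validate_cds(ProteinRecord(id="x", sequence="MK"),
                           CodingRecord(id="x", cds="ATGAAAATAA"))
        assert not rep.ok and rep.reason == "frame_shift"

    def test_translation_mismatch_names_first_codon(self):
        protein = "MKTVLAH"
        cds = "ATGAAAACAGTTCTTGCTGGG"  # codon 7 GGG -> G, protein says H
        rep = validate_cds(ProteinRecord(id="x", sequence=protein),
                           CodingRecord(id="x", cds=cds))
        assert not rep.ok
        assert rep.reason == "translation_mismatch" and rep.codon_index == 7

    def test_x_wildcards_match_anything(self):
        rep = validate_cds(ProteinRecord(id="x", sequence="MX"),
                           CodingRecord(id="x", cds="ATGANA"))
        assert rep.ok


class TestBacktranslate:
    def test_gaps_become_gap_codons(self):
        aln = MultipleAlignment(["x"], ["M-K"])
        out = backtranslate(aln, {"x": CodingRecord(id="x", cds="ATGAAA")})
        assert out.rows[0] == ["ATG", "---", "AAA"]

    def test_translation_round_trip(self, family):
        coding = {c.id: c for c in family.codings}
        out = backtranslate(family.alignment, coding)
        back = out.to_protein_alignment()
        assert back.rows == family.alignment.rows

    def test_frame_shifted_record_rejected_with_id(self):
        aln = MultipleAlignment(["x"], ["MK"])
        with pytest.raises(ValueError, match="x"):
            backtranslate(aln, {"x": CodingRecord(id="x", cds="ATGAAAA")})


class TestSiteCounts:
    def test_phenylalanine_codon_enumeration(self):
        # TTT: only the third-position T->C change is synonymous
        s, n = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_methionine_has_no_synonymous_sites(self):
        assert ng86_site_counts("ATG") == (0.0, 3.0)

    def test_conservation_all_sense_codons(self):
        for codon in SENSE:
            s, n = ng86_site_counts(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_matches_oracle_for_every_sense_codon(self):
        for codon in SENSE:
            assert ng86_site_counts(codon) == pytest.approx(oracle_site_counts(codon))

    def test_stop_and_ambiguous_codons_excluded(self):
        assert ng86_site_counts("TAA") == (0.0, 0.0)
        assert ng86_site_counts("ANA") == (0.0, 0.0)


class TestPairwise:
    def test_identical_rows_have_zero_rates_and_no_ratio(self):
        rows = {"a": ["ATG"] * 12, "b": ["ATG"] * 12}
        pair = ng86_pairwise(codon_aln(rows), "a", "b")
        assert pair.valid and pair.ka == 0.0 and pair.ks == 0.0
        assert pair.ratio is None

    def test_single_synonymous_change_matches_closed_form(self):
        row_a = ["GGA"] * 50
        row_b = ["GGA"] * 49 + ["GGC"]
        pair = ng86_pairwise(codon_aln({"a": row_a, "b": row_b}), "a", "b")
        # GGA/GGC are both glycine: one synonymous difference, S=1 per codon
        s_bar = 50 * 1.0
        assert pair.ka == 0.0
        assert pair.ks == pytest.approx(jukes_cantor(1 / s_bar))

    def test_correction_domain_violation_invalidates(self):
        rows = {"a": ["TTT"] * 12, "b": ["TTC"] * 12}
        pair = ng86_pairwise(codon_aln(rows), "a", "b")
        assert not pair.valid and pair.reason == "undefined_correction"

    def test_too_few_comparable_codons(self):
        rows = {"a": ["ATG"] * 5, "b": ["ATG"] * 5}
        pair = ng86_pairwise(codon_aln(rows), "a", "b")
        assert not pair.valid and pair.reason == "too_few_sites"

    def test_symmetry_under_id_swap(self):
        rng = np.random.default_rng(5)
        row_a = [SENSE[i] for i in rng.integers(len(SENSE), size=30)]
        row_b = [SENSE[i] for i in rng.integers(len(SENSE), size=30)]
        aln = codon_aln({"a": row_a, "b": row_b})
        pij = ng86_pairwise(aln, "a", "b", min_codons=1)
        pji = ng86_pairwise(aln, "b", "a", min_codons=1)
        assert (pij.ka, pij.ks, pij.valid) == (pji.ka, pji.ks, pji.valid)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_pairs_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            length = int(rng.integers(1, 6))
            def draw():
                cells = []
                for _ in range(length):
                    u = rng.random()
                    if u < 0.1:
                        cells.append("---")
                    elif u < 0.15:
                        cells.append("ANT")
                    else:
                        cells.append(SENSE[int(rng.integers(len(SENSE)))])
                return cells
            rows = {"a": draw(), "b": draw()}
            pair = ng86_pairwise(codon_aln(rows), "a", "b", min_codons=1)
            ref = oracle_ng86(rows["a"], rows["b"], min_codons=1)
            assert pair.valid == ref["valid"]
            assert pair.reason == ref["reason"]
            if pair.valid:
                assert pair.ka == pytest.approx(ref["ka"], abs=1e-12)
                assert pair.ks == pytest.approx(ref["ks"], abs=1e-12)


class TestMatrixAndFiltering:
    @pytest.mark.parametrize("n,expected", [(34, 561), (31, 465), (2, 1)])
    def test_pair_count_is_n_choose_2(self, n, expected):
        rows = {f"s{i:02d}": ["ATG"] * 12 for i in range(n)}
        pairs = pairwise_kaks_matrix(codon_aln(rows))
        assert len(pairs) == expected

    def test_pairs_ordered_lexicographically(self):
        rows = {"c": ["ATG"] * 12, "a": ["ATG"] * 12, "b": ["ATG"] * 12}
        pairs = pairwise_kaks_matrix(codon_aln(rows))
        assert [(p.id_i, p.id_j) for p in pairs] == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_filter_drops_invalid_saturated_and_zero_ks(self):
        from hsp70evo.kaks import KaKsPair

        pairs = [
            KaKsPair("a", "b", ka=0.1, ks=0.5, ratio=0.2, valid=True),
            KaKsPair("a", "c", ka=0.1, ks=5.0, ratio=0.02, valid=True),
            KaKsPair("a", "d", valid=False, reason="undefined_correction"),
            KaKsPair("b", "c", ka=0.1, ks=0.0, ratio=None, valid=True),
        ]
        retained, excluded = filter_saturated(pairs, ks_max=3.0)
        assert [(p.id_i, p.id_j) for p in retained] == [("a", "b")]
        reasons = {(p.id_i, p.id_j): p.reason for p in excluded}
        assert reasons[("a", "c")] == "saturated"
        assert reasons[("a", "d")] == "undefined_correction"
        assert reasons[("b", "c")] == "zero_ks"

    def test_low_divergence_family_fully_retained(self, family):
        coding = {c.id: c for c in family.codings}
        pairs = pairwise_kaks_matrix(backtranslate(family.alignment, coding))
        retained, excluded = filter_saturated(pairs)
        assert len(pairs) == 66 and not excluded


class TestCladePool:
    def test_inter_clade_pairs_contribute_to_both_pools(self):
        from hsp70evo.kaks import KaKsPair

        pairs = [
            KaKsPair("a1", "b1", ka=0.1, ks=0.5, ratio=0.2, valid=True),
            KaKsPair("a2", "b1", ka=0.2, ks=0.5, ratio=0.4, valid=True),
            KaKsPair("a1", "a2", ka=0.1, ks=0.5, ratio=0.2, valid=True),  # intra
        ]
        clades = {"a1": "A", "a2": "A", "b1": "B"}
        summaries = {s.clade: s for s in clade_pool(pairs, clades)}
        assert summaries["A"].values == [0.2, 0.4]
        assert summaries["B"].values == [0.2, 0.4]

    def test_all_intra_clade_gives_empty_pools(self):
        from hsp70evo.kaks import KaKsPair

        pairs = [KaKsPair("a1", "a2", ka=0.1, ks=0.5, ratio=0.2, valid=True)]
        assert clade_pool(pairs, {"a1": "A", "a2": "A"}) == []

    def test_unmapped_id_is_an_error(self):
        from hsp70evo.kaks import KaKsPair

        pairs = [KaKsPair("a1", "zz", ka=0.1, ks=0.5, ratio=0.2, valid=True)]
        with pytest.raises(KeyError, match="zz"):
            clade_pool(pairs, {"a1": "A"})


def test_strip_terminal_stop_only_when_in_frame():
    assert strip_terminal_stop("ATGAAATAA") == "ATGAAA"
    assert strip_terminal_stop("ATGAAATA") == "ATGAAATA"
    assert strip_terminal_stop("ATGTAAAAA") == "ATGTAAAAA"
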