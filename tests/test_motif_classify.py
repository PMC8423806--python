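import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsp70evo.motif_classify import (LOG2_20, classify_localization,
                                     column_profile, default_signatures,
                                     detect_cterm_motif, detect_lineageA_serine,
                                     discriminating_positions,
                                     locate_nterm_window, score_nterm_window)
from hsp70evo.seqio import Localization, MultipleAlignment

SIG = default_signatures()
CYT = SIG.consensus_window(Localization.CYTOSOL)
ER = SIG.consensus_window(Localization.ER)
MITO = SIG.consensus_window(Localization.MITOCHONDRIA)


class TestColumnProfile:
    def test_constant_column_has_maximal_information(self):
        prof = column_profile(["A", "A", "A"])
        assert prof.frequencies[0] == {"A": 1.0}
        assert prof.information[0] == pytest.approx(LOG2_20)

    def test_uniform_column_has_zero_information(self):
        rows = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"]
        prof = column_profile(rows)
        assert prof.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_one_split_matches_closed_form_entropy(self):
        prof = column_profile(["A", "A", "A", "V"])
        h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert prof.information[0] == pytest.approx(LOG2_20 - h)

    def test_all_gap_column_reported_missing(self):
        prof = column_profile(["-A", "-A"])
        assert math.isnan(prof.information[0])
        assert prof.frequencies[0] == {}

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY-", min_size=6, max_size=6),
                    min_size=2, max_size=12))
    def test_frequencies_normalized_and_information_bounded(self, rows):
        prof = column_profile(rows)
        for freqs, ic in zip(prof.frequencies, prof.information):
            if not freqs:
                assert math.isnan(ic)
                continue
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
            assert -1e-9 <= ic <= LOG2_20 + 1e-9


class TestDiscriminatingPositions:
    def test_cytosol_vs_er_consensus_recovers_known_sites(self):
        # the ER-diagnostic substitutions relative to the cytosolic form
        prof_c = column_profile([CYT] * 10)
        prof_e = column_profile([ER] * 10)
        assert discriminating_positions(prof_c, prof_e) == {8, 9, 11, 23}

    def test_identical_profiles_give_empty_set(self):
        prof = column_profile([CYT] * 5)
        assert discriminating_positions(prof, prof) == set()

    def test_low_majority_column_is_ignored(self):
        # 3/5 majority (0.6) is below the 0.7 default threshold
        rows_a = ["A", "A", "A", "V", "W"]
        rows_b = ["V", "V", "V", "A", "W"]
        assert discriminating_positions(column_profile(rows_a),
                                        column_profile(rows_b)) == set()

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            discriminating_positions(column_profile(["AA"]), column_profile(["A"]))


class TestLocateWindow:
    def test_exact_embedded_consensus_found_at_offset(self):
        seq = "W" * 10 + CYT + "W" * 30
        assert locate_nterm_window(seq) == 10

    def test_featureless_sequence_gives_none(self):
        assert locate_nterm_window("P" * 120) is None

    def test_three_substitutions_still_located_by_scan(self):
        window = list(CYT)
        window[0], window[7], window[22] = "W", "W", "W"  # break 3 signature sites
        seq = "G" * 25 + "".join(window) + "G" * 40
        # brute-force oracle: best offset by direct scoring
        positions = SIG.positions
        def score(off):
            return sum(seq[off + p - 1] in SIG.union_allowed(p) for p in positions)
        best = max(range(len(seq) - 23 + 1), key=lambda o: (score(o), -o))
        assert best == 25
        assert locate_nterm_window(seq) == 25

    def test_search_restricted_to_nterminal_region(self):
        seq = "P" * 200 + CYT
        assert locate_nterm_window(seq) is None


class TestScoreWindow:
    def test_cytosolic_consensus_scores_all_sixteen_votes(self):
        votes = score_nterm_window(CYT)
        assert votes[Localization.CYTOSOL] == 16

    def test_er_variants_gain_the_four_discriminating_votes(self):
        votes = score_nterm_window(ER)
        assert votes[Localization.ER] == 16
        assert votes[Localization.CYTOSOL] == 12  # shared positions only

    def test_mitochondrial_consensus_dominates(self):
        votes = score_nterm_window(MITO)
        assert votes[Localization.MITOCHONDRIA] == 15
        assert votes[Localization.CYTOSOL] <= 1

    def test_unmatchable_window_scores_zero(self):
        votes = score_nterm_window("W" * 90)
        assert all(v == 0 for v in votes.values())


class TestCtermMotif:
    @pytest.mark.parametrize("seq,motif", [
        ("MKT" * 10 + "SGPTIEEVD", "EEVD"),
        ("MKT" * 10 + "KDEL", "KDEL"),
        ("MKT" * 10 + "HDEL", "HDEL"),
        ("MKT" * 10 + "EEVDA", "none"),  # motif must be terminal
    ])
    def test_terminal_tetrapeptide(self, seq, motif):
        assert detect_cterm_motif(seq)[0] == motif

    def test_rarfeel_reported_but_er_label_wins(self):
        # RARFEEL occurs in ER-clade members, so it must not drive the label
        seq = "M" * 10 + "RARFEEL" + "K" * 50 + "KDEL"
        motif, rarfeel = detect_cterm_motif(seq)
        assert motif == "KDEL" and rarfeel is True
        call = classify_localization(seq)
        assert call.label == Localization.ER and call.rarfeel is True


class TestClassify:
    def test_mitochondrial_signature_without_motif(self):
        seq = "W" * 5 + MITO + "W" * 100
        assert classify_localization(seq).label == Localization.MITOCHONDRIA

    def test_eevd_with_uninformative_window(self):
        seq = "P" * 100 + "EEVD"
        call = classify_localization(seq)
        assert call.label == Localization.CYTOSOL

    def test_no_evidence_gives_unknown(self):
        call = classify_localization("P" * 100)
        assert call.label == Localization.UNKNOWN
        assert "no C-terminal motif" in call.note

    def test_conflict_resolved_for_motif_and_noted(self):
        seq = "W" * 5 + ER + "W" * 60 + "EEVD"
        call = classify_localization(seq)
        assert call.label == Localization.CYTOSOL
        assert "conflict" in call.note

    def test_fixture_family_fully_recovered(self, family):
        for rec in family.proteins:
            call = classify_localization(rec.sequence)
            assert call.label == family.localization[rec.id], rec.id


class TestSerineInsertion:
    def test_lineage_a_rows_flagged_serine_present(self, family):
        flags = detect_lineageA_serine(family.alignment, "sp1_cB")
        for rid, flag in flags.items():
            if rid.endswith("_cA"):
                assert flag.status == "serine_present", rid
            else:
                assert flag.status == "absent", rid

    def test_substituted_residue_is_reported(self, family):
        # emulate the alanine replacement seen in one lineage-A member
        col = detect_lineageA_serine(family.alignment, "sp1_cB")["sp1_cA"].column
        rows = list(family.alignment.rows)
        idx = family.alignment.ids.index("sp1_cA")
        rows[idx] = rows[idx][:col] + "A" + rows[idx][col + 1:]
        mutated = MultipleAlignment(list(family.alignment.ids), rows)
        flag = detect_lineageA_serine(mutated, "sp1_cB")["sp1_cA"]
        assert flag.status == "substituted" and flag.residue == "A"

    def test_reference_without_gap_gives_undetermined(self):
        aln = MultipleAlignment(["q", "ref"], ["MKTVLSAAA", "MKTVLSAAA"])
        flags = detect_lineageA_serine(aln, "ref")
        assert flags["q"].status == "undetermined"
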