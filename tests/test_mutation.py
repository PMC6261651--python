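"""Missense mutation parsing, application and impact classification."""

from collections import Counter

import pytest

from kopl.errors import MutationParseError, ReferenceMismatchError
from kopl.mutation import (
    MutationRecord,
    apply_mutation,
    classify_impacts,
    collapse_class,
    compare_proteomes,
    parse_mutation_token,
    parse_mutations,
)


class TestParsing:
    @pytest.mark.parametrize(
        "token, expected",
        [
            ("p.D353R", ("D", 353, "R")),
            ("p.K370R", ("K", 370, "R")),
            ("T356S", ("T", 356, "S")),
        ],
    )
    def test_compact_tokens(self, token, expected):
        m = parse_mutation_token("PROT", token)
        assert (m.ref_residue, m.position, m.alt_residue) == expected

    def test_identity_substitution_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            parse_mutation_token("PROT", "p.D353D")

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            parse_mutation_token("PROT", "p.B353R")

    def test_row_errors_collected_with_line_numbers(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "protein_id\tposition\tref\talt\n"
            "P1\t5\tD\tR\n"
            "P2\t0\tD\tR\n"
            "P3\t7\tD\tD\n"
        )
        with pytest.raises(MutationParseError) as exc:
            parse_mutations(str(path))
        msgs = exc.value.row_errors
        assert len(msgs) == 2
        assert msgs[0].startswith("line 3") and msgs[1].startswith("line 4")

    def test_token_list_input(self):
        records = parse_mutations([("P1", "p.D353R"), "P2:K10R"])
        assert records[0] == MutationRecord("P1", 353, "D", "R")
        assert records[1].protein_id == "P2" and records[1].position == 10


class TestApplyMutation:
    def test_substitution(self):
        assert apply_mutation("AADKA", MutationRecord("P", 3, "D", "R")) == "AARKA"

    def test_reference_mismatch(self):
        with pytest.raises(ReferenceMismatchError):
            apply_mutation("AADKA", MutationRecord("P", 3, "E", "R"))

    def test_length_preserved(self):
        seq = "MKTAYIAKQRQISFVK"
        out = apply_mutation(seq, MutationRecord("P", 8, "K", "R"))
        assert len(out) == len(seq)
        assert sum(a != b for a, b in zip(seq, out)) == 1

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            apply_mutation("AAA", MutationRecord("P", 9, "A", "R"))


class TestClassifyImpacts:
    def test_central_k_to_r_is_removed(self, design, profile_factory):
        prof = profile_factory(default=100.0)
        seq = "AAAARKLKSKRAAAA"  # central K at 8
        recs = classify_impacts(prof, seq, MutationRecord("P", 8, "K", "R"))
        target = [r for r in recs if r.k_position == 8]
        assert len(target) == 1
        assert target[0].impact_class == "removed"
        assert target[0].score_after is None

    def test_limiting_flank_substitution_strengthens(self, design, profile_factory):
        # D at -2 is limiting; D->R lifts the minimum well past the dead-band
        prof = profile_factory(raw={(-2, "D"): 10.0, (-2, "R"): 900.0},
                               default=100.0)
        seq = "AAAAADLKSAAAAA"  # K at 8, D at offset -2 of K8 (position 6)
        recs = classify_impacts(prof, seq, MutationRecord("P", 6, "D", "R"))
        target = [r for r in recs if r.k_position == 8][0]
        assert target.impact_class == "strengthened"
        assert target.score_before == 10.0 and target.score_after == 100.0

    def test_a_to_k_in_alanine_run_is_created(self, design, profile_factory):
        prof = profile_factory(default=100.0)
        recs = classify_impacts(prof, "AAAAAAAAA", MutationRecord("P", 5, "A", "K"))
        assert [r.impact_class for r in recs] == ["created"]
        assert recs[0].score_before is None and recs[0].score_after == 100.0

    def test_non_limiting_equal_signal_swap_is_unchanged(self, design,
                                                         profile_factory):
        # minimum pinned at +1; swapping -2 between equal-signal residues
        prof = profile_factory(raw={(1, "S"): 5.0, (-2, "D"): 300.0,
                                    (-2, "E"): 300.0}, default=400.0)
        seq = "AAAAADLKSAAAAA"
        recs = classify_impacts(prof, seq, MutationRecord("P", 6, "D", "E"))
        target = [r for r in recs if r.k_position == 8][0]
        # brute-force recompute of both scores
        before = min(prof.raw[(p, seq[7 + p])] for p in (-3, -2, -1, 1, 2, 3))
        after_seq = seq[:5] + "E" + seq[6:]
        after = min(prof.raw[(p, after_seq[7 + p])] for p in (-3, -2, -1, 1, 2, 3))
        assert before == after == 5.0
        assert target.impact_class == "unchanged"
        assert target.relative_change == 0.0

    def test_zero_threshold_unchanged_only_on_exact_equality(self, design,
                                                             profile_factory):
        prof = profile_factory(raw={(-2, "D"): 300.0, (-2, "E"): 300.0,
                                    (-2, "G"): 299.0, (1, "S"): 5.0},
                               default=400.0)
        seq = "AAAAADLKSAAAAA"
        equal = classify_impacts(prof, seq, MutationRecord("P", 6, "D", "E"),
                                 threshold=0.0)
        assert [r.impact_class for r in equal if r.k_position == 8] == ["unchanged"]
        prof2 = profile_factory(raw={(-2, "D"): 5.0, (-2, "G"): 4.0},
                                default=400.0)
        lower = classify_impacts(prof2, seq, MutationRecord("P", 6, "D", "G"),
                                 threshold=0.0)
        assert [r.impact_class for r in lower if r.k_position == 8] == ["weakened"]

    def test_cysteine_introduction_removes_window(self, design, profile_factory):
        prof = profile_factory(default=100.0)
        seq = "AAAARKLKSKRAAAA"
        recs = classify_impacts(prof, seq, MutationRecord("P", 6, "K", "C"))
        assert all(r.impact_class == "removed" for r in recs)

    def test_reverse_mutation_restores_scores(self, design, profile_factory):
        prof = profile_factory(raw={(-2, "D"): 10.0, (-2, "R"): 900.0},
                               default=100.0)
        seq = "AAAAADLKSAAAAA"
        fwd = MutationRecord("P", 6, "D", "R")
        mutated = apply_mutation(seq, fwd)
        rev = MutationRecord("P", 6, "R", "D")
        before = classify_impacts(prof, seq, fwd)
        back = classify_impacts(prof, mutated, rev)
        b = {r.k_position: r for r in before}
        a = {r.k_position: r for r in back}
        for k in b:
            assert a[k].score_after == b[k].score_before
            assert a[k].score_before == b[k].score_after


class TestCompareProteomes:
    def test_empty_mutation_table(self, design, profile_factory):
        table, counts, errors = compare_proteomes(
            profile_factory(), {"P": "AAAAKAAAA"}, [])
        assert len(table) == 0 and counts == Counter() and errors == []

    def test_mutation_far_from_lysine_yields_no_record(self, design,
                                                       profile_factory):
        seq = "AAAAKAAAAADAAAAA"  # K at 5, D at 11 (5 residues away)
        table, counts, _ = compare_proteomes(
            profile_factory(), {"P": seq}, [MutationRecord("P", 11, "D", "R")])
        assert len(table) == 0

    def test_missing_protein_reported_run_continues(self, design,
                                                    profile_factory):
        table, counts, errors = compare_proteomes(
            profile_factory(), {"P": "AAAARKLKSKRAAAA"},
            [MutationRecord("MISSING", 8, "K", "R"),
             MutationRecord("P", 8, "K", "R")])
        assert len(errors) == 1 and "MISSING" in errors[0]
        assert counts["removed"] == 1

    def test_class_counts_invariant_to_row_order(self, design, profile_factory):
        prof = profile_factory(raw={(-2, "D"): 10.0, (-2, "R"): 900.0},
                               default=100.0)
        proteome = {"P": "AAAAADLKSAAAAA", "Q": "AAAARKLKSKRAAAA"}
        muts = [MutationRecord("P", 6, "D", "R"), MutationRecord("Q", 8, "K", "R")]
        _, c1, _ = compare_proteomes(prof, proteome, muts)
        _, c2, _ = compare_proteomes(prof, proteome, list(reversed(muts)))
        assert c1 == c2

    def test_collapse_maps_removed_to_weakened(self, design, profile_factory):
        table, counts, _ = compare_proteomes(
            profile_factory(), {"P": "AAAARKLKSKRAAAA"},
            [MutationRecord("P", 8, "K", "R")], collapse_removed=True)
        # the lost K8 window reports as weakened; flanking K6/K10 windows
        # see a neutral K->R swap under a flat profile
        target = table[table.k_position == 8]
        assert list(target.impact_class) == ["weakened"]
        assert "removed" not in counts
        assert collapse_class("removed") == "weakened"
        assert collapse_class("created") == "created"
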