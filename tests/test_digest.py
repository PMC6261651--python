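"""In-silico digestion, detectability verdicts and K/R-content statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kopl.digest import (
    compare_kr_distributions,
    cut_positions,
    digest,
    get_rule,
    kr_content,
    site_detectable,
)
from kopl.errors import KoplError
from kopl.scan import KWindow

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


def _fragments(sequence, rule):
    """Independent zero-missed oracle: split at cut indices, keep order."""
    cuts = cut_positions(sequence, rule)
    bounds = [0, *cuts, len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds, bounds[1:])]


class TestDigest:
    def test_tryptic_hand_traced_example(self):
        peps = digest("AAKAAARAA", "trypsin", 0)
        assert [p.sequence for p in peps] == ["AAK", "AAAR", "AA"]
        assert [(p.start, p.end) for p in peps] == [(1, 3), (4, 7), (8, 9)]
        assert all(p.missed_cleavages == 0 for p in peps)

    def test_proline_blocks_tryptic_cleavage(self):
        peps = digest("AAKPAA", "trypsin", 0)
        assert [p.sequence for p in peps] == ["AAKPAA"]

    def test_argc_ignores_lysine(self):
        assert [p.sequence for p in digest("AAKAAARAA", "arg-c", 0)] == \
            ["AAKAAAR", "AA"]

    def test_aspn_cuts_before_aspartate(self):
        assert [p.sequence for p in digest("AADAAADA", "asp-n", 0)] == \
            ["AA", "DAAA", "DA"]

    def test_unknown_rule_rejected(self):
        with pytest.raises(KoplError):
            digest("AAKA", "chymotrypsin", 0)
        assert get_rule("TRYPSIN").name == "trypsin"

    @given(seq=sequences)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_zero_missed_peptides_tile_the_protein(self, seq):
        for rule in ("trypsin", "arg-c", "asp-n"):
            peps = [p for p in digest(seq, rule, 0)]
            assert "".join(p.sequence for p in peps) == seq
            assert peps[0].start == 1 and peps[-1].end == len(seq)
            for a, b in zip(peps, peps[1:]):
                assert b.start == a.end + 1

    def test_missed_cleavage_output_equals_concatenation_oracle(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list(AA), size=int(rng.integers(5, 50))))
            for max_missed in (1, 2):
                frags = _fragments(seq, "trypsin")
                expected = set()
                for i in range(len(frags)):
                    for m in range(min(max_missed, len(frags) - 1 - i) + 1):
                        expected.add(("".join(frags[i:i + m + 1]), m))
                got = {(p.sequence, p.missed_cleavages)
                       for p in digest(seq, "trypsin", max_missed)}
                assert got == expected

    def test_agrees_with_pyteomics_cleave(self, rng):
        # independent implementation cross-check (sequence multisets)
        from pyteomics import parser as pt_parser

        for _ in range(50):
            seq = "".join(rng.choice(list(AA), size=int(rng.integers(5, 60))))
            ours = sorted(p.sequence for p in digest(seq, "trypsin", 2))
            theirs = sorted(
                pt_parser.cleave(seq, "[KR](?!P)", missed_cleavages=2,
                                 min_length=None)
            )
            assert sorted(set(ours)) == theirs


class TestSiteDetectable:
    def test_basic_motif_evades_trypsin(self):
        v = site_detectable("AAAAAARKLKSKRAAAAAA", 10, "trypsin", min_len=6)
        assert not v.detectable
        assert v.covering_peptides == []

    def test_aspn_without_aspartate_leaves_whole_protein(self):
        seq = "AAAAAARKLKSKRAAAAAA"
        v = site_detectable(seq, 10, "asp-n", max_len=30)
        assert v.detectable  # one 19-residue peptide
        v2 = site_detectable(seq, 10, "asp-n", max_len=15)
        assert not v2.detectable

    def test_kr_poor_context_is_detectable(self):
        v = site_detectable("AAAAAAAAAKAAAAAAAAAA", 10, "trypsin")
        assert v.detectable

    def test_methyl_blocked_cleavage_can_rescue_detection(self):
        # K10 splits an otherwise long peptide; blocking its cleavage merges it
        seq = "AAAAAAAAAKAAAR"
        plain = site_detectable(seq, 10, "trypsin", min_len=11)
        blocked = site_detectable(seq, 10, "trypsin", min_len=11,
                                  methyl_blocks_cleavage=True)
        assert not plain.detectable and blocked.detectable

    def test_position_validation(self):
        with pytest.raises(ValueError):
            site_detectable("AAKA", 99, "trypsin")
        with pytest.raises(ValueError):
            site_detectable("AAKA", 1, "trypsin")

    def test_widening_parameters_never_loses_detectability(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list(AA), size=30))
            ks = [i + 1 for i, r in enumerate(seq) if r == "K"]
            for k in ks:
                base = site_detectable(seq, k, "trypsin", min_len=6, max_len=25,
                                       max_missed=0)
                wider = site_detectable(seq, k, "trypsin", min_len=5, max_len=30,
                                        max_missed=2)
                if base.detectable:
                    assert wider.detectable


class TestKrContent:
    @pytest.mark.parametrize("core, expected", [
        ("RKLKSKR", 4),
        ("AAAKAAA", 0),
        ("RRRKRRR", 6),
        ("KKKKKKK", 6),  # central K not counted
    ])
    def test_counts(self, core, expected):
        assert kr_content(core) == expected
        assert kr_content(KWindow("P", 10, core)) == expected

    def test_unaffected_by_mutation_outside_window(self):
        assert kr_content("RKLKSKR") == kr_content("RKLKSKR")  # same core
        # a mutation beyond +-3 does not enter the core at all by construction
        seq = "AAAARKLKSKRAAAA"
        core_before = seq[4:11]
        mutated = seq[:13] + "R" + seq[14:]
        assert mutated[4:11] == core_before


class TestCompareKrDistributions:
    def test_identical_lists_give_p_near_one(self):
        ws = [KWindow("P", 10, "RKLKSKR")] * 10
        out = compare_kr_distributions(ws, list(ws), n_permutations=200, seed=0)
        assert out["mean_difference"] == 0
        assert out["median_a"] == out["median_b"]
        assert out["p_value"] > 0.9

    def test_extreme_separation_gives_small_p(self):
        a = [KWindow("A", 10, "RRRKRRR")] * 20
        b = [KWindow("B", 10, "AAAKAAA")] * 20
        out = compare_kr_distributions(a, b, n_permutations=1000, seed=0)
        assert out["mean_difference"] == 6
        # only the original labelling separates completely: add-one bound
        assert out["p_value"] <= 0.002

    def test_histograms_sum_to_list_sizes(self, rng):
        cores = ["".join(rng.choice(list(AA), 3)) + "K"
                 + "".join(rng.choice(list(AA), 3)) for _ in range(30)]
        a = [KWindow("A", 10, c) for c in cores[:12]]
        b = [KWindow("B", 10, c) for c in cores[12:]]
        out = compare_kr_distributions(a, b, n_permutations=50, seed=1)
        assert out["histogram_a"].sum() == 12
        assert out["histogram_b"].sum() == 18

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compare_kr_distributions([], [KWindow("B", 10, "AAAKAAA")])
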