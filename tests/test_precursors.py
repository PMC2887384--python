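"""Gly-Gly cleavage scanning, composition, and identity statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pppmine import (
    CleavageSite,
    ScanParams,
    ValidationError,
    core_composition,
    find_cleavage_sites,
    pairwise_identity,
    paralog_variability,
    scan_proteome,
    split_leader_core,
)
from pppmine.precursors import PrecursorCandidate

from conftest import make_record

AA = "ACDEFGHIKLMNPQRSTVWY"
# Conserved 13-residue pre-cleavage leader motif (cyanobacterial N11P type)
N11P_MOTIF2 = "ELSDEELEAVAGG"


class TestFindCleavageSites:
    def test_motif_fixture_has_single_terminal_site(self):
        sites = find_cleavage_sites(N11P_MOTIF2, leader_window=(2, 13))
        assert sites == [CleavageSite(position=13, doublet="GG")]

    def test_no_doublet_no_sites(self):
        assert find_cleavage_sites("MKKAWSDEEF") == []

    def test_overlapping_triple_g_yields_two_sites(self):
        sites = find_cleavage_sites("AAGGGAA", leader_window=(2, 7))
        assert [s.position for s in sites] == [4, 5]

    def test_window_filters_positions(self):
        sites = find_cleavage_sites("GGAAAAGG", leader_window=(5, 10))
        assert [s.position for s in sites] == [8]

    def test_malformed_doublet_rejected(self):
        with pytest.raises(ValidationError):
            find_cleavage_sites("AAGG", doublets=("GGG",))

    def test_empty_sequence_empty_list(self):
        assert find_cleavage_sites("") == []


class TestSplitLeaderCore:
    def test_basic_partition_keeps_doublet_on_leader(self):
        leader, core = split_leader_core("AAGGCST", CleavageSite(4, "GG"))
        assert (leader, core) == ("AAGG", "CST")

    def test_site_at_end_gives_empty_core(self):
        leader, core = split_leader_core("AAGG", CleavageSite(4, "GG"))
        assert leader == "AAGG" and core == ""

    def test_out_of_range_site_rejected(self):
        with pytest.raises(ValidationError):
            split_leader_core("AAGG", CleavageSite(9, "GG"))

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_concatenation_identity(self, pre, post, seed):
        rng = np.random.default_rng(seed)
        seq = (
            "".join(np.array(list(AA))[rng.integers(0, 20, pre)])
            + "GG"
            + "".join(np.array(list(AA))[rng.integers(0, 20, post)])
        )
        site = CleavageSite(pre + 2, "GG")
        leader, core = split_leader_core(seq, site)
        assert leader + core == seq
        assert leader.endswith("GG")


class TestComposition:
    def test_all_heterocyclizable(self):
        stats = core_composition("CCSSTT")
        assert stats.heterocyclizable_fraction == 1.0
        assert stats.fractions["G"] == 0.0

    def test_none_heterocyclizable(self):
        assert core_composition("AAAA").heterocyclizable_fraction == 0.0

    def test_uniform_random_fraction_near_background(self, rng):
        n = 100_000
        core = "".join(np.array(list(AA))[rng.integers(0, 20, n)])
        stats = core_composition(core)
        se = math.sqrt(0.15 * 0.85 / n)
        assert abs(stats.heterocyclizable_fraction - 0.15) < 3 * se

    def test_x_excluded_from_denominator(self):
        stats = core_composition("CXXX")
        assert stats.valid_length == 1
        assert stats.heterocyclizable_fraction == 1.0

    def test_all_x_core_degenerate(self):
        stats = core_composition("XXX")
        assert stats.degenerate
        assert stats.valid_length == 0
        assert math.isnan(stats.heterocyclizable_fraction)

    def test_fraction_additivity(self):
        stats = core_composition("CSTGAA")
        assert stats.heterocyclizable_fraction == pytest.approx(
            stats.fractions["C"] + stats.fractions["S"] + stats.fractions["T"]
        )

    def test_bad_background_rejected(self):
        with pytest.raises(ValidationError):
            core_composition("CST", {aa: 0.1 for aa in AA})


def enumerate_alignments(a, b):
    """All global alignments as (score, matches, length) triples."""
    if not a and not b:
        return [(0, 0, 0)]
    out = []
    if a and b:
        hit = a[0] == b[0]
        for s, m, ln in enumerate_alignments(a[1:], b[1:]):
            out.append((s + (1 if hit else -1), m + hit, ln + 1))
    if a:
        for s, m, ln in enumerate_alignments(a[1:], b):
            out.append((s - 1, m, ln + 1))
    if b:
        for s, m, ln in enumerate_alignments(a, b[1:]):
            out.append((s - 1, m, ln + 1))
    return out


class TestPairwiseIdentity:
    def test_identical_strings(self):
        assert pairwise_identity("MAGGA", "MAGGA") == 1.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_identity("", "A")

    def test_gap_penalised_by_alignment_length(self):
        # AAAA vs AA: best alignment has 2 matches over length 4
        assert pairwise_identity("AAAA", "AA") == 0.5

    def test_symmetry(self, rng):
        letters = np.array(list("ACDE"))
        for _ in range(50):
            a = "".join(letters[rng.integers(0, 4, rng.integers(1, 10))])
            b = "".join(letters[rng.integers(0, 4, rng.integers(1, 10))])
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_identity_is_optimal_under_brute_force(self, rng):
        letters = np.array(list("ACD"))
        for _ in range(25):
            a = "".join(letters[rng.integers(0, 3, rng.integers(1, 7))])
            b = "".join(letters[rng.integers(0, 3, rng.integers(1, 7))])
            table = enumerate_alignments(a, b)
            best = max(s for s, _, _ in table)
            optimal_identities = {m / ln for s, m, ln in table if s == best and ln}
            assert pairwise_identity(a, b) in optimal_identities


def candidate(pid, leader, core):
    from pppmine.precursors import core_composition as cc

    return PrecursorCandidate(
        protein_id=pid,
        site=CleavageSite(len(leader), leader[-2:]),
        leader=leader,
        core=core,
        composition=cc(core) if core else cc("X"),
    )


class TestParalogVariability:
    def test_conserved_leaders_disjoint_cores(self):
        cands = [
            candidate("p1", "MAAEELSGG", "CCCC"),
            candidate("p2", "MAAEELSGG", "DDDD"),
            candidate("p3", "MAAEELSGG", "EEEE"),
        ]
        stats = paralog_variability(cands)
        assert stats.mean_leader_identity == 1.0
        assert stats.mean_core_identity == 0.0

    def test_identical_candidates(self):
        cands = [candidate("p1", "MAAGG", "CST")] * 2
        stats = paralog_variability(cands)
        assert stats == pytest.approx((1.0, 1.0, 1, 1, 0))

    def test_empty_core_pairs_skipped_and_counted(self):
        cands = [
            candidate("p1", "MAAGG", "CST"),
            candidate("p2", "MAAGG", ""),
            candidate("p3", "MAAGG", "CSA"),
        ]
        stats = paralog_variability(cands)
        assert stats.n_core_pairs == 1
        assert stats.n_skipped_pairs == 2

    def test_needs_two_candidates(self):
        with pytest.raises(ValidationError):
            paralog_variability([candidate("p1", "MAGG", "C")])

    def test_leader_more_conserved_than_core_in_simulated_family(self, rng):
        """Template leaders at 5% substitution vs random cores."""
        template = "".join(np.array(list(AA))[rng.integers(0, 20, 38)]) + "GG"
        wins = 0
        for _ in range(20):
            cands = []
            for i in range(5):
                chars = list(template)
                for j in range(38):
                    if rng.random() < 0.05:
                        chars[j] = AA[rng.integers(0, 20)]
                core = "".join(np.array(list(AA))[rng.integers(0, 20, 20)])
                cands.append(candidate(f"p{i}", "".join(chars), core))
            stats = paralog_variability(cands)
            wins += stats.mean_leader_identity > stats.mean_core_identity
        assert wins == 20


class TestScanProteome:
    def test_textbook_candidate_passes_all_flags(self):
        rec = make_record("p1", sequence="M" + "E" * 20 + "GG" + "CSCSCSC")
        cands = scan_proteome([rec])
        assert len(cands) == 1
        c = cands[0]
        assert c.passes_all
        assert c.site.position == 23
        assert c.core == "CSCSCSC"

    def test_length_cap_excludes_long_proteins(self):
        rec = make_record("p1", sequence="A" * 150 + "GG" + "C" * 148)
        assert scan_proteome([rec]) == []

    def test_failing_thresholds_flagged_not_dropped(self):
        rec = make_record("p1", sequence="M" + "E" * 20 + "GG" + "AAAAAA")
        (c,) = scan_proteome([rec])
        assert not c.prefilter_flags["composition"]
        assert c.prefilter_flags["core_length"]

    def test_order_invariance(self, rng):
        recs = [
            make_record(f"p{i}", sequence="M" + "E" * 20 + "GG" + "CST" * 4)
            for i in range(6)
        ]
        fwd = scan_proteome(recs)
        rev = scan_proteome(list(reversed(recs)))
        assert fwd == rev

    def test_motif_bits_attached_when_model_given(self):
        from pppmine import build_motif

        model = build_motif([N11P_MOTIF2] * 5, pseudocount=0.5)
        seq = "M" + "E" * 9 + N11P_MOTIF2 + "CSCSCS"
        rec = make_record("p1", sequence=seq)
        cands = scan_proteome([rec], motif_model=model)
        by_pos = {c.site.position: c for c in cands}
        true_pos = 10 + len(N11P_MOTIF2)
        assert by_pos[true_pos].motif_bits == pytest.approx(
            model.score_window(seq, true_pos - model.length)
        )
        # the planted site outscores any other candidate site
        assert all(
            c.motif_bits is None or c.motif_bits <= by_pos[true_pos].motif_bits
            for c in cands
        )
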