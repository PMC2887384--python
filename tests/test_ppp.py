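"""The depth-scanning binomial PPP statistic."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from pppmine import (
    DegenerateProfileError,
    HitList,
    Match,
    PPPOptions,
    ValidationError,
    log10_binomial_tail,
    ppp_rank_genome,
    ppp_score_protein,
)
from pppmine.profiles import PhylogeneticProfile

from oracles import exact_log10_tail, naive_ppp

# The seven unambiguous published PPP report rows (k, n, printed log10 score)
# for the precursor/transporter discovery collection of 14 YES genomes.
REPORT_ROWS = [
    (8, 8, -16.124),
    (9, 19, -13.212),
    (9, 22, -12.492),
    (10, 95, -7.475),
    (7, 19, -9.451),
    (8, 29, -9.570),
    (10, 88, -7.798),
]


def profile_of(values, family_id="F"):
    uni = tuple(f"g{i}" for i in range(len(values)))
    return PhylogeneticProfile(family_id, uni, tuple(values))


class TestLog10BinomialTail:
    @pytest.mark.parametrize("k,n,expected", REPORT_ROWS)
    def test_report_scores_with_calibrated_denominator(self, k, n, expected):
        assert log10_binomial_tail(k, n, 14 / 1451) == pytest.approx(
            expected, abs=0.005
        )

    @pytest.mark.parametrize("k,n,expected", REPORT_ROWS)
    def test_report_scores_with_stated_denominator(self, k, n, expected):
        assert log10_binomial_tail(k, n, 14 / 1450) == pytest.approx(
            expected, abs=0.01
        )

    def test_k_zero_is_exactly_zero(self):
        assert log10_binomial_tail(0, 17, 0.3) == 0.0

    def test_fair_coin_symmetry(self):
        # P(X >= 2 | n=3, p=1/2) = 1/2
        assert log10_binomial_tail(2, 3, 0.5) == pytest.approx(
            math.log10(0.5), abs=1e-12
        )

    @pytest.mark.parametrize(
        "k,n,p",
        [(5, 4, 0.5), (0, 0, 0.5), (1, 3, 0.0), (1, 3, 1.0), (-1, 3, 0.5)],
    )
    def test_domain_errors(self, k, n, p):
        with pytest.raises(ValidationError):
            log10_binomial_tail(k, n, p)

    def test_matches_exact_summation(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 26))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert log10_binomial_tail(k, n, p) == pytest.approx(
                exact_log10_tail(k, n, p), abs=1e-9
            )

    def test_matches_scipy_survival_function(self, rng):
        """Independent library cross-check on the same quantity."""
        for _ in range(100):
            n = int(rng.integers(1, 2000))
            k = int(rng.integers(1, n + 1))
            p = float(rng.uniform(0.005, 0.995))
            ours = log10_binomial_tail(k, n, p)
            ref = binom.logsf(k - 1, n, p) / math.log(10)
            if math.isinf(ref):
                # scipy's sf underflows below ~1e-308; the log-space path
                # keeps going, which is the point of computing in logs
                assert ours < -300
            else:
                assert ours == pytest.approx(ref, abs=1e-8)

    def test_complement_identity(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 1001))
            k = int(rng.integers(1, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            upper = 10 ** log10_binomial_tail(k, n, p)
            lower = binom.cdf(k - 1, n, p)
            assert upper + lower == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_k_and_p(self):
        n, p = 40, 0.2
        tails = [log10_binomial_tail(k, n, p) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        k = 11
        by_p = [log10_binomial_tail(k, n, q) for q in np.linspace(0.05, 0.95, 19)]
        assert all(a <= b for a, b in zip(by_p, by_p[1:]))


class TestScoreProtein:
    def test_self_hit_only(self):
        profile = profile_of([1, 0, 0, 0, 0])
        hits = HitList("q", [Match("q", "g0", 100.0)])
        res = ppp_score_protein(hits, profile)
        assert (res.k, res.n, res.best_depth) == (1, 1, 1)
        assert res.ppp_score == pytest.approx(-math.log10(profile.p))

    def test_all_no_genomes_scores_zero_at_depth_one(self):
        profile = profile_of([1, 0, 0, 0])
        hits = HitList(
            "q", [Match("a", "g1", 9.0), Match("b", "g2", 8.0), Match("c", "g3", 7.0)]
        )
        res = ppp_score_protein(hits, profile)
        assert res.ppp_score == 0.0
        assert res.best_depth == 1
        assert res.k == 0

    def test_distinct_genome_counting_lets_depth_exceed_n(self):
        # six genomes (4 YES); 12 hits revisit genomes, so depth > n
        profile = profile_of([1, 1, 1, 1, 0, 0])
        genomes = ["g0", "g1", "g0", "g2", "g3", "g1", "g4", "g0", "g2", "g5", "g3", "g1"]
        hits = HitList(
            "q",
            [Match(f"s{i}", g, float(100 - i)) for i, g in enumerate(genomes)],
        )
        res = ppp_score_protein(hits, profile)
        oracle = naive_ppp(hits, profile)
        assert (res.k, res.n, res.best_depth, res.log10_tail) == (
            oracle.k, oracle.n, oracle.best_depth, oracle.log10_tail,
        )
        assert res.best_depth > res.n  # revisits collapse into one genome

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n_genomes = int(rng.integers(4, 15))
            values = rng.integers(0, 2, n_genomes)
            if values.sum() in (0, n_genomes):
                values[0] = 1 - values[0]
            profile = profile_of([int(v) for v in values])
            n_hits = int(rng.integers(1, 51))
            scores = np.sort(rng.uniform(0, 100, n_hits))[::-1]
            hits = HitList(
                "q",
                [
                    Match(f"s{i}", f"g{int(rng.integers(0, n_genomes))}", float(s))
                    for i, s in enumerate(scores)
                ],
            )
            res = ppp_score_protein(hits, profile)
            oracle = naive_ppp(hits, profile)
            assert (res.k, res.n, res.best_depth) == (
                oracle.k, oracle.n, oracle.best_depth,
            )
            assert res.log10_tail == pytest.approx(oracle.log10_tail, abs=1e-12)

    def test_include_self_off_drops_the_free_success(self):
        profile = profile_of([1, 1, 0, 0])
        hits = HitList("q", [Match("q", "g0", 9.0), Match("s", "g1", 5.0)])
        with_self = ppp_score_protein(hits, profile)
        without = ppp_score_protein(hits, profile, PPPOptions(include_self=False))
        assert with_self.n == 2 and without.n == 1
        assert without.k == 1

    def test_p_override(self):
        profile = profile_of([1, 0, 0, 0])
        hits = HitList("q", [Match("q", "g0", 9.0)])
        res = ppp_score_protein(hits, profile, PPPOptions(p_override=14 / 1451))
        assert res.log10_tail == pytest.approx(math.log10(14 / 1451), abs=1e-12)

    def test_degenerate_profile_rejected(self):
        profile = profile_of([1, 1])
        hits = HitList("q", [Match("q", "g0", 9.0)])
        with pytest.raises(DegenerateProfileError):
            ppp_score_protein(hits, profile)

    def test_unknown_genome_in_hits_rejected(self):
        profile = profile_of([1, 0])
        hits = HitList("q", [Match("s", "gX", 9.0)])
        with pytest.raises(ValidationError, match="gX"):
            ppp_score_protein(hits, profile)


class TestRankGenome:
    def test_ranking_matches_independent_scores(self):
        profile = profile_of([1, 1, 1, 0, 0, 0])
        lists = {
            "a": HitList("a", [Match("a", "g0", 9.0), Match("x", "g1", 8.0),
                               Match("y", "g2", 7.0)]),
            "b": HitList("b", [Match("b", "g0", 9.0), Match("z", "g3", 8.0)]),
            "c": HitList("c", [Match("c", "g0", 9.0)]),
        }
        ranked = ppp_rank_genome("g0", lists, profile)
        solo = {pid: ppp_score_protein(hl, profile) for pid, hl in lists.items()}
        assert [r.protein_id for r in ranked] == sorted(
            solo, key=lambda pid: (-solo[pid].ppp_score, pid)
        )
        assert ranked[0].protein_id == "a"

    def test_input_order_invariance(self):
        profile = profile_of([1, 1, 0, 0])
        lists = {
            pid: HitList(pid, [Match(pid, "g0", 9.0), Match("x" + pid, "g1", 5.0)])
            for pid in ("p1", "p2", "p3")
        }
        forward = ppp_rank_genome("g0", lists, profile)
        reversed_input = ppp_rank_genome("g0", dict(reversed(lists.items())), profile)
        assert forward == reversed_input
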