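"""Independent reference implementations used only by the test suite."""

import math
from fractions import Fraction

from pppmine import log10_binomial_tail
from pppmine.ppp import PPPResult


def exact_log10_tail(k: int, n: int, p: float) -> float:
    """Binomial upper tail by exact rational summation, then one log10.

    ``p`` is taken at its exact binary-float value, so the only rounding
    is the final conversion of the rational tail to a float.
    """
    if k == 0:
        return 0.0
    pf = Fraction(p)
    qf = 1 - pf
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * pf**i * qf ** (n - i)
    # big-int log10 avoids float under/overflow of the huge rationals
    return math.log10(total.numerator) - math.log10(total.denominator)


def naive_ppp(hits, profile, p=None, include_self=True):
    """Exhaustive depth re-scan: rebuild the distinct-genome set from
    scratch at every depth and keep the most negative log10 tail."""
    p = p if p is not None else profile.p
    matches = [
        m for m in hits.matches
        if include_self or m.subject_protein_id != hits.query_protein_id
    ]
    yes = profile.yes_genomes
    best = None
    for depth in range(1, len(matches) + 1):
        genomes = {m.subject_genome_id for m in matches[:depth]}
        n = len(genomes)
        k = sum(1 for g in genomes if g in yes)
        tail = log10_binomial_tail(k, n, p) if k else 0.0
        if best is None or tail < best[0]:
            best = (tail, depth, k, n)
    tail, depth, k, n = best
    return PPPResult(
        protein_id=hits.query_protein_id, k=k, n=n, best_depth=depth, log10_tail=tail
    )
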