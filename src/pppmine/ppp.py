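"""Partial phylogenetic profiling (PPP).

PPP asks, for each protein of a genome: does the set of genomes producing
the protein's best similarity matches look like a given phylogenetic
profile?  Walking the ranked hit list to increasing depths ``d``, it tracks
the set of *distinct* genomes seen so far (size ``n``) and how many of them
are YES in the profile (``k``), and scores each depth by the binomial
upper-tail probability

    P(X >= k | n, p),   X ~ Binomial(n, p),   p = YES fraction of the profile.

The protein's score is the most negative ``log10`` tail over all depths —
the depth acts as a free parameter matching the unknown working size of the
candidate protein family.  Small tails mean the hit list is enriched for
YES genomes far beyond chance.

The tail is computed entirely in log space from log-gamma terms, so scores
such as 1e-16 are exact to ~1e-12 log10 units rather than underflowing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datamodel import DegenerateProfileError, HitList, ValidationError
from .profiles import PhylogeneticProfile

PathLike = Union[str, Path]

_LN10 = math.log(10.0)


def log10_binomial_tail(k: int, n: int, p: float) -> float:
    """log10 of the binomial upper tail ``P(X >= k)`` for ``X ~ Bin(n, p)``.

    Parameters
    ----------
    k : int
        Minimum number of successes, ``0 <= k <= n``.
    n : int
        Number of trials, ``n >= 1``.
    p : float
        Per-trial success probability, strictly inside (0, 1).

    Returns
    -------
    float
        ``log10 P(X >= k)``; exactly ``0.0`` when ``k == 0``.

    Notes
    -----
    The tail is summed as ``logsumexp`` over the individual term logs
    ``log C(n,i) + i log p + (n-i) log(1-p)`` for ``i = k..n``, which factors
    out the largest term and keeps relative accuracy in log10 units well
    below 1e-9 for ``n <= 1e4``.
    """
    if int(k) != k or int(n) != n:
        raise ValidationError("k and n must be integers")
    k, n = int(k), int(n)
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValidationError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must lie strictly in (0, 1), got {p}")
    if k == 0:
        return 0.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )
    return float(logsumexp(log_terms)) / _LN10


# PPP re-evaluates the same (k, n) pairs at many depths and across many
# queries of one genome; memoise on the full argument triple.
_cached_tail = lru_cache(maxsize=1 << 18)(log10_binomial_tail)


@dataclass(frozen=True)
class PPPOptions:
    """Scoring options.

    include_self
        Keep the query's own self-hit (its genome is YES by construction
        when the query belongs to the family); turn off to score a protein
        against a foreign profile without the free success.
    max_depth
        Truncate the hit list; default scans it entirely.
    p_override
        Use this per-trial probability instead of the profile's
        ``n_yes / n_total`` (e.g. to pin a published denominator).
    """

    include_self: bool = True
    max_depth: Optional[int] = None
    p_override: Optional[float] = None


@dataclass(frozen=True)
class PPPResult:
    """Best-depth PPP score for one protein.

    ``log10_tail`` is the signed (non-positive) log10 tail probability at
    the optimal depth, as printed in PPP reports; ``ppp_score`` is its
    negation, used for ranking.
    """

    protein_id: str
    k: int
    n: int
    best_depth: int
    log10_tail: float
    annotation: str = ""

    @property
    def ppp_score(self) -> float:
        return -self.log10_tail


def ppp_score_protein(
    hits: HitList,
    profile: PhylogeneticProfile,
    options: Optional[PPPOptions] = None,
) -> PPPResult:
    """Depth-scan one protein's hit list against a profile.

    At each depth ``d`` the d-th match's genome joins the distinct-genome
    set (a genome contributes once no matter how many of its proteins
    appear, which is why the optimal depth can exceed ``n``); the binomial
    tail is evaluated after every list entry and the most negative log10
    tail wins, ties broken toward the smallest depth.
    """
    options = options or PPPOptions()
    if profile.degenerate:
        raise DegenerateProfileError(
            f"profile {profile.family_id!r} has p = {profile.p}; "
            "PPP requires 0 < p < 1"
        )
    if not len(hits):
        raise ValidationError(f"empty hit list for {hits.query_protein_id!r}")
    p = options.p_override if options.p_override is not None else profile.p
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must lie strictly in (0, 1), got {p}")
    universe = set(profile.universe)
    yes = profile.yes_genomes

    matches = hits.matches
    if not options.include_self:
        matches = tuple(
            m for m in matches if m.subject_protein_id != hits.query_protein_id
        )
        if not matches:
            raise ValidationError(
                f"hit list for {hits.query_protein_id!r} holds only the self-hit"
            )
    if options.max_depth is not None:
        matches = matches[: options.max_depth]

    seen: set[str] = set()
    k = 0
    best: Optional[tuple[float, int, int, int]] = None  # (tail, depth, k, n)
    for depth, m in enumerate(matches, start=1):
        g = m.subject_genome_id
        if g not in universe:
            raise ValidationError(
                f"hit list for {hits.query_protein_id!r}: genome {g!r} "
                "missing from the profile universe"
            )
        if g not in seen:
            seen.add(g)
            if g in yes:
                k += 1
        n = len(seen)
        tail = _cached_tail(k, n, p) if k > 0 else 0.0
        if best is None or tail < best[0]:
            best = (tail, depth, k, n)
    assert best is not None
    tail, depth, k, n = best
    return PPPResult(
        protein_id=hits.query_protein_id,
        k=k,
        n=n,
        best_depth=depth,
        log10_tail=tail,
    )


def ppp_rank_genome(
    genome_id: str,
    hit_lists: Mapping[str, HitList],
    profile: PhylogeneticProfile,
    options: Optional[PPPOptions] = None,
    annotations: Optional[Mapping[str, str]] = None,
) -> list[PPPResult]:
    """Score every protein of one genome and rank by descending PPP score.

    ``hit_lists`` maps protein_id -> :class:`HitList` for the genome's
    proteins; ``annotations`` optionally attaches a label column to the
    report.  Ties in score break by protein_id.
    """
    results = []
    for protein_id in sorted(hit_lists):
        try:
            res = ppp_score_protein(hit_lists[protein_id], profile, options)
        except (ValidationError, DegenerateProfileError) as exc:
            raise type(exc)(f"[genome {genome_id}, protein {protein_id}] {exc}")
        if annotations and protein_id in annotations:
            res = PPPResult(
                protein_id=res.protein_id,
                k=res.k,
                n=res.n,
                best_depth=res.best_depth,
                log10_tail=res.log10_tail,
                annotation=annotations[protein_id],
            )
        results.append(res)
    results.sort(key=lambda r: (-r.ppp_score, r.protein_id))
    return results


def write_ppp_report(results: Sequence[PPPResult], path: PathLike) -> None:
    """Write a ranked PPP report TSV (one row per protein)."""
    frame = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "k": r.k,
                "n": r.n,
                "best_depth": r.best_depth,
                "log10_tail": f"{r.log10_tail:.3f}",
                "ppp_score": f"{r.ppp_score:.3f}",
                "annotation": r.annotation,
            }
            for r in results
        ],
        columns=[
            "protein_id", "k", "n", "best_depth",
            "log10_tail", "ppp_score", "annotation",
        ],
    )
    with open(path, "w") as handle:
        handle.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(handle, sep="\t", header=False, index=False)
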