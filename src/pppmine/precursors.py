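"""RiPP precursor-peptide scanning.

Precursors of ribosomally synthesised natural products are bipartite: a
conserved N-terminal leader peptide ends in a double-glycine cleavage
motif, and the C-terminal core peptide that follows is short, hypervariable
and enriched in the heterocyclizable residues Cys/Ser/Thr (and Gly).  This
module finds candidate Gly-Gly sites, partitions leader from core (the
doublet stays on the leader), computes core composition statistics, and
quantifies the conserved-leader / variable-core contrast across paralogs
via pairwise global-alignment identity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .datamodel import AA_ALPHABET, ProteinRecord, ValidationError

HETEROCYCLIZABLE = ("C", "S", "T")

#: Uniform background: every residue 0.05, so the heterocyclizable
#: (C+S+T) expectation is 0.15.
UNIFORM_BACKGROUND = {aa: 0.05 for aa in AA_ALPHABET}


@dataclass(frozen=True)
class CleavageSite:
    """A candidate cleavage point.

    ``position`` is the 0-based index of the first core residue, i.e. the
    index just past the second residue of the doublet, so
    ``sequence[position - 2:position] == doublet``.
    """

    position: int
    doublet: str


@dataclass(frozen=True)
class CompositionStats:
    """Core-peptide composition over the non-X residues.

    ``heterocyclizable_fraction`` is (C+S+T)/valid_length and ``enrichment``
    its log2 ratio over the background's C+S+T mass; both are NaN when the
    core has no valid residue (``degenerate``).
    """

    counts: dict
    fractions: dict
    valid_length: int
    heterocyclizable_fraction: float
    enrichment: float
    degenerate: bool


class VariabilityStats(NamedTuple):
    mean_leader_identity: float
    mean_core_identity: float
    n_leader_pairs: int
    n_core_pairs: int
    n_skipped_pairs: int


@dataclass(frozen=True)
class PrecursorCandidate:
    protein_id: str
    site: CleavageSite
    leader: str
    core: str
    composition: CompositionStats
    prefilter_flags: dict = field(default_factory=dict)
    motif_bits: Optional[float] = None

    @property
    def passes_all(self) -> bool:
        return all(self.prefilter_flags.values())


@dataclass(frozen=True)
class ScanParams:
    """Thresholds for proteome scanning.

    The leader window spans classic short bacteriocin leaders (~24 aa)
    through the long nitrile-hydratase-related leaders (~70-90 aa) with
    margin.  ``min_heterocyclizable_fraction`` encodes "rich in C/S/T";
    there is no published numeric threshold, so 0.25 is this package's
    default and is always configurable.
    """

    doublets: tuple = ("GG",)
    leader_window: tuple = (15, 150)
    min_core: int = 5
    max_core: int = 120
    min_heterocyclizable_fraction: float = 0.25
    protein_length_cap: int = 250


# ---------------------------------------------------------------------------
# Cleavage sites and leader/core partition
# ---------------------------------------------------------------------------

def find_cleavage_sites(
    sequence: str,
    doublets: Sequence[str] = ("GG",),
    leader_window: tuple = (15, 150),
) -> list[CleavageSite]:
    """All doublet occurrences whose cut position lies inside the window.

    Overlapping occurrences each count: ``GGG`` yields a site after the
    second and after the third G.  Sites are returned in position order.
    """
    for d in doublets:
        if len(d) != 2:
            raise ValidationError(f"cleavage doublet must have length 2, got {d!r}")
    if not sequence:
        return []
    lo, hi = leader_window
    sites = []
    for pos in range(2, len(sequence) + 1):
        pair = sequence[pos - 2:pos]
        if pair in doublets and lo <= pos <= hi:
            sites.append(CleavageSite(position=pos, doublet=pair))
    return sites


def split_leader_core(sequence: str, site: CleavageSite) -> tuple[str, str]:
    """Partition at the site; the doublet stays at the end of the leader."""
    if not 2 <= site.position <= len(sequence):
        raise ValidationError(
            f"site position {site.position} out of range for length {len(sequence)}"
        )
    if sequence[site.position - 2:site.position] != site.doublet:
        raise ValidationError(
            f"sequence does not carry doublet {site.doublet!r} at {site.position}"
        )
    return sequence[: site.position], sequence[site.position:]


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def core_composition(
    core: str, background_frequencies: Optional[Mapping[str, float]] = None
) -> CompositionStats:
    """Composition of a core peptide; X residues leave the denominator."""
    bg = dict(background_frequencies) if background_frequencies else dict(UNIFORM_BACKGROUND)
    total = sum(bg.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"background frequencies sum to {total}, expected 1")
    valid = [aa for aa in core if aa != "X"]
    counts = {aa: 0 for aa in ("C", "S", "T", "G")}
    for aa in valid:
        if aa in counts:
            counts[aa] += 1
    n = len(valid)
    if n == 0:
        return CompositionStats(
            counts=counts,
            fractions={aa: float("nan") for aa in counts},
            valid_length=0,
            heterocyclizable_fraction=float("nan"),
            enrichment=float("nan"),
            degenerate=True,
        )
    fractions = {aa: c / n for aa, c in counts.items()}
    het = sum(fractions[aa] for aa in HETEROCYCLIZABLE)
    bg_het = sum(bg.get(aa, 0.0) for aa in HETEROCYCLIZABLE)
    enrichment = math.log2(het / bg_het) if het > 0 and bg_het > 0 else float("-inf")
    return CompositionStats(
        counts=counts,
        fractions=fractions,
        valid_length=n,
        heterocyclizable_fraction=het,
        enrichment=enrichment,
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# Pairwise identity (minimal global aligner)
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH, _GAP = 1, -1, -1


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions under global alignment.

    Needleman-Wunsch with match +1, mismatch -1, gap -1; the traceback
    prefers the diagonal on score ties, and identity is counted over the
    full alignment length (gap columns included), so length mismatch is
    penalised.  Arguments are canonicalised by lexicographic order before
    aligning, which makes the function exactly symmetric even when several
    co-optimal alignments disagree on identity.
    """
    if not a or not b:
        raise ValidationError("pairwise_identity requires non-empty sequences")
    if b < a:
        a, b = b, a
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = -np.arange(m + 1)
    score[:, 0] = -np.arange(n + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_prev = score[i - 1]
        row = score[i]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (_MATCH if ai == b[j - 1] else _MISMATCH)
            up = row_prev[j] + _GAP
            left = row[j - 1] + _GAP
            row[j] = max(diag, up, left)
    # traceback, diagonal preferred on ties, then up, then left
    i, j = n, m
    matches = 0
    length = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (_MATCH if a[i - 1] == b[j - 1] else _MISMATCH)
            if score[i, j] == diag:
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                length += 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + _GAP:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches / length


def paralog_variability(
    candidates: Sequence[PrecursorCandidate],
) -> VariabilityStats:
    """Mean pairwise identity of leaders vs cores across a paralog family.

    Pairs with an empty core are skipped for the core mean (and counted in
    ``n_skipped_pairs``); leaders are always non-empty by construction.
    """
    if len(candidates) < 2:
        raise ValidationError("paralog_variability needs at least two candidates")
    leader_ids, core_ids = [], []
    skipped = 0
    for x, y in itertools.combinations(candidates, 2):
        leader_ids.append(pairwise_identity(x.leader, y.leader))
        if x.core and y.core:
            core_ids.append(pairwise_identity(x.core, y.core))
        else:
            skipped += 1
    return VariabilityStats(
        mean_leader_identity=float(np.mean(leader_ids)),
        mean_core_identity=float(np.mean(core_ids)) if core_ids else float("nan"),
        n_leader_pairs=len(leader_ids),
        n_core_pairs=len(core_ids),
        n_skipped_pairs=skipped,
    )


# ---------------------------------------------------------------------------
# Proteome scan
# ---------------------------------------------------------------------------

def scan_proteome(
    records: Iterable[ProteinRecord],
    params: Optional[ScanParams] = None,
    motif_model=None,
    background_frequencies: Optional[Mapping[str, float]] = None,
) -> list[PrecursorCandidate]:
    """Enumerate precursor candidates across a proteome.

    Every protein at or under the length cap contributes one candidate per
    valid cleavage site; ``prefilter_flags`` record which thresholds each
    candidate passes (it is never silently dropped for failing one).  When
    ``motif_model`` (a :class:`~pppmine.motifs.GaplessMotifModel`) is given,
    the window of model length ending at the cleavage position is bit-scored
    into ``motif_bits``.  Output is sorted by (protein_id, position), so it
    is invariant under input record order.
    """
    params = params or ScanParams()
    candidates = []
    for rec in records:
        if len(rec.sequence) > params.protein_length_cap:
            continue
        for site in find_cleavage_sites(
            rec.sequence, params.doublets, params.leader_window
        ):
            leader, core = split_leader_core(rec.sequence, site)
            comp = core_composition(core, background_frequencies)
            flags = {
                "leader_window": True,  # guaranteed by find_cleavage_sites
                "core_length": params.min_core <= len(core) <= params.max_core,
                "composition": (
                    not comp.degenerate
                    and comp.heterocyclizable_fraction
                    >= params.min_heterocyclizable_fraction
                ),
            }
            motif_bits = None
            if motif_model is not None and site.position >= motif_model.length:
                motif_bits = motif_model.score_window(
                    rec.sequence, site.position - motif_model.length
                )
            candidates.append(
                PrecursorCandidate(
                    protein_id=rec.protein_id,
                    site=site,
                    leader=leader,
                    core=core,
                    composition=comp,
                    prefilter_flags=flags,
                    motif_bits=motif_bits,
                )
            )
    candidates.sort(key=lambda c: (c.protein_id, c.site.position))
    return candidates


def write_candidate_table(candidates: Sequence[PrecursorCandidate], path) -> None:
    """Candidate TSV, one row per (protein, site)."""
    import pandas as pd

    def fmt(x):
        return "nan" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.4f}"

    rows = []
    for c in candidates:
        rows.append(
            {
                "protein_id": c.protein_id,
                "site_position": c.site.position,
                "leader_len": len(c.leader),
                "core_len": len(c.core),
                "fC": fmt(c.composition.fractions.get("C")),
                "fS": fmt(c.composition.fractions.get("S")),
                "fT": fmt(c.composition.fractions.get("T")),
                "fG": fmt(c.composition.fractions.get("G")),
                "het_fraction": fmt(c.composition.heterocyclizable_fraction),
                "enrichment": fmt(c.composition.enrichment),
                "flags": ",".join(k for k, v in sorted(c.prefilter_flags.items()) if v),
                "motif_bits": fmt(c.motif_bits),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "site_position", "leader_len", "core_len",
            "fC", "fS", "fT", "fG", "het_fraction", "enrichment",
            "flags", "motif_bits",
        ],
    )
    with open(path, "w") as handle:
        handle.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(handle, sep="\t", header=False, index=False)
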