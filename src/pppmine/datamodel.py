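"""Core record types shared by every pipeline stage.

The pipeline reasons about proteins as rows of a gene table: each protein
belongs to a genome, sits on a replicon at an integer gene-order position
(its *ordinal*), and may carry free-text family annotations.  Gene distance
is always measured in ordinals (ORF counts), never in base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

#: The 20 standard amino acids, alphabetically ordered.  ``X`` marks an
#: unknown residue; it is carried through but excluded from composition
#: denominators and motif counts.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

VALID_STRANDS = frozenset({"+", "-"})


class ValidationError(ValueError):
    """An input file or record violates a documented invariant."""


class DegenerateProfileError(ValueError):
    """A phylogenetic profile with p = 0 or p = 1 was passed to PPP."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein-coding gene.

    Parameters
    ----------
    protein_id : str
        Unique identifier within a collection.
    genome_id, replicon_id : str
        Owning genome and replicon.
    ordinal : int
        Gene-order index within the replicon (0-based, unique per replicon).
    strand : str
        ``+`` or ``-``.
    start, end : int, optional
        0-based half-open nucleotide coordinates, if known.
    sequence : str
        Amino-acid sequence (uppercase, 20-letter alphabet plus ``X``).
    annotations : frozenset of str
        Family labels attached to this gene.
    """

    protein_id: str
    genome_id: str
    replicon_id: str
    ordinal: int
    strand: str
    sequence: str
    start: Optional[int] = None
    end: Optional[int] = None
    annotations: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if self.ordinal < 0:
            raise ValidationError(
                f"{self.protein_id}: ordinal must be non-negative, got {self.ordinal}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"{self.protein_id}: unknown strand symbol {self.strand!r}"
            )
        if not self.sequence:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        if (self.start is None) != (self.end is None):
            raise ValidationError(
                f"{self.protein_id}: start and end must be given together"
            )
        if self.start is not None and not self.start < self.end:
            raise ValidationError(
                f"{self.protein_id}: require start < end, got [{self.start}, {self.end})"
            )
        if not isinstance(self.annotations, frozenset):
            object.__setattr__(self, "annotations", frozenset(self.annotations))

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeCollection:
    """An ordered set of genomes, each an ordered list of :class:`ProteinRecord`.

    Records are stored per genome sorted by (replicon_id, ordinal); the
    genome universe is the sorted list of genome ids unless an explicit
    ordering is supplied.  Both orderings are deterministic functions of the
    input records, so identical input files always yield an identical
    collection.
    """

    def __init__(
        self,
        records: Iterable[ProteinRecord],
        universe: Optional[Sequence[str]] = None,
    ) -> None:
        self._by_protein: dict[str, ProteinRecord] = {}
        by_genome: dict[str, list[ProteinRecord]] = {}
        seen_slots: set[tuple[str, str, int]] = set()
        for rec in records:
            if rec.protein_id in self._by_protein:
                raise ValidationError(f"duplicate protein_id {rec.protein_id!r}")
            slot = (rec.genome_id, rec.replicon_id, rec.ordinal)
            if slot in seen_slots:
                raise ValidationError(
                    f"duplicate ordinal {rec.ordinal} on replicon "
                    f"{rec.replicon_id!r} of genome {rec.genome_id!r}"
                )
            seen_slots.add(slot)
            self._by_protein[rec.protein_id] = rec
            by_genome.setdefault(rec.genome_id, []).append(rec)
        for recs in by_genome.values():
            recs.sort(key=lambda r: (r.replicon_id, r.ordinal))
        if universe is None:
            self.universe: tuple[str, ...] = tuple(sorted(by_genome))
        else:
            self.universe = tuple(universe)
            missing = set(by_genome) - set(self.universe)
            if missing:
                raise ValidationError(
                    f"records reference genomes outside the universe: {sorted(missing)}"
                )
        self._by_genome = {g: tuple(by_genome.get(g, ())) for g in self.universe}

    # -- lookups ----------------------------------------------------------

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_protein

    def __iter__(self) -> Iterator[ProteinRecord]:
        for g in self.universe:
            yield from self._by_genome[g]

    def __len__(self) -> int:
        return len(self._by_protein)

    def get(self, protein_id: str) -> ProteinRecord:
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein_id {protein_id!r}") from None

    def proteins(self, genome_id: str) -> tuple[ProteinRecord, ...]:
        """All records of one genome, ordered by (replicon, ordinal)."""
        try:
            return self._by_genome[genome_id]
        except KeyError:
            raise KeyError(f"unknown genome_id {genome_id!r}") from None

    def replicon(self, genome_id: str, replicon_id: str) -> tuple[ProteinRecord, ...]:
        return tuple(
            r for r in self.proteins(genome_id) if r.replicon_id == replicon_id
        )

    def protein_to_genome(self) -> dict[str, str]:
        """Map every protein id to its genome id (for hit-table readers)."""
        return {pid: rec.genome_id for pid, rec in self._by_protein.items()}

    def with_family(self, family_id: str) -> tuple[ProteinRecord, ...]:
        """All records annotated with ``family_id``, in collection order."""
        return tuple(r for r in self if family_id in r.annotations)


@dataclass(frozen=True)
class Match:
    """One entry of a ranked similarity hit list."""

    subject_protein_id: str
    subject_genome_id: str
    score: float


class HitList:
    """A query protein's ranked similarity matches.

    Scores must be non-increasing down the list; within a tie, input order
    is preserved.
    """

    def __init__(self, query_protein_id: str, matches: Iterable[Match]) -> None:
        self.query_protein_id = query_protein_id
        self.matches: tuple[Match, ...] = tuple(matches)
        for a, b in zip(self.matches, self.matches[1:]):
            if b.score > a.score:
                raise ValidationError(
                    f"hit list for {query_protein_id!r} is not sorted by "
                    f"descending score ({a.score} before {b.score})"
                )

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self) -> Iterator[Match]:
        return iter(self.matches)


class PresenceTable:
    """Per-(genome, family) best model score and the above-cutoff call.

    At most one row per (genome_id, family_id).  A genome is counted as
    carrying a family only when its row has ``above_cutoff`` set — exactly
    the trusted-cutoff rule used to build phylogenetic profiles.
    """

    def __init__(
        self, rows: Iterable[tuple[str, str, float, bool]]
    ) -> None:
        self._rows: dict[tuple[str, str], tuple[float, bool]] = {}
        for genome_id, family_id, best_score, above in rows:
            key = (genome_id, family_id)
            if key in self._rows:
                raise ValidationError(
                    f"duplicate presence row for genome {genome_id!r}, "
                    f"family {family_id!r}"
                )
            self._rows[key] = (float(best_score), bool(above))

    def __len__(self) -> int:
        return len(self._rows)

    def rows(self) -> Iterator[tuple[str, str, float, bool]]:
        for (g, f), (s, a) in sorted(self._rows.items()):
            yield g, f, s, a

    def families(self) -> tuple[str, ...]:
        return tuple(sorted({f for (_, f) in self._rows}))

    def yes_genomes(self, family_id: str) -> frozenset:
        """Genomes with an above-cutoff row for ``family_id``."""
        return frozenset(
            g for (g, f), (_, above) in self._rows.items()
            if f == family_id and above
        )
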