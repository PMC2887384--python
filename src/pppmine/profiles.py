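"""Binary phylogenetic profiles over a genome universe.

A profile records, for one protein family, which genomes of a fixed
collection carry at least one member scoring above the family's trusted
cutoff (YES = 1) and which do not (NO = 0).  The YES fraction
``p = n_yes / n_total`` is the per-trial success probability used by the
partial-phylogenetic-profiling statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import numpy as np

from .datamodel import PresenceTable, ValidationError

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PhylogeneticProfile:
    family_id: str
    universe: tuple
    values: tuple  # 0/1 per genome, aligned with universe

    def __post_init__(self) -> None:
        if len(self.values) != len(self.universe):
            raise ValidationError("profile values must align with the universe")
        if any(v not in (0, 1) for v in self.values):
            raise ValidationError("profile values must be 0 or 1")

    @property
    def n_total(self) -> int:
        return len(self.universe)

    @property
    def n_yes(self) -> int:
        return int(sum(self.values))

    @property
    def p(self) -> float:
        """YES fraction; the binomial per-trial probability."""
        return self.n_yes / self.n_total

    @property
    def degenerate(self) -> bool:
        """True when p is 0 or 1; such profiles cannot be scored by PPP."""
        return self.n_yes in (0, self.n_total)

    @property
    def yes_genomes(self) -> frozenset:
        return frozenset(g for g, v in zip(self.universe, self.values) if v)

    def is_yes(self, genome_id: str) -> bool:
        try:
            return bool(self.values[self.universe.index(genome_id)])
        except ValueError:
            raise KeyError(f"genome {genome_id!r} not in profile universe") from None


def build_profile(
    presence: PresenceTable, family_id: str, universe: Sequence[str]
) -> PhylogeneticProfile:
    """Call each genome YES iff it has an above-cutoff row for ``family_id``.

    Genomes with no row at all, or only below-cutoff rows, are NO.  A family
    absent from the table yields an all-NO (degenerate) profile rather than
    an error; degeneracy is rejected later, at PPP time.
    """
    if not len(universe):
        raise ValidationError("universe must be non-empty")
    yes = presence.yes_genomes(family_id)
    stray = yes - set(universe)
    if stray:
        raise ValidationError(
            f"presence rows reference genomes outside the universe: {sorted(stray)}"
        )
    return PhylogeneticProfile(
        family_id=family_id,
        universe=tuple(universe),
        values=tuple(1 if g in yes else 0 for g in universe),
    )


class Overlap(NamedTuple):
    both_yes: int
    a_only: int
    b_only: int
    neither: int


def profile_overlap(a: PhylogeneticProfile, b: PhylogeneticProfile) -> Overlap:
    """Co-occurrence counts of two profiles on the same universe."""
    if a.universe != b.universe:
        raise ValidationError("profiles are defined on different universes")
    va = np.asarray(a.values, dtype=bool)
    vb = np.asarray(b.values, dtype=bool)
    return Overlap(
        both_yes=int(np.sum(va & vb)),
        a_only=int(np.sum(va & ~vb)),
        b_only=int(np.sum(~va & vb)),
        neither=int(np.sum(~va & ~vb)),
    )


def write_profile_tsv(profile: PhylogeneticProfile, path: PathLike) -> None:
    """Profile TSV: '#family_id' + genome-id header row, then one 0/1 row."""
    with open(path, "w") as handle:
        handle.write("#" + "\t".join((profile.family_id,) + profile.universe) + "\n")
        handle.write("\t".join([profile.family_id] + [str(v) for v in profile.values]) + "\n")


def read_profile_tsv(path: PathLike) -> PhylogeneticProfile:
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise ValidationError(f"{path}: expected '#' header")
        cols = header.lstrip("#").rstrip("\n").split("\t")
        row = handle.readline().rstrip("\n").split("\t")
    if len(row) != len(cols):
        raise ValidationError(f"{path}: header/value column mismatch")
    return PhylogeneticProfile(
        family_id=row[0],
        universe=tuple(cols[1:]),
        values=tuple(int(v) for v in row[1:]),
    )
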