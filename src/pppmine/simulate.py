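"""Synthetic genome collections with planted precursor families.

The generator emulates the statistical structure the discovery pipeline
relies on, at desk scale: a collection of bacterial-like genomes in which

* a precursor family occurs in a small YES subset of genomes (default 14),
  each carrying 1-12 paralogs whose ~40-residue leaders derive from one
  template (ending in a double-glycine motif) under point substitution,
  followed by short hypervariable Cys/Ser/Thr/Gly-biased cores;
* a companion transporter family co-occurs in an overlapping subset,
  placed in the same gene neighborhood;
* modification-enzyme genes (cyclodehydratase-docking fusion ``CD`` or
  lanthionine synthase ``LanM``) sit adjacent to the planted precursors,
  defining each genome's true context class;
* ranked hit lists score within-family pairs by leader identity plus
  Gaussian noise, so true family members rank above background — the
  signal partial phylogenetic profiling exploits.

Everything is a pure function of :class:`SimulationParams` (one integer
seed drives documented substreams), so outputs are byte-identical across
reruns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .datamodel import (
    AA_ALPHABET,
    GenomeCollection,
    HitList,
    Match,
    PresenceTable,
    ProteinRecord,
    ValidationError,
)

_AA = np.array(list(AA_ALPHABET))
_AA_BYTES = np.array(list(AA_ALPHABET), dtype="S1")
_CSTG = np.array(list("CSTG"))

PRECURSOR_FAMILY = "NHLP"
COMPANION_FAMILY = "Trans"

#: Conserved 13-residue pre-cleavage motif used as the template tail.
LEADER_TAIL = "ELSDEELEAVAGG"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic collection.

    Defaults mirror the discovery setting: 14 YES genomes in the
    collection, 1-12 precursor paralogs per YES genome, conserved leaders
    ending in Gly-Gly, short C/S/T/G-biased hypervariable cores, and a
    transporter family overlapping 9 of the YES genomes.  The collection
    itself is 200 genomes (not the full published scale) so simulation
    sweeps stay fast; the YES fraction can be matched to any denominator
    via the PPP ``p_override``.
    """

    n_genomes: int = 200
    genes_per_genome: int = 300
    n_yes: int = 14
    paralogs_per_yes_genome: tuple = (1, 12)
    leader_template: Optional[str] = None  # default: 27 random residues + LEADER_TAIL
    leader_substitution_rate: float = 0.05
    core_length_range: tuple = (10, 40)
    core_alphabet_bias: float = 0.5  # combined extra C/S/T/G mass
    companion_family_overlap: int = 9
    hit_noise_sd: float = 2.0
    background_hit_rate: float = 0.1
    background_length_range: tuple = (50, 300)
    context_classes: tuple = ("TOMM", "LANTHIONINE")  # assigned round-robin
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_yes <= self.n_genomes:
            raise ValidationError("require 0 <= n_yes <= n_genomes")
        if not 0 <= self.companion_family_overlap <= self.n_yes:
            raise ValidationError("companion overlap must be <= n_yes")
        lo, hi = self.paralogs_per_yes_genome
        if not 1 <= lo <= hi:
            raise ValidationError("paralog range must satisfy 1 <= lo <= hi")
        for rate in (self.leader_substitution_rate, self.background_hit_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if not 0.0 <= self.core_alphabet_bias <= 1.0:
            raise ValidationError("core_alphabet_bias must lie in [0, 1]")
        if self.genes_per_genome < (hi + 2):
            raise ValidationError("genomes too small to host a planted block")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted alongside a simulated collection."""

    yes_genomes: tuple
    precursor_sites: dict  # protein_id -> true cleavage position
    companion_ids: tuple
    context_classes: dict  # precursor protein_id -> true context class
    leader_template: str
    companion_genomes: tuple


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _AA_BYTES[rng.integers(0, 20, length)].tobytes().decode("ascii")


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """Bulk draw: one buffer for a whole genome, sliced per gene."""
    total = int(lengths.sum())
    buf = _AA_BYTES[rng.integers(0, 20, total)].tobytes().decode("ascii")
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    return [buf[offsets[i]:offsets[i + 1]] for i in range(len(lengths))]


def _mutate(rng: np.random.Generator, template: str, rate: float, frozen_tail: int = 0) -> str:
    """Point-substitute ``template`` at ``rate`` per site, keeping the last
    ``frozen_tail`` residues intact (the cleavage doublet must survive)."""
    chars = np.array(list(template))
    n_mut = len(chars) - frozen_tail
    if n_mut > 0:
        mask = rng.random(n_mut) < rate
        repl = _AA[rng.integers(0, 20, int(mask.sum()))]
        chars[:n_mut][mask] = repl
    return "".join(chars)


def _biased_core(rng: np.random.Generator, length: int, bias: float) -> str:
    """Core residues: with probability ``bias`` from {C,S,T,G}, else uniform."""
    pick = rng.random(length) < bias
    out = _AA[rng.integers(0, 20, length)]
    out[pick] = _CSTG[rng.integers(0, 4, int(pick.sum()))]
    return "".join(out)


def simulate_collection(
    params: SimulationParams,
) -> tuple[GenomeCollection, PresenceTable, PlantedTruth]:
    """Generate the collection, its presence table and the planted truth."""
    params.validate()
    rng = np.random.default_rng([params.seed, 0])

    width = len(str(max(params.n_genomes, 1)))
    genome_ids = [f"G{i:0{width}d}" for i in range(params.n_genomes)]
    yes_idx = np.sort(
        rng.choice(params.n_genomes, size=params.n_yes, replace=False)
    )
    yes_genomes = tuple(genome_ids[i] for i in yes_idx)
    companion_genomes = tuple(yes_genomes[: params.companion_family_overlap])

    leader_template = params.leader_template
    if leader_template is None:
        leader_template = _random_sequence(rng, 40 - len(LEADER_TAIL)) + LEADER_TAIL
    if not leader_template.endswith("GG"):
        raise ValidationError("leader template must end with the Gly-Gly doublet")

    records: list[ProteinRecord] = []
    precursor_sites: dict[str, int] = {}
    context_truth: dict[str, str] = {}
    companion_ids: list[str] = []
    presence_rows: list[tuple[str, str, float, bool]] = []

    lo_par, hi_par = params.paralogs_per_yes_genome
    lo_core, hi_core = params.core_length_range
    lo_bg, hi_bg = params.background_length_range

    for gi, genome_id in enumerate(genome_ids):
        lengths = rng.integers(lo_bg, hi_bg + 1, params.genes_per_genome)
        strands = rng.integers(0, 2, params.genes_per_genome)
        seqs = _random_sequences(rng, lengths)
        annotations: dict[int, frozenset] = {}

        if genome_id in yes_genomes:
            order = list(yes_genomes).index(genome_id)
            context_class = params.context_classes[order % len(params.context_classes)]
            n_par = int(rng.integers(lo_par, hi_par + 1))
            block_len = n_par + 2  # precursors + modification gene + companion slot
            block_start = int(
                rng.integers(0, params.genes_per_genome - block_len + 1)
            )
            # The modification enzyme sits mid-block (as in real clusters),
            # so every paralog stays within a conservative context window.
            left = (n_par + 1) // 2
            precursor_ordinals = [block_start + j for j in range(left)] + [
                block_start + left + 2 + j for j in range(n_par - left)
            ]
            mod_ordinal = block_start + left
            comp_ordinal = block_start + left + 1
            for ordinal in precursor_ordinals:
                leader = _mutate(
                    rng, leader_template, params.leader_substitution_rate, frozen_tail=2
                )
                core = _biased_core(
                    rng,
                    int(rng.integers(lo_core, hi_core + 1)),
                    params.core_alphabet_bias,
                )
                pid = f"{genome_id}.p{ordinal:04d}"
                seqs[ordinal] = leader + core
                annotations[ordinal] = frozenset({PRECURSOR_FAMILY})
                precursor_sites[pid] = len(leader)
                context_truth[pid] = context_class
            mod_label = "CD" if context_class == "TOMM" else "LanM"
            annotations[mod_ordinal] = frozenset({mod_label})
            seqs[mod_ordinal] = _random_sequence(rng, 300)  # enzyme-sized
            if genome_id in companion_genomes:
                annotations[comp_ordinal] = frozenset({COMPANION_FAMILY})
                companion_ids.append(f"{genome_id}.p{comp_ordinal:04d}")
            presence_rows.append(
                (genome_id, PRECURSOR_FAMILY, float(30 + 10 * rng.random()), True)
            )
        else:
            # Below-cutoff noise rows exercise the trusted-cutoff rule.
            if rng.random() < 0.1:
                presence_rows.append(
                    (genome_id, PRECURSOR_FAMILY, float(5 * rng.random()), False)
                )

        if genome_id in companion_genomes:
            presence_rows.append(
                (genome_id, COMPANION_FAMILY, float(30 + 10 * rng.random()), True)
            )

        for ordinal in range(params.genes_per_genome):
            records.append(
                ProteinRecord(
                    protein_id=f"{genome_id}.p{ordinal:04d}",
                    genome_id=genome_id,
                    replicon_id="chr",
                    ordinal=ordinal,
                    strand="+" if strands[ordinal] else "-",
                    sequence=seqs[ordinal],
                    annotations=annotations.get(ordinal, frozenset()),
                )
            )

    # Companion proteins share a conserved sequence family of their own so
    # their hit lists interconnect the overlap genomes.
    companion_template = _random_sequence(rng, 200)
    collection_records = []
    companion_set = set(companion_ids)
    for rec in records:
        if rec.protein_id in companion_set:
            seq = _mutate(rng, companion_template, params.leader_substitution_rate)
            rec = replace(rec, sequence=seq)
        collection_records.append(rec)

    collection = GenomeCollection(collection_records, universe=genome_ids)
    presence = PresenceTable(presence_rows)
    truth = PlantedTruth(
        yes_genomes=yes_genomes,
        precursor_sites=precursor_sites,
        companion_ids=tuple(companion_ids),
        context_classes=context_truth,
        leader_template=leader_template,
        companion_genomes=companion_genomes,
    )
    _audit(collection, truth, params)
    return collection, presence, truth


def _audit(collection: GenomeCollection, truth: PlantedTruth, params: SimulationParams) -> None:
    """Generator self-check: the emitted truth must match the collection."""
    lo, hi = params.paralogs_per_yes_genome
    per_genome: dict[str, int] = {}
    for pid, pos in truth.precursor_sites.items():
        rec = collection.get(pid)
        if rec.sequence[pos - 2:pos] != "GG":
            raise AssertionError(f"planted site lost its doublet: {pid}")
        per_genome[rec.genome_id] = per_genome.get(rec.genome_id, 0) + 1
    for genome_id in truth.yes_genomes:
        if not lo <= per_genome.get(genome_id, 0) <= hi:
            raise AssertionError(f"paralog count out of range in {genome_id}")


def _identity_score(a: str, b: str) -> int:
    """Identical positions over the shared prefix (a BLAST-like proxy)."""
    return sum(x == y for x, y in zip(a, b))


def simulate_hit_lists(
    collection: GenomeCollection,
    truth: PlantedTruth,
    params: SimulationParams,
    query_genomes: Optional[Sequence[str]] = None,
) -> dict[str, HitList]:
    """Ranked hit lists for every protein of the query genomes.

    By default queries span the YES genomes (the profile is queried against
    its YES genomes, as in the discovery method).  Within-family pairs
    score as leader-identical positions plus Gaussian noise; background
    pairs appear per genome with probability ``background_hit_rate`` at low
    scores.  Each query's self-hit is forced to the top with a maximal
    score, and lists are sorted by descending score.
    """
    rng = np.random.default_rng([params.seed, 1])
    if query_genomes is None:
        query_genomes = truth.yes_genomes

    precursor_members = sorted(truth.precursor_sites)
    companion_members = sorted(truth.companion_ids)
    family_of: dict[str, list[str]] = {}
    for pid in precursor_members:
        family_of[pid] = precursor_members
    for pid in companion_members:
        family_of[pid] = companion_members

    genome_ids = list(collection.universe)
    out: dict[str, HitList] = {}
    for genome_id in query_genomes:
        for rec in collection.proteins(genome_id):
            query_id = rec.protein_id
            entries: list[tuple[float, int, Match]] = []
            members = family_of.get(query_id, ())
            leader_len = truth.precursor_sites.get(query_id)
            for other_id in members:
                if other_id == query_id:
                    continue
                other = collection.get(other_id)
                if leader_len is not None:
                    a = rec.sequence[:leader_len]
                    b = other.sequence[: truth.precursor_sites[other_id]]
                else:
                    a, b = rec.sequence, other.sequence
                score = _identity_score(a, b) + rng.normal(0.0, params.hit_noise_sd)
                entries.append(
                    (score, len(entries), Match(other_id, other.genome_id, round(score, 3)))
                )
            # background hits: one candidate per foreign genome at the noise rate
            draws = rng.random(len(genome_ids))
            for g_idx, g in enumerate(genome_ids):
                if g == genome_id or draws[g_idx] >= params.background_hit_rate:
                    continue
                subject = collection.proteins(g)[
                    int(rng.integers(0, len(collection.proteins(g))))
                ]
                score = abs(rng.normal(5.0, params.hit_noise_sd))
                entries.append(
                    (score, len(entries),
                     Match(subject.protein_id, g, round(score, 3)))
                )
            entries.sort(key=lambda t: (-t[0], t[1]))
            self_score = max((t[0] for t in entries), default=0.0) + 50.0
            matches = [Match(query_id, genome_id, round(self_score, 3))]
            matches.extend(m for _, _, m in entries)
            out[query_id] = HitList(query_id, matches)
    return out
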