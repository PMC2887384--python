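"""Genome-context classification of precursor candidates.

A candidate precursor gains functional meaning from its gene neighborhood:
co-clustering with a cyclodehydratase/docking scaffold (labels C, D, CD,
optionally B) marks a thiazole/oxazole (TOMM) cluster, a LanM-like
lanthionine synthase marks a lanthipeptide cluster, and ABC-transporter
genes alone mark an export cassette with no visible modification enzyme.
Distances are measured in ORF ordinals on the same replicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .datamodel import GenomeCollection, ProteinRecord, ValidationError
from .profiles import PhylogeneticProfile

#: Controlled annotation labels and their functional classes.
DEFAULT_LABEL_CLASSES: dict[str, str] = {
    "C": "modification-TOMM",
    "D": "modification-TOMM",
    "CD": "modification-TOMM",
    "B": "modification-TOMM",
    "LanM": "modification-lanthionine",
    "Trans": "transport",
    "Trans-Cleave": "transport",
    "Trans-Fuse": "transport",
    "NHLP": "precursor",
    "NHLP-Burk": "precursor",
    "N11P": "precursor",
    "other": "other",
}

CONTEXT_CLASSES = ("TOMM", "LANTHIONINE", "AMBIGUOUS", "TRANSPORT_ONLY", "ORPHAN")


@dataclass(frozen=True)
class AnnotationVocabulary:
    """Maps free-text gene annotations onto the controlled label set."""

    synonyms: dict = field(default_factory=dict)
    label_classes: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_CLASSES))

    def label(self, annotation: str) -> str:
        if annotation in self.label_classes:
            return annotation
        return self.synonyms.get(annotation, "other")

    def labels_of(self, record: ProteinRecord) -> frozenset:
        return frozenset(self.label(a) for a in record.annotations)


@dataclass(frozen=True)
class Neighbor:
    record: ProteinRecord
    distance: int  # signed ORF-ordinal offset from the query


@dataclass(frozen=True)
class ClusterCall:
    protein_id: str
    context_class: str
    evidence: tuple  # (neighbor protein_id, label, signed distance)
    window: int


def neighborhood(
    collection: GenomeCollection, protein_id: str, window_orfs: int = 10
) -> list[Neighbor]:
    """Same-replicon genes within ``window_orfs`` ordinals of the query,
    excluding the query itself, sorted by signed distance."""
    query = collection.get(protein_id)
    out = []
    for rec in collection.replicon(query.genome_id, query.replicon_id):
        if rec.protein_id == protein_id:
            continue
        dist = rec.ordinal - query.ordinal
        if abs(dist) <= window_orfs:
            out.append(Neighbor(record=rec, distance=dist))
    out.sort(key=lambda nb: nb.distance)
    return out


def classify_context(
    neighbors: Sequence[Neighbor],
    vocabulary: Optional[AnnotationVocabulary] = None,
    protein_id: str = "",
    window: int = 10,
) -> ClusterCall:
    """Classify a candidate from its neighbor label multiset.

    Rules (a pure function of the labels, order-independent):

    * TOMM evidence: CD present, or both C and D, or (C or D) plus B.
    * TOMM              — TOMM evidence and no LanM.
    * LANTHIONINE       — LanM present and no TOMM evidence.
    * AMBIGUOUS         — both machineries visible; the chemical fate of
                          the candidate cannot be called.
    * TRANSPORT_ONLY    — transport labels only.
    * ORPHAN            — none of the above.
    """
    vocabulary = vocabulary or AnnotationVocabulary()
    labels: set[str] = set()
    evidence = []
    for nb in neighbors:
        for lab in sorted(vocabulary.labels_of(nb.record)):
            labels.add(lab)
            evidence.append((nb.record.protein_id, lab, nb.distance))
    tomm = (
        "CD" in labels
        or ("C" in labels and "D" in labels)
        or (("C" in labels or "D" in labels) and "B" in labels)
    )
    lanthionine = "LanM" in labels
    transport = labels & {"Trans", "Trans-Cleave", "Trans-Fuse"}
    if tomm and lanthionine:
        cls = "AMBIGUOUS"
    elif tomm:
        cls = "TOMM"
    elif lanthionine:
        cls = "LANTHIONINE"
    elif transport and labels <= (transport | {"other", "NHLP", "NHLP-Burk", "N11P"}):
        cls = "TRANSPORT_ONLY"
    else:
        cls = "ORPHAN"
    return ClusterCall(
        protein_id=protein_id,
        context_class=cls,
        evidence=tuple(evidence),
        window=window,
    )


def classify_candidate(
    collection: GenomeCollection,
    protein_id: str,
    vocabulary: Optional[AnnotationVocabulary] = None,
    window_orfs: int = 10,
) -> ClusterCall:
    """Convenience wrapper: neighborhood lookup + classification."""
    nbs = neighborhood(collection, protein_id, window_orfs)
    return classify_context(nbs, vocabulary, protein_id=protein_id, window=window_orfs)


def detect_tandem_pairs(
    candidate_ids: Iterable[str],
    collection: GenomeCollection,
    max_gap_orfs: int = 1,
) -> list[tuple[str, str]]:
    """Pairs of candidates adjacent on one replicon (ordinal gap <= max_gap).

    A chain of adjacent candidates yields every consecutive pair, so a
    candidate may appear in several pairs.  Pairs are sorted by genome,
    replicon and position.
    """
    records = sorted(
        (collection.get(pid) for pid in set(candidate_ids)),
        key=lambda r: (r.genome_id, r.replicon_id, r.ordinal),
    )
    pairs = []
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            if (b.genome_id, b.replicon_id) != (a.genome_id, a.replicon_id):
                break
            if b.ordinal - a.ordinal > max_gap_orfs:
                break
            pairs.append((a.protein_id, b.protein_id))
    return pairs


def cooccurrence_report(
    profile_a: PhylogeneticProfile,
    profile_b: PhylogeneticProfile,
    collection: GenomeCollection,
    window_orfs: int = 10,
) -> pd.DataFrame:
    """Per-genome co-occurrence of two families, with a same-neighborhood
    flag set when members of both fall within ``window_orfs`` anywhere.

    Family membership is read from gene annotations matching each
    profile's ``family_id``.
    """
    if profile_a.universe != profile_b.universe:
        raise ValidationError("profiles are defined on different universes")
    rows = []
    for genome_id in profile_a.universe:
        a_yes = profile_a.is_yes(genome_id)
        b_yes = profile_b.is_yes(genome_id)
        near = False
        if a_yes and b_yes:
            members_a = [
                r for r in collection.proteins(genome_id)
                if profile_a.family_id in r.annotations
            ]
            members_b = [
                r for r in collection.proteins(genome_id)
                if profile_b.family_id in r.annotations
            ]
            near = any(
                ra.replicon_id == rb.replicon_id
                and abs(ra.ordinal - rb.ordinal) <= window_orfs
                for ra in members_a
                for rb in members_b
            )
        rows.append(
            {
                "genome_id": genome_id,
                "a_present": int(a_yes),
                "b_present": int(b_yes),
                "both": int(a_yes and b_yes),
                "either": int(a_yes or b_yes),
                "neither": int(not a_yes and not b_yes),
                "same_neighborhood": int(near),
            }
        )
    return pd.DataFrame(rows)


def write_context_report(calls: Sequence[ClusterCall], path) -> None:
    rows = [
        {
            "candidate_id": c.protein_id,
            "context_class": c.context_class,
            "window": c.window,
            "evidence": ";".join(f"{pid}:{lab}:{d:+d}" for pid, lab, d in c.evidence),
        }
        for c in calls
    ]
    frame = pd.DataFrame(rows, columns=["candidate_id", "context_class", "window", "evidence"])
    with open(path, "w") as handle:
        handle.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(handle, sep="\t", header=False, index=False)
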