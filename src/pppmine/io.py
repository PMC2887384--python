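"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
* Protein FASTA with headers ``genome_id|protein_id [free text]`` (the
  delimiter is configurable).
* Gene table TSV: genome_id, replicon_id, protein_id, ordinal, strand,
  and optional start, end, annotations columns.
* Presence table TSV: genome_id, family_id, best_score, above_cutoff.
* Hit table TSV: query_id, subject_id, score — a named-column superset of
  BLAST outfmt-6 columns 1, 2 and 12; extra columns are ignored.

Every TSV carries one header line beginning with ``#``.  All readers are
deterministic: the same bytes always produce the same records in the same
order, and each ``write_x``/``read_x`` pair round-trips exactly up to
whitespace normalisation.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    GenomeCollection,
    HitList,
    Match,
    PresenceTable,
    ProteinRecord,
    ValidationError,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: PathLike,
    delimiter: str = "|",
    genome_map: Optional[Mapping[str, ProteinRecord]] = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA whose headers encode ``genome_id|protein_id``.

    Sequences are uppercased and terminal stop symbols (``*``) stripped.
    When ``genome_map`` is given (protein_id -> existing record, e.g. from a
    gene table), positional fields are taken from it; otherwise records get
    placeholder coordinates (one replicon per genome, file-order ordinals).

    Raises
    ------
    ValidationError
        On a duplicate protein_id, an empty sequence, or a header missing
        the delimiter.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    per_genome_ordinal: dict[str, int] = {}
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        token = seq_rec.id
        if delimiter not in token:
            raise ValidationError(
                f"FASTA header {token!r} lacks the {delimiter!r} delimiter"
            )
        genome_id, protein_id = token.split(delimiter, 1)
        if protein_id in seen:
            raise ValidationError(f"duplicate protein_id {protein_id!r} in FASTA")
        seen.add(protein_id)
        sequence = str(seq_rec.seq).upper().rstrip("*")
        if not sequence:
            raise ValidationError(f"empty sequence for protein {protein_id!r}")
        if genome_map is not None and protein_id in genome_map:
            base = genome_map[protein_id]
            records.append(
                ProteinRecord(
                    protein_id=protein_id,
                    genome_id=base.genome_id,
                    replicon_id=base.replicon_id,
                    ordinal=base.ordinal,
                    strand=base.strand,
                    start=base.start,
                    end=base.end,
                    annotations=base.annotations,
                    sequence=sequence,
                )
            )
        else:
            ordinal = per_genome_ordinal.get(genome_id, 0)
            per_genome_ordinal[genome_id] = ordinal + 1
            records.append(
                ProteinRecord(
                    protein_id=protein_id,
                    genome_id=genome_id,
                    replicon_id="r1",
                    ordinal=ordinal,
                    strand="+",
                    sequence=sequence,
                )
            )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike, delimiter: str = "|") -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.genome_id}{delimiter}{r.protein_id}", description="")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: PathLike, required: list[str]) -> pd.DataFrame:
    """Read a #-headed TSV and check the required columns are present."""
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise ValidationError(f"{path}: expected a header line starting with '#'")
        columns = header.lstrip("#").strip().split("\t")
        body = handle.read()
    if body.strip():
        frame = pd.read_csv(
            _stdio.StringIO(body), sep="\t", names=columns, dtype=str,
            keep_default_na=False,
        )
    else:
        frame = pd.DataFrame(columns=columns)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return frame


def _write_tsv(frame: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(handle, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["genome_id", "replicon_id", "protein_id", "ordinal", "strand"]


def read_gene_table(
    path: PathLike, sequences: Optional[Mapping[str, str]] = None
) -> GenomeCollection:
    """Read a gene table TSV into a :class:`GenomeCollection`.

    ``sequences`` maps protein_id -> amino-acid sequence (e.g. from
    :func:`read_fasta`); proteins absent from it get a one-residue
    placeholder so the table can be used for pure neighborhood analysis.
    The ``annotations`` column is split on commas into a set of labels.
    """
    frame = _read_tsv(path, _GENE_COLUMNS)
    records = []
    for row in frame.itertuples(index=False):
        annotations: frozenset = frozenset()
        if "annotations" in frame.columns and row.annotations:
            annotations = frozenset(
                a for a in row.annotations.split(",") if a
            )
        start = end = None
        if "start" in frame.columns and row.start != "" and row.end != "":
            start, end = int(row.start), int(row.end)
        seq = "M"
        if sequences is not None and row.protein_id in sequences:
            seq = sequences[row.protein_id]
        records.append(
            ProteinRecord(
                protein_id=row.protein_id,
                genome_id=row.genome_id,
                replicon_id=row.replicon_id,
                ordinal=int(row.ordinal),
                strand=row.strand,
                start=start,
                end=end,
                annotations=annotations,
                sequence=seq,
            )
        )
    return GenomeCollection(records)


def write_gene_table(collection: GenomeCollection, path: PathLike) -> None:
    rows = []
    for rec in collection:
        rows.append(
            {
                "genome_id": rec.genome_id,
                "replicon_id": rec.replicon_id,
                "protein_id": rec.protein_id,
                "ordinal": rec.ordinal,
                "strand": rec.strand,
                "start": "" if rec.start is None else rec.start,
                "end": "" if rec.end is None else rec.end,
                "annotations": ",".join(sorted(rec.annotations)),
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=_GENE_COLUMNS + ["start", "end", "annotations"]), path)


# ---------------------------------------------------------------------------
# Presence table
# ---------------------------------------------------------------------------

_PRESENCE_COLUMNS = ["genome_id", "family_id", "best_score", "above_cutoff"]


def read_presence_table(path: PathLike) -> PresenceTable:
    frame = _read_tsv(path, _PRESENCE_COLUMNS)
    return PresenceTable(
        (r.genome_id, r.family_id, float(r.best_score), r.above_cutoff == "1")
        for r in frame.itertuples(index=False)
    )


def write_presence_table(table: PresenceTable, path: PathLike) -> None:
    rows = [
        {
            "genome_id": g,
            "family_id": f,
            "best_score": f"{s:g}",
            "above_cutoff": "1" if a else "0",
        }
        for g, f, s, a in table.rows()
    ]
    _write_tsv(pd.DataFrame(rows, columns=_PRESENCE_COLUMNS), path)


# ---------------------------------------------------------------------------
# Hit table
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ["query_id", "subject_id", "score"]


def read_hit_table(
    path: PathLike, protein_to_genome: Mapping[str, str]
) -> dict[str, HitList]:
    """Read a ranked hit table into per-query :class:`HitList` objects.

    Rows are grouped by query, sorted by descending score with ties kept in
    file order, and each subject is annotated with its source genome via
    ``protein_to_genome``.  Subjects missing from the map are an error.
    """
    frame = _read_tsv(path, _HIT_COLUMNS)
    unknown = sorted(
        {s for s in frame["subject_id"] if s not in protein_to_genome}
    )
    if unknown:
        raise ValidationError(
            f"{path}: subject ids not resolvable to a genome: {unknown[:10]}"
            + ("..." if len(unknown) > 10 else "")
        )
    lists: dict[str, list[tuple[float, int, Match]]] = {}
    for order, row in enumerate(frame.itertuples(index=False)):
        match = Match(
            subject_protein_id=row.subject_id,
            subject_genome_id=protein_to_genome[row.subject_id],
            score=float(row.score),
        )
        lists.setdefault(row.query_id, []).append((-match.score, order, match))
    out: dict[str, HitList] = {}
    for query_id, entries in lists.items():
        entries.sort(key=lambda t: (t[0], t[1]))
        out[query_id] = HitList(query_id, (m for _, _, m in entries))
    return out


def write_hit_table(hit_lists: Mapping[str, HitList], path: PathLike) -> None:
    rows = []
    for query_id in sorted(hit_lists):
        for m in hit_lists[query_id]:
            rows.append(
                {
                    "query_id": query_id,
                    "subject_id": m.subject_protein_id,
                    "score": f"{m.score:g}",
                }
            )
    _write_tsv(pd.DataFrame(rows, columns=_HIT_COLUMNS), path)
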