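import numpy as np
import pytest

from pppmine import GenomeCollection, ProteinRecord


def make_record(
    protein_id,
    genome_id="gA",
    replicon_id="chr",
    ordinal=0,
    strand="+",
    sequence="MAGG",
    annotations=(),
):
    return ProteinRecord(
        protein_id=protein_id,
        genome_id=genome_id,
        replicon_id=replicon_id,
        ordinal=ordinal,
        strand=strand,
        sequence=sequence,
        annotations=frozenset(annotations),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_collection():
    """Two genomes; gA has an annotated neighborhood around ordinal 5."""
    annotations_by_ordinal = {
        3: ("CD",),
        4: ("Trans",),
        6: ("Trans-Cleave",),
        7: ("Trans-Fuse",),
    }
    records = [
        make_record(
            f"gA.p{i}", "gA", "chr", i,
            sequence="M" + "A" * 30,
            annotations=annotations_by_ordinal.get(i, ()),
        )
        for i in range(10)
    ]
    records += [
        make_record(f"gB.p{i}", "gB", "chr", i, sequence="M" + "C" * 30)
        for i in range(4)
    ]
    return GenomeCollection(records)


def random_protein(rng, protein_id, genome_id, ordinal, length):
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = "".join(alphabet[rng.integers(0, 20, length)])
    return make_record(protein_id, genome_id, "chr", ordinal, sequence=seq)
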