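"""End-to-end discovery run: profile -> PPP -> precursor scan -> context.

A run is a pure function of (inputs, config, seed): every output file is
byte-identical across reruns.  Stage timings and progress go to the stderr
logger only, never into output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from . import io as pio
from .context import (
    AnnotationVocabulary,
    classify_candidate,
    cooccurrence_report,
    detect_tandem_pairs,
    write_context_report,
)
from .datamodel import (
    DegenerateProfileError,
    GenomeCollection,
    PresenceTable,
    ValidationError,
)
from .ppp import PPPOptions, ppp_rank_genome, write_ppp_report
from .precursors import ScanParams, scan_proteome, write_candidate_table
from .profiles import build_profile, write_profile_tsv
from .simulate import (
    COMPANION_FAMILY,
    PRECURSOR_FAMILY,
    SimulationParams,
    simulate_collection,
    simulate_hit_lists,
)

logger = logging.getLogger("pppmine")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for :func:`run_discovery`.

    ``inputs`` points at a gene table / FASTA / presence / hit-table set on
    disk; alternatively ``simulate`` requests a synthetic collection.  The
    remaining blocks carry per-stage parameters.  Unknown keys anywhere in
    the file are rejected.
    """

    outdir: str = "pppmine_out"
    seed: int = 0
    log_level: str = "INFO"
    family_id: str = PRECURSOR_FAMILY
    companion_family_id: str = COMPANION_FAMILY
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    ppp: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    context: dict = field(default_factory=dict)

    _BLOCKS = {
        "inputs": {"gene_table", "fasta", "presence_table", "hit_table"},
        "simulate": {f.name for f in dataclasses.fields(SimulationParams)},
        "ppp": {"include_self", "max_depth", "p_override"},
        "scan": {f.name for f in dataclasses.fields(ScanParams)},
        "context": {"window_orfs", "max_gap_orfs"},
    }

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known_top = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known_top
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for block, allowed in cls._BLOCKS.items():
            extra = set(data.get(block, {})) - allowed
            if extra:
                raise ValidationError(
                    f"unknown keys in config block {block!r}: {sorted(extra)}"
                )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_mapping(data)

    def resolved(self) -> dict:
        """Fully-resolved copy (defaults filled) for the run record."""
        out = dataclasses.asdict(self)
        out.pop("outdir")  # a location, not a run parameter
        sim = dataclasses.asdict(self.simulation_params()) if not self.inputs else None
        out["simulate"] = sim
        out["scan"] = dataclasses.asdict(self.scan_params())
        # tuples -> lists so the record is plain YAML
        return json.loads(json.dumps(out))

    def simulation_params(self) -> SimulationParams:
        merged = dict(self.simulate)
        merged.setdefault("seed", self.seed)
        for key in ("paralogs_per_yes_genome", "core_length_range",
                    "background_length_range", "context_classes"):
            if key in merged and isinstance(merged[key], list):
                merged[key] = tuple(merged[key])
        return SimulationParams(**merged)

    def scan_params(self) -> ScanParams:
        merged = dict(self.scan)
        for key in ("doublets", "leader_window"):
            if key in merged and isinstance(merged[key], list):
                merged[key] = tuple(merged[key])
        return ScanParams(**merged)

    def ppp_options(self) -> PPPOptions:
        return PPPOptions(**self.ppp)


@dataclass
class DiscoveryReport:
    """Summary of one discovery run (also written as summary.json)."""

    yes_genomes: list
    n_candidates: int
    n_candidates_pass: int
    context_class_counts: dict
    top_ppp_hits: dict  # genome_id -> (protein_id, ppp_score)
    n_tandem_pairs: int
    outdir: str


def run_discovery(config: RunConfig) -> DiscoveryReport:
    """Execute the full discovery workflow and write per-stage TSVs.

    Stages: build the family profile from the presence table; PPP-rank the
    proteins of every YES genome; scan YES-genome proteomes for precursor
    candidates; classify each passing candidate's genome context; report
    family/companion co-occurrence and tandem precursor pairs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load-inputs"
    try:
        t0 = time.perf_counter()
        collection, presence, hit_lists = _load_inputs(config, outdir)
        logger.info("[%s] %.2fs", stage, time.perf_counter() - t0)

        stage = "profiling"
        t0 = time.perf_counter()
        profile = build_profile(presence, config.family_id, collection.universe)
        if profile.degenerate:
            raise DegenerateProfileError(
                f"profile {config.family_id!r} is degenerate (p = {profile.p})"
            )
        companion_profile = build_profile(
            presence, config.companion_family_id, collection.universe
        )
        write_profile_tsv(profile, outdir / "profile.tsv")
        logger.info("[%s] %.2fs", stage, time.perf_counter() - t0)

        stage = "ppp"
        t0 = time.perf_counter()
        annotations = {
            rec.protein_id: ",".join(sorted(rec.annotations))
            for rec in collection
            if rec.annotations
        }
        options = config.ppp_options()
        top_hits = {}
        for genome_id in sorted(profile.yes_genomes):
            genome_lists = {
                pid: hl
                for pid, hl in hit_lists.items()
                if pid in collection and collection.get(pid).genome_id == genome_id
            }
            if not genome_lists:
                continue
            ranked = ppp_rank_genome(
                genome_id, genome_lists, profile, options, annotations
            )
            write_ppp_report(ranked, outdir / f"ppp_{genome_id}.tsv")
            top_hits[genome_id] = (ranked[0].protein_id, round(ranked[0].ppp_score, 3))
        logger.info("[%s] %.2fs", stage, time.perf_counter() - t0)

        stage = "precursor-scan"
        t0 = time.perf_counter()
        scan_records = [
            rec
            for genome_id in sorted(profile.yes_genomes)
            for rec in collection.proteins(genome_id)
        ]
        candidates = scan_proteome(scan_records, config.scan_params())
        write_candidate_table(candidates, outdir / "candidates.tsv")
        passing = [c for c in candidates if c.passes_all]
        logger.info("[%s] %.2fs", stage, time.perf_counter() - t0)

        stage = "genome-context"
        t0 = time.perf_counter()
        vocab = AnnotationVocabulary()
        window = int(config.context.get("window_orfs", 10))
        max_gap = int(config.context.get("max_gap_orfs", 1))
        calls = []
        class_counts: dict[str, int] = {}
        for pid in sorted({c.protein_id for c in passing}):
            call = classify_candidate(collection, pid, vocab, window)
            calls.append(call)
            class_counts[call.context_class] = class_counts.get(call.context_class, 0) + 1
        write_context_report(calls, outdir / "context.tsv")
        pairs = detect_tandem_pairs(
            [c.protein_id for c in passing], collection, max_gap
        )
        cooc = cooccurrence_report(profile, companion_profile, collection, window)
        with open(outdir / "cooccurrence.tsv", "w") as handle:
            handle.write("#" + "\t".join(cooc.columns) + "\n")
            cooc.to_csv(handle, sep="\t", header=False, index=False)
        logger.info("[%s] %.2fs", stage, time.perf_counter() - t0)
    except (ValidationError, DegenerateProfileError) as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    report = DiscoveryReport(
        yes_genomes=sorted(profile.yes_genomes),
        n_candidates=len(candidates),
        n_candidates_pass=len(passing),
        context_class_counts=dict(sorted(class_counts.items())),
        top_ppp_hits=top_hits,
        n_tandem_pairs=len(pairs),
        outdir=str(outdir),
    )
    summary = dataclasses.asdict(report)
    summary.pop("outdir")  # keep outputs location-independent
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    with open(outdir / "resolved_config.yaml", "w") as handle:
        yaml.safe_dump(config.resolved(), handle, sort_keys=True)
    return report


def _load_inputs(config: RunConfig, outdir: Path):
    """Load on-disk inputs, or synthesise them when ``simulate`` is set."""
    if config.inputs:
        gene_table = config.inputs.get("gene_table")
        fasta = config.inputs.get("fasta")
        presence_path = config.inputs.get("presence_table")
        hits_path = config.inputs.get("hit_table")
        if not all([gene_table, fasta, presence_path, hits_path]):
            raise ValidationError(
                "inputs block needs gene_table, fasta, presence_table and hit_table"
            )
        seq_records = pio.read_fasta(fasta)
        sequences = {r.protein_id: r.sequence for r in seq_records}
        collection = pio.read_gene_table(gene_table, sequences)
        presence = pio.read_presence_table(presence_path)
        hit_lists = pio.read_hit_table(hits_path, collection.protein_to_genome())
        return collection, presence, hit_lists

    params = config.simulation_params()
    collection, presence, truth = simulate_collection(params)
    hit_lists = simulate_hit_lists(collection, truth, params)
    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(exist_ok=True)
    pio.write_gene_table(collection, inputs_dir / "gene_table.tsv")
    pio.write_fasta(collection, inputs_dir / "proteins.fasta")
    pio.write_presence_table(presence, inputs_dir / "presence.tsv")
    pio.write_hit_table(hit_lists, inputs_dir / "hits.tsv")
    return collection, presence, hit_lists
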