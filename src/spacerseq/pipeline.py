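"""End-to-end pipeline orchestration with manifests and determinism.

Two composed runs mirror the two experimental workflows:

* acquisition: simulate barcoded amplicon reads -> demultiplex -> call
  expanded arrays -> map spacers to the phage genome -> summary stats;
* integration: design a BbsI-cassette prespacer -> simulate selected
  colonies -> annotate integration events -> cohort summary.

Every stage draws its randomness from seeds derived deterministically
from the single run seed, and each run writes a JSON manifest (seed,
parameters, a parameter hash and per-stage record counts) sufficient to
re-execute it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import PlasmidFeatureDb, annotate_colonies, events_table, summarize_events
from .calling import call_all, demultiplex
from .io import Read, write_fasta, write_fastq, write_tsv
from .mapping import map_all
from .models import BarcodeSpec
from .simulate import (
    default_cassette,
    default_parent_model,
    design_prespacer,
    make_phage_genome,
    simulate_acquisition_reads,
    simulate_integration_colonies,
)
from .stats import length_distribution, normalize_counts, summarize_mapping

log = logging.getLogger("spacerseq")


class ConfigError(ValueError):
    """A run configuration is missing or malformed."""


@dataclass
class AcquisitionConfig:
    genome_length: int = 20000
    genome_gc: float = 0.35
    n_events: int = 500
    length_weights: dict[int, float] = field(
        default_factory=lambda: {29: 0.05, 30: 0.60, 31: 0.25, 32: 0.10})
    barcodes: dict[str, str] = field(default_factory=lambda: {"S1": "ACG",
                                                              "S2": "TGCA"})
    pcr_mean_duplication: float = 3.0
    error_rate: float = 0.0
    n_parent_spacers: int = 0
    max_repeat_mismatches: int = 2


@dataclass
class IntegrationConfig:
    duplex_length: int = 45
    overhang_left: int = 8
    overhang_right: int = 8
    n_colonies: int = 200
    class_probs: dict[str, float] = field(default_factory=lambda: {
        "full_site_repeat_edge": 0.70, "ectopic_site": 0.10,
        "nonconsecutive_flank": 0.08, "prespacer_end_indel": 0.05,
        "low_quality_trace": 0.07})
    trimmed_length: int | None = None
    read_len: int = 500
    error_rate: float = 0.0
    n_parent_spacers: int = 3


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "spacerseq_run"
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        kwargs = dict(data)
        if "acquisition" in kwargs:
            kwargs["acquisition"] = _sub_config(AcquisitionConfig,
                                                kwargs["acquisition"])
        if "integration" in kwargs:
            kwargs["integration"] = _sub_config(IntegrationConfig,
                                                kwargs["integration"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML/JSON keys are strings; keep length_weights round-trippable
        d["acquisition"]["length_weights"] = {
            str(k): v for k, v in d["acquisition"]["length_weights"].items()}
        return d


def _sub_config(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    extra = set(data) - known
    if extra:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(extra)}")
    data = dict(data)
    if "length_weights" in data:
        data["length_weights"] = {int(k): float(v)
                                  for k, v in data["length_weights"].items()}
    return cls(**data)


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds below 2^31, derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _manifest(path: Path, config: RunConfig, stages: dict) -> dict:
    cfg = config.to_dict()
    payload = json.dumps(cfg, sort_keys=True)
    manifest = dict(tool="spacerseq", version=__version__, config=cfg,
                    parameter_sha256=hashlib.sha256(payload.encode()).hexdigest(),
                    stages=stages)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_acquisition_pipeline(config: RunConfig) -> dict:
    """simulate -> demultiplex -> call -> map -> stats; returns the summary."""
    cfg = config.acquisition
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_genome, s_model, s_reads = _derive_seeds(config.seed, 3)
    stages: dict = {}

    genome = make_phage_genome(cfg.genome_length, cfg.genome_gc, seed=s_genome)
    model = default_parent_model(seed=s_model, n_spacers=cfg.n_parent_spacers)
    barcodes = [BarcodeSpec(sid, bc) for sid, bc in sorted(cfg.barcodes.items())]
    from .simulate.acquisition import geometric_duplication
    reads, truth = simulate_acquisition_reads(
        model, genome, barcodes, cfg.n_events, cfg.length_weights,
        pcr_bias=geometric_duplication(cfg.pcr_mean_duplication),
        error_rate=cfg.error_rate, seed=s_reads)
    write_fasta(genome, out / "genome.fasta")
    model.to_json(out / "array_model.json")
    write_fastq(reads, out / "reads.fastq")
    write_tsv(truth, out / "truth_events.tsv")
    stages["simulate"] = dict(n_events=cfg.n_events, n_reads=len(reads))
    log.info("simulate: %d events -> %d reads", cfg.n_events, len(reads))

    demuxed, rejected = demultiplex(reads, barcodes)
    write_tsv(rejected, out / "rejected_reads.tsv")
    stages["demultiplex"] = dict(n_assigned=len(demuxed), n_rejected=len(rejected))

    calls, call_log = call_all(demuxed, model,
                               max_repeat_mismatches=cfg.max_repeat_mismatches)
    write_tsv(calls, out / "spacer_calls.tsv")
    write_tsv(call_log, out / "call_log.tsv")
    stages["call"] = dict(n_calls=len(calls), n_no_call=len(call_log))

    per_spacer = normalize_counts(calls)
    mapping = map_all(sorted(per_spacer["sequence"].unique()), genome)
    write_tsv(per_spacer, out / "per_spacer.tsv")
    write_tsv(mapping, out / "mapping.tsv")
    stages["map"] = dict(n_unique_spacers=len(mapping))

    mapped_seqs = set(mapping.loc[mapping["hit_count"] >= 1, "spacer"])
    phage_derived = per_spacer[per_spacer["sequence"].isin(mapped_seqs)]
    dists = {sid: dataclasses.asdict(length_distribution(phage_derived, sid))
             for sid in sorted(per_spacer["sample_id"].unique())}
    summary = dict(
        n_reads=len(reads), n_assigned=len(demuxed), n_calls=int(len(calls)),
        n_unique_spacers=int(len(per_spacer)),
        mapping=summarize_mapping(mapping),
        length_distributions=dists)
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    stages["stats"] = dict(n_samples=len(dists))
    _manifest(out / "manifest.json", config, stages)
    return summary


def run_integration_pipeline(config: RunConfig) -> dict:
    """design substrate -> simulate colonies -> annotate -> summarise."""
    cfg = config.integration
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_model, s_sub, s_col = _derive_seeds(config.seed + 1, 3)
    stages: dict = {}

    model = default_parent_model(seed=s_model, n_spacers=cfg.n_parent_spacers)
    substrate = design_prespacer(cfg.duplex_length, cfg.overhang_left,
                                 cfg.overhang_right, with_bbsi=True, seed=s_sub)
    cassette = default_cassette()
    model.to_json(out / "array_model.json")
    substrate.to_json(out / "substrate.json")
    pairs, truth = simulate_integration_colonies(
        model, substrate, cfg.class_probs, cfg.n_colonies,
        read_len=cfg.read_len, error_rate=cfg.error_rate, cassette=cassette,
        trimmed_length=cfg.trimmed_length, seed=s_col)
    write_tsv(truth, out / "truth_colonies.tsv")
    write_fastq([Read(p.colony_id + "/fwd", p.fwd_read, p.fwd_quality)
                 for p in pairs], out / "colonies_fwd.fastq")
    write_fastq([Read(p.colony_id + "/rev", p.rev_read, p.rev_quality)
                 for p in pairs], out / "colonies_rev.fastq")
    stages["simulate"] = dict(n_colonies=len(pairs))

    db = PlasmidFeatureDb(model=model, cassette=cassette)
    events = annotate_colonies(pairs, db, substrate)
    write_tsv(events_table(events), out / "events.tsv")
    summary = summarize_events(events)
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    stages["annotate"] = dict(n_events=len(events), n_kept=summary["n_kept"])
    _manifest(out / "manifest.json", config, stages)
    return summary
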