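"""End-to-end orchestration: simulate -> preprocess -> cluster -> quantify ->
satellites, with per-stage seeds, persisted intermediates and a manifest.

A run is driven by a :class:`RunConfig` (YAML on disk); rerunning with the
same config and seeds reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import __version__
from .clustering import (build_clusters, classify_graph_shape,
                         cluster_representative, cluster_summary,
                         detect_tandem_period, find_overlaps, overlap_graph)
from .preprocess import TrimRule, dedup_long_reads, filter_tags, subsample_tags
from .quantify import (SpikeInControl, TagIndex, assign_tags,
                       calibrate_with_controls, cluster_gc_from_reads,
                       gc_bias_diagnostic, quantify)
from .records import ReadSet
from .satellites import kmer_census, reconstruct_monomer
from .simulate import (GenomeSimSpec, add_spike_ins, build_genome_pair,
                       demo_spec, long_read_config, short_read_config,
                       simulate_reads)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage runs)."""


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with per-stage seeds."""

    out_dir: str = "replowpass_run"
    # simulation
    sim_spec: GenomeSimSpec | None = None       # None -> bundled demo spec
    long_reads_per_sample: int = 450
    short_reads_per_sample: int = 60000
    spike_total_fraction: float = 0.03
    spike_split_male: float = 0.75              # lambda share in male; female mirrored
    # preprocessing
    trim_start: int = 3
    trim_end: int = 32
    min_quality: int = 10
    min_quality_fraction: float = 0.9
    subsample_n: int = 40000
    # clustering
    min_identity: float = 0.90
    min_shorter_coverage: float = 0.55
    # quantification
    max_mismatches: int = 2
    reporting_floor: float = 5e-5
    genome_1c_male: float | None = None         # defaults to simulated sizes
    genome_1c_female: float | None = None
    # satellites
    kmer_k: int = 14
    kmer_range: tuple[int, int] = (10, 17)
    # seeds per stage
    seed_genome: int = 11
    seed_long: int = 12
    seed_short: int = 13
    seed_spike: int = 14
    seed_subsample: int = 15
    seed_diagnostic: int = 16

    def validate(self) -> None:
        checks = [
            (0.5 < self.min_identity <= 1.0, "min_identity must be in (0.5, 1]"),
            (0.0 < self.min_shorter_coverage <= 1.0,
             "min_shorter_coverage must be in (0, 1]"),
            (0 <= self.max_mismatches <= 5, "max_mismatches must be in [0, 5]"),
            (self.trim_end - self.trim_start + 1 >= 10, "trim window too short"),
            (0.0 <= self.min_quality_fraction <= 1.0,
             "min_quality_fraction must be in [0, 1]"),
            (0.0 <= self.spike_total_fraction < 0.5,
             "spike_total_fraction must be in [0, 0.5)"),
            (0.0 <= self.spike_split_male <= 1.0,
             "spike_split_male must be in [0, 1]"),
            (self.kmer_range[0] >= 10 and self.kmer_range[1] <= 17
             and self.kmer_range[0] <= self.kmer_k <= self.kmer_range[1],
             "k-mer length must lie within [10, 17]"),
            (self.subsample_n > 0, "subsample_n must be positive"),
            (self.long_reads_per_sample > 0, "long_reads_per_sample must be positive"),
            (self.short_reads_per_sample >= self.subsample_n,
             "short_reads_per_sample must cover subsample_n"),
            (self.reporting_floor >= 0, "reporting_floor must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if self.sim_spec is not None:
            try:
                self.sim_spec.validate()
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if self.sim_spec is not None:
            data["sim_spec"] = _spec_to_dict(self.sim_spec)
        data["kmer_range"] = list(self.kmer_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("sim_spec") is not None:
            data["sim_spec"] = _spec_from_dict(data["sim_spec"])
        if "kmer_range" in data:
            data["kmer_range"] = tuple(data["kmer_range"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _spec_to_dict(spec: GenomeSimSpec) -> dict:
    from .simulate import RepeatFamilySpec
    d = asdict(spec)
    return d


def _spec_from_dict(data: dict) -> GenomeSimSpec:
    from .simulate import RepeatFamilySpec
    fams = tuple(
        RepeatFamilySpec(**{**f, "monomer_variants":
                            tuple(tuple(v) for v in f.get("monomer_variants", ()))})
        for f in data["families"]
    )
    rest = {k: v for k, v in data.items() if k != "families"}
    return GenomeSimSpec(families=fams, **rest)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage order: genome simulation, long-read simulation + dedup, overlap
    clustering, short-read simulation + spike-ins, tag extraction and
    subsampling, tag assignment + quantification + calibration + GC
    diagnostic, satellite reconstruction for globular clusters.  Any stage
    failure aborts with the stage name in the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "files": {}}
    conservation: dict = {}

    def _stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    try:
        stage = "simulate_genomes"
        _stage(stage)
        spec = config.sim_spec or demo_spec(seed=config.seed_genome)
        pair = build_genome_pair(spec)
        rio.write_fasta(out / "genome_male.fasta", [("male_1C", pair.male)])
        rio.write_fasta(out / "genome_female.fasta", [("female_1C", pair.female)])
        pair.layout.to_csv(out / "truth_layout.tsv", sep="\t", index=False)
        pair.proportions.to_csv(out / "truth_proportions.tsv", sep="\t", index=False)

        stage = "simulate_long_reads"
        _stage(stage)
        long_reads = []
        for sex, genome, seed in (("male", pair.male, config.seed_long),
                                  ("female", pair.female, config.seed_long + 1)):
            cfg = long_read_config(config.long_reads_per_sample, seed=seed)
            long_reads.extend(simulate_reads(genome, cfg, prefix=f"{sex[0]}L",
                                             sample=sex))
        deduped, n_removed = dedup_long_reads(long_reads)
        conservation["long_reads_total"] = len(long_reads)
        conservation["long_reads_deduped"] = len(deduped)
        conservation["long_duplicates_removed"] = n_removed
        rio.write_fasta(out / "long_reads.fasta", deduped)
        seqs = {r.id: r.bases for r in deduped}

        stage = "cluster_long_reads"
        _stage(stage)
        edges = find_overlaps(deduped, config.min_identity,
                              config.min_shorter_coverage)
        clusters, singletons = build_clusters([r.id for r in deduped], edges)
        graph = overlap_graph(list(seqs), edges)
        for cl in clusters:
            cl.shape_class = classify_graph_shape(cl, graph)
            rep = cluster_representative(cl, seqs)
            cl.tandem_period = detect_tandem_period(seqs[rep])
        rio.write_edges_tsv(out / "edges.tsv", edges)
        rio.write_membership_tsv(out / "clusters.tsv", clusters)
        summary = cluster_summary(clusters, len(deduped))
        summary["shape"] = [cl.shape_class for cl in
                            sorted(clusters, key=lambda c: (-c.size, c.id))]
        summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
        cluster_dir = out / "cluster_reads"
        cluster_dir.mkdir(exist_ok=True)
        for cl in clusters[:50]:
            rio.write_fasta(cluster_dir / f"{cl.id}.fasta",
                            [(rid, seqs[rid]) for rid in cl.members])
        conservation["clusters"] = len(clusters)
        conservation["singletons"] = len(singletons)

        stage = "simulate_short_reads"
        _stage(stage)
        split = {"male": (config.spike_split_male, 1 - config.spike_split_male),
                 "female": (1 - config.spike_split_male, config.spike_split_male)}
        control_names = sorted(pair.controls)
        tag_pools: dict[str, list[str]] = {}
        spike_truth: dict[str, dict[str, float]] = {}
        for i, (sex, genome) in enumerate((("male", pair.male),
                                           ("female", pair.female))):
            cfg = short_read_config(config.short_reads_per_sample,
                                    seed=config.seed_short + i)
            pool = simulate_reads(genome, cfg, prefix=f"{sex[0]}S", sample=sex)
            if pair.controls and config.spike_total_fraction > 0:
                fracs = {name: config.spike_total_fraction * share
                         for name, share in zip(control_names, split[sex])}
                pool, truth = add_spike_ins(pool, pair.controls, fracs, cfg,
                                            seed=config.seed_spike + i)
                spike_truth[sex] = truth
            rio.write_fastq(out / f"short_reads_{sex}.fastq", pool)

            stagep = "preprocess_tags"
            manifest["stages"][stagep] = "ok"
            rule = TrimRule(config.trim_start, config.trim_end,
                            config.min_quality, config.min_quality_fraction)
            tags, stats = filter_tags(pool, rule)
            conservation[f"tags_{sex}_raw"] = len(pool)
            conservation[f"tags_{sex}_accepted"] = stats["accepted"]
            tags = subsample_tags(tags, min(config.subsample_n, len(tags)),
                                  seed=config.seed_subsample + i)
            conservation[f"tags_{sex}_sampled"] = len(tags)
            rio.write_tags_tsv(out / f"tags_{sex}.tsv", tags, prefix=f"{sex[0]}T")
            tag_pools[sex] = tags

        stage = "quantify"
        _stage(stage)
        cluster_of = {rid: cl.id for cl in clusters for rid in cl.members}
        # control reference clusters from dedicated control-derived long reads
        ctrl_reads: dict[str, str] = {}
        ctrl_cluster_of: dict[str, str] = {}
        ctrl_cluster_ids: dict[str, str] = {}
        for j, name in enumerate(control_names):
            cfg = long_read_config(
                max(40, int(3 * len(pair.controls[name]) / 250)),
                seed=config.seed_long + 100 + j, duplicate_rate=0.0)
            creads = simulate_reads(pair.controls[name], cfg, prefix=f"ctl{j}")
            cid = f"CTRL{j + 1}"
            ctrl_cluster_ids[name] = cid
            for r in creads:
                ctrl_reads[r.id] = r.bases
                ctrl_cluster_of[r.id] = cid
        index = TagIndex({**seqs, **ctrl_reads},
                         {**cluster_of, **ctrl_cluster_of},
                         max_mismatches=config.max_mismatches)
        counts = {}
        assignment: dict[str, list[str | None]] = {}
        for sex in ("male", "female"):
            hits = [index.assign(t) for t in tag_pools[sex]]
            assignment[sex] = [h[0] if h else None for h in hits]
            counts[sex] = Counter(c for c in assignment[sex] if c is not None)
            conservation[f"tags_{sex}_assigned"] = sum(counts[sex].values())
            conservation[f"tags_{sex}_unassigned"] = sum(
                1 for c in assignment[sex] if c is None)
        gc = cluster_gc_from_reads(clusters, seqs)
        for name, cid in ctrl_cluster_ids.items():
            members = [r for r, c in ctrl_cluster_of.items() if c == cid]
            gc[cid] = float(np.mean([_gc(ctrl_reads[r]) for r in members]))
        table = quantify(counts["male"], counts["female"],
                         len(tag_pools["male"]), len(tag_pools["female"]),
                         cluster_gc=gc, reporting_floor=config.reporting_floor)
        controls = [
            SpikeInControl(name,
                           spike_truth.get("male", {}).get(name, 0.0),
                           spike_truth.get("female", {}).get(name, 0.0))
            for name in control_names
        ]
        calib = None
        if controls and spike_truth:
            calib = calibrate_with_controls(table, controls, ctrl_cluster_ids)
            table["flagged"] = table["cluster_id"].isin(calib.flagged)
            ctrl_rows = pd.DataFrame([
                {"control": c.name, "expected_male": c.expected_male,
                 "expected_female": c.expected_female,
                 "observed_male": c.observed_male,
                 "observed_female": c.observed_female,
                 "expected_mf": c.expected_mf, "observed_mf": c.observed_mf}
                for c in calib.controls])
            ctrl_rows.to_csv(out / "controls.tsv", sep="\t", index=False)
        table.to_csv(out / "proportions.tsv", sep="\t", index=False)
        try:
            diag = gc_bias_diagnostic(table, seed=config.seed_diagnostic)
            (out / "gc_bias.json").write_text(json.dumps(
                {"rho": diag.rho, "p_value": diag.p_value,
                 "n_clusters": diag.n_clusters, "defined": diag.defined}))
        except ValueError:
            (out / "gc_bias.json").write_text(json.dumps({"defined": False}))

        stage = "satellites"
        _stage(stage)
        sat_dir = out / "satellites"
        sat_dir.mkdir(exist_ok=True)
        consensus_records = []
        cluster_by_id = {cl.id: cl for cl in clusters}
        for cl in clusters:
            if cl.shape_class != "globular":
                continue
            assigned = [t for sex in ("male", "female")
                        for t, c in zip(tag_pools[sex], assignment[sex])
                        if c == cl.id]
            if len(assigned) < 50:
                continue
            spectrum = kmer_census(assigned, config.kmer_k)
            monomer = reconstruct_monomer(spectrum)
            if monomer is None:
                continue
            consensus_records.append(
                (f"{cl.id}|len={monomer.length}|k={config.kmer_k}"
                 f"|circular={monomer.circular}", monomer.sequence))
            sup = pd.DataFrame({"position": range(monomer.length),
                                "base": list(monomer.sequence),
                                "support": monomer.support})
            sup.to_csv(sat_dir / f"{cl.id}_support.tsv", sep="\t", index=False)
        if consensus_records:
            rio.write_fasta(sat_dir / "consensus.fasta", consensus_records)

        stage = "manifest"
        _stage(stage)
        manifest["conservation"] = conservation
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest["files"][str(path.relative_to(out))] = _sha256(path)
        manifest["config"] = yaml.safe_load(_config_yaml(config))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _config_yaml(config: RunConfig) -> str:
    data = asdict(config)
    if config.sim_spec is not None:
        data["sim_spec"] = _spec_to_dict(config.sim_spec)
    data["kmer_range"] = list(config.kmer_range)
    return yaml.safe_dump(data, sort_keys=True)


def _gc(seq: str) -> float:
    from ._seq import gc_content
    return gc_content(seq)


def demo_config(out_dir: str, seed: int = 11) -> RunConfig:
    """Small bundled demo: full pipeline in well under a minute."""
    return RunConfig(
        out_dir=out_dir,
        sim_spec=None,
        long_reads_per_sample=130,
        short_reads_per_sample=30000,
        subsample_n=25000,
        seed_genome=seed,
        seed_long=seed + 1,
        seed_short=seed + 2,
        seed_spike=seed + 3,
        seed_subsample=seed + 4,
        seed_diagnostic=seed + 5,
    )
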