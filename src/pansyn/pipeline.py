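"""End-to-end pipeline: clustering -> graph building -> (optional)
chromosomization -> pattern detection, with shared configuration, logging
and deterministic seeding."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import yaml

from . import chromosomize as chrom
from . import clustering, io_formats, pangraph, patterns
from .model import (
    CascadeConfig,
    ClusterSet,
    DEFAULT_THRESHOLDS,
    PartitionThresholds,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_all", "PipelineResult"]


class ConfigError(ValueError):
    """All configuration violations, reported together."""


@dataclass
class RunConfig:
    """Validated run parameters with the pipeline's defaults applied."""

    gff_dir: Optional[Path] = None
    proteins: Optional[Path] = None
    out_dir: Optional[Path] = None
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    retention_mode: str = "protein_count"
    hard: float = 0.99
    soft: float = 0.95
    shell: float = 0.15
    w_min: int = 1
    template_file: Optional[Path] = None
    circular_contigs_file: Optional[Path] = None
    max_insertion_len: int = 10
    max_cycle_len: int = 100
    seed: int = 42
    verbosity: str = "info"

    def partition_thresholds(self) -> PartitionThresholds:
        return PartitionThresholds(hard=self.hard, soft=self.soft, shell=self.shell)


_CONFIG_KEYS = {
    "gff_dir",
    "proteins",
    "out_dir",
    "thresholds",
    "retention_mode",
    "hard",
    "soft",
    "shell",
    "w_min",
    "template_file",
    "circular_contigs_file",
    "max_insertion_len",
    "max_cycle_len",
    "seed",
    "verbosity",
}

_PATH_KEYS = ("gff_dir", "proteins", "template_file", "circular_contigs_file")


def validate_config(source) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a mapping,
    applying defaults and aggregating every violation into one error."""
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {source} must hold key: value pairs")
    errors: List[str] = []
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        errors.append(f"unknown config keys: {', '.join(unknown)}")
        for key in unknown:
            data.pop(key)
    if isinstance(data.get("thresholds"), str):
        try:
            data["thresholds"] = [float(t) for t in data["thresholds"].split(",")]
        except ValueError:
            errors.append(f"unparsable thresholds {data['thresholds']!r}")
            data.pop("thresholds")
    for key in _PATH_KEYS + ("out_dir",):
        if data.get(key) is not None:
            data[key] = Path(data[key])
    cfg = RunConfig(**{k: v for k, v in data.items() if k in _CONFIG_KEYS})
    try:
        cfg.partition_thresholds()
    except ValueError as exc:
        errors.append(str(exc))
    try:
        CascadeConfig(n_genomes=1, thresholds=cfg.thresholds,
                      retention_mode=cfg.retention_mode, seed=cfg.seed)
    except ValueError as exc:
        errors.append(str(exc))
    if cfg.w_min < 1:
        errors.append(f"w_min must be >= 1, got {cfg.w_min}")
    for key in _PATH_KEYS:
        value = getattr(cfg, key)
        if value is not None and not Path(value).exists():
            errors.append(f"{key}: path {value} does not exist")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


@dataclass
class PipelineResult:
    genomes: List[str]
    cluster_set: ClusterSet
    strain_graphs: Dict[str, nx.Graph]
    pangenome: nx.Graph
    report: patterns.PatternReport
    assignment: Optional[Dict[str, str]] = None
    counts: Dict[str, int] = field(default_factory=dict)


def _read_inputs(cfg: RunConfig):
    gff_paths = sorted(
        p for p in Path(cfg.gff_dir).iterdir() if p.suffix in (".gff", ".gff3")
    )
    if not gff_paths:
        raise ConfigError(f"no .gff/.gff3 files in {cfg.gff_dir}")
    records = {p.stem: io_formats.read_gff3(p, p.stem) for p in gff_paths}
    proteins = io_formats.read_protein_fasta(cfg.proteins)
    for genome, recs in records.items():
        proteins.assign_genomes(recs)
        missing = [r.locus_id for r in recs if r.locus_id not in proteins]
        if missing:
            raise ConfigError(
                f"genome {genome}: {len(missing)} loci lack protein sequences "
                f"(e.g. {missing[0]!r})"
            )
    circular = set()
    if cfg.circular_contigs_file:
        with open(cfg.circular_contigs_file) as fh:
            circular = {line.strip() for line in fh if line.strip()}
    return records, proteins, circular


def run_all(cfg: RunConfig) -> PipelineResult:
    """Execute cluster -> build -> (chromosomize) -> patterns and write all
    artifacts plus a run log under ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    log_lines = [f"seed={cfg.seed}", f"w_min={cfg.w_min}",
                 f"thresholds={','.join(map(str, cfg.thresholds))}",
                 f"partitions={cfg.hard}/{cfg.soft}/{cfg.shell}"]
    try:
        records, proteins, circular = _read_inputs(cfg)
        genomes = sorted(records)
        n_genomes = len(genomes)
        log_lines.append(f"genomes={n_genomes} proteins={len(proteins)}")

        stage = "cluster"
        cascade = CascadeConfig(
            n_genomes=n_genomes,
            thresholds=cfg.thresholds,
            retention_mode=cfg.retention_mode,
            seed=cfg.seed,
        )
        cluster_set = clustering.iterative_cluster(proteins, cascade)
        products = {
            rec.locus_id: rec.product for recs in records.values() for rec in recs
        }
        clustering.write_cluster_file(cluster_set, out_dir / "clusters.tsv")
        clustering.write_representative_fasta(
            cluster_set, proteins, out_dir / "representatives.faa", products
        )
        log_lines.append(f"clusters={len(cluster_set)}")

        stage = "build"
        cluster_of = cluster_set.cluster_of()
        strain_graphs = {
            g: pangraph.build_strain_graph(records[g], cluster_of, circular)
            for g in genomes
        }
        pangenome, relabelled, submap = pangraph.build_pangenome(
            strain_graphs,
            cluster_set,
            n_genomes,
            w_min=cfg.w_min,
            thresholds=cfg.partition_thresholds(),
        )
        log_lines.append(
            f"subclusters={pangenome.number_of_nodes()} "
            f"edges={pangenome.number_of_edges()}"
        )

        stage = "chromosomize"
        assignment = None
        if cfg.template_file:
            templates = chrom.read_templates(cfg.template_file)
            assignment = chrom.assign_chromosomes(templates, relabelled, pangenome)
            chrom.chromosomize_graphs(assignment, relabelled, pangenome)
            log_lines.append(
                "chromosomized="
                + str(sum(1 for v in assignment.values() if v != "unknown"))
            )

        stage = "write_graphs"
        for g in genomes:
            io_formats.write_graph(relabelled[g], out_dir / f"strain_{g}.graphml")
        io_formats.write_graph(pangenome, out_dir / "pangenome.graphml")
        io_formats.write_presence_absence(
            pangenome, out_dir / "presence_absence.tsv", genomes
        )

        stage = "patterns"
        report = patterns.detect_patterns(
            pangenome,
            max_insertion_len=cfg.max_insertion_len,
            max_cycle_len=cfg.max_cycle_len,
        )
        patterns.write_pattern_outputs(report, pangenome, out_dir / "patterns")
        counts = {
            "genomes": n_genomes,
            "proteins": len(proteins),
            "clusters": len(cluster_set),
            "subclusters": pangenome.number_of_nodes(),
            "edges": pangenome.number_of_edges(),
            "orphans": len(report.orphans),
            "uniques": len(report.uniques),
            "variant_groups": len(report.variants),
            "insertions": len(report.insertions),
            "indels": len(report.indels),
        }
        log_lines.append(
            "patterns=" + ",".join(f"{k}:{v}" for k, v in sorted(counts.items()))
        )
    except Exception:
        (out_dir / "run_log.txt").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}"]) + "\n"
        )
        logger.exception("pipeline failed at stage %s", stage)
        raise
    (out_dir / "run_log.txt").write_text("\n".join(log_lines + ["status=ok"]) + "\n")
    return PipelineResult(
        genomes=genomes,
        cluster_set=cluster_set,
        strain_graphs=relabelled,
        pangenome=pangenome,
        report=report,
        assignment=assignment,
        counts=counts,
    )
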