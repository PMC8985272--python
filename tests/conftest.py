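"""Shared fixtures: synthetic cohorts at several sizes and one full
pipeline run on the reference cohort, shared session-wide."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import networkx as nx
import pytest

from pansyn.fixtures import Cohort, FixtureConfig, Replicon, generate_cohort
from pansyn.pipeline import PipelineResult, run_all, validate_config


@dataclass
class CohortRun:
    cohort: Cohort
    result: PipelineResult
    data_dir: Path
    out_dir: Path


def run_cohort(cohort: Cohort, base_dir: Path, w_min=None, seed=None) -> CohortRun:
    data = cohort.write(base_dir / "data")
    cfg = validate_config(
        dict(
            gff_dir=str(data),
            proteins=str(data / "proteins.faa"),
            out_dir=str(base_dir / "out"),
            w_min=w_min if w_min is not None else cohort.config.min_edge_weight,
            circular_contigs_file=str(data / "circular_contigs.txt"),
            template_file=str(data / "templates.tsv")
            if cohort.templates
            else None,
            seed=seed if seed is not None else cohort.config.seed,
        )
    )
    result = run_all(cfg)
    return CohortRun(cohort, result, data, base_dir / "out")


@pytest.fixture(scope="session")
def reference_cohort() -> Cohort:
    """The 20-genome reference cohort: 400-gene circular backbone with all
    pattern classes planted (generator defaults, fixed seed)."""
    return generate_cohort(FixtureConfig(seed=42))


@pytest.fixture(scope="session")
def reference_run(reference_cohort, tmp_path_factory) -> CohortRun:
    base = tmp_path_factory.mktemp("reference_run")
    return run_cohort(reference_cohort, base)


SMALL_CONFIG = FixtureConfig(
    n_genomes=5,
    replicons=(Replicon("chromosome_1", 80, True),),
    n_uniques=1,
    n_orphans=1,
    orphan_carriers=2,
    n_variant_pairs=1,
    n_insertions=1,
    insertion_carriers=2,
    insertion_length=2,
    n_indel_loops=1,
    indel_carriers=2,
    n_paralog_families=1,
    seed=3,
)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A 5-genome cohort small enough for brute-force oracles."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_run(small_cohort, tmp_path_factory) -> CohortRun:
    base = tmp_path_factory.mktemp("small_run")
    return run_cohort(small_cohort, base)


def brute_force_edge_weights(cohort: Cohort, strain_graphs: Dict[str, nx.Graph]):
    """Independent recount of pangenome edge weights: iterate every
    genome's consecutive locus pairs (from the raw gene records, honouring
    circular contigs) and count genomes per unordered subcluster pair."""
    from collections import defaultdict

    weights = defaultdict(set)
    for genome, records in cohort.records.items():
        label_of = {
            locus: strain_graphs[genome].nodes[locus]["subcluster"]
            for locus in strain_graphs[genome].nodes
        }
        per_contig = defaultdict(list)
        for rec in records:
            per_contig[rec.contig_id].append(rec)
        for contig, recs in per_contig.items():
            recs = sorted(recs, key=lambda r: r.ordinal)
            pairs = list(zip(recs, recs[1:]))
            if contig in cohort.circular_contigs and len(recs) > 2:
                pairs.append((recs[-1], recs[0]))
            for a, b in pairs:
                key = tuple(sorted((label_of[a.locus_id], label_of[b.locus_id])))
                weights[key].add(genome)
    return {pair: len(genomes) for pair, genomes in weights.items()}
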