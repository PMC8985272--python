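"""Synthetic annotated-genome cohorts with planted structural patterns.

The generator emulates the inputs of the pipeline — one GFF3 per genome
plus a pooled protein FASTA — for a cohort of strains sharing a collinear
core backbone, into which structures of every detectable pattern class
are planted at controlled positions:

* **uniques** — a novel gene in exactly one genome;
* **orphans** — a shared gene placed at unrelated positions in each
  carrier genome, so all of its adjacencies are supported by one genome
  only and vanish under the cohort's minimum-edge-weight filter;
* **variant pairs** — two alleles of one genomic slot, mutually below the
  70% clustering floor, split across two genome subsets;
* **insertions** — a contiguous run of novel genes between fixed anchors
  in a small carrier subset (the anchors stay directly adjacent in all
  other genomes);
* **InDel loops** — two alternative paths between anchors segregating
  across genome subsets, closing a cycle of more than four nodes;
* **paralog families** — one protein repeated at several distinct flank
  contexts in every genome, exercising neighbourhood subcluster
  splitting (and, with contexts on different replicons, the
  "undetermined" replicon class).

Backbone proteins are independent random sequences (pairwise identity
around the 5% random-composition floor, far below the 70% clustering
threshold), so no accidental co-clustering occurs; this is checked during
generation. A machine-readable truth manifest records every planted
structure with its expected pattern class, partition and replicon class.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .chromosomize import ReplicionTemplate, write_templates
from .clustering import sequence_identity
from .model import GeneRecord, PartitionThresholds, ProteinSet

__all__ = [
    "FixtureConfig",
    "PlantedStructure",
    "Cohort",
    "mutate_protein",
    "generate_cohort",
    "read_manifest",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Replicon:
    label: str
    n_genes: int
    circular: bool = True


@dataclass
class FixtureConfig:
    """Cohort layout and planted-structure counts.

    Defaults describe the reference cohort used throughout the test
    suite: 20 genomes over one 400-gene circular chromosome, with planted
    counts covering every pattern class, designed to be recovered under a
    minimum edge weight of 2 (``min_edge_weight``) — the support filter
    that isolates randomly-placed orphans and strips single-genome
    adjacencies.
    """

    n_genomes: int = 20
    replicons: Tuple[Replicon, ...] = (Replicon("chromosome_1", 400, True),)
    n_uniques: int = 5
    n_orphans: int = 3
    orphan_carriers: int = 3
    n_variant_pairs: int = 4
    n_insertions: int = 4
    insertion_carriers: int = 4
    insertion_length: int = 3
    n_indel_loops: int = 3
    indel_loop_length: int = 6
    indel_carriers: int = 8
    n_paralog_families: int = 2
    paralog_contexts: int = 2
    n_cross_replicon_repeats: int = 0
    variant_identity: float = 0.40
    protein_length: int = 120
    min_edge_weight: int = 2
    with_templates: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.n_indel_loops and self.indel_loop_length < 5:
            raise ValueError("InDel loops must span more than four nodes")
        for count, carriers in (
            (self.n_orphans, self.orphan_carriers),
            (self.n_insertions, self.insertion_carriers),
            (self.n_indel_loops, self.indel_carriers),
        ):
            if count and not (1 <= carriers <= self.n_genomes):
                raise ValueError("carrier counts must lie in 1..n_genomes")
        if self.n_orphans and self.orphan_carriers < 2:
            raise ValueError("orphans need at least two carrier genomes")
        if self.n_uniques and self.n_genomes < 2:
            raise ValueError("uniques need a cohort of at least two genomes")
        if self.n_indel_loops and self.indel_carriers >= self.n_genomes:
            raise ValueError("InDel loops need a non-carrier genome subset")
        if not (0.0 < self.variant_identity < 0.70):
            raise ValueError("variant alleles must diverge below the 0.70 tier")
        if self.n_cross_replicon_repeats and len(self.replicons) < 2:
            raise ValueError("cross-replicon repeats need >= 2 replicons")


@dataclass
class PlantedStructure:
    """One manifest entry: a planted cluster slot and what the pipeline is
    expected to make of it."""

    structure_id: str
    stype: str
    slot: str
    loci: Tuple[str, ...]
    carriers: Tuple[str, ...]
    expected_pattern: str
    expected_partition: str
    expected_chromosome: str
    expected_subclusters: int = 1


@dataclass
class Cohort:
    """A generated cohort: in-memory records plus writers for the on-disk
    formats the pipeline consumes."""

    config: FixtureConfig
    genomes: List[str]
    records: Dict[str, List[GeneRecord]]
    proteins: ProteinSet
    circular_contigs: set
    templates: List[ReplicionTemplate]
    manifest: List[PlantedStructure]
    slot_loci: Dict[str, Tuple[str, ...]]
    clades: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    clade_gene_loci: Dict[str, Tuple[str, ...]] = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for genome in self.genomes:
            write_gff3(self.records[genome], out_dir / f"{genome}.gff")
        write_protein_fasta(self.proteins, out_dir / "proteins.faa")
        with open(out_dir / "circular_contigs.txt", "w") as fh:
            for contig in sorted(self.circular_contigs):
                fh.write(contig + "\n")
        if self.templates:
            write_templates(self.templates, out_dir / "templates.tsv")
        write_manifest(self.manifest, out_dir / "manifest.tsv")
        with open(out_dir / "clades.tsv", "w") as fh:
            for clade in sorted(self.clades):
                for genome in sorted(self.clades[clade]):
                    fh.write(f"{clade}\t{genome}\n")
        with open(out_dir / "clade_genes_loci.tsv", "w") as fh:
            for clade in sorted(self.clade_gene_loci):
                for locus in sorted(self.clade_gene_loci[clade]):
                    fh.write(f"{clade}\t{locus}\n")
        return out_dir

    def slot_nodes(
        self, strain_graphs: Mapping[str, nx.Graph], slot: str
    ) -> set:
        """Pangenome node IDs a planted slot resolved to (several for a
        split paralog family)."""
        nodes = set()
        for locus in self.slot_loci[slot]:
            genome = self.proteins.genome_of[locus]
            nodes.add(strain_graphs[genome].nodes[locus]["subcluster"])
        return nodes


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Substitute residues (no indels) to hit a target identity +/- 0.02.

    With equal lengths and substitution-only edits, identity is exact-
    position matching, so the achieved value is (L - m) / L for m
    substituted positions.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target identity must lie in (0, 1]")
    length = len(seq)
    n_sub = round((1.0 - target_identity) * length)
    achieved = (length - n_sub) / length
    if abs(achieved - target_identity) > 0.02:
        raise ValueError(
            f"cannot reach identity {target_identity} within +/-0.02 on a "
            f"{length}-residue sequence; use a longer seed sequence"
        )
    if n_sub == 0:
        return seq
    rng = random.Random(seed)
    positions = rng.sample(range(length), n_sub)
    chars = list(seq)
    for pos in positions:
        chars[pos] = rng.choice([a for a in AMINO_ACIDS if a != seq[pos]])
    return "".join(chars)


def _check_backbone_divergence(sequences: List[str]) -> None:
    """Assert backbone proteins are mutually far below the clustering
    floor (exact-position identity over equal lengths)."""
    if len(sequences) < 2:
        return
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(sequences), -1)
    sims = (arr[:, None, :] == arr[None, :, :]).mean(axis=2)
    np.fill_diagonal(sims, 0.0)
    worst = float(sims.max())
    if worst >= 0.60:
        raise RuntimeError(
            f"backbone proteins unexpectedly similar (identity {worst:.2f})"
        )


def _allocate_boundaries(
    pool: List[int], count: int, taken: List[int], rng: random.Random, spacing: int = 3
) -> List[int]:
    """Pick ``count`` insertion boundaries at least ``spacing`` apart from
    each other and from already-taken ones."""
    if count == 0:
        return []
    chosen: List[int] = []
    candidates = pool[:]
    rng.shuffle(candidates)
    for pos in candidates:
        if all(abs(pos - t) >= spacing for t in taken + chosen):
            chosen.append(pos)
            if len(chosen) == count:
                taken.extend(chosen)
                return chosen
    raise ValueError(
        "backbone too small for the requested planted structures "
        f"(needed {count} more boundaries with spacing {spacing})"
    )


def generate_cohort(cfg: FixtureConfig) -> Cohort:
    """Generate a cohort deterministically under ``cfg.seed``."""
    rng = random.Random(cfg.seed)
    genomes = [f"g{i + 1:02d}" for i in range(cfg.n_genomes)]
    template_genome = genomes[0]
    thresholds = PartitionThresholds()

    # --- backbone proteins --------------------------------------------------
    seq_table: Dict[str, str] = {}
    products: Dict[str, str] = {}
    backbone: Dict[int, List[str]] = {}
    backbone_seqs = []
    for r_idx, rep in enumerate(cfg.replicons):
        keys = [f"bb{r_idx}_{i:04d}" for i in range(rep.n_genes)]
        backbone[r_idx] = keys
        for key in keys:
            seq_table[key] = random_protein(rng, cfg.protein_length)
            products[key] = "hypothetical protein"
            backbone_seqs.append(seq_table[key])
    _check_backbone_divergence(backbone_seqs)

    # --- boundary allocation (all single-replicon structures on replicon 0,
    #     paralog contexts round-robin across replicons) ---------------------
    pools = {
        r_idx: list(range(rep.n_genes - 1))
        for r_idx, rep in enumerate(cfg.replicons)
    }
    taken: Dict[int, List[int]] = {r_idx: [] for r_idx in pools}

    def grab(r_idx: int, count: int) -> List[int]:
        return _allocate_boundaries(pools[r_idx], count, taken[r_idx], rng)

    # schedule[(r_idx, boundary)][genome] -> list of slot keys to insert
    schedule: Dict[Tuple[int, int], Dict[str, List[str]]] = defaultdict(
        lambda: defaultdict(list)
    )
    manifest: List[PlantedStructure] = []
    slot_carriers: Dict[str, List[str]] = {}
    slot_replicons: Dict[str, set] = defaultdict(set)

    def fraction_partition(carriers: Sequence[str]) -> str:
        return thresholds.classify(len(carriers) / cfg.n_genomes)

    # uniques: one novel gene in one (non-template) genome
    for k, boundary in enumerate(grab(0, cfg.n_uniques)):
        slot = f"uniq{k}"
        seq_table[slot] = random_protein(rng, cfg.protein_length)
        products[slot] = "hypothetical protein, strain-specific"
        carrier = rng.choice(genomes[1:])
        schedule[(0, boundary)][carrier].append(slot)
        slot_carriers[slot] = [carrier]
        slot_replicons[slot].add(0)

    # orphans: same gene, an unrelated position per carrier genome
    for k in range(cfg.n_orphans):
        slot = f"orph{k}"
        seq_table[slot] = random_protein(rng, cfg.protein_length)
        products[slot] = "mobile element protein"
        carriers = sorted(rng.sample(genomes, cfg.orphan_carriers))
        for carrier, boundary in zip(carriers, grab(0, cfg.orphan_carriers)):
            schedule[(0, boundary)][carrier].append(slot)
        slot_carriers[slot] = carriers
        slot_replicons[slot].add(0)

    # variant pairs: two sub-70%-identity alleles of one slot
    for k, boundary in enumerate(grab(0, cfg.n_variant_pairs)):
        slot_a, slot_b = f"var{k}a", f"var{k}b"
        seq_table[slot_a] = random_protein(rng, cfg.protein_length)
        seq_table[slot_b] = mutate_protein(
            seq_table[slot_a], cfg.variant_identity, seed=rng.randrange(2**31)
        )
        products[slot_a] = products[slot_b] = "surface protein variant"
        subset_a = sorted(rng.sample(genomes, cfg.n_genomes // 2))
        subset_b = sorted(set(genomes) - set(subset_a))
        for g in subset_a:
            schedule[(0, boundary)][g].append(slot_a)
        for g in subset_b:
            schedule[(0, boundary)][g].append(slot_b)
        slot_carriers[slot_a] = subset_a
        slot_carriers[slot_b] = subset_b
        slot_replicons[slot_a].add(0)
        slot_replicons[slot_b].add(0)

    # insertions: contiguous novel genes in a carrier subset
    for k, boundary in enumerate(grab(0, cfg.n_insertions)):
        slots = [f"ins{k}_{j}" for j in range(cfg.insertion_length)]
        carriers = sorted(rng.sample(genomes, cfg.insertion_carriers))
        for slot in slots:
            seq_table[slot] = random_protein(rng, cfg.protein_length)
            products[slot] = "phage-like protein"
            slot_carriers[slot] = carriers
            slot_replicons[slot].add(0)
        for g in carriers:
            schedule[(0, boundary)][g].extend(slots)

    # InDel loops: path of 1 gene vs path of (length - 3) genes
    for k, boundary in enumerate(grab(0, cfg.n_indel_loops)):
        short_slot = f"del{k}_s"
        long_slots = [f"del{k}_l{j}" for j in range(cfg.indel_loop_length - 3)]
        short_set = sorted(rng.sample(genomes, cfg.indel_carriers))
        long_set = sorted(set(genomes) - set(short_set))
        seq_table[short_slot] = random_protein(rng, cfg.protein_length)
        products[short_slot] = "O-antigen biosynthesis protein"
        slot_carriers[short_slot] = short_set
        slot_replicons[short_slot].add(0)
        for slot in long_slots:
            seq_table[slot] = random_protein(rng, cfg.protein_length)
            products[slot] = "O-antigen biosynthesis protein"
            slot_carriers[slot] = long_set
            slot_replicons[slot].add(0)
        for g in short_set:
            schedule[(0, boundary)][g].append(short_slot)
        for g in long_set:
            schedule[(0, boundary)][g].extend(long_slots)

    # paralog families: one protein at several flank contexts, every genome
    for k in range(cfg.n_paralog_families):
        slot = f"par{k}"
        seq_table[slot] = random_protein(rng, cfg.protein_length)
        products[slot] = "IS200/IS605 family transposase"
        for ctx in range(cfg.paralog_contexts):
            r_idx = ctx % len(cfg.replicons)
            boundary = grab(r_idx, 1)[0]
            for g in genomes:
                schedule[(r_idx, boundary)][g].append(slot)
            slot_replicons[slot].add(r_idx)
        slot_carriers[slot] = genomes

    # cross-replicon repeats: a two-gene mobile-element motif planted on
    # replicons 0 and 1 in every genome. The two genes flank each other at
    # both occurrences, so the occurrence contexts share a flank and each
    # gene stays a single subcluster spanning both replicons — the
    # misassembly signature that replicon assignment reports as
    # "undetermined".
    for k in range(cfg.n_cross_replicon_repeats):
        pair = [f"xrep{k}_a", f"xrep{k}_b"]
        for slot in pair:
            seq_table[slot] = random_protein(rng, cfg.protein_length)
            products[slot] = "IS200/IS605 family transposase"
            slot_carriers[slot] = genomes
        for r_idx in (0, 1):
            boundary = grab(r_idx, 1)[0]
            for g in genomes:
                schedule[(r_idx, boundary)][g].extend(pair)
            for slot in pair:
                slot_replicons[slot].add(r_idx)

    # --- lay out genomes ----------------------------------------------------
    records: Dict[str, List[GeneRecord]] = {g: [] for g in genomes}
    proteins = ProteinSet()
    circular_contigs = set()
    slot_loci: Dict[str, List[str]] = defaultdict(list)
    for genome in genomes:
        counter = 0
        for r_idx, rep in enumerate(cfg.replicons):
            contig = f"{genome}_{rep.label}"
            if rep.circular:
                circular_contigs.add(contig)
            keys: List[str] = []
            for i, bb_key in enumerate(backbone[r_idx]):
                keys.append(bb_key)
                extra = schedule.get((r_idx, i), {}).get(genome, [])
                keys.extend(extra)
            for ordinal, key in enumerate(keys):
                locus = f"{genome}_{counter:05d}"
                counter += 1
                seq = seq_table[key]
                start = 1 + ordinal * 400
                records[genome].append(
                    GeneRecord(
                        genome_id=genome,
                        contig_id=contig,
                        ordinal=ordinal,
                        start=start,
                        end=start + 3 * len(seq) + 2,
                        strand="+",
                        locus_id=locus,
                        product=products[key],
                    )
                )
                proteins.add(locus, seq, genome_id=genome)
                if not key.startswith("bb"):
                    slot_loci[key].append(locus)

    # --- templates ----------------------------------------------------------
    templates: List[ReplicionTemplate] = []
    if cfg.with_templates:
        templates.append(
            ReplicionTemplate(
                template_genome,
                {
                    f"{template_genome}_{rep.label}": rep.label
                    for rep in cfg.replicons
                },
            )
        )

    def expected_chromosome(slot: str) -> str:
        if not cfg.with_templates:
            return "unknown"
        if template_genome not in slot_carriers[slot]:
            return "unknown"
        labels = {cfg.replicons[r].label for r in slot_replicons[slot]}
        return labels.pop() if len(labels) == 1 else "undetermined"

    # --- manifest -----------------------------------------------------------
    def entry(sid, stype, slot, pattern, partition=None, subclusters=1,
              chromosome=None):
        manifest.append(
            PlantedStructure(
                structure_id=sid,
                stype=stype,
                slot=slot,
                loci=tuple(slot_loci[slot]),
                carriers=tuple(slot_carriers[slot]),
                expected_pattern=pattern,
                expected_partition=partition
                or fraction_partition(slot_carriers[slot]),
                expected_chromosome=chromosome or expected_chromosome(slot),
                expected_subclusters=subclusters,
            )
        )

    for k in range(cfg.n_uniques):
        entry(f"unique_{k}", "unique", f"uniq{k}", "unique")
    for k in range(cfg.n_orphans):
        entry(f"orphan_{k}", "orphan", f"orph{k}", "orphan")
    for k in range(cfg.n_variant_pairs):
        entry(f"variant_{k}", "variant", f"var{k}a", "variant")
        entry(f"variant_{k}", "variant", f"var{k}b", "variant")
    for k in range(cfg.n_insertions):
        for j in range(cfg.insertion_length):
            entry(f"insertion_{k}", "insertion", f"ins{k}_{j}", "insertion")
    for k in range(cfg.n_indel_loops):
        entry(f"indel_{k}", "indel", f"del{k}_s", "indel")
        for j in range(cfg.indel_loop_length - 3):
            entry(f"indel_{k}", "indel", f"del{k}_l{j}", "indel")
    for k in range(cfg.n_paralog_families):
        # each context-specific subcluster resolves to its own replicon, so
        # the expectation is the set of context labels, not "undetermined"
        context_labels = sorted(
            {cfg.replicons[r].label for r in slot_replicons[f"par{k}"]}
        )
        entry(
            f"paralog_{k}",
            "paralog",
            f"par{k}",
            "paralog_split",
            partition="hard_core",
            subclusters=cfg.paralog_contexts,
            chromosome=";".join(context_labels) if cfg.with_templates else "unknown",
        )
    for k in range(cfg.n_cross_replicon_repeats):
        for suffix in ("a", "b"):
            entry(
                f"cross_repeat_{k}",
                "cross_repeat",
                f"xrep{k}_{suffix}",
                "none",
                partition="hard_core",
                subclusters=1,
            )

    # --- clades: variant-pair subsets double as phylogenetic clades ---------
    clades: Dict[str, Tuple[str, ...]] = {}
    clade_gene_loci: Dict[str, Tuple[str, ...]] = {}
    if cfg.n_variant_pairs >= 1:
        clades["clade_1"] = tuple(slot_carriers["var0a"])
        clades["clade_2"] = tuple(slot_carriers["var0b"])
        clade_gene_loci["clade_1"] = tuple(slot_loci["var0a"])
        clade_gene_loci["clade_2"] = tuple(slot_loci["var0b"])

    return Cohort(
        config=cfg,
        genomes=genomes,
        records=records,
        proteins=proteins,
        circular_contigs=circular_contigs,
        templates=templates,
        manifest=manifest,
        slot_loci={k: tuple(v) for k, v in slot_loci.items()},
        clades=clades,
        clade_gene_loci=clade_gene_loci,
    )


def write_gff3(records: List[GeneRecord], path) -> None:
    """Write gene records as a minimal, deterministic GFF3 file."""
    contigs: Dict[str, int] = {}
    for rec in records:
        contigs[rec.contig_id] = max(contigs.get(rec.contig_id, 0), rec.end + 200)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in contigs:
            fh.write(f"##sequence-region {contig} 1 {contigs[contig]}\n")
        for rec in records:
            attrs = f"ID={rec.locus_id}"
            if rec.product:
                attrs += f";product={rec.product}"
            fh.write(
                f"{rec.contig_id}\tpansyn_sim\tCDS\t{rec.start}\t{rec.end}"
                f"\t.\t{rec.strand}\t0\t{attrs}\n"
            )


def write_protein_fasta(proteins: ProteinSet, path) -> None:
    with open(path, "w") as fh:
        for locus in proteins.loci():
            fh.write(f">{locus}\n")
            seq = proteins[locus]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


_MANIFEST_COLS = (
    "structure_id",
    "stype",
    "slot",
    "loci",
    "carriers",
    "expected_pattern",
    "expected_partition",
    "expected_chromosome",
    "expected_subclusters",
)


def write_manifest(manifest: List[PlantedStructure], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for ps in manifest:
            fh.write(
                "\t".join(
                    [
                        ps.structure_id,
                        ps.stype,
                        ps.slot,
                        ";".join(ps.loci),
                        ";".join(ps.carriers),
                        ps.expected_pattern,
                        ps.expected_partition,
                        ps.expected_chromosome,
                        str(ps.expected_subclusters),
                    ]
                )
                + "\n"
            )


def read_manifest(path) -> List[PlantedStructure]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            out.append(
                PlantedStructure(
                    structure_id=cols[0],
                    stype=cols[1],
                    slot=cols[2],
                    loci=tuple(cols[3].split(";")) if cols[3] else (),
                    carriers=tuple(cols[4].split(";")) if cols[4] else (),
                    expected_pattern=cols[5],
                    expected_partition=cols[6],
                    expected_chromosome=cols[7],
                    expected_subclusters=int(cols[8]),
                )
            )
    return out
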