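"""Core domain types shared across the pipeline.

The pipeline operates on annotated bacterial genomes: each input GFF3 file is
one *strain*, its CDS features become :class:`GeneRecord` objects, and the
pooled predicted proteins are clustered into :class:`ProteinCluster` groups
that later become the nodes of the pangenome graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "GeneRecord",
    "ProteinSet",
    "ProteinCluster",
    "ClusterSet",
    "CascadeConfig",
    "PartitionThresholds",
    "PARTITIONS",
]

#: Partition labels in decreasing occupancy order.
PARTITIONS = ("hard_core", "soft_core", "shell", "cloud")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS.

    Coordinates are 1-based inclusive (GFF3 convention). ``ordinal`` is the
    0-based rank of the CDS among CDS on its contig, ordered by start
    coordinate; gene-neighbourhood (synteny) edges are defined purely on
    consecutive ordinals, so downstream code never touches coordinates.
    """

    genome_id: str
    contig_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    locus_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"locus {self.locus_id}: start {self.start} > end {self.end}"
            )


@dataclass
class ProteinSet:
    """All predicted protein sequences of a cohort, keyed by locus ID.

    ``genome_of`` maps each locus back to its genome; it is filled from the
    GFF3 records (a FASTA file alone does not carry genome identity).
    """

    sequences: Dict[str, str] = field(default_factory=dict)
    genome_of: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.sequences

    def __getitem__(self, locus_id: str) -> str:
        return self.sequences[locus_id]

    def add(self, locus_id: str, sequence: str, genome_id: Optional[str] = None) -> None:
        if locus_id in self.sequences:
            raise ValueError(f"duplicate locus ID {locus_id!r}")
        if not sequence:
            raise ValueError(f"empty sequence for locus {locus_id!r}")
        self.sequences[locus_id] = sequence
        if genome_id is not None:
            self.genome_of[locus_id] = genome_id

    def assign_genomes(self, records: Iterable[GeneRecord]) -> None:
        """Fill ``genome_of`` from GFF3-derived gene records."""
        for rec in records:
            self.genome_of[rec.locus_id] = rec.genome_id

    def loci(self) -> List[str]:
        return list(self.sequences)


@dataclass
class ProteinCluster:
    """A protein family: member loci, a representative, and the similarity
    tier (identity fraction) at which the cascade finalised it."""

    cluster_id: str
    members: frozenset
    representative: str
    tier: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(
                f"cluster {self.cluster_id}: representative "
                f"{self.representative!r} not a member"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """The full clustering result: a partition of the input locus set."""

    clusters: List[ProteinCluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def cluster_of(self) -> Dict[str, str]:
        """Locus -> cluster_id mapping (each locus in exactly one cluster)."""
        mapping: Dict[str, str] = {}
        for cl in self.clusters:
            for locus in cl.members:
                if locus in mapping:
                    raise ValueError(f"locus {locus!r} in two clusters")
                mapping[locus] = cl.cluster_id
        return mapping

    def by_id(self) -> Dict[str, ProteinCluster]:
        return {cl.cluster_id: cl for cl in self.clusters}

    def total_members(self) -> int:
        return sum(len(cl) for cl in self.clusters)


# Default cascade: descending identity tiers, as used by the iterative
# re-clustering scheme (90% -> 80% -> 75% -> 70%).
DEFAULT_THRESHOLDS: Tuple[float, ...] = (0.90, 0.80, 0.75, 0.70)


@dataclass
class CascadeConfig:
    """Configuration of the descending-similarity clustering cascade.

    ``n_genomes`` is the number of input strains; clusters reaching the
    retention rule at a tier are frozen there, smaller ones fall through to
    the next (lower) identity threshold.
    """

    n_genomes: int
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    retention_mode: str = "protein_count"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        ts = tuple(self.thresholds)
        if not ts:
            raise ValueError("at least one threshold required")
        if any(not (0.0 < t <= 1.0) for t in ts):
            raise ValueError(f"thresholds must lie in (0, 1]: {ts}")
        if any(a <= b for a, b in zip(ts, ts[1:])):
            raise ValueError(f"thresholds must be strictly decreasing: {ts}")
        if self.retention_mode not in ("protein_count", "genome_count"):
            raise ValueError(f"unknown retention mode {self.retention_mode!r}")
        self.thresholds = ts


@dataclass
class PartitionThresholds:
    """Occupancy fractions dividing the pangenome into hard core / soft core
    / shell / cloud. A cluster present in a fraction f of the genomes is
    hard core if f >= hard, soft core if f >= soft, shell if f >= shell,
    otherwise cloud."""

    hard: float = 0.99
    soft: float = 0.95
    shell: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.shell < self.soft < self.hard <= 1.0):
            raise ValueError(
                f"need 0 < shell < soft < hard <= 1, got "
                f"shell={self.shell}, soft={self.soft}, hard={self.hard}"
            )

    def classify(self, fraction: float) -> str:
        if fraction >= self.hard:
            return "hard_core"
        if fraction >= self.soft:
            return "soft_core"
        if fraction >= self.shell:
            return "shell"
        return "cloud"
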