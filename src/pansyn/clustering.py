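"""Greedy incremental protein clustering with a descending-similarity cascade.

Proteins are clustered at 90% identity first; clusters that reach the
retention rule (by default, at least as many members as there are input
genomes) are frozen there, and the remaining proteins are re-clustered at
80%, then 75%, then 70%. At the final tier every remaining cluster is kept.
One member of each cluster is chosen, uniformly at random under a fixed
seed, as its representative.

Identity between two proteins is defined as the number of identical aligned
residues in a global alignment (BLOSUM62, affine gaps: open 10, extend 1)
divided by the length of the shorter sequence — the convention of greedy
incremental clustering tools.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .model import CascadeConfig, ClusterSet, ProteinCluster, ProteinSet

__all__ = [
    "sequence_identity",
    "greedy_cluster",
    "iterative_cluster",
    "choose_representative",
    "write_cluster_file",
    "read_cluster_file",
    "write_representative_fasta",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues over the shorter length.

    Symmetric, 1.0 for identical sequences. Arguments are canonically
    ordered before alignment so that co-optimal alignments cannot make the
    measure asymmetric.
    """
    if not a or not b:
        raise ValueError("sequence_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if a > b:
        a, b = b, a
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def _ordered_unique_sequences(
    items: List[Tuple[str, str]]
) -> List[Tuple[str, List[str]]]:
    """Group identical sequences, preserving greedy processing order.

    ``items`` is (locus, seq) pairs already in processing order. Identical
    sequences trivially join the same cluster as their first occurrence
    (identity 1.0 passes any threshold), so each distinct sequence is
    aligned only once.
    """
    groups: Dict[str, List[str]] = {}
    order: List[str] = []
    for locus, seq in items:
        if seq not in groups:
            groups[seq] = []
            order.append(seq)
        groups[seq].append(locus)
    return [(seq, groups[seq]) for seq in order]


def greedy_cluster(
    proteins: ProteinSet,
    t: float,
    seed: int = 42,
    subset: Optional[Iterable[str]] = None,
) -> ClusterSet:
    """One greedy incremental clustering pass at identity threshold ``t``.

    Sequences are processed in decreasing length order (ties broken
    lexicographically by locus ID). Each sequence joins the first existing
    cluster whose founding sequence it matches at identity >= t, otherwise
    it founds a new cluster. Cluster IDs are provisional (finalised by
    :func:`iterative_cluster`); the founder serves as representative until
    :func:`choose_representative` replaces it.
    """
    if not (0.0 < t <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {t}")
    loci = list(subset) if subset is not None else proteins.loci()
    items = sorted(
        ((locus, proteins[locus]) for locus in loci),
        key=lambda kv: (-len(kv[1]), kv[0]),
    )
    founders: List[str] = []  # founding sequence per cluster, in creation order
    members: List[List[str]] = []
    for seq, group_loci in _ordered_unique_sequences(items):
        for idx, founder in enumerate(founders):
            if sequence_identity(seq, founder) >= t:
                members[idx].extend(group_loci)
                break
        else:
            founders.append(seq)
            members.append(list(group_loci))
    clusters = []
    for idx, group in enumerate(members):
        founder_locus = min(
            (l for l in group if proteins[l] == founders[idx]), default=group[0]
        )
        clusters.append(
            ProteinCluster(
                cluster_id=f"tmp{idx:06d}",
                members=frozenset(group),
                representative=founder_locus,
                tier=t,
            )
        )
    return ClusterSet(clusters=clusters)


def _retained(cluster: ProteinCluster, cfg: CascadeConfig, proteins: ProteinSet) -> bool:
    if cfg.retention_mode == "protein_count":
        return len(cluster) >= cfg.n_genomes
    genomes = {proteins.genome_of[l] for l in cluster.members}
    return len(genomes) >= cfg.n_genomes


def iterative_cluster(proteins: ProteinSet, cfg: CascadeConfig) -> ClusterSet:
    """Run the full descending cascade and finalise cluster IDs and
    representatives.

    At each threshold, clusters satisfying the retention rule are frozen
    with that tier and their members leave the pool; everything else is
    re-clustered at the next lower threshold. At the final threshold all
    remaining clusters are kept. Cluster IDs are assigned deterministically
    (sorted by smallest member locus) and representatives drawn uniformly
    from a generator keyed by (seed, cluster_id).
    """
    if cfg.retention_mode == "genome_count":
        missing = [l for l in proteins.loci() if l not in proteins.genome_of]
        if missing:
            raise ValueError(
                f"genome_count retention requires genome_of for every locus; "
                f"missing e.g. {missing[0]!r}"
            )
    remaining: List[str] = proteins.loci()
    frozen: List[ProteinCluster] = []
    n_tiers = len(cfg.thresholds)
    for round_idx, t in enumerate(cfg.thresholds):
        if not remaining:
            break
        passed = greedy_cluster(proteins, t, seed=cfg.seed, subset=remaining)
        last = round_idx == n_tiers - 1
        next_pool: List[str] = []
        for cl in passed:
            if last or _retained(cl, cfg, proteins):
                frozen.append(cl)
            else:
                next_pool.extend(sorted(cl.members))
        remaining = next_pool
    frozen.sort(key=lambda cl: min(cl.members))
    final = []
    for idx, cl in enumerate(frozen):
        cid = f"C{idx:05d}"
        stub = ProteinCluster(cid, cl.members, cl.representative, cl.tier)
        rep = choose_representative(stub, cfg.seed)
        final.append(ProteinCluster(cid, cl.members, rep, cl.tier))
    return ClusterSet(clusters=final)


def choose_representative(cluster: ProteinCluster, seed: int = 42) -> str:
    """Uniform random member choice, reproducible for a given (seed,
    cluster_id) pair."""
    if not cluster.members:
        raise ValueError("cannot choose a representative of an empty cluster")
    rng = random.Random(f"{seed}:{cluster.cluster_id}")
    return rng.choice(sorted(cluster.members))


def write_cluster_file(cluster_set: ClusterSet, path) -> None:
    """One cluster per line: ``cluster_id TAB tier TAB representative TAB
    member1;member2;...`` sorted by cluster ID."""
    with open(path, "w") as fh:
        for cl in sorted(cluster_set, key=lambda c: c.cluster_id):
            members = ";".join(sorted(cl.members))
            fh.write(f"{cl.cluster_id}\t{cl.tier:g}\t{cl.representative}\t{members}\n")


def read_cluster_file(path) -> ClusterSet:
    clusters = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, tier, rep, members = line.split("\t")
            clusters.append(
                ProteinCluster(
                    cluster_id=cid,
                    members=frozenset(members.split(";")),
                    representative=rep,
                    tier=float(tier),
                )
            )
    return ClusterSet(clusters=clusters)


def write_representative_fasta(
    cluster_set: ClusterSet,
    proteins: ProteinSet,
    path,
    products: Optional[Dict[str, str]] = None,
) -> None:
    """FASTA of representative sequences, one per cluster, headers carrying
    the cluster ID, representative locus and (when known) its product."""
    products = products or {}
    with open(path, "w") as fh:
        for cl in sorted(cluster_set, key=lambda c: c.cluster_id):
            product = products.get(cl.representative, "")
            header = f">{cl.cluster_id} {cl.representative}"
            if product:
                header += f" {product}"
            fh.write(header + "\n")
            seq = proteins[cl.representative]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
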