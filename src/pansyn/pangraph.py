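"""Strain graphs, the weighted pangenome graph, paralog subcluster
splitting, and core/accessory partitioning.

A *strain graph* is built per genome: nodes are that genome's loci
(labelled by their protein cluster), adjacency edges join loci with
consecutive ordinals on a contig (closing the ring for contigs flagged
circular), and paralogy edges form a clique over same-cluster loci of the
genome.

The *pangenome graph* has one node per (sub)cluster; an edge between two
nodes carries weight = number of genomes in which the two clusters hold
directly neighbouring proteins. Paralogous clusters are split into
neighbourhood subclusters before weighting, and edges below a configurable
minimum weight are dropped (nodes never are).
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import networkx as nx

from .model import ClusterSet, GeneRecord, PartitionThresholds

__all__ = [
    "build_strain_graph",
    "adjacency_pairs",
    "build_pangenome_graph",
    "split_paralog_subclusters",
    "compute_node_attributes",
    "assign_partitions",
    "filter_min_weight",
    "build_pangenome",
]


def build_strain_graph(
    records: List[GeneRecord],
    cluster_of: Mapping[str, str],
    circular_contigs: Iterable[str] = (),
) -> nx.Graph:
    """Build one genome's locus-level graph.

    Node attributes: ``cluster``, ``contig``, ``ordinal``, ``product``.
    Edge attribute ``etype`` is ``adjacency`` (consecutive loci on a
    contig) or ``paralogy`` (same genome, same cluster). Adjacency never
    crosses a contig end unless the contig is flagged circular.
    """
    circular = set(circular_contigs)
    g = nx.Graph()
    if records:
        g.graph["genome_id"] = records[0].genome_id
    per_contig: Dict[str, List[GeneRecord]] = defaultdict(list)
    for rec in records:
        if rec.locus_id not in cluster_of:
            raise ValueError(f"locus {rec.locus_id!r} has no cluster assignment")
        g.add_node(
            rec.locus_id,
            cluster=cluster_of[rec.locus_id],
            contig=rec.contig_id,
            ordinal=rec.ordinal,
            product=rec.product,
        )
        per_contig[rec.contig_id].append(rec)
    for contig, recs in per_contig.items():
        recs = sorted(recs, key=lambda r: r.ordinal)
        for a, b in zip(recs, recs[1:]):
            g.add_edge(a.locus_id, b.locus_id, etype="adjacency")
        if contig in circular and len(recs) > 2:
            g.add_edge(recs[-1].locus_id, recs[0].locus_id, etype="adjacency")
    # paralogy cliques per (genome, cluster)
    by_cluster: Dict[str, List[str]] = defaultdict(list)
    for rec in records:
        by_cluster[cluster_of[rec.locus_id]].append(rec.locus_id)
    for loci in by_cluster.values():
        if len(loci) < 2:
            continue
        for u, v in combinations(sorted(loci), 2):
            if g.has_edge(u, v):  # tandem copies: adjacency wins, flag kept
                g.edges[u, v]["also_paralog"] = True
            else:
                g.add_edge(u, v, etype="paralogy")
    return g


def adjacency_pairs(strain_graph: nx.Graph) -> List[Tuple[str, str]]:
    """Locus pairs joined by adjacency edges (paralogy-only edges excluded)."""
    return [
        (u, v)
        for u, v, attrs in strain_graph.edges(data=True)
        if attrs.get("etype") == "adjacency"
    ]


def build_pangenome_graph(
    strain_graphs: Mapping[str, nx.Graph],
    w_min: int = 1,
    label_attr: str = "cluster",
) -> nx.Graph:
    """Aggregate strain graphs into the cluster-level pangenome graph.

    Edge weight counts *genomes* (not occurrences): a genome with the same
    cluster pair adjacent twice still contributes 1. Self-loops record
    tandem same-cluster adjacencies. Edges with weight < ``w_min`` are
    omitted; every cluster node is kept regardless.
    """
    if w_min < 1:
        raise ValueError(f"w_min must be >= 1, got {w_min}")
    g = nx.Graph(w_min=w_min)
    labels = set()
    for sg in strain_graphs.values():
        labels.update(sg.nodes[n][label_attr] for n in sg.nodes)
    g.add_nodes_from(sorted(labels))
    weights: Dict[Tuple[str, str], int] = defaultdict(int)
    for genome in sorted(strain_graphs):
        sg = strain_graphs[genome]
        pairs = set()
        for u, v in adjacency_pairs(sg):
            cu, cv = sg.nodes[u][label_attr], sg.nodes[v][label_attr]
            pairs.add(tuple(sorted((cu, cv))))
        for pair in pairs:
            weights[pair] += 1
    for (cu, cv), w in sorted(weights.items()):
        if w >= w_min:
            g.add_edge(cu, cv, weight=w)
    return g


def _flank_labels(sg: nx.Graph, locus: str, label_attr: str) -> FrozenSet[str]:
    """Clusters of the loci adjacent (window 1) to ``locus``."""
    flanks = set()
    for nbr in sg.neighbors(locus):
        if sg.edges[locus, nbr].get("etype") == "adjacency":
            flanks.add(sg.nodes[nbr][label_attr])
    return frozenset(flanks)


def split_paralog_subclusters(
    strain_graphs: Mapping[str, nx.Graph],
    label_attr: str = "cluster",
) -> Tuple[Dict[str, nx.Graph], Dict[str, List[str]]]:
    """Split paralogous clusters into genomic-neighbourhood subclusters.

    A cluster is paralogous if some genome holds >= 2 of its members. Its
    occurrences (one per member locus, across all genomes) are connected
    whenever their flanking cluster sets intersect; connected components of
    this occurrence graph are the "unrelated neighbourhoods", each becoming
    one subcluster. Every strain-graph node gains a ``subcluster``
    attribute (equal to the cluster ID for unsplit clusters, or
    ``<cluster>_<k>`` for split ones).

    Returns the relabelled strain graphs (copies) and a mapping
    cluster_id -> list of its subcluster IDs.
    """
    out = {genome: sg.copy() for genome, sg in strain_graphs.items()}
    occ: Dict[str, List[Tuple[str, str]]] = defaultdict(list)  # cluster -> [(genome, locus)]
    per_genome_count: Dict[str, Dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for genome in sorted(out):
        sg = out[genome]
        for locus in sorted(sg.nodes, key=lambda l: (sg.nodes[l]["contig"], sg.nodes[l]["ordinal"])):
            label = sg.nodes[locus][label_attr]
            occ[label].append((genome, locus))
            per_genome_count[label][genome] += 1
    submap: Dict[str, List[str]] = {}
    for label in sorted(occ):
        paralogous = max(per_genome_count[label].values()) >= 2
        occurrences = occ[label]
        if not paralogous:
            submap[label] = [label]
            for genome, locus in occurrences:
                out[genome].nodes[locus]["subcluster"] = label
            continue
        flanks = [
            _flank_labels(out[genome], locus, label_attr)
            for genome, locus in occurrences
        ]
        og = nx.Graph()
        og.add_nodes_from(range(len(occurrences)))
        for i, j in combinations(range(len(occurrences)), 2):
            if flanks[i] & flanks[j]:
                og.add_edge(i, j)
        components = sorted(nx.connected_components(og), key=min)
        sub_ids = []
        for k, comp in enumerate(components, start=1):
            sub_id = f"{label}_{k}"
            sub_ids.append(sub_id)
            for idx in comp:
                genome, locus = occurrences[idx]
                out[genome].nodes[locus]["subcluster"] = sub_id
        submap[label] = sub_ids
    return out, submap


def compute_node_attributes(
    g: nx.Graph,
    strain_graphs: Mapping[str, nx.Graph],
    cluster_set: Optional[ClusterSet] = None,
    label_attr: str = "subcluster",
) -> nx.Graph:
    """Annotate pangenome nodes with strain sets, paralog counts, protein
    counts, per-genome weighting, representative and product.

    ``max_paralogs`` is the largest member count in any single genome;
    ``avg_per_genome`` is total members / number of strains. Subclusters
    share their parent cluster's representative (and its product).
    """
    members: Dict[str, Dict[str, int]] = defaultdict(lambda: defaultdict(int))
    products: Dict[str, str] = {}
    locus_product: Dict[str, str] = {}
    for genome, sg in strain_graphs.items():
        for locus in sg.nodes:
            label = sg.nodes[locus][label_attr]
            members[label][genome] += 1
            locus_product[locus] = sg.nodes[locus].get("product", "")
    reps = {}
    if cluster_set is not None:
        for cl in cluster_set:
            reps[cl.cluster_id] = cl.representative
    for node in g.nodes:
        counts = members.get(node, {})
        strains = frozenset(counts)
        protein_count = sum(counts.values())
        max_paralogs = max(counts.values(), default=0)
        parent = node.rsplit("_", 1)[0] if node not in reps else node
        rep = reps.get(node, reps.get(parent, ""))
        g.nodes[node].update(
            strains=strains,
            protein_count=protein_count,
            max_paralogs=max_paralogs,
            avg_per_genome=protein_count / len(strains) if strains else 0.0,
            representative=rep,
            product=locus_product.get(rep, ""),
        )
    return g


def assign_partitions(
    g: nx.Graph, thresholds: PartitionThresholds, n_genomes: int
) -> nx.Graph:
    """Label every node hard_core / soft_core / shell / cloud from its
    occupancy fraction |strains| / n_genomes (>= at every boundary)."""
    for node in g.nodes:
        strains = g.nodes[node].get("strains", frozenset())
        f = len(strains) / n_genomes
        g.nodes[node]["partition"] = thresholds.classify(f)
    return g


def filter_min_weight(g: nx.Graph, w_min: int) -> nx.Graph:
    """Drop edges with weight < w_min; the node set is untouched."""
    if w_min < 1:
        raise ValueError(f"w_min must be >= 1, got {w_min}")
    out = g.copy()
    out.graph["w_min"] = w_min
    drop = [
        (u, v) for u, v, w in out.edges(data="weight") if (w or 0) < w_min
    ]
    out.remove_edges_from(drop)
    return out


def build_pangenome(
    strain_graphs: Mapping[str, nx.Graph],
    cluster_set: ClusterSet,
    n_genomes: int,
    w_min: int = 1,
    thresholds: Optional[PartitionThresholds] = None,
) -> Tuple[nx.Graph, Dict[str, nx.Graph], Dict[str, List[str]]]:
    """Full graph stage: split paralogs, build the subcluster-level
    pangenome graph with all edges, annotate and partition, then apply the
    minimum-weight filter (splitting precedes filtering so rare contexts
    are resolved before edges are discarded)."""
    thresholds = thresholds or PartitionThresholds()
    relabelled, submap = split_paralog_subclusters(strain_graphs)
    g = build_pangenome_graph(relabelled, w_min=1, label_attr="subcluster")
    compute_node_attributes(g, relabelled, cluster_set)
    assign_partitions(g, thresholds, n_genomes)
    g = filter_min_weight(g, w_min)
    return g, relabelled, submap
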