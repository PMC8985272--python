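"""Overlaying genome groups and clade gene sets onto the pangenome graph.

Highlight colours are stored as plain attribute values ("orange" for
elements already in the graph, "yellow" for elements a strain carries but
the minimum-weight filter removed) so any GraphML viewer can style them.
Clade definitions follow a minimal two-column TSV dialect (clade file:
clade_id, genome_id; gene-set file: clade_id, cluster_id), a reduced form
of the tables phylogenetic post-processing pipelines export.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set

import networkx as nx

from .io_formats import node_strains
from .pangraph import adjacency_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "CladeSpec",
    "highlight_strains",
    "read_clades",
    "highlight_clades",
]

MODES = ("specifically_present", "specifically_absent")


@dataclass
class CladeSpec:
    clade_id: str
    members: Set[str] = field(default_factory=set)
    gene_set: Set[str] = field(default_factory=set)
    mode: str = "specifically_present"


def highlight_strains(
    g: nx.Graph,
    strains: List[str],
    strain_graphs: Mapping[str, nx.Graph],
    label_attr: str = "subcluster",
) -> nx.Graph:
    """Mark the sub-pangenome of a genome group.

    Nodes and edges of the pangenome graph occurring in any listed strain
    are marked ``highlight="orange"``. Adjacencies the listed strains carry
    that fell below the minimum edge weight (and clusters missing from the
    graph entirely) are added with ``highlight="yellow"``. Nothing existing
    is removed or re-weighted, so the overlay is idempotent.
    """
    unknown = [s for s in strains if s not in strain_graphs]
    if unknown:
        raise ValueError(f"unknown strain IDs: {', '.join(sorted(unknown))}")
    out = g.copy()
    listed = set(strains)
    covered_nodes: Set[str] = set()
    covered_pairs: Set[tuple] = set()
    for s in sorted(listed):
        sg = strain_graphs[s]
        covered_nodes.update(sg.nodes[l][label_attr] for l in sg.nodes)
        for u, v in adjacency_pairs(sg):
            cu, cv = sg.nodes[u][label_attr], sg.nodes[v][label_attr]
            covered_pairs.add(tuple(sorted((cu, cv))))
    for label in sorted(covered_nodes):
        if label in out.nodes:
            out.nodes[label]["highlight"] = "orange"
        else:
            out.add_node(label, highlight="yellow")
    for cu, cv in sorted(covered_pairs):
        if out.has_edge(cu, cv):
            if out.edges[cu, cv].get("highlight") != "yellow":
                out.edges[cu, cv]["highlight"] = "orange"
        else:
            out.add_edge(cu, cv, highlight="yellow")
    return out


def read_clades(clade_file, gene_set_file, mode: str) -> List[CladeSpec]:
    """Parse clade membership and clade-specific gene-set tables."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    members: Dict[str, Set[str]] = defaultdict(set)
    order: List[str] = []
    with open(clade_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            clade, genome = line.split("\t")
            if clade not in members:
                order.append(clade)
            members[clade].add(genome)
    genes: Dict[str, Set[str]] = defaultdict(set)
    with open(gene_set_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            clade, gene = line.split("\t")
            if clade not in members:
                raise ValueError(
                    f"clade {clade!r} appears in the gene-set file but not "
                    f"in the clade file"
                )
            genes[clade].add(gene)
    return [
        CladeSpec(clade_id=c, members=members[c], gene_set=genes.get(c, set()),
                  mode=mode)
        for c in order
    ]


def highlight_clades(g: nx.Graph, clades: List[CladeSpec]) -> nx.Graph:
    """Mark clade membership and clade-specific genes on the graph.

    Per clade: nodes whose strain set intersects the clade's genomes gain
    ``clade_<id>="member"``; nodes in the clade's gene set additionally
    gain ``clade_<id>_specific=<mode>``. Attributes are additive across
    clades. Gene-set IDs missing from the graph (e.g. renamed by paralog
    subcluster splitting) produce a warning, not an error.
    """
    out = g.copy()
    for clade in clades:
        member_key = f"clade_{clade.clade_id}"
        specific_key = f"clade_{clade.clade_id}_specific"
        for node in out.nodes:
            if node_strains(out, node) & clade.members:
                out.nodes[node][member_key] = "member"
        missing = sorted(gid for gid in clade.gene_set if gid not in out.nodes)
        if missing:
            logger.warning(
                "clade %s: gene-set IDs not in graph: %s",
                clade.clade_id,
                ", ".join(missing),
            )
        for gid in sorted(clade.gene_set):
            if gid in out.nodes:
                out.nodes[gid][specific_key] = clade.mode
    return out
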