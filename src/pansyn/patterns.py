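"""Structural-pattern detection on the pangenome graph.

Five pattern classes are detected:

* **orphans** — clusters present in several genomes but with no consistent
  genomic neighbourhood (isolated nodes after minimum-weight filtering);
* **uniques** — clusters present in exactly one genome, regardless of
  connectivity;
* **variants** — parallel alternative clusters occupying the same genomic
  slot between shared anchors (small bubbles whose internal nodes touch
  the outside only through one or two anchor nodes), typically alleles
  whose divergence exceeds the clustering identity floor;
* **insertions** — a direct anchor edge plus an alternative path whose
  internal nodes all belong to the shell or cloud: a short gain carried by
  a few genomes;
* **InDels** — cycles of more than four nodes, with no restriction on how
  common the member clusters are.

Self-loops are excluded from every detector. Exhaustive simple-cycle
enumeration being exponential, InDel detection uses a minimum cycle basis,
made deterministic by sorted node/edge insertion.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .io_formats import node_strains, write_graph

__all__ = [
    "VariantGroup",
    "Insertion",
    "PatternReport",
    "find_orphans",
    "find_uniques",
    "find_variants",
    "find_insertions",
    "find_indels",
    "detect_patterns",
    "write_pattern_outputs",
    "highlight_subgraph",
    "clear_highlight",
]


@dataclass
class VariantGroup:
    anchors: Tuple[str, ...]  # one or two anchor nodes
    members: List[str]
    strain_overlap: int = 0  # genomes shared by >= 2 members (for filtering)


@dataclass
class Insertion:
    anchors: Tuple[str, str]
    path: List[str]  # internal (inserted) nodes, in path order


@dataclass
class PatternReport:
    orphans: List[str] = field(default_factory=list)
    uniques: List[str] = field(default_factory=list)
    variants: List[VariantGroup] = field(default_factory=list)
    insertions: List[Insertion] = field(default_factory=list)
    indels: List[List[str]] = field(default_factory=list)


def _adjacency_view(g: nx.Graph) -> nx.Graph:
    """Copy of g without self-loops (pattern detectors ignore them)."""
    out = nx.Graph()
    out.add_nodes_from(sorted(g.nodes(data=True)))
    for u, v, attrs in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        if u != v:
            out.add_edge(u, v, **attrs)
    return out


def find_orphans(g: nx.Graph) -> List[str]:
    """Nodes with no connection to any other node but present in >= 2
    genomes (run on the post-filter graph, so the minimum edge weight
    directly influences orphan calls)."""
    adj = _adjacency_view(g)
    return sorted(
        n for n in adj.nodes if adj.degree(n) == 0 and len(node_strains(g, n)) >= 2
    )


def find_uniques(g: nx.Graph) -> List[str]:
    """Nodes present in exactly one genome, connected or not."""
    return sorted(n for n in g.nodes if len(node_strains(g, n)) == 1)


def find_variants(g: nx.Graph) -> List[VariantGroup]:
    """Bubbles of parallel alternatives between shared anchors.

    A candidate internal node touches the rest of the graph through at
    most two neighbours. Candidates are grouped by their exact neighbour
    set — parallel alternatives occupy the same slot, so they share both
    anchors (or the single anchor, for dead-end variants). A group needs
    >= 2 internal nodes: a lone node between two anchors is a linear
    path, not an alternative.
    """
    adj = _adjacency_view(g)
    by_anchor: Dict[FrozenSet[str], List[str]] = defaultdict(list)
    for n in adj.nodes:
        nbrs = frozenset(adj.neighbors(n))
        if 1 <= len(nbrs) <= 2:
            by_anchor[nbrs].append(n)
    groups = []
    for anchors in sorted(by_anchor, key=sorted):
        members = sorted(by_anchor[anchors])
        if len(members) < 2:
            continue
        overlap = 0
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                overlap += len(node_strains(g, a) & node_strains(g, b))
        groups.append(
            VariantGroup(anchors=tuple(sorted(anchors)), members=members,
                         strain_overlap=overlap)
        )
    return groups


def find_insertions(g: nx.Graph, max_len: int = 10) -> List[Insertion]:
    """Shell/cloud-only alternative paths alongside a direct anchor edge.

    For every edge (a, b), any simple path a - v1 - ... - vk - b
    (1 <= k <= max_len) whose internal nodes are all shell or cloud is an
    insertion; the internal nodes are reported with their degree and
    weighting in :func:`write_pattern_outputs`.
    """
    adj = _adjacency_view(g)
    accessory = {
        n for n in adj.nodes if adj.nodes[n].get("partition") in ("shell", "cloud")
    }
    found: List[Insertion] = []
    seen = set()
    for a, b in sorted(adj.edges, key=lambda e: tuple(sorted(map(str, e)))):
        a, b = sorted((a, b))
        sub_nodes = accessory | {a, b}
        sub = adj.subgraph(sub_nodes)
        for path in nx.all_simple_paths(sub, a, b, cutoff=max_len + 1):
            internal = path[1:-1]
            if not internal:
                continue
            key = (a, b, tuple(internal))
            rkey = (a, b, tuple(reversed(internal)))
            if key in seen or rkey in seen:
                continue
            seen.add(key)
            found.append(Insertion(anchors=(a, b), path=list(internal)))
    return found


def _order_cycle(g: nx.Graph, nodes: FrozenSet[str]) -> List[str]:
    """Order a basis cycle's nodes along the cycle, starting from the
    lexicographically smallest node toward its smaller neighbour. Falls
    back to sorted order if the induced subgraph is not a plain cycle
    (chords)."""
    sub = g.subgraph(nodes)
    if any(sub.degree(n) != 2 for n in sub.nodes):
        return sorted(nodes)
    start = min(nodes)
    nxt = min(sub.neighbors(start))
    order = [start, nxt]
    prev = start
    while order[-1] != start:
        cur = order[-1]
        nbrs = [n for n in sub.neighbors(cur) if n != prev]
        prev = cur
        order.append(nbrs[0])
        if len(order) > len(nodes) + 1:  # chordless guarantee failed
            return sorted(nodes)
    return order[:-1]


def find_indels(
    g: nx.Graph, max_cycle_len: int = 100, min_cycle_len: int = 5
) -> List[List[str]]:
    """Cycles with more than four nodes, from a minimum cycle basis.

    Cycles longer than ``max_cycle_len`` (e.g. the whole-replicon ring of
    a circular chromosome) are suppressed. Each cycle is an ordered node
    list starting from its lexicographically smallest node.
    """
    adj = _adjacency_view(g)
    cycles = []
    for basis_nodes in nx.minimum_cycle_basis(adj):
        if min_cycle_len <= len(basis_nodes) <= max_cycle_len:
            cycles.append(_order_cycle(adj, frozenset(basis_nodes)))
    cycles.sort(key=lambda c: (c[0], len(c), c))
    return cycles


def detect_patterns(
    g: nx.Graph, max_insertion_len: int = 10, max_cycle_len: int = 100
) -> PatternReport:
    """Run all five detectors and disambiguate overlapping bubble classes.

    An insertion bubble with k internal nodes also closes a cycle of k + 2
    nodes through the direct anchor edge, which the cycle-basis InDel
    detector would re-report whenever k >= 3. Such cycles are assigned to
    the insertion class only: an InDel here is a cycle not already
    explained as an insertion bubble.
    """
    insertions = find_insertions(g, max_len=max_insertion_len)
    insertion_cycles = {
        frozenset(ins.path) | set(ins.anchors) for ins in insertions
    }
    indels = [
        cyc
        for cyc in find_indels(g, max_cycle_len=max_cycle_len)
        if frozenset(cyc) not in insertion_cycles
    ]
    return PatternReport(
        orphans=find_orphans(g),
        uniques=find_uniques(g),
        variants=find_variants(g),
        insertions=insertions,
        indels=indels,
    )


def _pattern_subgraphs(report: PatternReport, g: nx.Graph) -> Dict[str, nx.Graph]:
    subs: Dict[str, nx.Graph] = {}
    orphan_g = nx.Graph()
    for n in report.orphans:
        orphan_g.add_node(n, **g.nodes[n])
    subs["orphans"] = orphan_g
    unique_g = nx.Graph()
    for n in report.uniques:
        unique_g.add_node(n, **g.nodes[n])
    subs["uniques"] = unique_g
    var_g = nx.Graph()
    for grp in report.variants:
        for n in list(grp.anchors) + grp.members:
            var_g.add_node(n, **g.nodes[n])
        for m in grp.members:
            for a in grp.anchors:
                if g.has_edge(m, a):
                    var_g.add_edge(m, a, **g.edges[m, a])
    subs["variants"] = var_g
    ins_g = nx.Graph()
    for ins in report.insertions:
        chain = [ins.anchors[0]] + ins.path + [ins.anchors[1]]
        for n in chain:
            ins_g.add_node(n, **g.nodes[n])
        for u, v in zip(chain, chain[1:]):
            if g.has_edge(u, v):
                ins_g.add_edge(u, v, **g.edges[u, v])
        if g.has_edge(*ins.anchors):
            ins_g.add_edge(*ins.anchors, **g.edges[ins.anchors])
    subs["insertions"] = ins_g
    indel_g = nx.Graph()
    for cyc in report.indels:
        for n in cyc:
            indel_g.add_node(n, **g.nodes[n])
        for u, v in zip(cyc, cyc[1:] + cyc[:1]):
            if g.has_edge(u, v):
                indel_g.add_edge(u, v, **g.edges[u, v])
    subs["indels"] = indel_g
    return subs


def write_pattern_outputs(report: PatternReport, g: nx.Graph, out_dir) -> None:
    """Write the text/tabular report files plus one GraphML per pattern
    class (only that pattern's nodes and edges), suitable for overlaying
    onto the full pangenome graph via :func:`highlight_subgraph`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "orphans.txt", "w") as fh:
        for n in report.orphans:
            fh.write(n + "\n")
    with open(out_dir / "uniques.txt", "w") as fh:
        for n in report.uniques:
            fh.write(n + "\n")
    with open(out_dir / "variants.txt", "w") as fh:
        for grp in report.variants:
            anchors = ",".join(grp.anchors)
            fh.write(anchors + "\t" + "\t".join(grp.members) + "\n")
    with open(out_dir / "insertions.tsv", "w") as fh:
        fh.write("node\tdegree\tweight\tanchor_a\tanchor_b\n")
        for ins in report.insertions:
            for n in ins.path:
                degree = g.degree(n)
                weight = g.nodes[n].get("avg_per_genome", "")
                fh.write(
                    f"{n}\t{degree}\t{weight}\t{ins.anchors[0]}\t{ins.anchors[1]}\n"
                )
    with open(out_dir / "indels.txt", "w") as fh:
        for cyc in report.indels:
            fh.write("\t".join(cyc) + "\n")
    for name, sub in _pattern_subgraphs(report, g).items():
        write_graph(sub, out_dir / f"{name}.graphml")


def highlight_subgraph(g: nx.Graph, pattern_graph: nx.Graph) -> nx.Graph:
    """Overlay a pattern subgraph onto the full pangenome graph: matched
    nodes and edges gain ``highlight=True``; everything else is untouched."""
    missing = sorted(set(pattern_graph.nodes) - set(g.nodes))
    if missing:
        raise ValueError(f"pattern nodes absent from graph: {', '.join(missing)}")
    out = g.copy()
    for n in pattern_graph.nodes:
        out.nodes[n]["highlight"] = True
    for u, v in pattern_graph.edges:
        if out.has_edge(u, v):
            out.edges[u, v]["highlight"] = True
    return out


def clear_highlight(g: nx.Graph) -> nx.Graph:
    """Remove highlight attributes (inverse of :func:`highlight_subgraph`)."""
    out = g.copy()
    for n in out.nodes:
        out.nodes[n].pop("highlight", None)
    for u, v in out.edges:
        out.edges[u, v].pop("highlight", None)
    return out
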