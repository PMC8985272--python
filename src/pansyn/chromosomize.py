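"""Replicon assignment of protein clusters from finished template genomes.

Template genomes are finished (or nearly finished) assemblies whose contigs
map one-to-one to known replicons (chromosomes/plasmids). A subcluster
whose template-genome members all sit on contigs with a single replicon
label receives that label; conflicting labels yield "undetermined" (the
signature of repeats spanning replicons, and of misassemblies); clusters
absent from every template are "unknown".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import networkx as nx

__all__ = [
    "ReplicionTemplate",
    "read_templates",
    "write_templates",
    "assign_chromosomes",
    "chromosomize_graphs",
]

UNDETERMINED = "undetermined"
UNKNOWN = "unknown"


@dataclass
class ReplicionTemplate:
    """Replicon labels for every contig of one finished genome."""

    genome_id: str
    contig_labels: Dict[str, str] = field(default_factory=dict)


def read_templates(path) -> List[ReplicionTemplate]:
    """Read the template TSV (genome_id, contig_id, replicon_label per row)."""
    by_genome: Dict[str, Dict[str, str]] = defaultdict(dict)
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            genome, contig, label = line.split("\t")
            if genome not in by_genome:
                order.append(genome)
            by_genome[genome][contig] = label
    return [ReplicionTemplate(g, by_genome[g]) for g in order]


def write_templates(templates: List[ReplicionTemplate], path) -> None:
    with open(path, "w") as fh:
        for tpl in templates:
            for contig in sorted(tpl.contig_labels):
                fh.write(f"{tpl.genome_id}\t{contig}\t{tpl.contig_labels[contig]}\n")


def assign_chromosomes(
    templates: List[ReplicionTemplate],
    strain_graphs: Mapping[str, nx.Graph],
    g: nx.Graph,
    label_attr: str = "subcluster",
) -> Dict[str, str]:
    """Assign each pangenome node a replicon class.

    For every node, the replicon labels of its member loci in template
    genomes are pooled across templates (label-set union). Exactly one
    distinct label -> that label; several -> "undetermined"; none ->
    "unknown".
    """
    node_labels: Dict[str, set] = defaultdict(set)
    for tpl in templates:
        if tpl.genome_id not in strain_graphs:
            raise ValueError(f"template genome {tpl.genome_id!r} not among inputs")
        sg = strain_graphs[tpl.genome_id]
        genome_contigs = {sg.nodes[l]["contig"] for l in sg.nodes}
        for contig in tpl.contig_labels:
            if contig not in genome_contigs:
                raise ValueError(
                    f"template contig {contig!r} not found in genome "
                    f"{tpl.genome_id!r}"
                )
        for locus in sg.nodes:
            contig = sg.nodes[locus]["contig"]
            if contig in tpl.contig_labels:
                node_labels[sg.nodes[locus][label_attr]].add(
                    tpl.contig_labels[contig]
                )
    assignment: Dict[str, str] = {}
    for node in g.nodes:
        labels = node_labels.get(node, set())
        if not labels:
            assignment[node] = UNKNOWN
        elif len(labels) == 1:
            assignment[node] = next(iter(labels))
        else:
            assignment[node] = UNDETERMINED
    return assignment


def chromosomize_graphs(
    assignment: Mapping[str, str],
    strain_graphs: Mapping[str, nx.Graph],
    g: nx.Graph,
    label_attr: str = "subcluster",
) -> None:
    """Annotate the pangenome graph and all strain graphs in place with the
    replicon class of each (sub)cluster."""
    for node in g.nodes:
        g.nodes[node]["chromosome_class"] = assignment.get(node, UNKNOWN)
    for sg in strain_graphs.values():
        for locus in sg.nodes:
            label = sg.nodes[locus][label_attr]
            sg.nodes[locus]["chromosome_class"] = assignment.get(label, UNKNOWN)
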