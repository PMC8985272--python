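"""Readers and writers for the formats the pipeline consumes and emits.

GFF3 (CDS features only) and protein FASTA on the input side; GraphML,
cluster tables and presence/absence TSV on the output side. All writers
produce deterministic, sorted output so identical runs yield byte-identical
files.
"""

from __future__ import annotations

import logging
import urllib.parse
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
from Bio import SeqIO

from .model import GeneRecord, ProteinSet

logger = logging.getLogger(__name__)

__all__ = [
    "GFF3ParseError",
    "read_gff3",
    "read_protein_fasta",
    "write_graph",
    "read_graph",
    "node_strains",
    "write_presence_absence",
]


class GFF3ParseError(ValueError):
    """Raised for structurally invalid GFF3 input."""


def _parse_attributes(column: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in column.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff3(path, genome_id: str, id_attr: str = "ID") -> List[GeneRecord]:
    """Read the CDS features of one genome's GFF3 annotation.

    Each input file is treated as one strain. Only ``CDS`` features are
    ingested; records are sorted per contig by (start, end) and 0-based
    ordinals are assigned after sorting, so consecutive ordinals define the
    gene neighbourhood used for synteny edges.

    Parameters
    ----------
    path : path-like
        GFF3 file (9 tab-separated columns; an optional ``##FASTA`` section
        terminates parsing).
    genome_id : str
        Identifier recorded on every returned :class:`GeneRecord`.
    id_attr : str
        Attribute holding the locus identifier (``ID`` by default;
        annotation tools that populate ``locus_tag`` instead are supported
        by switching this).
    """
    path = Path(path)
    raw: Dict[str, List[dict]] = {}
    contig_order: List[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"columns, found {len(cols)}"
                )
            if cols[2] != "CDS":
                continue
            contig, start_s, end_s, strand = cols[0], cols[3], cols[4], cols[6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            attrs = _parse_attributes(cols[8])
            if id_attr not in attrs or not attrs[id_attr]:
                raise GFF3ParseError(
                    f"{path.name} line {lineno}: CDS at {contig}:{start}-{end} "
                    f"has no {id_attr} attribute"
                )
            if contig not in raw:
                raw[contig] = []
                contig_order.append(contig)
            raw[contig].append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "locus_id": attrs[id_attr],
                    "product": attrs.get("product", ""),
                }
            )
    records: List[GeneRecord] = []
    seen: Dict[str, str] = {}
    for contig in contig_order:
        feats = sorted(raw[contig], key=lambda f: (f["start"], f["end"]))
        for ordinal, f in enumerate(feats):
            if f["locus_id"] in seen:
                raise GFF3ParseError(
                    f"{path.name}: duplicate locus ID {f['locus_id']!r}"
                )
            seen[f["locus_id"]] = contig
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    contig_id=contig,
                    ordinal=ordinal,
                    start=f["start"],
                    end=f["end"],
                    strand=f["strand"],
                    locus_id=f["locus_id"],
                    product=f["product"],
                )
            )
    if not records:
        logger.warning("%s: no CDS features found", path)
    return records


def read_protein_fasta(path) -> ProteinSet:
    """Read the pooled multi-FASTA of predicted proteins.

    Record IDs (first whitespace-delimited header token) must equal GFF3
    locus IDs. Sequences are uppercased and a trailing stop symbol ``*`` is
    stripped.
    """
    proteins = ProteinSet()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {record.id!r}")
        proteins.add(record.id, seq)
    return proteins


_SCALARS = (str, int, float, bool)


def _serialize_attrs(attrs: dict, where: str) -> dict:
    out = {}
    for key, value in attrs.items():
        if isinstance(value, (set, frozenset, list, tuple)):
            out[key] = ";".join(sorted(str(v) for v in value))
        elif isinstance(value, _SCALARS):
            out[key] = value
        else:
            raise TypeError(
                f"{where}: attribute {key!r} has unserializable type "
                f"{type(value).__name__}"
            )
    return out


def write_graph(graph: nx.Graph, path) -> None:
    """Write a graph to GraphML with deterministic ordering.

    Nodes are emitted sorted by ID and edges sorted by endpoint pair, so a
    graph writes byte-identically every time. Set/list attribute values are
    serialized as semicolon-joined sorted strings; scalars keep their types
    through a read round trip.
    """
    out = graph.__class__()
    out.graph.update(_serialize_attrs(graph.graph, "graph"))
    for node in sorted(graph.nodes, key=str):
        out.add_node(node, **_serialize_attrs(graph.nodes[node], f"node {node}"))
    edges = sorted(
        (tuple(sorted((str(u), str(v)))), u, v) for u, v in graph.edges
    )
    for _, u, v in edges:
        out.add_edge(u, v, **_serialize_attrs(graph.edges[u, v], f"edge {u}-{v}"))
    nx.write_graphml(out, str(path))


def read_graph(path) -> nx.Graph:
    """Read a GraphML file written by :func:`write_graph` (typed attributes
    are restored; set-valued attributes come back as their string form)."""
    return nx.read_graphml(str(path), node_type=str)


def node_strains(graph: nx.Graph, node) -> frozenset:
    """Strain set of a pangenome node, whether held as a set (in memory) or
    as the semicolon-joined GraphML string form."""
    strains = graph.nodes[node].get("strains", frozenset())
    if isinstance(strains, str):
        return frozenset(s for s in strains.split(";") if s)
    return frozenset(strains)


def write_presence_absence(
    graph: nx.Graph, path, genomes: Optional[Sequence[str]] = None
) -> None:
    """Write the cluster x genome presence/absence matrix as TSV.

    Rows are subcluster node IDs (sorted), columns genome IDs (sorted),
    cells 1/0 for membership of the genome in the node's strain set.
    """
    if genomes is None:
        pool = set()
        for node in graph.nodes:
            pool |= node_strains(graph, node)
        genomes = sorted(pool)
    else:
        genomes = sorted(genomes)
    with open(path, "w") as fh:
        fh.write("subcluster\t" + "\t".join(genomes) + "\n")
        for node in sorted(graph.nodes, key=str):
            strains = node_strains(graph, node)
            row = "\t".join("1" if g in strains else "0" for g in genomes)
            fh.write(f"{node}\t{row}\n")
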