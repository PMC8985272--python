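# pansyn

Synteny-aware pangenome graphs for bacterial genome cohorts.

Most pangenome tools reduce a cohort of related genomes to a
presence/absence matrix of unconnected gene families. `pansyn` keeps the
gene *neighbourhood* (synteny): it builds one graph per strain over that
strain's loci, aggregates them into a weighted pangenome graph over protein
clusters, and then mines that graph for the structural signatures that
matter in comparative microbiology — strain-specific genes, mobile
elements with no fixed home, allelic variants, horizontally acquired
insertions and segregating insertion/deletion loops.

## The model

**Inputs.** One GFF3 file per genome (CDS features with `ID` and optional
`product` attributes) and a single multi-FASTA of all predicted proteins
whose record IDs match the CDS IDs. Each GFF3 file is one *strain*.

**Clustering cascade.** All proteins are clustered greedily at descending
identity tiers 90% → 80% → 75% → 70%. Identity between two proteins is
the number of identical aligned residues of a global alignment (BLOSUM62,
affine gaps) divided by the shorter length. At each tier, clusters with at
least as many members as there are input genomes are frozen; smaller
clusters fall through to the next tier, and everything left at 70% is
kept. One random member (seeded, reproducible) represents each cluster.

**Graphs.** Per strain, adjacency edges join loci with consecutive
positions on a contig (circular contigs close the ring) and paralogy edges
join same-cluster loci of one genome. The pangenome graph has one node per
cluster; an edge between clusters *u, v* carries weight

&nbsp;&nbsp;&nbsp;&nbsp;w(u,v) = |{genomes in which u and v hold directly neighbouring proteins}|

and edges with w < w_min are dropped (nodes never are). Paralogous
clusters are first split into *subclusters*, one per connected component
of their occurrence graph (occurrences linked when their flanking
clusters intersect) — i.e. one per unrelated genomic neighbourhood.

**Partitions.** With occupancy fraction f = |strains| / n_genomes, a node
is **hard core** (f ≥ 0.99), **soft core** (f ≥ 0.95), **shell**
(f ≥ 0.15) or **cloud** (below).

**Replicon assignment.** Given finished *template* genomes whose contigs
carry replicon labels, each subcluster is assigned the label of its
template members — a single label, `undetermined` on conflict (the
signature of cross-replicon repeats and misassemblies), or `unknown` when
absent from every template.

**Patterns.** Five detector classes on the filtered graph: *orphans*
(isolated nodes present in ≥ 2 genomes), *uniques* (single-genome nodes),
*variants* (≥ 2 parallel nodes sharing the same one or two anchors),
*insertions* (a direct anchor edge bypassed by a shell/cloud-only path)
and *InDels* (minimum-cycle-basis cycles of more than four nodes).

## Worked example

```bash
pansyn simulate --n-genomes 20 --backbone-genes 400 --seed 42 --out cohort/
pansyn run-all --gff-dir cohort/ --proteins cohort/proteins.faa \
    --min-weight 2 --circular-contigs cohort/circular_contigs.txt \
    --templates cohort/templates.tsv --out results/
```

The second command prints the per-stage summary:

```
clusters=442 edges=447 genomes=20 indels=3 insertions=4 orphans=3
proteins=8342 subclusters=444 uniques=5 variant_groups=4
```

Reading: the 8354 proteins of the 20 genomes collapse into 442 clusters;
two paralogous transposase families split into two context subclusters
each (444 nodes). At minimum edge weight 2 the detectors report 3 orphans
(mobile genes with a different neighbourhood in every carrier), 5
strain-unique genes, 4 variant bubbles (allele pairs below the 70%
clustering floor occupying one slot), 4 shell insertions bridged by their
anchors' direct edge, and 3 InDel cycles (alternative paths segregating
across the cohort). `results/` holds one strain GraphML per genome,
`pangenome.graphml`, `presence_absence.tsv`, cluster tables and the
`patterns/` reports with per-pattern overlay graphs.

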