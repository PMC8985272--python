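# Methods

This note records the model behind `pansyn`, the choices made where the
design was genuinely open, and what the synthetic test cohorts do and do
not demonstrate.

## Sequence identity and the clustering cascade

The cascade needs a pairwise identity measure compatible with greedy
incremental clustering tools. We define it as the number of identical
aligned residues in a global alignment divided by the **shorter**
sequence length, with BLOSUM62 scoring and affine gaps (open −10,
extend −1, end gaps penalised). The shorter-length denominator means a
truncated protein is still ~100% identical to its full-length homolog —
the convention that makes the cascade robust to fragmented annotations.
Arguments are ordered canonically before alignment so the measure is
exactly symmetric even when co-optimal alignments differ; identities are
counted from one optimal alignment, so in principle a co-optimal
alignment with more matches may exist, but all decisions sit far from
the thresholds in practice.

Greedy clustering processes sequences in decreasing length
(lexicographic tiebreak on locus ID), joining the first cluster whose
*founding* sequence matches at or above the tier. This makes the result
order-independent and reproducible, where external greedy tools are
input-order dependent. Identical sequences are deduplicated before
alignment (identity 1.0 passes any tier), which is what keeps the
cascade fast on cohorts where core genes are identical across strains.

The cascade runs at 0.90 / 0.80 / 0.75 / 0.70. Retention defaults to
`protein_count` (a cluster is frozen when its member count reaches the
number of input genomes); the alternative reading — distinct genomes
rather than members — is available as `retention_mode=genome_count`,
since paralogs make the two differ.

The cluster representative is drawn uniformly from the members by a
generator keyed on `(seed, cluster_id)`, so it is stable per cluster and
per run. One consequence worth noting: the greedy tier guarantee is to
the *founder*, and identity is not a metric, so a re-drawn
representative could in principle sit below the tier for a borderline
member. Cohorts generated here plant exact-copy members, where the
guarantee is trivially preserved.

## Graph construction

Adjacency is defined purely by consecutive CDS rank on a contig
(1-based GFF3 coordinates are kept but never used downstream); strand is
recorded but ignored. Contigs are linear unless flagged circular in a
side file, in which case last–first loci are adjacent. Edge weight
counts **genomes**, not occurrences: tandem repeats of a pair inside one
genome contribute 1. Self-loops (a cluster adjacent to itself) are
recorded but excluded from all pattern detectors.

Paralog splitting operationalises "minimal number of unrelated
neighbourhoods" as connected components of an occurrence graph: one
vertex per member locus across all genomes, an edge when the two
occurrences' flanking cluster sets (window of one adjacent locus each
side) intersect. Splitting runs **before** the minimum-weight filter, so
rare contexts are resolved while all evidence is still present; edges
are then re-weighted at subcluster level and filtered. Subclusters are
named `<cluster>_<k>` in order of their smallest occurrence; clusters
without paralogs keep their ID unchanged.

Partition boundaries use ≥ at every threshold and compare exact
fractions (ratios of small integers; no epsilon).

## Pattern detection

* **Orphans** run on the post-filter graph, so the minimum edge weight
  directly controls orphan calls — a node whose every adjacency is
  supported by a single genome becomes isolated at w_min = 2. This is
  intended: per-genome random placement is exactly what the filter is
  meant to expose.
* **Variants** group candidate nodes (≤ 2 neighbours) by their *exact*
  neighbour set. Parallel alternatives of one slot necessarily share
  both anchors, and exact grouping avoids spurious groups that a
  subset-of-anchors rule produces around degree-1 nodes. A truncated
  dead-end allele that has lost one anchor contact therefore forms its
  own (single-anchor) group rather than joining the two-anchor bubble —
  a deliberate precision/recall trade. Per-group strain overlap is
  reported so users can filter further.
* **Insertions** require the direct anchor edge to exist and every
  internal node of the alternative path (up to 10, configurable) to be
  shell or cloud.
* **InDels** use a minimum cycle basis (exhaustive simple-cycle
  enumeration is exponential; the basis is the tractable stand-in and is
  made deterministic by sorted node/edge insertion). Cycles of more than
  four nodes are reported, capped at 100 nodes so the whole-replicon
  ring of a circular chromosome is not reported as a structural variant.
  An insertion bubble with k ≥ 3 internal nodes also closes a (k+2)-cycle
  through its direct anchor edge; the orchestrator assigns such cycles to
  the insertion class only, so one biological event is reported once.
  The standalone cycle detector keeps the unfiltered behaviour.

## Synthetic cohorts

The generator emulates annotated cohorts with a shared collinear core
backbone of independent random proteins (pairwise identity ≈ 5%,
checked at generation against a 60% ceiling), one GFF3 per genome plus a
pooled protein FASTA, and a truth manifest per planted structure. The
reference cohort is 20 genomes over a 400-gene circular chromosome with
5 uniques, 3 orphans (3 carriers each), 4 variant pairs (alleles at 40%
mutual identity, 10/10 genome split), 4 three-gene insertions in 4
carriers, 3 six-node InDel loops (8/12 split) and 2 two-context paralog
families — sizes chosen so every partition class and every detector is
exercised while a full pipeline run stays around half a minute. The
planted structures are designed to be recovered at a minimum edge
weight of 2 (the generator records this as `min_edge_weight`), which is
also the regime in which random-placement orphans become isolated.

Protein mutation is substitution-only by default, so realized identity
is exact-position matching and can be controlled to ±0.02; alleles and
mutated family members therefore have exactly known divergence.

What passing on these cohorts does **not** show: robustness to
annotation noise (missed or split CDS), to real length variation and
indel-rich divergence, to contamination contigs, or to the skewed
occupancy distributions of real populations. The cohorts are a
correctness bed for the graph algorithms, not a realism simulator — no
codon models, no phylogeny-conditioned gain/loss rates.

## Replicon assignment

Multiple templates aggregate by label-set union; any conflict —
including chromosome-vs-plasmid conflict inside a single template — is
`undetermined`. Assignment happens at subcluster level, so a repeat
split into replicon-specific contexts resolves to distinct labels per
subcluster, while a repeat whose contexts share flanks (the generator's
cross-replicon two-gene motif, modelling an IS-element-induced
misassembly signature) stays one subcluster and is flagged
`undetermined`. Adding templates can move a cluster only from `unknown`
toward a label or `undetermined`, never back.

## Determinism and numerics

Every source of randomness (backbone sequences, planted placements,
carrier subsets, representative draws) descends from one integer seed;
writers sort nodes, edges, rows and keys, so identical seeds produce
byte-identical GraphML, TSV and text outputs. Thresholds are compared
with ≥ on exact fractions; the only floating-point comparison in the
pipeline (greedy identity vs tier) carries a 1e-12 slack against
representation error.

## Known limitations

* Variant detection misses mixed bubbles in which alleles do not share
  an identical anchor set (see above).
* The minimum cycle basis reports an independent cycle *basis*, not
  every cycle; nested or overlapping InDel loops may be summarised by a
  different but equivalent set of cycles.
* Insertion search enumerates simple paths up to length 10 between
  anchor pairs; dense accessory regions could in principle make this
  expensive, though shell/cloud subgraphs are sparse in practice.
* No annotation correction or gene refinding: what the GFF3 says is
  what the graph contains.
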