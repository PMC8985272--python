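"""Structural-pattern detectors on hand-built graphs and on the planted
reference cohort."""

import networkx as nx
import pytest

from pansyn.io_formats import read_graph
from pansyn.patterns import (
    clear_highlight,
    detect_patterns,
    find_indels,
    find_insertions,
    find_orphans,
    find_uniques,
    find_variants,
    highlight_subgraph,
    write_pattern_outputs,
)


def node(g, name, strains, partition="shell"):
    g.add_node(name, strains=frozenset(strains), partition=partition)


class TestOrphans:
    def test_isolated_multi_strain_node_reported(self):
        g = nx.Graph()
        node(g, "o", {"A", "B", "C"})
        assert find_orphans(g) == ["o"]

    def test_isolated_single_strain_node_is_not_an_orphan(self):
        g = nx.Graph()
        node(g, "u", {"A"})
        assert find_orphans(g) == []
        assert find_uniques(g) == ["u"]

    def test_connected_node_not_reported(self):
        g = nx.Graph()
        node(g, "o", {"A", "B"})
        node(g, "x", {"A", "B"})
        g.add_edge("o", "x", weight=2)
        assert find_orphans(g) == []

    def test_self_loop_does_not_count_as_connection(self):
        g = nx.Graph()
        node(g, "o", {"A", "B"})
        g.add_edge("o", "o", weight=2)
        assert find_orphans(g) == ["o"]


class TestUniques:
    def test_connected_single_strain_node_reported(self):
        g = nx.Graph()
        node(g, "u", {"A"})
        node(g, "x", {"A", "B"})
        node(g, "y", {"A", "B"})
        g.add_edge("u", "x")
        g.add_edge("u", "y")
        assert find_uniques(g) == ["u"]

    def test_two_strain_node_not_reported(self):
        g = nx.Graph()
        node(g, "n", {"A", "B"})
        assert find_uniques(g) == []

    def test_reference_cohort_uniques_match_manifest(self, reference_run):
        planted = {
            n
            for ps in reference_run.cohort.manifest
            if ps.expected_pattern == "unique"
            for n in reference_run.cohort.slot_nodes(
                reference_run.result.strain_graphs, ps.slot
            )
        }
        assert set(reference_run.result.report.uniques) == planted


def bubble_graph(n_internal=2, anchor_edge=False):
    """u, w anchors (with backbone context); internal v0..vk each adjacent
    to exactly {u, w}."""
    g = nx.Graph()
    node(g, "u", {"A", "B"}, "hard_core")
    node(g, "w", {"A", "B"}, "hard_core")
    node(g, "t_u", {"A", "B"}, "hard_core")
    node(g, "t_w", {"A", "B"}, "hard_core")
    g.add_edge("t_u", "u", weight=2)
    g.add_edge("w", "t_w", weight=2)
    for i in range(n_internal):
        node(g, f"v{i}", {"A"} if i % 2 else {"B"})
        g.add_edge("u", f"v{i}", weight=1)
        g.add_edge(f"v{i}", "w", weight=1)
    if anchor_edge:
        g.add_edge("u", "w", weight=2)
    return g


class TestVariants:
    def test_two_parallel_nodes_form_one_group(self):
        groups = find_variants(bubble_graph(2))
        assert len(groups) == 1
        assert groups[0].anchors == ("u", "w")
        assert groups[0].members == ["v0", "v1"]

    def test_single_internal_node_is_no_variant(self):
        assert find_variants(bubble_graph(1)) == []

    def test_dead_end_variants_on_one_anchor(self):
        g = nx.Graph()
        node(g, "u", {"A", "B"}, "hard_core")
        node(g, "t", {"A", "B"}, "hard_core")
        node(g, "t2", {"A", "B"}, "hard_core")
        node(g, "v0", {"A"})
        node(g, "v1", {"B"})
        g.add_edge("t2", "t")
        g.add_edge("t", "u")
        g.add_edge("u", "v0")
        g.add_edge("u", "v1")
        groups = find_variants(g)
        assert len(groups) == 1
        assert groups[0].anchors == ("u",)
        assert groups[0].members == ["v0", "v1"]

    def test_members_have_degree_at_most_two(self, reference_run):
        g = reference_run.result.pangenome
        for grp in reference_run.result.report.variants:
            for m in grp.members:
                assert g.degree(m) <= 2

    def test_reference_cohort_variants_match_manifest(self, reference_run):
        planted = {
            n
            for ps in reference_run.cohort.manifest
            if ps.expected_pattern == "variant"
            for n in reference_run.cohort.slot_nodes(
                reference_run.result.strain_graphs, ps.slot
            )
        }
        detected = {
            m for grp in reference_run.result.report.variants for m in grp.members
        }
        assert detected == planted


class TestInsertions:
    def test_single_cloud_node_alongside_direct_edge(self):
        g = bubble_graph(1, anchor_edge=True)
        g.nodes["v0"]["partition"] = "cloud"
        found = find_insertions(g)
        assert len(found) == 1
        assert found[0].anchors == ("u", "w") and found[0].path == ["v0"]

    def test_core_internal_node_disqualifies_path(self):
        g = bubble_graph(1, anchor_edge=True)
        g.nodes["v0"]["partition"] = "hard_core"
        assert find_insertions(g) == []

    def test_no_direct_anchor_edge_no_insertion(self):
        g = bubble_graph(1)
        g.nodes["v0"]["partition"] = "cloud"
        assert find_insertions(g) == []

    def test_reference_cohort_insertions_match_manifest(self, reference_run):
        planted = {
            n
            for ps in reference_run.cohort.manifest
            if ps.expected_pattern == "insertion"
            for n in reference_run.cohort.slot_nodes(
                reference_run.result.strain_graphs, ps.slot
            )
        }
        detected = {
            n for ins in reference_run.result.report.insertions for n in ins.path
        }
        assert detected == planted


def cycle_graph(lengths):
    g = nx.Graph()
    for k, length in enumerate(lengths):
        names = [f"c{k}_{i}" for i in range(length)]
        for n in names:
            node(g, n, {"A", "B"})
        for u, v in zip(names, names[1:] + names[:1]):
            g.add_edge(u, v, weight=1)
    return g


class TestInDels:
    @pytest.mark.parametrize("length,reported", [(3, 0), (4, 0), (5, 1), (6, 1)])
    def test_more_than_four_nodes_boundary(self, length, reported):
        assert len(find_indels(cycle_graph([length]))) == reported

    def test_mixed_lengths_report_only_long_cycles(self):
        cycles = find_indels(cycle_graph([3, 4, 5, 6]))
        assert sorted(len(c) for c in cycles) == [5, 6]

    def test_cycle_ordering_starts_at_smallest_node(self):
        (cycle,) = find_indels(cycle_graph([5]))
        assert cycle[0] == min(cycle)
        assert cycle[1] < cycle[-1]  # traverse toward the smaller neighbour

    def test_max_cycle_length_suppresses_giant_rings(self):
        g = cycle_graph([120])
        assert find_indels(g, max_cycle_len=100) == []
        assert len(find_indels(g, max_cycle_len=150)) == 1

    def test_reported_cycles_are_closed_with_existing_edges(self, reference_run):
        g = reference_run.result.pangenome
        for cyc in reference_run.result.report.indels:
            assert len(cyc) == len(set(cyc)) > 4
            for u, v in zip(cyc, cyc[1:] + cyc[:1]):
                assert g.has_edge(u, v)

    def test_reference_cohort_indels_match_manifest(self, reference_run):
        planted_internal = {
            n
            for ps in reference_run.cohort.manifest
            if ps.expected_pattern == "indel"
            for n in reference_run.cohort.slot_nodes(
                reference_run.result.strain_graphs, ps.slot
            )
        }
        report = reference_run.result.report
        assert len(report.indels) == reference_run.cohort.config.n_indel_loops
        detected_internal = set()
        for cyc in report.indels:
            detected_internal |= set(cyc)
        # every planted path node is inside a reported cycle (anchors are
        # backbone clusters and appear too)
        assert planted_internal <= detected_internal


class TestDetectPatternsOrchestration:
    def test_insertion_bubbles_not_double_reported_as_indels(self):
        # 3 internal cloud nodes + direct anchor edge: a 5-node cycle that
        # is an insertion, not an InDel
        g = nx.Graph()
        node(g, "a", {"A", "B", "C"}, "hard_core")
        node(g, "b", {"A", "B", "C"}, "hard_core")
        g.add_edge("a", "b", weight=2)
        chain = ["a", "i0", "i1", "i2", "b"]
        for n in chain[1:-1]:
            node(g, n, {"C"}, "cloud")
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v, weight=1)
        report = detect_patterns(g)
        assert len(report.insertions) == 1
        assert report.indels == []
        assert len(find_indels(g)) == 1  # the raw detector still sees the cycle

    def test_clean_backbone_cohort_has_no_patterns(self, tmp_path):
        from pansyn.fixtures import FixtureConfig, Replicon, generate_cohort
        from .conftest import run_cohort

        # the ring must exceed the InDel cycle cap (whole-replicon rings
        # are suppressed by max_cycle_len, not mistaken for InDels)
        cfg = FixtureConfig(
            n_genomes=3,
            replicons=(Replicon("chromosome_1", 120, True),),
            n_uniques=0, n_orphans=0, n_variant_pairs=0, n_insertions=0,
            n_indel_loops=0, n_paralog_families=0, min_edge_weight=1, seed=6,
        )
        run = run_cohort(generate_cohort(cfg), tmp_path)
        report = run.result.report
        assert report.orphans == [] and report.uniques == []
        assert report.variants == [] and report.insertions == []
        assert report.indels == []
        g = run.result.pangenome
        # pure circular backbone: a single ring, all hard core, weight 3
        assert g.number_of_nodes() == 120 and g.number_of_edges() == 120
        assert all(w == 3 for _, _, w in g.edges(data="weight"))
        assert all(d["partition"] == "hard_core" for _, d in g.nodes(data=True))


class TestPatternOutputs:
    def test_empty_report_writes_empty_files(self, tmp_path):
        from pansyn.patterns import PatternReport

        g = nx.Graph()
        write_pattern_outputs(PatternReport(), g, tmp_path)
        assert (tmp_path / "orphans.txt").read_text() == ""
        assert (tmp_path / "indels.txt").read_text() == ""
        assert (tmp_path / "insertions.tsv").read_text().startswith("node\t")
        assert read_graph(tmp_path / "indels.graphml").number_of_nodes() == 0

    def test_insertion_rows_carry_recounted_degree(self, reference_run):
        g = reference_run.result.pangenome
        rows = (
            (reference_run.out_dir / "patterns" / "insertions.tsv")
            .read_text()
            .splitlines()[1:]
        )
        assert rows
        for row in rows:
            node_id, degree = row.split("\t")[:2]
            assert int(degree) == g.degree(node_id)

    def test_indel_line_count_matches_report(self, reference_run):
        lines = (
            (reference_run.out_dir / "patterns" / "indels.txt")
            .read_text()
            .splitlines()
        )
        assert len(lines) == len(reference_run.result.report.indels)

    def test_pattern_files_are_deterministic(self, tmp_path, reference_run):
        report = reference_run.result.report
        g = reference_run.result.pangenome
        write_pattern_outputs(report, g, tmp_path / "a")
        write_pattern_outputs(report, g, tmp_path / "b")
        for name in ("orphans.txt", "uniques.txt", "variants.txt",
                     "insertions.tsv", "indels.txt", "indels.graphml"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestHighlightSubgraph:
    def test_empty_pattern_graph_highlights_nothing(self):
        g = bubble_graph(2)
        out = highlight_subgraph(g, nx.Graph())
        assert all("highlight" not in d for _, d in out.nodes(data=True))

    def test_cycle_pattern_highlights_exact_counts(self):
        g = cycle_graph([6])
        pattern = g.copy()
        out = highlight_subgraph(g, pattern)
        assert sum(1 for _, d in out.nodes(data=True) if d.get("highlight")) == 6
        assert sum(1 for *_, d in out.edges(data=True) if d.get("highlight")) == 6

    def test_missing_pattern_node_is_an_error(self):
        g = bubble_graph(2)
        pattern = nx.Graph()
        pattern.add_node("nope")
        with pytest.raises(ValueError, match="nope"):
            highlight_subgraph(g, pattern)

    def test_highlight_then_strip_is_identity(self):
        g = cycle_graph([6])
        stripped = clear_highlight(highlight_subgraph(g, g.copy()))
        assert nx.utils.graphs_equal(stripped, g)
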