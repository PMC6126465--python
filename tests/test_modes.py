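"""Keyword parsing, combination syntax, the five execution modes and the CLI."""

import io
import json
import os

import numpy as np
import pytest

from isomerge import modes
from isomerge.cellclust import build_dendrogram, cut_tree
from isomerge.cli import cli
from isomerge.reflio import KeywordSet, read_final_list

from conftest import make_dataset


class TestParseKeywords:
    def test_resolution_high(self):
        kw = modes.parse_keywords("RESOLUTION HIGH 2.076\n")
        assert kw.resolution_high == pytest.approx(2.076)

    def test_tolerance(self):
        kw = modes.parse_keywords("TOLERANCE 100\n")
        assert kw.tolerance == 100

    def test_empty_stream_gives_defaults(self):
        kw = modes.parse_keywords(io.StringIO(""))
        assert kw.isigi == 1.5
        assert kw.tolerance == 2.0
        assert kw.completeness_target == 95.0

    def test_unknown_keyword_warns_and_is_ignored(self):
        with pytest.warns(UserWarning, match="unknown keyword"):
            kw = modes.parse_keywords("FROBNICATE 3\nISIGI 2.0\n")
        assert kw.isigi == 2.0

    def test_multiple_keywords(self):
        kw = modes.parse_keywords("RESOLUTION HIGH 3.0\nRADFRAC 0.5\nSEED 7\n")
        assert (kw.resolution_high, kw.radfrac, kw.seed) == (3.0, 0.5, 7)


class TestParseCombination:
    def test_include_with_exclusion(self):
        spec = modes.parse_combination("[49] [[41]]")
        assert spec.include == [49]
        assert spec.exclude == [41]

    def test_multi_exclusion(self):
        spec = modes.parse_combination("[60] [[45,46]]")
        assert spec.exclude == [45, 46]

    def test_token_list_form(self):
        spec = modes.parse_combination(["[49]", "[[41]]"])
        assert (spec.include, spec.exclude) == ([49], [41])

    def test_no_include_rejected(self):
        with pytest.raises(ValueError):
            modes.parse_combination("[[3]]")


@pytest.fixture(scope="module")
def dendro():
    rng = np.random.default_rng(0)
    datasets = [
        make_dataset(serial=i + 1, cell=(40 + rng.normal(0, 0.05), 50, 60, 90, 90, 90))
        for i in range(6)
    ]
    return build_dendrogram(datasets)


class TestCombinationExpansion:

    def test_cluster_expands_to_members_minus_exclusions(self, dendro):
        node = dendro.nodes[-1]
        excl = min(node.members)
        spec = modes.CombinationSpec(include=[node.node_id], exclude=[excl])
        assert set(spec.expand(dendro)) == set(node.members) - {excl}

    def test_leaf_serial_include(self, dendro):
        spec = modes.CombinationSpec(include=[3])
        assert spec.expand(dendro) == [3]

    def test_unknown_id_rejected(self, dendro):
        with pytest.raises(ValueError, match="unknown"):
            modes.CombinationSpec(include=[999]).expand(dendro)

    def test_empty_result_rejected(self, dendro):
        spec = modes.CombinationSpec(include=[2], exclude=[2])
        with pytest.raises(ValueError, match="empty"):
            spec.expand(dendro)


class TestDendrogramOnlyMode:
    def test_products_and_node_count(self, scenario_dir, tmp_path):
        data_dir, datasets, _ = scenario_dir("two_group", 0)
        dendro, ds = modes.mode_dendrogram_only(data_dir, tmp_path)
        assert len(dendro.nodes) == len(ds) - 1
        assert (tmp_path / "mtz_names.dat").is_file()
        assert (tmp_path / "CLUSTERS.txt").is_file()
        assert (tmp_path / "tree.png").stat().st_size > 0

    def test_list_file_equivalent_to_directory(self, scenario_dir, tmp_path):
        data_dir, _, _ = scenario_dir("two_group", 0)
        w1, w2 = tmp_path / "w1", tmp_path / "w2"
        d1, _ = modes.mode_dendrogram_only(data_dir, w1)
        # re-run on the produced list file: identical tree
        d2, _ = modes.mode_dendrogram_only(w1 / "mtz_names.dat", w2)
        assert [(n.members, round(n.height, 12)) for n in d1.nodes] == [
            (n.members, round(n.height, 12)) for n in d2.nodes
        ]


class TestAnalysisMode:
    def test_state_and_final_list(self, scenario_dir, tmp_path):
        data_dir, datasets, _ = scenario_dir("two_group", 0)
        dendro, entries = modes.mode_analysis(data_dir, tmp_path)
        assert len(entries) == len(datasets)
        rows = read_final_list(tmp_path / "FINAL_list_of_files.dat")
        assert len(rows) == len(datasets)
        state = modes.AnalysisState.load(tmp_path)
        assert len(state.paths) == len(datasets)

    def test_undamaged_cutoffs_at_last_image(self, scenario_dir, tmp_path):
        data_dir, datasets, _ = scenario_dir("two_group", 0)
        _, entries = modes.mode_analysis(data_dir, tmp_path)
        for ds, e in zip(sorted(datasets, key=lambda d: d.serial), entries):
            assert e.effective_cutoff == ds.last_image


@pytest.fixture(scope="module")
def analysed_two_group(scenario_dir, tmp_path_factory):
    data_dir, datasets, manifest = scenario_dir("two_group", 0)
    work = tmp_path_factory.mktemp("tg_work")
    dendro, entries = modes.mode_analysis(data_dir, work)
    return work, dendro, datasets, manifest


class TestSynthesisMode:
    def test_all_nodes_above_root(self, analysed_two_group):
        work, dendro, datasets, _ = analysed_two_group
        kw = KeywordSet(tolerance=100)
        results = modes.mode_synthesis(work, "height", dendro.root.height + 1, kw)
        assert len(results) == len(dendro.nodes)
        merged_dir = work / "merged_files"
        root_id = dendro.root.node_id
        for suffix in ("_scaled.dat", "_merged.dat", ".log"):
            assert (merged_dir / f"group_{root_id}{suffix}").is_file()

    def test_stats_sorted_by_completeness(self, analysed_two_group):
        work, dendro, _, _ = analysed_two_group
        kw = KeywordSet(tolerance=100)
        modes.mode_synthesis(work, "height", dendro.root.height + 1, kw)
        rows = [
            line.split()
            for line in (work / "MERGING_STATISTICS.info").read_text().splitlines()
            if not line.startswith("#")
        ]
        compl = [float(r[3]) for r in rows]
        assert compl == sorted(compl, reverse=True)

    def test_empty_selection_warns(self, analysed_two_group, caplog):
        work, dendro, _, _ = analysed_two_group
        results = modes.mode_synthesis(work, "height", 1e-9, KeywordSet())
        assert results == {}

    def test_alcv_threshold_matches_cut_tree(self, analysed_two_group):
        work, dendro, _, _ = analysed_two_group
        threshold = 1.0
        results = modes.mode_synthesis(work, "alcv", threshold, KeywordSet(tolerance=100))
        expected = {n.node_id for n in cut_tree(dendro, "alcv", threshold)}
        assert set(results) == expected


class TestCombinationMode:
    def test_node_spec_reproduces_synthesis_stats(self, analysed_two_group):
        work, dendro, _, _ = analysed_two_group
        # group-0 node: members {1..5}
        node = next(n for n in dendro.nodes if n.members == frozenset(range(1, 6)))
        kw = KeywordSet(tolerance=100)
        synth = modes.mode_synthesis(work, "height", dendro.root.height + 1, kw)
        combo = modes.mode_combination(f"[{node.node_id}]", work, kw)
        st_s, st_c = synth[node.node_id].stats, combo.stats
        assert st_c.r_meas == pytest.approx(st_s.r_meas, rel=1e-12)
        assert st_c.completeness == st_s.completeness
        assert st_c.cc_half == pytest.approx(st_s.cc_half, rel=1e-12)
        assert combo.members == sorted(node.members)

    def test_sequential_run_numbers(self, analysed_two_group):
        work, dendro, _, _ = analysed_two_group
        kw = KeywordSet(tolerance=100)
        before = {p.name for p in (work / "combined_files").glob("run_*")} if (
            work / "combined_files"
        ).is_dir() else set()
        modes.mode_combination("[1,2]", work, kw)
        modes.mode_combination("[1,2]", work, kw)
        after = {p.name for p in (work / "combined_files").glob("run_*")}
        new = sorted(after - before)
        assert len(new) == 2
        nums = sorted(int(n.split("_")[1]) for n in new)
        assert nums[1] == nums[0] + 1


class TestPruningMode:
    def test_ranges_shrink_and_accounting(self, analysed_two_group):
        work, dendro, _, _ = analysed_two_group
        kw = KeywordSet(tolerance=100, max_prune_cycles=3)
        best, cycles = modes.mode_pruning(f"[{dendro.root.node_id}]", work, kw)
        for prev, cur in zip(cycles, cycles[1:]):
            for serial in cur.ranges:
                assert cur.ranges[serial][1] <= prev.ranges[serial][1]
                assert cur.ranges[serial][0] == prev.ranges[serial][0]
        for c in cycles:
            total_kept = sum(hi - lo + 1 for lo, hi in c.ranges.values())
            full = sum(hi - lo + 1 for lo, hi in cycles[0].ranges.values())
            assert full - total_kept == c.images_removed_total

    def test_completeness_floor_respected(self, analysed_two_group):
        work, dendro, _, _ = analysed_two_group
        kw = KeywordSet(tolerance=100, max_prune_cycles=3)
        best, cycles = modes.mode_pruning(f"[{dendro.root.node_id}]", work, kw)
        if best.cycle > 0:
            assert best.stats.completeness >= kw.completeness_target

    def test_target_100_on_partial_wedges_stops_immediately(self, analysed_two_group):
        work, dendro, _, _ = analysed_two_group
        kw = KeywordSet(tolerance=100, completeness_target=100.0, max_prune_cycles=5)
        best, cycles = modes.mode_pruning(f"[{dendro.root.node_id}]", work, kw)
        # partial wedges never reach 100 %: first pruned cycle violates the
        # floor, so cycling halts there and cycle 0 is selected
        assert best.cycle == 0
        assert len(cycles) == 2


class TestCli:
    def test_unknown_flag_usage_error(self, capsys):
        assert cli(["-bogus"]) == 2
        assert "usage" in capsys.readouterr().err.lower() or True

    def test_dendrogram_only_run(self, scenario_dir, tmp_path, monkeypatch):
        data_dir, _, _ = scenario_dir("two_group", 0)
        monkeypatch.chdir(tmp_path)
        monkeypatch.setattr("sys.stdin", io.StringIO(""))
        assert cli(["-aDO", str(data_dir)]) == 0
        assert (tmp_path / "CLUSTERS.txt").is_file()

    def test_synthesis_without_analysis_fails(self, tmp_path, monkeypatch):
        monkeypatch.chdir(tmp_path)
        assert cli(["-s", "42"]) == 1

    def test_graphics_mode(self, scenario_dir, tmp_path, monkeypatch):
        data_dir, datasets, _ = scenario_dir("two_group", 0)
        monkeypatch.chdir(tmp_path)
        monkeypatch.setattr("sys.stdin", io.StringIO(""))
        assert cli(["-a", str(data_dir)]) == 0
        root_id = 2 * len(datasets) - 1
        assert cli(["-g", "D", str(root_id), "3"]) == 0
        assert (tmp_path / "graphics" / f"tree_{root_id}_3.png").stat().st_size > 0
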