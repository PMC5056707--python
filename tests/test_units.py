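import numpy as np
import pandas as pd
import pytest

from gsikit.assignment import ConfusionTable
from gsikit.core import BaselineHierarchy
from gsikit.units import (apply_merges, iterate_units, merge_step,
                          misassignment_graph, replay_ledger)


def _ct(filtered: pd.DataFrame) -> ConfusionTable:
    empty = pd.DataFrame(index=filtered.index, columns=filtered.columns)
    return ConfusionTable(filtered.copy(), filtered, empty, pd.DataFrame())


def _hier(units: list[str], adjacency=None):
    ind_map = {f"f_{u}": f"s_{u}" for u in units}
    site_map = {f"s_{u}": u for u in units}
    return BaselineHierarchy(ind_map, site_map, adjacency=adjacency or [])


class TestMisassignmentGraph:
    def test_diagonal_tables_give_zero_weights(self):
        units = ["a", "b", "c"]
        diag = pd.DataFrame(np.diag([10, 12, 8]), index=units, columns=units)
        g = misassignment_graph(_ct(diag), diag)
        assert (g.to_numpy() == 0).all()

    def test_exclusive_exchange_is_max_edge(self):
        units = ["a", "b", "c"]
        m = pd.DataFrame([[5, 5, 0], [6, 4, 0], [0, 0, 10]],
                         index=units, columns=units)
        g = misassignment_graph(_ct(m), m)
        assert g.loc["a", "b"] == g.to_numpy().max()
        assert g.loc["a", "c"] == 0

    def test_weights_match_hand_recount(self):
        units = ["a", "b"]
        ho = pd.DataFrame([[8, 2], [1, 9]], index=units, columns=units)
        tf = pd.DataFrame([[16, 4], [6, 14]], index=units, columns=units)
        g = misassignment_graph(_ct(ho), tf)
        want = 0.5 * ((2 + 1) / 20 + (4 + 6) / 40)
        assert g.loc["a", "b"] == pytest.approx(want, abs=1e-12)
        assert g.loc["b", "a"] == pytest.approx(want, abs=1e-12)

    def test_partition_mismatch_rejected(self):
        a = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        b = pd.DataFrame(np.eye(2), index=["a", "c"], columns=["a", "c"])
        with pytest.raises(ValueError, match="different unit partitions"):
            misassignment_graph(_ct(a), b)


class TestMergeStep:
    def _graph(self, units, edges):
        g = pd.DataFrame(0.0, index=units, columns=units)
        for (u, v), w in edges.items():
            g.loc[u, v] = g.loc[v, u] = w
        return g

    def test_constructed_rule_application(self):
        units = ["R1", "R2", "R3"]
        hier = _hier(units, adjacency=[("R2", "R3")])
        precisions = {"R1": (0.95, 0.92), "R2": (0.60, 0.55),
                      "R3": (0.62, 0.58)}
        graph = self._graph(units, {("R2", "R3"): 0.3, ("R1", "R2"): 0.05})
        clusters = {"R1": 1, "R2": 2, "R3": 2}
        part, decisions = merge_step(precisions, graph, hier, clusters)
        assert part == {"R1": "R1", "R2": "R2+R3", "R3": "R2+R3"}
        by_unit = {d.unit: d.decision for d in decisions}
        assert by_unit == {"R1": "keep", "R2": "merge", "R3": "merge"}

    def test_all_passing_is_fixed_point(self):
        units = ["R1", "R2"]
        hier = _hier(units)
        precisions = {u: (0.9, 0.85) for u in units}
        part, decisions = merge_step(precisions, self._graph(units, {}), hier,
                                     {u: 1 for u in units})
        assert part == {u: u for u in units}
        assert all(d.decision == "keep" for d in decisions)

    def test_case_by_case_margin_keeps_near_miss(self):
        # one method 0.95, the other 0.79 >= 0.75: kept case-by-case
        units = ["R1", "R2"]
        hier = _hier(units)
        precisions = {"R1": (0.95, 0.79), "R2": (0.9, 0.9)}
        part, decisions = merge_step(precisions, self._graph(units, {}), hier,
                                     {u: 1 for u in units})
        assert part["R1"] == "R1"
        assert decisions[0].decision == "case_by_case_keep"

    def test_case_by_case_below_margin_merges(self):
        units = ["R1", "R2"]
        hier = _hier(units, adjacency=[("R1", "R2")])
        precisions = {"R1": (0.95, 0.60), "R2": (0.9, 0.9)}
        graph = self._graph(units, {("R1", "R2"): 0.2})
        part, decisions = merge_step(precisions, graph, hier,
                                     {u: 1 for u in units})
        assert part["R1"] == "R1+R2"
        assert decisions[0].decision == "case_by_case_merge"

    def test_isolated_subthreshold_unit_kept(self):
        units = ["R1", "R2"]
        hier = _hier(units)
        precisions = {"R1": (0.5, 0.5), "R2": (0.9, 0.9)}
        part, decisions = merge_step(precisions, self._graph(units, {}), hier,
                                     {"R1": 1, "R2": 2})  # different clusters
        assert part == {u: u for u in units}
        assert decisions[0].decision == "isolated"

    def test_manual_override_wins(self):
        units = ["R1", "R2"]
        hier = _hier(units)
        precisions = {"R1": (0.5, 0.5), "R2": (0.9, 0.9)}
        part, _ = merge_step(precisions, self._graph(units, {}), hier,
                             {u: 1 for u in units},
                             overrides={"R1": "keep"})
        assert part == {u: u for u in units}

    def test_nan_precision_counts_as_failing(self):
        units = ["R1", "R2"]
        hier = _hier(units, adjacency=[("R1", "R2")])
        precisions = {"R1": (np.nan, np.nan), "R2": (0.9, 0.9)}
        graph = self._graph(units, {("R1", "R2"): 0.1})
        part, decisions = merge_step(precisions, graph, hier,
                                     {u: 1 for u in units})
        assert part["R1"] == "R1+R2"


class TestApplyMerges:
    def test_chain_union(self):
        part = {"a": "a", "b": "b", "c": "c"}
        out = apply_merges(part, {"a": "b", "b": "c"})
        assert len(set(out.values())) == 1
        assert out["a"] == "a+b+c"

    def test_untouched_units_keep_names(self):
        part = {"a": "a", "b": "b", "c": "c"}
        out = apply_merges(part, {"a": "b"})
        assert out["c"] == "c" and out["a"] == "a+b"


class TestIterateUnits:
    def test_planted_pairs_merge_and_only_those(self, planted_baseline):
        gm, hierarchy = planted_baseline
        res = iterate_units(gm, hierarchy, panel_size=96, sizes=(12, 24, 96),
                            cv_repeats=5, seed=3)
        final = {u: res.hierarchy.rivers_of_unit(u)
                 for u in res.hierarchy.units()}
        assert final == {
            "river01+river02": ["river01", "river02"],
            "river03": ["river03"],
            "river04+river05": ["river04", "river05"],
            "river06": ["river06"],
        }
        assert res.converged
        assert len(res.ledger) <= len(hierarchy.rivers())

    def test_differentiated_baseline_is_fixed_point(self, small_baseline):
        gm, hierarchy = small_baseline
        res = iterate_units(gm, hierarchy, panel_size=96, sizes=(12, 24, 96),
                            cv_repeats=5, seed=3)
        assert res.hierarchy.river_to_unit == hierarchy.river_to_unit
        assert res.converged and len(res.ledger) == 1

    def test_unit_count_non_increasing(self, planted_baseline):
        gm, hierarchy = planted_baseline
        res = iterate_units(gm, hierarchy, panel_size=96, sizes=(12, 24, 96),
                            cv_repeats=5, seed=3)
        counts = [len(set(it.partition.values())) for it in res.ledger]
        counts.append(len(res.hierarchy.units()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ledger_replay_reproduces_partition(self, planted_baseline):
        gm, hierarchy = planted_baseline
        res = iterate_units(gm, hierarchy, panel_size=96, sizes=(12, 24, 96),
                            cv_repeats=5, seed=3)
        replayed = replay_ledger({r: r for r in hierarchy.rivers()},
                                 res.ledger)
        assert replayed == res.hierarchy.river_to_unit

    def test_final_panel_ranked_on_final_units(self, planted_baseline):
        gm, hierarchy = planted_baseline
        res = iterate_units(gm, hierarchy, panel_size=96, sizes=(12, 24, 96),
                            cv_repeats=5, seed=3)
        assert res.final_panel.grouping == "unit"
        assert len(res.final_panel.table) > 0
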