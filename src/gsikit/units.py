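"""Iterative definition of assignment units.

Rivers start as their own assignment units.  Each iteration evaluates
per-unit precision with two independent methods (hold-out/training and
two-fold cross-validation); a unit passing the 80% threshold with both is
kept, a unit failing both is merged with its strongest reciprocal-
misassignment partner among geographically/regionally admissible
neighbours, and a unit failing exactly one method is a case-by-case
decision mechanized with a margin rule (keep if the failing estimate is
within ``margin`` of the threshold) and overridable via config.  After
any merge, loci are re-ranked on the new unit partition and the
evaluation repeats until a fixed point (or ``max_iter``).

Every decision is appended to a ledger with the evidence used, and the
ledger alone is sufficient to replay the final partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import (ConfusionTable, TwofoldResult, evaluate_holdout,
                         holdout_split, twofold_cv)
from .core import BaselineHierarchy, GenotypeMatrix, counts_by_group
from .panel import DEFAULT_PANEL_SIZES, RankedPanel, rank_and_select, wc_theta_per_locus
from .structure import kmeans_bic_scan, river_cluster_labels

logger = logging.getLogger(__name__)


def misassignment_graph(ct_holdout: ConfusionTable,
                        ct_tfcv_filtered: pd.DataFrame,
                        ct_tfcv_unfiltered: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Symmetric reciprocal-misassignment rates between units.

    weight(u, v) = mean over the two evaluation methods of
    (mis(u->v) + mis(v->u)) / (fish from u + fish from v), computed on the
    cut-off-filtered confusion tables.  Returns a symmetric DataFrame.
    """
    a = ct_holdout.filtered
    b = ct_tfcv_filtered
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("confusion tables on different unit partitions")
    units = list(a.index)
    w = pd.DataFrame(0.0, index=units, columns=units)
    for tab in (a, b):
        m = tab.to_numpy(dtype=float)
        row = m.sum(axis=1)
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                denom = row[i] + row[j]
                if denom > 0:
                    w.iloc[i, j] += 0.5 * (m[i, j] + m[j, i]) / denom
    vals = w.to_numpy()
    vals = vals + vals.T
    return pd.DataFrame(vals, index=units, columns=units)


@dataclass
class UnitDecision:
    unit: str
    precision_holdout: float
    precision_tfcv: float
    decision: str                 # keep | merge | case_by_case_keep | case_by_case_merge | isolated
    target: str | None = None     # merge partner (unit label), if any
    evidence: dict = field(default_factory=dict)


@dataclass
class UnitIteration:
    iteration: int
    partition: dict[str, str]         # river -> unit at entry
    decisions: list[UnitDecision]
    new_partition: dict[str, str]     # river -> unit at exit


@dataclass
class UnitResult:
    hierarchy: BaselineHierarchy      # with the final river -> unit partition
    ledger: list[UnitIteration]
    converged: bool
    final_panel: RankedPanel | None = None
    final_holdout: ConfusionTable | None = None
    final_tfcv: TwofoldResult | None = None


def _admissible_partners(unit: str, units: list[str], cluster_of: dict[str, int],
                         hierarchy: BaselineHierarchy):
    same_cluster = [v for v in units
                    if v != unit and cluster_of.get(v) == cluster_of.get(unit)]
    adjacent = [v for v in same_cluster if hierarchy.units_adjacent(unit, v)]
    return (adjacent, True) if adjacent else (same_cluster, False)


def merge_step(precisions: dict[str, tuple[float, float]],
               graph: pd.DataFrame, hierarchy: BaselineHierarchy,
               cluster_of: dict[str, int], threshold: float = 0.80,
               margin: float = 0.05,
               overrides: dict[str, str] | None = None):
    """One round of keep/merge/case-by-case decisions.

    ``precisions`` maps unit -> (hold-out precision, two-fold CV mean
    precision); NaN counts as failing.  ``overrides`` maps unit ->
    "keep" or the label of a unit to merge with, standing in for the
    judgement calls a geneticist would make by hand.  Returns (new river
    -> unit partition, decisions).
    """
    units = hierarchy.units()
    overrides = overrides or {}
    decisions: list[UnitDecision] = []
    merge_with: dict[str, str] = {}

    def _pick_partner(unit: str):
        partners, used_adj = _admissible_partners(unit, units, cluster_of,
                                                  hierarchy)
        if not partners:
            return None, used_adj, {}
        weights = {v: float(graph.loc[unit, v]) for v in partners}
        best = max(sorted(weights), key=lambda v: weights[v])
        top = dict(sorted(weights.items(), key=lambda kv: -kv[1])[:3])
        return best, used_adj, top

    for unit in units:
        ph, pt = precisions[unit]
        ok_h = (not np.isnan(ph)) and ph >= threshold
        ok_t = (not np.isnan(pt)) and pt >= threshold
        ov = overrides.get(unit)
        if ov is not None:
            if ov == "keep":
                decisions.append(UnitDecision(unit, ph, pt, "keep",
                                              evidence={"override": True}))
            else:
                merge_with[unit] = ov
                decisions.append(UnitDecision(unit, ph, pt, "merge", ov,
                                              {"override": True}))
            continue
        if ok_h and ok_t:
            decisions.append(UnitDecision(unit, ph, pt, "keep"))
            continue
        partner, used_adj, top = _pick_partner(unit)
        evidence = {"partners": top, "cluster": cluster_of.get(unit),
                    "adjacency_used": used_adj}
        if not ok_h and not ok_t:
            if partner is None:
                logger.warning("unit %s sub-threshold but isolated; kept", unit)
                decisions.append(UnitDecision(unit, ph, pt, "isolated",
                                              evidence=evidence))
            else:
                merge_with[unit] = partner
                decisions.append(UnitDecision(unit, ph, pt, "merge", partner,
                                              evidence))
        else:  # exactly one method passed
            failing = pt if ok_h else ph
            if (not np.isnan(failing)) and failing >= threshold - margin:
                decisions.append(UnitDecision(
                    unit, ph, pt, "case_by_case_keep", evidence=evidence))
            elif partner is None:
                decisions.append(UnitDecision(unit, ph, pt, "isolated",
                                              evidence=evidence))
            else:
                merge_with[unit] = partner
                decisions.append(UnitDecision(unit, ph, pt,
                                              "case_by_case_merge", partner,
                                              evidence))

    new_partition = apply_merges(hierarchy.river_to_unit, merge_with)
    return new_partition, decisions


def apply_merges(river_to_unit: dict[str, str],
                 merge_with: dict[str, str]) -> dict[str, str]:
    """Union-find over the requested merges; merged units are renamed to the
    '+'-joined sorted list of their member rivers."""
    parent = {u: u for u in set(river_to_unit.values())}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for u, v in merge_with.items():
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    members_of_unit: dict[str, list[str]] = {}
    for river, unit in river_to_unit.items():
        members_of_unit.setdefault(unit, []).append(river)
    groups: dict[str, list[str]] = {}
    merged_units: dict[str, list[str]] = {}
    for unit, rivers in members_of_unit.items():
        root = find(unit)
        groups.setdefault(root, []).extend(rivers)
        merged_units.setdefault(root, []).append(unit)
    out: dict[str, str] = {}
    for root, rivers in groups.items():
        if len(merged_units[root]) == 1:   # membership unchanged: keep name
            label = merged_units[root][0]
        else:
            label = "+".join(sorted(rivers))
        for r in rivers:
            out[r] = label
    return out


def replay_ledger(initial_partition: dict[str, str],
                  ledger: list[UnitIteration]) -> dict[str, str]:
    """Reapply the recorded merge decisions; must reproduce the final
    partition bit-exactly (audit property)."""
    part = dict(initial_partition)
    for it in ledger:
        merge_with = {d.unit: d.target for d in it.decisions
                      if d.target is not None}
        part = apply_merges(part, merge_with)
    return part


def iterate_units(gm: GenotypeMatrix, hierarchy: BaselineHierarchy,
                  panel_size: int = 288, sizes=DEFAULT_PANEL_SIZES,
                  threshold: float = 0.80, margin: float = 0.05,
                  cutoff: float = 80.0, per_site_holdout: int = 6,
                  cv_repeats: int = 10, k_max: int = 12, max_iter: int = 20,
                  seed: int = 0,
                  overrides: dict[str, str] | None = None) -> UnitResult:
    """Run the full iterative unit-definition loop.

    Regional clusters (k-means/BIC on all individuals, majority vote per
    river) and the hold-out split are computed once; within the loop, loci
    are ranked on the current unit partition, both evaluators are run on
    the ``panel_size`` top loci, and ``merge_step`` updates the partition
    until nothing changes.  The final panel is re-ranked on the final
    units.
    """
    rng = np.random.default_rng(seed)
    train, hold = holdout_split(gm, hierarchy, per_site_holdout,
                                int(rng.integers(2 ** 31)))
    scan = kmeans_bic_scan(gm, k_max=min(k_max, gm.n_individuals),
                           seed=int(rng.integers(2 ** 31)))
    river_clusters = river_cluster_labels(scan, gm, hierarchy)

    hier = hierarchy
    ledger: list[UnitIteration] = []
    converged = False
    final_panel = None
    final_holdout = None
    final_tfcv = None
    for it in range(max_iter):
        cluster_of = {u: _majority(
            [river_clusters[r] for r in hier.rivers_of_unit(u)])
            for u in hier.units()}
        theta = wc_theta_per_locus(counts_by_group(train, hier, "unit"))
        ranked = rank_and_select(theta, sizes=tuple(sorted(set(sizes) |
                                                           {panel_size})),
                                 grouping="unit")
        use_size = min(panel_size, len(ranked.table))
        panel_loci = ranked.panel(use_size)
        ct_hold = evaluate_holdout(train, hold, hier, panel_loci, cutoff)
        tfcv = twofold_cv(gm, hier, panel_loci, repeats=cv_repeats,
                          cutoff=cutoff, seed=int(rng.integers(2 ** 31)))
        final_panel, final_holdout, final_tfcv = ranked, ct_hold, tfcv
        precisions = {
            u: (float(ct_hold.metrics.loc[u, "proportion_correct"]),
                float(tfcv.per_unit.loc[u, "mean"]))
            for u in hier.units()}
        graph = misassignment_graph(ct_hold, tfcv.confusion_filtered)
        new_part, decisions = merge_step(precisions, graph, hier, cluster_of,
                                         threshold, margin, overrides)
        ledger.append(UnitIteration(it, dict(hier.river_to_unit), decisions,
                                    dict(new_part)))
        if new_part == hier.river_to_unit:
            converged = True
            break
        hier = hier.with_units(new_part)
    if not converged:
        logger.warning("iterate_units: max_iter=%d reached without fixed point",
                       max_iter)
    return UnitResult(hier, ledger, converged, final_panel, final_holdout,
                      final_tfcv)


def _majority(labels: list[int]) -> int:
    vals, cnts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(cnts)])
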