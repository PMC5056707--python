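"""Bayesian individual assignment and its evaluation.

The genotype likelihood is the Rannala-Mountain compound-Dirichlet
predictive: with reference gene counts (x_A, x_B), n = x_A + x_B, and a
per-allele prior of 1/2 (k = 2 alleles, lambda = 1/k):

    P(AA) = (x_A + 1/2)(x_A + 3/2) / ((n + 1)(n + 2))
    P(AB) = 2 (x_A + 1/2)(x_B + 1/2) / ((n + 1)(n + 2))
    P(BB) = (x_B + 1/2)(x_B + 3/2) / ((n + 1)(n + 2))

multiplied over loci (missing loci skipped).  An individual is scored
against every baseline *site*; the per-site likelihoods are normalized to
a 0-100 scale across all sites, and site scores are summed within each
river/unit — so a fish spread thinly over the several sites of one river
still scores highly for that river.  The best unit's score is compared
with a cut-off (default 80) to decide whether the fish is "assigned".

Evaluators maintain a strict leave-out discipline: a fish's own genotypes
never contribute to the reference counts it is scored against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (MISSING, AlleleCountTable, BaselineHierarchy,
                   GenotypeMatrix, Locus, counts_by_group)

logger = logging.getLogger(__name__)

TIE_TOL = 1e-9


def rm_genotype_logprobs(n_a: np.ndarray, n_b: np.ndarray) -> np.ndarray:
    """log P(genotype code | reference counts) for codes 0, 1, 2.

    Accepts arrays of any matching shape; returns shape (..., 3) ordered
    (BB, AB, AA) by A-copy count.  Probabilities sum to 1 by construction,
    including at n = 0 where they reduce to the prior predictive
    (3/8, 1/4, 3/8).
    """
    xa = np.asarray(n_a, dtype=float)
    xb = np.asarray(n_b, dtype=float)
    n = xa + xb
    denom = np.log(n + 1.0) + np.log(n + 2.0)
    lp0 = np.log(xb + 0.5) + np.log(xb + 1.5) - denom
    lp1 = np.log(2.0) + np.log(xa + 0.5) + np.log(xb + 0.5) - denom
    lp2 = np.log(xa + 0.5) + np.log(xa + 1.5) - denom
    return np.stack([lp0, lp1, lp2], axis=-1)


def genotype_loglik(codes: np.ndarray, n_a: np.ndarray, n_b: np.ndarray) -> float:
    """Log-likelihood of one individual's genotypes against one reference.

    ``codes`` is the per-locus A-copy vector (-1 = missing, skipped);
    ``n_a``/``n_b`` the reference gene counts per locus.  Raises if no
    locus is usable.
    """
    codes = np.asarray(codes)
    ok = codes != MISSING
    if not ok.any():
        raise ValueError("individual unscorable: no usable loci")
    lp = rm_genotype_logprobs(np.asarray(n_a)[ok], np.asarray(n_b)[ok])
    return float(lp[np.arange(ok.sum()), codes[ok]].sum())


def loglik_matrix(codes: np.ndarray, counts: AlleleCountTable) -> np.ndarray:
    """(N individuals x G reference groups) log-likelihood matrix."""
    lp = rm_genotype_logprobs(counts.n_a, counts.n_b)  # (G, L, 3)
    N = codes.shape[0]
    ll = np.zeros((N, len(counts.groups)))
    for g in range(3):
        ll += (codes == g).astype(float) @ lp[:, :, g].T
    return ll


@dataclass
class AssignmentScore:
    """Per-unit summed scores (0-100 scale) for one individual."""

    individual: str
    scores: dict[str, float]
    best_unit: str | None
    best_score: float
    passes_cutoff: bool
    tie: bool = False
    site_loglik: dict[str, float] | None = None


def _unit_membership(counts: AlleleCountTable,
                     hierarchy: BaselineHierarchy) -> tuple[list[str], np.ndarray]:
    units = hierarchy.units()
    upos = {u: k for k, u in enumerate(units)}
    m = np.zeros((len(counts.groups), len(units)))
    for s, site in enumerate(counts.groups):
        m[s, upos[hierarchy.unit_of_site(site)]] = 1.0
    return units, m


def assign_all(gm: GenotypeMatrix, site_counts: AlleleCountTable,
               hierarchy: BaselineHierarchy, panel: list[str] | None = None,
               cutoff: float = 80.0) -> pd.DataFrame:
    """Assign every individual of ``gm`` against per-site reference counts.

    Returns a DataFrame indexed by individual with one score column per
    unit plus best_unit, best_score, passes_cutoff, tie and scorable.
    Likelihoods are computed in log space with max-subtraction so extreme
    panels never underflow to NaN.
    """
    if panel is not None:
        gm = gm.subset_loci(panel)
        jj = [site_counts.locus_ids.index(l) for l in panel]
        site_counts = AlleleCountTable(
            list(site_counts.groups), list(panel),
            site_counts.n_a[:, jj], site_counts.n_b[:, jj],
            site_counts.n_het[:, jj], site_counts.n_ind[:, jj],
            site_counts.grouping)
    units, member = _unit_membership(site_counts, hierarchy)
    ll = loglik_matrix(gm.codes, site_counts)              # (N, S)
    scorable = (gm.codes != MISSING).any(axis=1)
    shifted = ll - ll.max(axis=1, keepdims=True)
    w = np.exp(shifted)
    site_scores = 100.0 * w / w.sum(axis=1, keepdims=True)
    unit_scores = site_scores @ member                     # (N, U)

    best_idx = np.argmax(unit_scores, axis=1)
    best = unit_scores[np.arange(len(gm.individuals)), best_idx]
    sorted_scores = np.sort(unit_scores, axis=1)
    tie = (len(units) > 1) & (sorted_scores[:, -1] - sorted_scores[:, -2] <= TIE_TOL)

    df = pd.DataFrame(unit_scores, index=gm.individuals, columns=units)
    df["best_unit"] = [units[k] for k in best_idx]
    df["best_score"] = best
    df["tie"] = tie
    df["scorable"] = scorable
    df.loc[~scorable, units] = np.nan
    df.loc[~scorable, ["best_unit"]] = None
    df.loc[~scorable, "best_score"] = np.nan
    df["passes_cutoff"] = scorable & (best >= cutoff)
    return df


def assign_individual(codes: np.ndarray, site_counts: AlleleCountTable,
                      hierarchy: BaselineHierarchy,
                      cutoff: float = 80.0,
                      individual: str = "ind") -> AssignmentScore:
    """Score one individual; see ``assign_all`` for the scoring rule."""
    gm = GenotypeMatrix(np.asarray(codes, dtype=np.int8)[None, :], [individual],
                        [Locus(lid) for lid in site_counts.locus_ids])
    row = assign_all(gm, site_counts, hierarchy, cutoff=cutoff).iloc[0]
    units = hierarchy.units()
    if not row["scorable"]:
        return AssignmentScore(individual, {}, None, np.nan, False)
    ll = loglik_matrix(gm.codes, site_counts)[0]
    return AssignmentScore(
        individual, {u: float(row[u]) for u in units}, row["best_unit"],
        float(row["best_score"]), bool(row["passes_cutoff"]), bool(row["tie"]),
        dict(zip(site_counts.groups, ll)))


@dataclass
class ConfusionTable:
    """True unit x assigned unit counts, unfiltered and cut-off-filtered.

    ``metrics`` has one row per unit: n_fish (true origin), n_assigned_in
    (fish passing the cut-off), proportion_assigned (of the unit's own
    fish), and proportion_correct (precision: of fish assigned TO the
    unit at the cut-off, the fraction truly from it; NaN when nothing was
    assigned to the unit).
    """

    unfiltered: pd.DataFrame
    filtered: pd.DataFrame
    metrics: pd.DataFrame
    assignments: pd.DataFrame

    @property
    def units(self) -> list[str]:
        return list(self.unfiltered.index)

    def overall_accuracy(self, filtered: bool = False) -> float:
        t = self.filtered if filtered else self.unfiltered
        total = t.to_numpy().sum()
        return float(np.nan) if total == 0 else float(np.diag(t).sum() / total)

    def proportion_assigned_overall(self) -> float:
        n = self.unfiltered.to_numpy().sum()
        return float(self.filtered.to_numpy().sum() / n) if n else float(np.nan)


def tabulate_assignments(assignments: pd.DataFrame, true_units: pd.Series,
                         units: list[str]) -> ConfusionTable:
    """Build confusion tables and per-unit metrics from raw assignments."""
    unf = pd.DataFrame(0, index=units, columns=units, dtype=int)
    fil = pd.DataFrame(0, index=units, columns=units, dtype=int)
    df = assignments.copy()
    df["true_unit"] = true_units.reindex(df.index)
    for (t, a), grp in df[df["scorable"]].groupby(["true_unit", "best_unit"]):
        unf.loc[t, a] += len(grp)
        fil.loc[t, a] += int(grp["passes_cutoff"].sum())
    n_fish = df.groupby("true_unit").size().reindex(units).fillna(0).astype(int)
    assigned_of_own = fil.sum(axis=1)
    assigned_to = fil.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_assigned = np.where(n_fish > 0, assigned_of_own / n_fish, np.nan)
        precision = np.where(assigned_to > 0, np.diag(fil) / assigned_to, np.nan)
    metrics = pd.DataFrame({
        "unit": units, "n_fish": n_fish.to_numpy(),
        "n_assigned_in": assigned_to.to_numpy(),
        "proportion_assigned": prop_assigned,
        "proportion_correct": precision,
    }).set_index("unit")
    return ConfusionTable(unf, fil, metrics, df)


def holdout_split(gm: GenotypeMatrix, hierarchy: BaselineHierarchy,
                  per_site_holdout: int = 6, seed: int = 0):
    """Randomly move ``per_site_holdout`` fish per site into a hold-out set.

    Sites with too few fish contribute all but one (logged).  Returns
    (training GenotypeMatrix, hold-out GenotypeMatrix); together they
    partition the baseline.
    """
    rng = np.random.default_rng(seed)
    sites = np.array([hierarchy.site_of(i) for i in gm.individuals])
    hold_idx: list[int] = []
    for site in hierarchy.sites():
        members = np.nonzero(sites == site)[0]
        if members.size == 0:
            continue
        take = min(per_site_holdout, members.size - 1)
        if take < per_site_holdout:
            logger.info("holdout_split: site %s has %d fish, holding out %d",
                        site, members.size, take)
        if take > 0:
            hold_idx.extend(rng.choice(members, size=take, replace=False))
    hold = np.zeros(gm.n_individuals, dtype=bool)
    hold[hold_idx] = True
    return gm.subset_individuals(np.nonzero(~hold)[0]), \
        gm.subset_individuals(np.nonzero(hold)[0])


def evaluate_holdout(train: GenotypeMatrix, holdout: GenotypeMatrix,
                     hierarchy: BaselineHierarchy, panel: list[str],
                     cutoff: float = 80.0) -> ConfusionTable:
    """Assign hold-out fish against training-set site counts.

    The training counts cannot contain any hold-out fish because the two
    matrices partition the baseline (checked).
    """
    overlap = set(train.individuals) & set(holdout.individuals)
    if overlap:
        raise ValueError(f"hold-out fish present in training set: {overlap}")
    site_counts = counts_by_group(train, hierarchy, "site")
    assignments = assign_all(holdout, site_counts, hierarchy, panel, cutoff)
    true_units = pd.Series({i: hierarchy.group_of(i, "unit")
                            for i in holdout.individuals})
    return tabulate_assignments(assignments, true_units, hierarchy.units())


@dataclass
class TwofoldResult:
    """Two-fold cross-validation: N = 2 x repeats precision estimates/unit."""

    estimates: pd.DataFrame       # units x (2*repeats) precision values
    per_unit: pd.DataFrame        # mean, sd, n over the estimates
    confusion_filtered: pd.DataFrame
    confusion_unfiltered: pd.DataFrame


def twofold_cv(gm: GenotypeMatrix, hierarchy: BaselineHierarchy,
               panel: list[str], repeats: int = 10, cutoff: float = 80.0,
               seed: int = 0) -> TwofoldResult:
    """Repeated site-stratified random halving; each half is reference for
    the other, so every fish is used both as reference and as test.

    Stratifying by site keeps every site represented in both halves; with
    an odd site, the extra fish alternates halves across repeats (a
    single-fish site alternates entirely, with a warning).
    """
    rng = np.random.default_rng(seed)
    units = hierarchy.units()
    sites = np.array([hierarchy.site_of(i) for i in gm.individuals])
    single = [s for s in hierarchy.sites() if (sites == s).sum() == 1]
    if single:
        logger.warning("twofold_cv: single-fish sites %s alternate halves",
                       single)
    est_cols = []
    sum_fil = pd.DataFrame(0, index=units, columns=units, dtype=int)
    sum_unf = pd.DataFrame(0, index=units, columns=units, dtype=int)
    for rep in range(repeats):
        in_a = np.zeros(gm.n_individuals, dtype=bool)
        for site in hierarchy.sites():
            members = np.nonzero(sites == site)[0]
            if members.size == 0:
                continue
            perm = rng.permutation(members)
            half = members.size // 2 + (members.size % 2) * (rep % 2)
            in_a[perm[:half]] = True
        ga = gm.subset_individuals(np.nonzero(in_a)[0])
        gb = gm.subset_individuals(np.nonzero(~in_a)[0])
        for test, ref in ((ga, gb), (gb, ga)):
            counts = counts_by_group(ref, hierarchy, "site")
            assignments = assign_all(test, counts, hierarchy, panel, cutoff)
            true_units = pd.Series({i: hierarchy.group_of(i, "unit")
                                    for i in test.individuals})
            ct = tabulate_assignments(assignments, true_units, units)
            est_cols.append(ct.metrics["proportion_correct"])
            sum_fil += ct.filtered
            sum_unf += ct.unfiltered
    estimates = pd.concat(est_cols, axis=1)
    estimates.columns = [f"rep{j + 1}" for j in range(len(est_cols))]
    per_unit = pd.DataFrame({
        "mean": estimates.mean(axis=1), "sd": estimates.std(axis=1, ddof=1),
        "n": estimates.notna().sum(axis=1)})
    return TwofoldResult(estimates, per_unit, sum_fil, sum_unf)


def exclusion_test(codes: np.ndarray, unit_n_a: np.ndarray,
                   unit_n_b: np.ndarray, n_sim: int = 1000,
                   seed: int = 0) -> float:
    """Monte-Carlo exclusion p-value for one individual against one unit.

    Simulates ``n_sim`` genotypes from the unit's posterior-mean allele
    frequencies (HWE per locus, the individual's missing loci excluded)
    and returns the fraction of simulated individuals whose log-likelihood
    is <= the observed one.  Small p means the genotype is unusually
    unlikely for that unit.  Diagnostic only; it does not gate assignment.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    codes = np.asarray(codes)
    ok = codes != MISSING
    if not ok.any():
        raise ValueError("individual unscorable: no usable loci")
    xa = np.asarray(unit_n_a, dtype=float)[ok]
    xb = np.asarray(unit_n_b, dtype=float)[ok]
    lp = rm_genotype_logprobs(xa, xb)              # (L, 3)
    obs = float(lp[np.arange(ok.sum()), codes[ok]].sum())
    rng = np.random.default_rng(seed)
    freqs = (xa + 0.5) / (xa + xb + 1.0)
    sim = rng.binomial(2, freqs, size=(n_sim, ok.sum()))
    sim_ll = np.zeros(n_sim)
    for g in range(3):
        sim_ll += (sim == g) @ lp[:, g]
    return float((sim_ll <= obs).mean())
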