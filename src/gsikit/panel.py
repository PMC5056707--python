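"""Per-locus Weir-Cockerham theta, locus ranking and panel selection.

The single-locus estimator is the 1984 variance-components theta-hat =
a/(a+b+c), with a the among-population, b the among-individual-within-
population, and c the within-individual component, computed from
per-group sample sizes, allele frequencies and observed heterozygosities.
Multi-locus theta combines loci as a ratio of sums, sum(a)/sum(a+b+c),
which is the standard way to average the estimator over loci.

Negative single-locus estimates (sampling noise around zero
differentiation) are kept as-is; they simply rank last.  Loci
monomorphic across all groups, or informative in fewer than two groups,
have no defined theta and are excluded from ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core import AlleleCountTable

logger = logging.getLogger(__name__)


def wc_components(counts: AlleleCountTable):
    """Weir-Cockerham variance components (a, b, c) per locus.

    Returns three float arrays of length L with NaN where the estimator is
    undefined (< 2 groups with data, or mean sample size <= 1).
    """
    n_i = counts.n_ind.astype(float)          # (G, L) individuals
    has = n_i > 0
    r = has.sum(axis=0).astype(float)         # populations with data
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.where(has, counts.n_a / np.maximum(counts.n, 1), 0.0)
        h_i = np.where(has, counts.n_het / np.maximum(n_i, 1), 0.0)
        n_tot = n_i.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n_i ** 2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    undefined = (r < 2) | (nbar <= 1) | (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c):
        arr[undefined] = np.nan
    return a, b, c


def wc_theta_per_locus(counts: AlleleCountTable) -> pd.Series:
    """Single-locus theta-hat = a/(a+b+c); NaN where undefined."""
    a, b, c = wc_components(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return pd.Series(theta, index=counts.locus_ids, name="theta")


def multilocus_theta(counts: AlleleCountTable) -> float:
    """Ratio-of-sums multi-locus theta over all loci with defined components."""
    a, b, c = wc_components(counts)
    ok = ~np.isnan(a)
    denom = (a + b + c)[ok].sum()
    if not ok.any() or denom == 0:
        raise ValueError("no informative loci for multi-locus theta")
    return float(a[ok].sum() / denom)


DEFAULT_PANEL_SIZES = (12, 24, 96, 192, 288, 384, 480)


@dataclass
class RankedPanel:
    """Loci ordered by descending theta; panel of size m = first m loci."""

    table: pd.DataFrame           # locus_id, theta, rank (1-based)
    sizes: tuple[int, ...]
    grouping: str = "river"

    def panel(self, size: int) -> list[str]:
        if size > len(self.table):
            raise ValueError(f"panel size {size} > {len(self.table)} ranked loci")
        return list(self.table["locus_id"].iloc[:size])

    @property
    def locus_order(self) -> list[str]:
        return list(self.table["locus_id"])


def rank_and_select(theta: pd.Series, sizes=DEFAULT_PANEL_SIZES,
                    grouping: str = "river") -> RankedPanel:
    """Rank loci by descending theta (ties by locus id) and fix panel sizes.

    Sizes beyond the number of rankable loci are dropped with a warning;
    the panels are nested by construction.
    """
    t = theta.dropna()
    if t.empty:
        raise ValueError("no loci with defined theta")
    df = (t.rename("theta").rename_axis("locus_id").reset_index()
          .sort_values(["theta", "locus_id"], ascending=[False, True],
                       kind="mergesort").reset_index(drop=True))
    df["rank"] = np.arange(1, len(df) + 1)
    usable = tuple(s for s in sizes if s <= len(df))
    if usable != tuple(sizes):
        logger.warning("rank_and_select: truncating sizes %s to %s "
                       "(%d rankable loci)", sizes, usable, len(df))
    return RankedPanel(df, usable, grouping)


@dataclass
class OutlierScreen:
    """Simplified chi-square/trimmed-mean F_ST outlier screen."""

    table: pd.DataFrame   # locus_id, theta, p, q, outlier
    mean_fst: float
    df: int
    trim: float

    @property
    def outliers(self) -> list[str]:
        return list(self.table.loc[self.table["outlier"], "locus_id"])


def detect_outlier_loci(theta: pd.Series, n_groups: int, trim: float = 0.05,
                        fdr: float = 0.05) -> OutlierScreen:
    """Flag loci whose theta is extreme relative to the genome-wide mean.

    The neutral mean F_ST is the two-sided ``trim``-fraction trimmed mean
    of theta; under the null, theta * (r-1) / mean_FST is treated as
    chi-square with r-1 degrees of freedom, giving a right-tail p per
    locus; Benjamini-Hochberg q-values are thresholded at ``fdr``.  A
    deliberately simple screen for the neutral-only pipeline variant, not
    a reimplementation of MCMC outlier methods.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    t = theta.dropna()
    if len(t) < 50:
        raise ValueError("need >= 50 loci with defined theta")
    srt = np.sort(t.to_numpy())
    k = int(np.floor(trim * len(srt)))
    core = srt[k:len(srt) - k] if k else srt
    fbar = float(core.mean())
    df = n_groups - 1
    if fbar <= 0:
        p = np.ones(len(t))
    else:
        p = chi2.sf(np.maximum(t.to_numpy(), 0.0) * df / fbar, df)
    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    out = pd.DataFrame({"locus_id": t.index, "theta": t.to_numpy(),
                        "p": p, "q": q, "outlier": q < fdr})
    return OutlierScreen(out.reset_index(drop=True), fbar, df, trim)


def class_rank_report(ranked: RankedPanel, locus_class: dict[str, str]) -> pd.DataFrame:
    """Descriptive mean/median rank per SNP class (no inference)."""
    df = ranked.table.copy()
    df["snp_class"] = df["locus_id"].map(locus_class)
    return (df.groupby("snp_class")["rank"]
            .agg(["count", "mean", "median"]).reset_index())
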