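"""Locus and site quality control.

Call-rate filtering, exact Hardy-Weinberg tests per site-locus
combination, Fisher's method to combine the per-locus p-values into one
per-site statistic, and a Holm (sequential Bonferroni) correction across
sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core import AlleleCountTable, BaselineHierarchy, GenotypeMatrix, Locus, counts_by_group

logger = logging.getLogger(__name__)


def filter_call_rate(loci: list[Locus], threshold: float = 0.90):
    """Discard loci with call rate strictly below ``threshold``.

    Returns (retained, removed); loci of either recognised class (SNP or
    MSV-3) are eligible for retention.
    """
    retained = [l for l in loci if l.call_rate >= threshold]
    removed = [l for l in loci if l.call_rate < threshold]
    if removed:
        logger.info("call-rate filter < %.2f removed %d of %d loci",
                    threshold, len(removed), len(loci))
    return retained, removed


def hwe_heterozygote_distribution(n_a: int, n_b: int):
    """Conditional distribution of the heterozygote count given allele counts.

    P(h | n_A, n_B) = n! 2^h n_A! n_B! / (n_AA! n_AB! n_BB! (2n)!) over all
    admissible h (same parity as n_A, h <= min(n_A, n_B)).  Returns
    (h values, probabilities).
    """
    if n_a < 0 or n_b < 0 or (n_a + n_b) % 2:
        raise ValueError("allele counts must be non-negative with even sum")
    n = (n_a + n_b) // 2
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    logp = (gammaln(n + 1) + hs * np.log(2.0) + gammaln(n_a + 1)
            + gammaln(n_b + 1) - gammaln((n_a - hs) / 2 + 1) - gammaln(hs + 1)
            - gammaln((n_b - hs) / 2 + 1) - gammaln(2 * n + 1))
    return hs, np.exp(logp)


@lru_cache(maxsize=200_000)
def _hwe_exact_cached(n_a: int, n_b: int, h_obs: int) -> float:
    hs, probs = hwe_heterozygote_distribution(n_a, n_b)
    p_obs = probs[np.nonzero(hs == h_obs)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test for one biallelic sample.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.  A
    monomorphic sample carries no information and returns 1.0.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype counts")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one individual required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    return _hwe_exact_cached(n_a, n_b, n_ab)


def combine_fisher(pvals) -> tuple[float, int, float]:
    """Fisher's method: X^2 = -2 sum(ln p), df = 2k, upper chi-square tail.

    Zero p-values are clipped to the smallest positive float (and logged)
    so the statistic stays finite.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("combine_fisher: clipping %d zero p-values", n_zero)
        p = np.maximum(p, np.finfo(float).tiny)
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return x2, df, float(chi2.sf(x2, df))


def holm_adjust(pvals, alpha: float = 0.05):
    """Holm step-down (sequential Bonferroni) adjustment.

    Returns (adjusted p-values, reject flags) in the input order.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject


@dataclass
class HweResult:
    """Per-site combined Hardy-Weinberg test."""

    site_id: str
    locus_pvalues: dict[str, float]
    statistic: float
    df: int
    p_combined: float
    p_adjusted: float = np.nan
    reject: bool = False
    uninformative_loci: tuple[str, ...] = ()


def hwe_site_scan(gm: GenotypeMatrix, hierarchy: BaselineHierarchy,
                  alpha: float = 0.05) -> list[HweResult]:
    """Exact HWE per site-locus, Fisher-combined per site, Holm across sites.

    Monomorphic (uninformative) site-loci contribute p = 1 to the
    combination so the degrees of freedom stay comparable across sites;
    they are flagged in the result.
    """
    sites = hierarchy.sites()
    counts = counts_by_group(gm, hierarchy, "site")
    n_het = counts.n_het
    n_ind = counts.n_ind
    n_a = counts.n_a
    results: list[HweResult] = []
    for si, site in enumerate(sites):
        pvals: dict[str, float] = {}
        uninformative: list[str] = []
        for j, lid in enumerate(gm.locus_ids):
            n = int(n_ind[si, j])
            if n == 0:
                uninformative.append(lid)
                pvals[lid] = 1.0
                continue
            het = int(n_het[si, j])
            aa = (int(n_a[si, j]) - het) // 2
            bb = n - aa - het
            p = hwe_exact_p(aa, het, bb)
            if int(n_a[si, j]) == 0 or int(n_a[si, j]) == 2 * n:
                uninformative.append(lid)
            pvals[lid] = p
        x2, df, p_comb = combine_fisher(list(pvals.values()))
        results.append(HweResult(site, pvals, x2, df, p_comb,
                                 uninformative_loci=tuple(uninformative)))
    adjusted, reject = holm_adjust([r.p_combined for r in results], alpha)
    for r, padj, rej in zip(results, adjusted, reject):
        r.p_adjusted = float(padj)
        r.reject = bool(rej)
    return results
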