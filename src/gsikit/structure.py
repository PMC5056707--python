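"""Between-site distance geometry and regional clustering.

Nei's D_A distance between site allele-frequency profiles, classical
(Torgerson) principal-coordinates analysis of the resulting distance
matrix for outlier-site screening, and PCA + k-means with a BIC scan to
choose the number of regional clusters.

D_A is not a metric (the triangle inequality can fail), which is fine for
ordination but means the PCoA of a D_A matrix can have negative
eigenvalues; those are reported but excluded from the coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import MISSING, AlleleCountTable, GenotypeMatrix

logger = logging.getLogger(__name__)


def nei_da(freqs_g1: np.ndarray, freqs_g2: np.ndarray) -> float:
    """Nei's D_A = 1 - (1/L) sum_l sum_alleles sqrt(x_l,a * y_l,a).

    Inputs are per-locus A-allele frequencies for two groups (biallelic);
    loci where either group has no observed genes (NaN frequency) are
    excluded and logged.
    """
    x = np.asarray(freqs_g1, dtype=float)
    y = np.asarray(freqs_g2, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError("no shared informative loci")
    n_drop = int((~ok).sum())
    if n_drop:
        logger.debug("nei_da: excluding %d loci without data in a group", n_drop)
    x, y = x[ok], y[ok]
    sim = np.sqrt(x * y) + np.sqrt((1 - x) * (1 - y))
    return float(1.0 - sim.mean())


@dataclass
class DistanceMatrix:
    """Symmetric site x site D_A matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def da_distance_matrix(counts: AlleleCountTable) -> DistanceMatrix:
    """Pairwise D_A between groups from observed allele frequencies."""
    freqs = counts.frequencies()
    G = len(counts.groups)
    d = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            d[i, j] = d[j, i] = nei_da(freqs[i], freqs[j])
    return DistanceMatrix(list(counts.groups), d)


def pcoa(dm: DistanceMatrix, n_axes: int = 2):
    """Classical Torgerson scaling of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and scales eigenvectors of
    positive eigenvalues by sqrt(eigenvalue).  Returns (coordinates
    DataFrame with up to ``n_axes`` columns, all eigenvalues descending —
    negative ones are reported but never embedded).
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(1.0, abs(evals).max(initial=1.0))
    pos = np.nonzero(evals > tol)[0][:n_axes]
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"axis{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dm.labels, columns=cols), evals


def flag_outlier_sites(coords: pd.DataFrame, n_mads: float = 3.0,
                       manual: list[str] | None = None) -> list[str]:
    """Flag sites far from the main cluster on the first two ordination axes.

    A site is flagged when its Euclidean distance from the coordinate-wise
    median exceeds median(distance) + ``n_mads`` x MAD(distance).  An
    explicit ``manual`` list overrides the rule entirely.  Flagged sites
    are reported, not removed; removal is the caller's decision.
    """
    if manual is not None:
        return list(manual)
    if len(coords) < 4:
        logger.warning("flag_outlier_sites: fewer than 4 sites, no flags")
        return []
    xy = coords.to_numpy(dtype=float)[:, :2]
    med = np.median(xy, axis=0)
    dist = np.sqrt(((xy - med) ** 2).sum(axis=1))
    mad = np.median(np.abs(dist - np.median(dist)))
    cut = np.median(dist) + n_mads * mad
    return [s for s, d in zip(coords.index, dist) if d > cut]


@dataclass
class ClusterScan:
    """k-means/BIC scan over candidate numbers of regional clusters."""

    ks: list[int]
    wss: list[float]
    bic: list[float]
    chosen_k: int
    labels: np.ndarray  # cluster label per individual at chosen_k
    n_pcs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "wss": self.wss, "bic": self.bic})


def _impute_and_project(gm: GenotypeMatrix, n_pcs: int | None, seed: int):
    x = gm.codes.astype(float)
    x[gm.codes == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    x -= x.mean(axis=0)
    max_pc = min(x.shape) - 1
    pca = PCA(n_components=max_pc, random_state=seed)
    scores = pca.fit_transform(x)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, 0.90) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    return scores[:, :n_pcs], n_pcs


def kmeans_bic_scan(gm: GenotypeMatrix, k_max: int = 12,
                    n_pcs: int | None = None, seed: int = 0,
                    elbow_fraction: float = 0.05,
                    chosen_k: int | None = None) -> ClusterScan:
    """k-means on the top principal components, BIC(k) = n ln(WSS/n) + k ln n.

    Missing genotypes are mean-imputed for the PCA only.  The number of
    clusters defaults to the elbow rule: the smallest k whose BIC gain to
    k+1 falls below ``elbow_fraction`` of the scan's total BIC range
    (manual ``chosen_k`` overrides, mirroring a visual elbow choice).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if gm.n_individuals < k_max:
        raise ValueError("more clusters requested than individuals")
    scores, n_pcs = _impute_and_project(gm, n_pcs, seed)
    n = scores.shape[0]
    ks, wss, bic, all_labels = [], [], [], []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(scores)
        w = max(float(km.inertia_), 1e-12)
        ks.append(k)
        wss.append(w)
        bic.append(n * np.log(w / n) + k * np.log(n))
        all_labels.append(km.labels_ + 1)
    if chosen_k is None:
        rng_bic = max(bic) - min(bic)
        chosen_k = k_max
        for i in range(len(ks) - 1):
            if bic[i] - bic[i + 1] < elbow_fraction * rng_bic or rng_bic == 0:
                chosen_k = ks[i]
                break
    return ClusterScan(ks, wss, bic, chosen_k, all_labels[chosen_k - 1], n_pcs)


def river_cluster_labels(scan: ClusterScan, gm: GenotypeMatrix,
                         hierarchy) -> dict[str, int]:
    """Majority k-means cluster per river (ties to the smaller label)."""
    out: dict[str, int] = {}
    rivers = np.array([hierarchy.group_of(i, "river") for i in gm.individuals])
    for river in hierarchy.rivers():
        labs = scan.labels[rivers == river]
        if labs.size == 0:
            continue
        vals, cnts = np.unique(labs, return_counts=True)
        out[river] = int(vals[np.argmax(cnts)])
    return out
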