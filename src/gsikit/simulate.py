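"""Synthetic hierarchical baselines and fishery mixtures with known structure.

The generator uses the Balding-Nichols F-model at each level of the
region -> river -> site hierarchy: given a parent frequency p and a
differentiation parameter F, the child frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F p(1-p).
F = 0 copies the parent frequency exactly.  Genotypes are then
Binomial(2, site frequency) per individual, i.e. Hardy-Weinberg within
site and no linkage between loci.

The default scenario ("demo18") is a desk-scale stand-in for a national
salmon baseline: 6 regions x 3 rivers x 2 sites x 24 fish at 300 loci,
with most differentiation at the region and river levels and only a
little between sites of the same river.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, BaselineHierarchy, GenotypeMatrix, Locus


@dataclass
class SimConfig:
    """Parameters of the hierarchical baseline generator.

    F_* are Balding-Nichols differentiation fractions in [0, 1) applied at
    the region, river and site levels respectively; ancestral frequencies
    are drawn uniformly from ``ancestral_freq_range``.
    """

    n_regions: int = 6
    rivers_per_region: int = 3
    sites_per_river: int = 2
    fish_per_site: int = 24
    n_loci: int = 300
    f_region: float = 0.03
    f_river: float = 0.03
    f_site: float = 0.005
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.02
    msv3_fraction: float = 0.16
    seed: int = 0

    def __post_init__(self):
        for name in ("f_region", "f_river", "f_site"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} outside [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        for name in ("missing_rate", "msv3_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_loci < 1 or self.fish_per_site < 1:
            raise ValueError("n_loci and fish_per_site must be >= 1")
        if min(self.n_regions, self.rivers_per_region, self.sites_per_river) < 1:
            raise ValueError("hierarchy dimensions must be >= 1")


def demo18(seed: int = 0, **overrides) -> SimConfig:
    """The default 18-river demonstration scenario."""
    return SimConfig(seed=seed, **overrides)


@dataclass
class MixtureTruth:
    """Known composition of a simulated fishery mixture."""

    units: list[str]
    pi_true: np.ndarray
    origin: list[str]            # true unit per mixture fish
    realized_counts: np.ndarray  # multinomial draw, sums to n_fish

    def __post_init__(self):
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        if not np.isclose(self.pi_true.sum(), 1.0):
            raise ValueError("pi_true must sum to 1")
        if self.realized_counts.sum() != len(self.origin):
            raise ValueError("realized counts do not match origins")


def _drift(parent: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols step: Beta around ``parent`` with parameter f."""
    if f == 0.0:
        return parent.copy()
    scale = (1.0 - f) / f
    return rng.beta(parent * scale, (1.0 - parent) * scale)


def simulate_baseline(cfg: SimConfig,
                      identical_river_pairs: list[tuple[int, int]] | None = None):
    """Draw a baseline; returns (GenotypeMatrix, BaselineHierarchy, loci).

    ``identical_river_pairs`` optionally lists pairs of global river
    indices (0-based) whose river-level frequencies are forced equal,
    planting undifferentiated river pairs for unit-merging experiments;
    both rivers of a pair must lie in the same region.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    n_rivers = cfg.n_regions * cfg.rivers_per_region
    n_sites = n_rivers * cfg.sites_per_river

    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=L)
    region_f = np.vstack([_drift(p_anc, cfg.f_region, rng)
                          for _ in range(cfg.n_regions)])
    river_f = np.vstack([
        _drift(region_f[r // cfg.rivers_per_region], cfg.f_river, rng)
        for r in range(n_rivers)])
    if identical_river_pairs:
        for a, b in identical_river_pairs:
            if a // cfg.rivers_per_region != b // cfg.rivers_per_region:
                raise ValueError(f"planted pair {(a, b)} spans regions")
            river_f[b] = river_f[a]
    site_f = np.vstack([
        _drift(river_f[s // cfg.sites_per_river], cfg.f_site, rng)
        for s in range(n_sites)])

    region_names = [f"region{k + 1:02d}" for k in range(cfg.n_regions)]
    river_names = [f"river{k + 1:02d}" for k in range(n_rivers)]
    site_names = [f"{river_names[s // cfg.sites_per_river]}_s{s % cfg.sites_per_river + 1}"
                  for s in range(n_sites)]

    codes = np.empty((n_sites * cfg.fish_per_site, L), dtype=np.int8)
    individuals: list[str] = []
    ind_to_site: dict[str, str] = {}
    row = 0
    for s in range(n_sites):
        g = rng.binomial(2, site_f[s], size=(cfg.fish_per_site, L))
        codes[row:row + cfg.fish_per_site] = g
        for k in range(cfg.fish_per_site):
            ind = f"{site_names[s]}_f{k + 1:03d}"
            individuals.append(ind)
            ind_to_site[ind] = site_names[s]
        row += cfg.fish_per_site
    if cfg.missing_rate > 0:
        drop = rng.random(codes.shape) < cfg.missing_rate
        codes[drop] = MISSING

    n_msv = int(round(cfg.msv3_fraction * L))
    msv_idx = set(rng.choice(L, size=n_msv, replace=False).tolist())
    loci = [Locus(f"locus{j + 1:04d}", "MSV3" if j in msv_idx else "SNP")
            for j in range(L)]

    site_to_river = {site_names[s]: river_names[s // cfg.sites_per_river]
                     for s in range(n_sites)}
    river_to_region = {river_names[r]: region_names[r // cfg.rivers_per_region]
                       for r in range(n_rivers)}
    # geographic stand-in: consecutive rivers within a region are neighbours
    adjacency = [(river_names[r], river_names[r + 1])
                 for r in range(n_rivers - 1)
                 if r // cfg.rivers_per_region == (r + 1) // cfg.rivers_per_region]

    gm = GenotypeMatrix(codes, individuals, loci).with_call_rates()
    hierarchy = BaselineHierarchy(ind_to_site, site_to_river, river_to_region,
                                  adjacency=adjacency)
    return gm, hierarchy, gm.loci


def simulate_mixture(unit_freqs: dict[str, np.ndarray], pi_true, n_fish: int,
                     seed: int, locus_ids: list[str] | None = None):
    """Draw a fishery mixture of known composition.

    ``unit_freqs`` maps unit -> per-locus A-allele frequency; fish origins
    are Multinomial(n_fish, pi_true) over the sorted unit labels (or the
    order of ``pi_true`` if it is a dict), genotypes Binomial(2, f_unit).
    Returns (GenotypeMatrix, MixtureTruth).
    """
    if isinstance(pi_true, dict):
        units = list(pi_true)
        pi = np.array([pi_true[u] for u in units], dtype=float)
    else:
        units = sorted(unit_freqs)
        pi = np.asarray(pi_true, dtype=float)
    if len(units) != len(pi):
        raise ValueError("pi_true length does not match units")
    if (pi < 0).any():
        raise ValueError("negative mixture proportions")
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi_true must sum to 1")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_fish, pi)
    freqs = np.vstack([np.asarray(unit_freqs[u], dtype=float) for u in units])
    L = freqs.shape[1]
    origin_idx = np.repeat(np.arange(len(units)), counts)
    codes = rng.binomial(2, freqs[origin_idx], size=(n_fish, L)).astype(np.int8)
    if locus_ids is None:
        locus_ids = [f"locus{j + 1:04d}" for j in range(L)]
    loci = [Locus(lid) for lid in locus_ids]
    individuals = [f"mix_f{i + 1:05d}" for i in range(n_fish)]
    gm = GenotypeMatrix(codes, individuals, loci)
    truth = MixtureTruth(units, pi, [units[k] for k in origin_idx], counts)
    return gm, truth
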