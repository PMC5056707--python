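"""Core domain types and I/O for SNP baselines.

A *baseline* is a collection of diploid, biallelic SNP genotypes for
individuals of known origin, organised hierarchically: individuals are
sampled at sites, sites belong to rivers, rivers may be grouped into
regions, and rivers are partitioned into *assignment units* (initially one
unit per river; the partition is refined by the unit-definition stage).

Genotypes are stored as copies of a designated "A" allele (0, 1, 2) with
-1 for missing, so a genotype matrix is a dense ``int8`` array tied to
individual, site and locus metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

logger = logging.getLogger(__name__)

MISSING = -1

SNP_CLASSES = ("SNP", "MSV3")


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class Locus:
    """A single biallelic marker.

    snp_class distinguishes normal diploid SNPs from multi-site variants
    residing on a single paralogue of a duplicated genomic region (MSV-3);
    the class is metadata only and never changes a computation.
    """

    locus_id: str
    snp_class: str = "SNP"
    call_rate: float = 1.0

    def __post_init__(self):
        if self.snp_class not in SNP_CLASSES:
            raise ValueError(f"unknown snp_class {self.snp_class!r}")
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValueError(f"call_rate {self.call_rate} outside [0, 1]")


@dataclass
class BaselineHierarchy:
    """individual -> site -> river -> (region, unit) grouping backbone.

    ``river_to_unit`` is the current assignment-unit partition; it starts
    as the identity (each river its own unit) and is updated by the
    unit-definition stage.  ``adjacency`` lists undirected river pairs
    regarded as geographic neighbours.
    """

    individual_to_site: dict[str, str]
    site_to_river: dict[str, str]
    river_to_region: dict[str, str] = field(default_factory=dict)
    river_to_unit: dict[str, str] = field(default_factory=dict)
    adjacency: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        for site in set(self.individual_to_site.values()):
            if site not in self.site_to_river:
                raise ValueError(f"site {site!r} has no river")
        if not self.river_to_unit:
            self.river_to_unit = {r: r for r in self.rivers()}

    # -- resolution helpers -------------------------------------------------
    def sites(self) -> list[str]:
        return sorted(self.site_to_river)

    def rivers(self) -> list[str]:
        return sorted(set(self.site_to_river.values()))

    def units(self) -> list[str]:
        return sorted(set(self.river_to_unit.values()))

    def site_of(self, individual: str) -> str:
        return self.individual_to_site[individual]

    def river_of_site(self, site: str) -> str:
        return self.site_to_river[site]

    def unit_of_site(self, site: str) -> str:
        return self.river_to_unit[self.site_to_river[site]]

    def group_of(self, individual: str, grouping: str) -> str:
        site = self.individual_to_site[individual]
        if grouping == "site":
            return site
        if grouping == "river":
            return self.site_to_river[site]
        if grouping == "unit":
            return self.river_to_unit[self.site_to_river[site]]
        raise ValueError(f"unknown grouping {grouping!r}")

    def groups(self, grouping: str) -> list[str]:
        if grouping == "site":
            return self.sites()
        if grouping == "river":
            return self.rivers()
        if grouping == "unit":
            return self.units()
        raise ValueError(f"unknown grouping {grouping!r}")

    def rivers_of_unit(self, unit: str) -> list[str]:
        return sorted(r for r, u in self.river_to_unit.items() if u == unit)

    def with_units(self, river_to_unit: dict[str, str]) -> "BaselineHierarchy":
        return replace(self, river_to_unit=dict(river_to_unit))

    def units_adjacent(self, unit_a: str, unit_b: str) -> bool:
        """Two units are adjacent if any of their member rivers are."""
        ra = set(self.rivers_of_unit(unit_a))
        rb = set(self.rivers_of_unit(unit_b))
        for x, y in self.adjacency:
            if (x in ra and y in rb) or (x in rb and y in ra):
                return True
        return False


@dataclass
class GenotypeMatrix:
    """individuals x loci matrix of A-allele copy numbers.

    codes[i, l] in {0, 1, 2} counts copies of the per-locus A allele;
    ``MISSING`` (-1) marks a failed genotype.  ``alleles[l]`` stores the
    (A, B) allele labels used when writing Genepop.
    """

    codes: np.ndarray
    individuals: list[str]
    loci: list[Locus]
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes at {np.argwhere(bad)[:5]}")
        if not self.alleles:
            self.alleles = [("001", "002")] * len(self.loci)
        if len(set(l.locus_id for l in self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus_ids) -> np.ndarray:
        pos = {l.locus_id: j for j, l in enumerate(self.loci)}
        return np.array([pos[lid] for lid in locus_ids], dtype=int)

    def call_rates(self) -> np.ndarray:
        """Fraction of non-missing cells per locus."""
        return (self.codes != MISSING).mean(axis=0)

    def with_call_rates(self) -> "GenotypeMatrix":
        """Return a copy whose Locus metadata carries observed call rates."""
        rates = self.call_rates()
        loci = [replace(l, call_rate=float(r)) for l, r in zip(self.loci, rates)]
        return GenotypeMatrix(self.codes.copy(), list(self.individuals), loci,
                              list(self.alleles))

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.codes[idx], [self.individuals[i] for i in idx],
            list(self.loci), list(self.alleles))

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        jj = self.locus_index(locus_ids)
        return GenotypeMatrix(
            self.codes[:, jj], list(self.individuals),
            [self.loci[j] for j in jj], [self.alleles[j] for j in jj])


@dataclass
class AlleleCountTable:
    """Observed allele (and heterozygote) counts per group per locus.

    n_a + n_b = n is the gene count (2 x genotyped individuals, always
    even because a missing genotype removes both copies).  Heterozygote
    and genotyped-individual counts are carried alongside because the
    Weir-Cockerham variance components need observed heterozygosity, not
    just allele frequencies.
    """

    groups: list[str]
    locus_ids: list[str]
    n_a: np.ndarray
    n_b: np.ndarray
    n_het: np.ndarray
    n_ind: np.ndarray
    grouping: str = "site"

    def __post_init__(self):
        shape = (len(self.groups), len(self.locus_ids))
        for name in ("n_a", "n_b", "n_het", "n_ind"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")
            if (arr < 0).any():
                raise ValueError(f"negative counts in {name}")
            setattr(self, name, arr)

    @property
    def n(self) -> np.ndarray:
        return self.n_a + self.n_b

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def select_groups(self, groups) -> "AlleleCountTable":
        gi = np.array([self.groups.index(g) for g in groups], dtype=int)
        return AlleleCountTable(list(groups), list(self.locus_ids),
                                self.n_a[gi], self.n_b[gi], self.n_het[gi],
                                self.n_ind[gi], self.grouping)

    def frequencies(self) -> np.ndarray:
        """Observed A-allele frequency per group/locus (NaN where no genes)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.n_a / np.maximum(self.n, 1), np.nan)

    def posterior_mean_frequencies(self) -> np.ndarray:
        """(x_A + 1/2)/(n + 1): posterior mean under the per-allele 1/2 prior."""
        return (self.n_a + 0.5) / (self.n + 1.0)


def counts_by_group(gm: GenotypeMatrix, hierarchy: BaselineHierarchy,
                    grouping: str = "site") -> AlleleCountTable:
    """Aggregate allele/heterozygote counts at site, river or unit level.

    Missing genotypes are excluded (they remove both gene copies).  Groups
    defined in the hierarchy but empty in ``gm`` get zero counts and a log
    message rather than an error.
    """
    groups = hierarchy.groups(grouping)
    gpos = {g: k for k, g in enumerate(groups)}
    labels = np.array(
        [gpos[hierarchy.group_of(ind, grouping)] for ind in gm.individuals],
        dtype=int)
    G, L = len(groups), gm.n_loci
    member = np.zeros((G, gm.n_individuals))
    member[labels, np.arange(gm.n_individuals)] = 1.0
    nz = gm.codes != MISSING
    a_copies = np.where(nz, gm.codes, 0).astype(float)
    n_a = (member @ a_copies).astype(np.int64)
    n_ind = (member @ nz.astype(float)).astype(np.int64)
    n_het = (member @ (gm.codes == 1).astype(float)).astype(np.int64)
    n_b = 2 * n_ind - n_a
    empty = [g for g, row in zip(groups, n_ind) if row.sum() == 0]
    if empty:
        logger.info("counts_by_group(%s): empty groups %s", grouping, empty)
    return AlleleCountTable(groups, gm.locus_ids, n_a, n_b, n_het, n_ind,
                            grouping)


# ---------------------------------------------------------------------------
# Genepop dialect
#
# Machine-written dialect: title line; one locus name per line; POP separator
# in upper case; individual lines "id ,  aabbcc ..." with 3-digit allele
# codes and 000000 for missing; one site per POP block.  A sidecar YAML
# (hierarchy config) names the site of each POP block and the site->river->
# region structure, which Genepop itself cannot express.
# ---------------------------------------------------------------------------

def _read_hierarchy_config(config) -> dict:
    import os

    if isinstance(config, (str, bytes, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    return config


def write_hierarchy_config(hierarchy: BaselineHierarchy, pop_sites, path,
                           locus_classes: dict[str, str] | None = None,
                           locus_alleles: dict[str, tuple[str, str]] | None = None):
    doc = {
        "pop_sites": list(pop_sites),
        "site_to_river": dict(hierarchy.site_to_river),
        "river_to_region": dict(hierarchy.river_to_region),
        "adjacency": [list(p) for p in hierarchy.adjacency],
    }
    if locus_classes:
        doc["locus_classes"] = dict(locus_classes)
    if locus_alleles:
        # records the A/B orientation, which Genepop cannot express for
        # loci where only one allele is observed
        doc["locus_alleles"] = {k: list(v) for k, v in locus_alleles.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_genepop(path, hierarchy_config):
    """Parse a Genepop file plus hierarchy config into the core types.

    Returns (GenotypeMatrix, BaselineHierarchy, list[Locus]); the loci
    carry call rates computed from the parsed matrix, and snp_class from
    the config's optional ``locus_classes`` map.
    """
    cfg = _read_hierarchy_config(hierarchy_config)
    pop_sites = list(cfg["pop_sites"])
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("line 1: empty file")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        name = lines[i].strip()
        if not name:
            raise GenepopParseError(f"line {i + 1}: blank line before first POP")
        if "," in name:  # single-line comma-separated locus list
            locus_names.extend(t.strip() for t in name.split(",") if t.strip())
        else:
            locus_names.append(name)
        i += 1
    if i == len(lines):
        raise GenepopParseError(f"line {i}: no POP block found")
    L = len(locus_names)

    pop_blocks: list[list[tuple[str, list[str], int]]] = []
    current: list[tuple[str, list[str], int]] | None = None
    while i < len(lines):
        line = lines[i]
        if line.strip().upper() == "POP":
            current = []
            pop_blocks.append(current)
        elif line.strip():
            if current is None:
                raise GenepopParseError(f"line {i + 1}: genotypes before POP")
            if "," not in line:
                raise GenepopParseError(
                    f"line {i + 1}: missing comma after individual id")
            ind_id, geno_part = line.split(",", 1)
            toks = geno_part.split()
            if len(toks) != L:
                raise GenepopParseError(
                    f"line {i + 1}: expected {L} genotypes, got {len(toks)}")
            for t in toks:
                if len(t) not in (4, 6) or not t.isdigit():
                    raise GenepopParseError(
                        f"line {i + 1}: malformed genotype token {t!r}")
            current.append((ind_id.strip(), toks, i + 1))
        i += 1
    if len(pop_blocks) != len(pop_sites):
        raise GenepopParseError(
            f"{len(pop_blocks)} POP blocks but {len(pop_sites)} pop_sites in "
            "hierarchy config")

    # First pass: collect allele codes per locus.
    observed: list[set[str]] = [set() for _ in range(L)]
    for block in pop_blocks:
        for _, toks, lineno in block:
            for j, t in enumerate(toks):
                w = len(t) // 2
                a1, a2 = t[:w], t[w:]
                for a in (a1, a2):
                    if int(a) != 0:
                        observed[j].add(a)
    allele_pairs: list[tuple[str, str]] = []
    cfg_alleles = cfg.get("locus_alleles", {})
    for j, name in enumerate(locus_names):
        obs = sorted(observed[j])
        if len(obs) > 2:
            raise GenepopParseError(
                f"locus {name!r}: >2 allele codes observed: {obs}")
        listed = cfg_alleles.get(name)
        if listed:
            a, b = listed[0], listed[1]
        elif len(obs) == 2:
            a, b = obs
        elif len(obs) == 1:
            a, b = obs[0], "002" if obs[0] != "002" else "001"
        else:
            a, b = "001", "002"
        allele_pairs.append((a, b))

    individuals: list[str] = []
    ind_to_site: dict[str, str] = {}
    rows: list[list[int]] = []
    for site, block in zip(pop_sites, pop_blocks):
        for ind_id, toks, lineno in block:
            row = []
            for j, t in enumerate(toks):
                w = len(t) // 2
                a1, a2 = t[:w], t[w:]
                if int(a1) == 0 or int(a2) == 0:
                    row.append(MISSING)
                    continue
                code = 0
                for a in (a1, a2):
                    if a == allele_pairs[j][0]:
                        code += 1
                    elif a != allele_pairs[j][1]:
                        raise GenepopParseError(
                            f"line {lineno}: allele {a!r} not in "
                            f"{allele_pairs[j]} at locus {locus_names[j]!r}")
                row.append(code)
            individuals.append(ind_id)
            ind_to_site[ind_id] = site
            rows.append(row)

    classes = cfg.get("locus_classes", {})
    loci = [Locus(n, classes.get(n, "SNP")) for n in locus_names]
    gm = GenotypeMatrix(np.array(rows, dtype=np.int8), individuals, loci,
                        allele_pairs).with_call_rates()
    hierarchy = BaselineHierarchy(
        individual_to_site=ind_to_site,
        site_to_river=dict(cfg["site_to_river"]),
        river_to_region=dict(cfg.get("river_to_region", {}) or {}),
        adjacency=[tuple(p) for p in cfg.get("adjacency", []) or []],
    )
    return gm, hierarchy, gm.loci


def write_genepop(gm: GenotypeMatrix, hierarchy: BaselineHierarchy, path,
                  title: str = "gsikit baseline") -> list[str]:
    """Write the matrix in the dialect above; returns the POP-block site order.

    Sites appear in order of first appearance in ``gm.individuals`` so a
    read/write round trip preserves both individual and site order.
    """
    site_order: list[str] = []
    by_site: dict[str, list[int]] = {}
    for i, ind in enumerate(gm.individuals):
        s = hierarchy.site_of(ind)
        if s not in by_site:
            by_site[s] = []
            site_order.append(s)
        by_site[s].append(i)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for l in gm.loci:
            fh.write(l.locus_id + "\n")
        for site in site_order:
            fh.write("POP\n")
            for i in by_site[site]:
                toks = []
                for j in range(gm.n_loci):
                    c = gm.codes[i, j]
                    if c == MISSING:
                        toks.append("000000")
                    else:
                        a, b = gm.alleles[j]
                        pair = [a] * int(c) + [b] * (2 - int(c))
                        toks.append(pair[0] + pair[1])
                fh.write(f"{gm.individuals[i]} ,  " + " ".join(toks) + "\n")
    return site_order


def write_genotypes_tsv(gm: GenotypeMatrix, hierarchy: BaselineHierarchy, path):
    import pandas as pd

    df = pd.DataFrame(gm.codes.astype(float), columns=gm.locus_ids)
    df[df < 0] = np.nan
    df.insert(0, "site_id", [hierarchy.site_of(i) for i in gm.individuals])
    df.insert(0, "individual_id", gm.individuals)
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.0f")


def read_genotypes_tsv(path, hierarchy_config):
    import pandas as pd

    cfg = _read_hierarchy_config(hierarchy_config)
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "site_id": str})
    locus_names = [c for c in df.columns if c not in ("individual_id", "site_id")]
    codes = df[locus_names].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    classes = cfg.get("locus_classes", {})
    loci = [Locus(n, classes.get(n, "SNP")) for n in locus_names]
    gm = GenotypeMatrix(codes, list(df["individual_id"]), loci).with_call_rates()
    hierarchy = BaselineHierarchy(
        individual_to_site=dict(zip(df["individual_id"], df["site_id"])),
        site_to_river=dict(cfg["site_to_river"]),
        river_to_region=dict(cfg.get("river_to_region", {}) or {}),
        adjacency=[tuple(p) for p in cfg.get("adjacency", []) or []],
    )
    return gm, hierarchy, gm.loci
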