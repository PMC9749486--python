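"""Seeded simulator of a biparental RIL cross with selective bulking.

The generator emulates the study design the package analyses: 213 recombinant
inbred lines from a cross between two near-isogenic soybean parents that
differ at two unlinked large-effect flowering-time loci; phenotypic extremes
are bulked (30 early / 21 late) and each bulk is pool-sequenced at
parent-informative biallelic sites.

Model summary
-------------
* Gametes follow a Markov chain along each chromosome with inter-marker
  recombination probability ``kosambi_r(delta cM)`` and no crossover
  interference; lines are advanced by single-seed-descent selfing from the F1.
* Phenotype: ``y_i = mu + sum_q a_q * (dose_iq - 1) + eps_i`` with
  ``dose`` = count of parent-B alleles at the QTL and
  ``eps ~ Normal(0, sigma^2)``.  A positive effect means the parent-B allele
  delays flowering.
* Pool reads at a site: true parent-B allele frequency
  ``f = sum(dose) / (2 * bulk size)``; total depth ``~ Poisson(lambda)``;
  parent-B read count ``~ Binomial(depth, f (1 - e) + (1 - f) e)`` with
  sequencing error rate ``e``.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genmap import kosambi_r

__all__ = [
    "MarkerMap",
    "QTL",
    "CrossConfig",
    "Population",
    "BulkSpec",
    "simulate_cross",
    "assign_phenotypes",
    "select_bulks",
    "simulate_pool_reads",
    "build_site_table",
    "study_cross",
    "null_cross",
    "linkage_subset",
]


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers with physical (bp) and genetic (cM) positions.

    ``table`` columns: ``chrom``, ``marker``, ``pos_bp``, ``cm``.  Within a
    chromosome physical positions are strictly increasing and genetic
    positions non-decreasing (two markers may be 0 cM apart).
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = ["chrom", "marker", "pos_bp", "cm"]
        if list(self.table.columns[:4]) != req:
            raise ValueError(f"marker map must have columns {req}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos_bp"].to_numpy()) > 0):
                raise ValueError(f"physical positions not strictly increasing on {chrom}")
            if not np.all(np.diff(sub["cm"].to_numpy()) >= 0):
                raise ValueError(f"genetic positions decrease on {chrom}")
            if np.any(sub["cm"].to_numpy() < 0):
                raise ValueError("cM positions must be >= 0")

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    @classmethod
    def uniform(
        cls,
        n_chrom: int = 2,
        length_cm: float = 100.0,
        n_markers: int = 200,
        bp_per_cm: float = 500_000.0,
        prefix: str = "chr",
    ) -> "MarkerMap":
        """Evenly spaced markers on ``n_chrom`` chromosomes of ``length_cm``."""
        rows = []
        for c in range(1, n_chrom + 1):
            cm = np.linspace(0.0, length_cm, n_markers)
            for j, x in enumerate(cm):
                rows.append(
                    (f"{prefix}{c}", f"{prefix}{c}_m{j + 1}",
                     int(round(x * bp_per_cm)) + 1, float(x))
                )
        return cls(pd.DataFrame(rows, columns=["chrom", "marker", "pos_bp", "cm"]))


@dataclass(frozen=True)
class QTL:
    """An additive locus: ``effect`` (days) is the shift per parent-B allele
    relative to the heterozygote; positive = parent-B allele delays flowering."""

    chrom: str
    cm: float
    effect: float


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated cross and pooled sequencing."""

    marker_map: MarkerMap
    n_lines: int = 213
    generations: int = 6          # filial generation; F6 = five selfings from F1
    qtls: tuple[QTL, ...] = ()
    mu: float = 35.0              # baseline days to first flower (R1 stage)
    sigma: float = 2.0            # residual SD, days
    depth: float = 50.0           # mean pool depth per site (lambda)
    error_rate: float = 0.005     # per-read allele error rate
    overdispersion: float | None = None  # optional NB dispersion of depth
    n_early: int = 30
    n_late: int = 21
    site_qual: float = 200.0      # site quality written into the site table
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 2:
            raise ValueError("need at least two lines")
        if self.sigma < 0 or self.depth <= 0:
            raise ValueError("sigma must be >= 0 and depth > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must lie in [0, 0.5)")
        for q in self.qtls:
            sub = self.marker_map.chrom_table(q.chrom)
            if sub.empty:
                raise ValueError(f"QTL chromosome {q.chrom!r} not on the map")
            if not (sub["cm"].min() <= q.cm <= sub["cm"].max()):
                raise ValueError(f"QTL at {q.cm} cM lies off the map of {q.chrom}")


@dataclass
class Population:
    """Simulated RIL population.

    ``genotypes``: DataFrame, lines x markers, codes 0 = homozygous parent-A,
    1 = heterozygous, 2 = homozygous parent-B.  ``phenotypes``: days to first
    flower per line (None until assigned).
    """

    genotypes: pd.DataFrame
    marker_map: MarkerMap
    phenotypes: pd.Series | None = None

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    def qtl_marker(self, qtl: QTL) -> str:
        """Marker nearest the QTL's cM position on its chromosome."""
        sub = self.marker_map.chrom_table(qtl.chrom)
        i = int(np.argmin(np.abs(sub["cm"].to_numpy() - qtl.cm)))
        return sub["marker"].iloc[i]

    def qtl_dose(self, qtl: QTL) -> np.ndarray:
        return self.genotypes[self.qtl_marker(qtl)].to_numpy()


@dataclass(frozen=True)
class BulkSpec:
    """A phenotypic-extreme bulk: label and member line indices."""

    label: str
    members: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("bulk members must be unique")


def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per row from parental haplotype pair (n, m) arrays."""
    n, m = hap_a.shape
    steps = np.empty((n, m), dtype=np.int8)
    steps[:, 0] = rng.random(n) < 0.5
    if m > 1:
        steps[:, 1:] = rng.random((n, m - 1)) < r
    strand = np.cumsum(steps, axis=1, dtype=np.int64) & 1
    return np.where(strand == 0, hap_a, hap_b)


def simulate_cross(config: CrossConfig, seed: int | None = None) -> Population:
    """Simulate ``n_lines`` RILs by single-seed descent from the F1.

    Each line carries two haplotypes per chromosome; every selfing generation
    replaces them with two independent gametes of the current plant.  The
    recombination probability between adjacent markers is
    ``kosambi_r(delta cM)`` (no interference along the chromosome).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_lines
    blocks = []
    for chrom in config.marker_map.chroms:
        sub = config.marker_map.chrom_table(chrom)
        cm = sub["cm"].to_numpy()
        r = kosambi_r(np.diff(cm))
        m = len(cm)
        hap_a = np.zeros((n, m), dtype=np.int8)   # parent-A haplotype
        hap_b = np.ones((n, m), dtype=np.int8)    # parent-B haplotype
        for _ in range(config.generations - 1):  # F1 -> F_g
            g1 = _gametes(hap_a, hap_b, r, rng)
            g2 = _gametes(hap_a, hap_b, r, rng)
            hap_a, hap_b = g1, g2
        blocks.append(pd.DataFrame(hap_a + hap_b, columns=sub["marker"].tolist()))
    genos = pd.concat(blocks, axis=1)
    genos.index = [f"RIL{i + 1:03d}" for i in range(n)]
    return Population(genotypes=genos, marker_map=config.marker_map)


def assign_phenotypes(pop: Population, config: CrossConfig,
                      seed: int | None = None) -> Population:
    """Attach additive two-(or k-)locus phenotypes to a simulated population."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1_000_003)
    y = np.full(pop.n_lines, config.mu, dtype=float)
    for q in config.qtls:
        y += q.effect * (pop.qtl_dose(q).astype(float) - 1.0)
    if config.sigma > 0:
        y += rng.normal(0.0, config.sigma, size=pop.n_lines)
    pheno = pd.Series(y, index=pop.genotypes.index, name="days_to_r1")
    return Population(genotypes=pop.genotypes, marker_map=pop.marker_map,
                      phenotypes=pheno)


def select_bulks(phenotypes: pd.Series, n_early: int = 30,
                 n_late: int = 21) -> tuple[BulkSpec, BulkSpec]:
    """Bulk the ``n_early`` earliest and ``n_late`` latest lines.

    Ties at either cut are resolved by ascending line position (stable sort),
    and the two bulks are disjoint by construction.
    """
    n = len(phenotypes)
    if n_early + n_late > n:
        raise ValueError("bulk sizes exceed the population size")
    order = np.argsort(phenotypes.to_numpy(), kind="stable")
    ef = tuple(int(i) for i in order[:n_early])
    lf = tuple(int(i) for i in order[n - n_late:])
    return BulkSpec("EF", ef), BulkSpec("LF", lf)


def _pool_depths(n_sites: int, depth: float, overdispersion: float | None,
                 rng: np.random.Generator) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(depth, size=n_sites)
    # Negative binomial via gamma-Poisson mixture; overdispersion = shape k,
    # variance = depth + depth^2 / k.
    lam = rng.gamma(overdispersion, depth / overdispersion, size=n_sites)
    return rng.poisson(lam)


def simulate_pool_reads(pop: Population, bulk: BulkSpec, depth: float = 50.0,
                        error_rate: float = 0.005,
                        overdispersion: float | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Pooled allele counts for one bulk at every marker site.

    Returns a DataFrame with ``chrom, pos, b_reads, a_reads`` where
    ``b_reads`` supports the parent-B allele.
    """
    if bulk.size == 0:
        raise ValueError("empty bulk")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    doses = pop.genotypes.iloc[list(bulk.members)].to_numpy(dtype=float)
    f = doses.sum(axis=0) / (2.0 * bulk.size)
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    total = _pool_depths(len(f), depth, overdispersion, rng)
    b = rng.binomial(total, p)
    mt = pop.marker_map.table
    return pd.DataFrame({
        "chrom": mt["chrom"].to_numpy(),
        "pos": mt["pos_bp"].to_numpy(),
        "b_reads": b,
        "a_reads": total - b,
    })


def build_site_table(pop: Population, ef: BulkSpec, lf: BulkSpec,
                     config: CrossConfig, seed: int | None = None) -> pd.DataFrame:
    """Full four-sample site table (parents + two bulks) for the scan.

    Parent-A carries the REF allele and parent-B the ALT allele at every
    simulated informative site; parental samples are sequenced at the same
    mean depth as the pools.  Columns follow the canonical site-table schema
    of :mod:`bsaqtl.sites`.
    """
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(base + 7_777_777)
    n_sites = len(pop.marker_map.table)
    e = config.error_rate
    pa_tot = _pool_depths(n_sites, config.depth, config.overdispersion, rng)
    pb_tot = _pool_depths(n_sites, config.depth, config.overdispersion, rng)
    pa_alt = rng.binomial(pa_tot, e)
    pb_alt = rng.binomial(pb_tot, 1.0 - e)
    ef_counts = simulate_pool_reads(pop, ef, config.depth, e,
                                    config.overdispersion, seed=base + 11)
    lf_counts = simulate_pool_reads(pop, lf, config.depth, e,
                                    config.overdispersion, seed=base + 13)
    mt = pop.marker_map.table
    return pd.DataFrame({
        "chrom": mt["chrom"].to_numpy(),
        "pos": mt["pos_bp"].to_numpy(),
        "vclass": "SNP",
        "indel_len": 0,
        "qual": config.site_qual,
        "pA_ref": pa_tot - pa_alt,
        "pA_alt": pa_alt,
        "pB_ref": pb_tot - pb_alt,
        "pB_alt": pb_alt,
        "ef_ref": ef_counts["a_reads"].to_numpy(),
        "ef_alt": ef_counts["b_reads"].to_numpy(),
        "lf_ref": lf_counts["a_reads"].to_numpy(),
        "lf_alt": lf_counts["b_reads"].to_numpy(),
    })


# ---------------------------------------------------------------------------
# Presets


def study_cross(seed: int = 0) -> CrossConfig:
    """Desk-scale emulation of the study design: 213 lines, two 100 cM
    chromosomes with 200 informative sites each, one planted QTL per
    chromosome (parent-B allele delays flowering by 5 and 4 days), residual
    SD 2 days, pool depth 50x, bulks of 30 early / 21 late."""
    mm = MarkerMap.uniform(n_chrom=2, length_cm=100.0, n_markers=200)
    return CrossConfig(
        marker_map=mm,
        qtls=(QTL("chr1", 50.0, 5.0), QTL("chr2", 50.0, 4.0)),
        seed=seed,
    )


def null_cross(seed: int = 0) -> CrossConfig:
    """The study preset with no planted QTL (phenotype = mu + noise)."""
    return replace(study_cross(seed), qtls=())


def linkage_subset(marker_map: MarkerMap, spacing_cm: float = 10.0) -> list[str]:
    """Genotyped-marker subset for linkage mapping: roughly one marker every
    ``spacing_cm`` (11 markers per 100 cM chromosome by default), emulating
    the sparse PCR-marker maps used for QTL confirmation."""
    names: list[str] = []
    for chrom in marker_map.chroms:
        sub = marker_map.chrom_table(chrom)
        cm = sub["cm"].to_numpy()
        targets = np.arange(0.0, cm.max() + spacing_cm / 2, spacing_cm)
        idx = sorted({int(np.argmin(np.abs(cm - t))) for t in targets})
        names.extend(sub["marker"].iloc[idx])
    return names


# ---------------------------------------------------------------------------
# Plain-text writers (tab-separated)


def write_genotypes_tsv(pop: Population, path) -> None:
    pop.genotypes.to_csv(path, sep="\t", index_label="line")


def write_phenotypes_tsv(pop: Population, path) -> None:
    if pop.phenotypes is None:
        raise ValueError("population has no phenotypes")
    pop.phenotypes.to_frame().to_csv(path, sep="\t", index_label="line")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="line")


def read_phenotypes_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="line")
    return df.iloc[:, 0]
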