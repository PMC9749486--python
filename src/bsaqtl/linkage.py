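"""Marker-based linkage mapping and single-marker QTL scan for RILs.

Workflow: estimate pairwise recombinant fractions and linkage p-values from
the genotype matrix (codes 0/1/2 = parent-A hom / het / parent-B hom, NA
allowed), cluster markers into linkage groups (edge iff p < 0.001, the
classical 1-d.f. criterion), order each group by minimising the sum of
adjacent recombinant fractions, convert adjacent fractions to centimorgans
via the inbred-line correction and the Kosambi function, then scan each
marker with one-way ANOVA of phenotype on genotype class.  The LOD score is
the base-10 log-likelihood ratio of the class-mean regression,

    LOD = (n / 2) * log10(RSS0 / RSS1),

and genome-wide significance uses a phenotype-permutation threshold with a
floor of 2.5 (a permutation quantile below the floor never lowers it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genmap import kosambi_cm, r_from_ril_R

__all__ = [
    "pairwise_linkage",
    "linkage_matrices",
    "group_markers",
    "order_markers",
    "build_map",
    "marker_scan",
    "lod_threshold",
    "LodThreshold",
]

LOD_CAP_LOG10_RATIO = 12.0  # cap log10(RSS0/RSS1) when the fit is exact


def pairwise_linkage(gi, gj, min_lines: int = 20):
    """Observed recombinant fraction and linkage p-value for two markers.

    Heterozygous and missing calls are excluded; among lines homozygous at
    both markers, ``R_obs`` is the fraction in the recombinant classes
    (0/2 or 2/0).  The p-value comes from the Yates-corrected 1-d.f.
    chi-square test of the 2x2 homozygote table.  Returns
    ``(R_obs, p, n_used)``; both statistics are NaN when fewer than two
    genotype classes are observed or fewer than ``min_lines`` lines inform
    the pair.
    """
    a = np.asarray(gi, dtype=float)
    b = np.asarray(gj, dtype=float)
    hom = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    a, b = a[hom], b[hom]
    n = len(a)
    if n < min_lines or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return np.nan, np.nan, n
    rec = np.sum(a != b)
    table = np.array([
        [np.sum((a == 0) & (b == 0)), np.sum((a == 0) & (b == 2))],
        [np.sum((a == 2) & (b == 0)), np.sum((a == 2) & (b == 2))],
    ])
    p = stats.chi2_contingency(table)[1]
    return rec / n, float(p), n


def linkage_matrices(genotypes: pd.DataFrame,
                     min_lines: int = 20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs ``R_obs`` and p-value matrices (marker x marker)."""
    markers = list(genotypes.columns)
    m = len(markers)
    g = genotypes.to_numpy(dtype=float)
    R = np.full((m, m), np.nan)
    P = np.full((m, m), np.nan)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(P, 0.0)
    for i in range(m):
        for j in range(i + 1, m):
            r, p, _ = pairwise_linkage(g[:, i], g[:, j], min_lines)
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    return (pd.DataFrame(R, index=markers, columns=markers),
            pd.DataFrame(P, index=markers, columns=markers))


def group_markers(P: pd.DataFrame, p_crit: float = 0.001,
                  R: pd.DataFrame | None = None) -> list[list[str]]:
    """Single-linkage grouping: an edge joins two markers iff p < ``p_crit``.

    When the ``R_obs`` matrix is supplied, an edge additionally requires
    ``R_obs < 0.5``: linkage is one-sided (recombinants rarer than chance),
    so a significant repulsion-direction association is noise, not linkage.
    """
    markers = list(P.columns)
    adj = (P.to_numpy() < p_crit)
    if R is not None:
        adj &= (R.to_numpy() < 0.5)
    np.fill_diagonal(adj, False)
    n, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n)]
    for name, lab in zip(markers, labels):
        groups[lab].append(name)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def order_markers(R: pd.DataFrame) -> tuple[list[str], float]:
    """Order a linkage group by minimising the sum of adjacent ``R_obs``.

    Greedy chain extension from the tightest pair, then 2-opt segment
    reversals until no improvement.  Raises if the distance data are
    disconnected (NaN between chain neighbours cannot be avoided).
    """
    markers = list(R.columns)
    m = len(markers)
    if m <= 2:
        return markers, float(R.iloc[0, 1]) if m == 2 else 0.0
    D = R.to_numpy(dtype=float).copy()
    np.fill_diagonal(D, np.inf)
    Dw = np.where(np.isnan(D), np.inf, D)
    i, j = np.unravel_index(np.argmin(Dw), Dw.shape)
    chain = [i, j]
    unused = set(range(m)) - {i, j}
    while unused:
        best = None
        for end, side in ((chain[0], "left"), (chain[-1], "right")):
            for k in unused:
                d = Dw[end, k]
                if best is None or d < best[0]:
                    best = (d, k, side)
        d, k, side = best
        if not np.isfinite(d):
            raise ValueError("disconnected distance data; cannot order markers")
        chain.insert(0, k) if side == "left" else chain.append(k)
        unused.remove(k)

    def objective(order):
        s = 0.0
        for a, b in zip(order, order[1:]):
            d = Dw[a, b]
            if not np.isfinite(d):
                return np.inf
            s += d
        return s

    improved = True
    while improved:
        improved = False
        cur = objective(chain)
        for a in range(m - 1):
            for b in range(a + 1, m):
                cand = chain[:a] + chain[a:b + 1][::-1] + chain[b + 1:]
                o = objective(cand)
                if o < cur - 1e-15:
                    chain, cur, improved = cand, o, True
    obj = objective(chain)
    if not np.isfinite(obj):
        raise ValueError("disconnected distance data; cannot order markers")
    return [markers[k] for k in chain], float(obj)


def build_map(order: list[str], R: pd.DataFrame) -> pd.DataFrame:
    """Kosambi map for an ordered group from adjacent recombinant fractions.

    Each interval: ``r = r_from_ril_R(R_obs)`` (infinite-selfing correction)
    and ``cM = kosambi_cm(r)``; observed fractions above 0.5 are clipped to
    0.4999 with a warning.  Returns per-marker rows with the interval to the
    previous marker and the cumulative position.
    """
    rows = []
    cum = 0.0
    prev = None
    for marker in order:
        if prev is None:
            rows.append((marker, np.nan, np.nan, 0.0, 0.0))
        else:
            R_obs = float(R.loc[prev, marker])
            if R_obs > 0.5:
                warnings.warn(f"R_obs {R_obs:.3f} > 0.5 between {prev} and "
                              f"{marker}; clipped to 0.4999")
                R_obs = 0.4999
            r = r_from_ril_R(R_obs)
            d = kosambi_cm(min(r, 0.499999))
            cum += d
            rows.append((marker, R_obs, r, d, cum))
        prev = marker
    return pd.DataFrame(rows, columns=["marker", "R_obs", "r", "interval_cm",
                                       "cum_cm"])


def _class_rss(y: np.ndarray, g: np.ndarray) -> tuple[float, float, int]:
    """(RSS0, RSS1, k classes) of the one-way class-mean model at one marker."""
    ok = np.isfinite(g) & np.isfinite(y)
    y, g = y[ok], g[ok]
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = 0.0
    classes = np.unique(g)
    for c in classes:
        yc = y[g == c]
        rss1 += float(np.sum((yc - yc.mean()) ** 2))
    return rss0, rss1, len(classes)


def _lod_from_rss(rss0: float, rss1: float, n: int) -> tuple[float, bool]:
    if rss0 <= 0:
        return np.nan, True
    if rss1 <= rss0 * 10.0 ** (-LOD_CAP_LOG10_RATIO):
        return n / 2.0 * LOD_CAP_LOG10_RATIO, True
    return n / 2.0 * np.log10(rss0 / rss1), False


def marker_scan(genotypes: pd.DataFrame, phenotypes: pd.Series) -> pd.DataFrame:
    """One-way ANOVA of phenotype on genotype class at every marker.

    Returns per-marker ``F``, ``p``, ``lod``, ``n``, ``flagged``.  Markers
    with a single observed class or a constant phenotype are flagged with NaN
    statistics; an exact fit (zero residual) caps the LOD and flags the row.
    Heterozygotes form a third class where present.
    """
    y_all = phenotypes.loc[genotypes.index].to_numpy(dtype=float)
    rows = []
    for marker in genotypes.columns:
        g = genotypes[marker].to_numpy(dtype=float)
        ok = np.isfinite(g) & np.isfinite(y_all)
        n = int(ok.sum())
        if n < 3 or len(np.unique(g[ok])) < 2:
            rows.append((marker, np.nan, np.nan, np.nan, n, True))
            continue
        rss0, rss1, k = _class_rss(y_all, g)
        if rss0 <= 0:  # constant phenotype
            rows.append((marker, np.nan, np.nan, np.nan, n, True))
            continue
        lod, flagged = _lod_from_rss(rss0, rss1, n)
        if rss1 > 0:
            F = ((rss0 - rss1) / (k - 1)) / (rss1 / (n - k))
            p = float(stats.f.sf(F, k - 1, n - k))
        else:
            F, p = np.inf, 0.0
        rows.append((marker, F, p, lod, n, flagged))
    return pd.DataFrame(rows, columns=["marker", "F", "p", "lod", "n", "flagged"])


class _FastLodScanner:
    """Vectorised max-LOD over markers for many phenotype vectors at once.

    Assumes a complete genotype matrix (no NA), codes in {0, 1, 2}; used by
    the permutation threshold where the same matrix is scanned thousands of
    times.
    """

    def __init__(self, genotypes: pd.DataFrame):
        g = genotypes.to_numpy(dtype=int)
        self.n, self.m = g.shape
        self.indicators = [(g == c).astype(float) for c in (0, 1, 2)]
        self.counts = [ind.sum(axis=0) for ind in self.indicators]

    def max_lod(self, Y: np.ndarray) -> np.ndarray:
        """Genome-wide max LOD for each row of phenotype matrix ``Y``."""
        Y = np.atleast_2d(Y)
        tot = Y.sum(axis=1, keepdims=True)
        ss = (Y ** 2).sum(axis=1, keepdims=True)
        rss0 = ss - tot ** 2 / self.n
        rss1 = np.broadcast_to(ss, (Y.shape[0], self.m)).copy()
        for ind, cnt in zip(self.indicators, self.counts):
            sums = Y @ ind
            with np.errstate(invalid="ignore", divide="ignore"):
                term = np.where(cnt > 0, sums ** 2 / np.where(cnt > 0, cnt, 1), 0.0)
            rss1 -= term
        ratio = np.clip(rss0 / np.maximum(rss1, rss0 * 10.0 ** (-LOD_CAP_LOG10_RATIO)),
                        1.0, None)
        lod = self.n / 2.0 * np.log10(ratio)
        return lod.max(axis=1)


@dataclass(frozen=True)
class LodThreshold:
    value: float
    quantile: float
    floor: float
    alpha: float
    n_perm: int
    seed: int
    maxima: np.ndarray | None = field(default=None, repr=False, compare=False)


def lod_threshold(genotypes: pd.DataFrame, phenotypes: pd.Series,
                  n_perm: int = 1000, alpha: float = 0.05, floor: float = 2.5,
                  seed: int = 0, keep_maxima: bool = False) -> LodThreshold:
    """Genome-wide LOD threshold by phenotype permutation, floored at 2.5.

    Phenotypes are permuted across lines (breaking every marker-trait
    association while preserving both marginals), the genome-wide max LOD is
    recorded per replicate, and the threshold is the empirical ``(1 - alpha)``
    quantile of the maxima or ``floor``, whichever is larger.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutation replicates; threshold unstable")
    rng = np.random.default_rng(seed)
    y = phenotypes.loc[genotypes.index].to_numpy(dtype=float)
    scanner = _FastLodScanner(genotypes)
    Y = np.empty((n_perm, len(y)))
    for i in range(n_perm):
        Y[i] = rng.permutation(y)
    maxima = scanner.max_lod(Y)
    q = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    return LodThreshold(value=max(q, floor), quantile=q, floor=floor,
                        alpha=alpha, n_perm=n_perm, seed=seed,
                        maxima=maxima if keep_maxima else None)
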