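"""Independent oracles used by the unit and acceptance tests.

Each function re-derives an expected value by brute force (enumeration,
direct simulation, or an independent closed form) without touching the code
path it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_ril_recombinant_fraction(r: float, n_lineages: int = 100_000,
                                   generations: int = 40, seed: int = 0):
    """Gamete-by-gamete two-locus selfing simulation.

    Each lineage starts as the F1 (haplotypes 00 / 11 over two loci) and is
    selfed by single-seed descent for ``generations`` rounds (enough to reach
    effective fixation).  Returns ``(R, SE)``: the recombinant fraction among
    lineages homozygous at both loci and its binomial standard error.
    """
    rng = np.random.default_rng(seed)
    # haplotype = (allele at locus 1, allele at locus 2)
    h1 = np.zeros((n_lineages, 2), dtype=np.int8)
    h2 = np.ones((n_lineages, 2), dtype=np.int8)
    for _ in range(generations):
        g = []
        for _ in range(2):
            pick1 = rng.random(n_lineages) < 0.5
            recomb = rng.random(n_lineages) < r
            pick2 = pick1 ^ recomb
            gam = np.empty_like(h1)
            gam[:, 0] = np.where(pick1, h1[:, 0], h2[:, 0])
            gam[:, 1] = np.where(pick2, h1[:, 1], h2[:, 1])
            g.append(gam)
        h1, h2 = g
    hom = np.all(h1 == h2, axis=1)
    rec = hom & (h1[:, 0] != h1[:, 1])
    R = rec.sum() / hom.sum()
    se = np.sqrt(R * (1 - R) / hom.sum())
    return R, se


def lstsq_lod(genotypes, phenotypes) -> float:
    """LOD of the genotype-class regression via an explicit least-squares fit.

    One-hot encodes the observed classes, fits by ``numpy.linalg.lstsq`` and
    forms (n/2) * log10(RSS_null / RSS_model) directly from the residuals.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    classes = np.unique(g)
    X = np.column_stack([(g == c).astype(float) for c in classes])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return len(y) / 2.0 * np.log10(rss0 / rss1)


def enumerate_locus_intervals(codes: list, status: str,
                              early_allele: str = "A") -> set[int]:
    """All elementary intervals where the locus may lie for one line.

    Enumerates every single-transition chromosome configuration (one
    breakpoint, or one heterozygous segment bounded by homozygous flanks)
    consistent with the observed marker calls and the progeny status, and
    collects the intervals each configuration allows.  Interval ``k`` spans
    markers ``k`` and ``k + 1``.
    """
    late_allele = "B" if early_allele == "A" else "A"
    m = len(codes)

    def matches(call, value):
        return call not in ("A", "B", "H") or call == value

    allowed: set[int] = set()
    if status == "segregating":
        # het segment strictly between marker i and marker j (hom flanks),
        # markers inside are H; flank sides are uniform and different.
        for i in range(-1, m):
            for j in range(i + 1, m + 1):
                for left, right in itertools.product("AB", repeat=2):
                    if left == right and i >= 0 and j < m:
                        continue  # would need a double crossover
                    ok = all(matches(codes[k], left) for k in range(0, i + 1))
                    ok &= all(matches(codes[k], "H") for k in range(i + 1, j))
                    ok &= all(matches(codes[k], right) for k in range(j, m))
                    if ok:
                        # locus lies inside (marker i, marker j)
                        for k in range(max(i, 0), min(j, m - 1)):
                            allowed.add(k)
    else:
        want = early_allele if status == "fixed_early" else late_allele
        # single breakpoint before marker b (b = 0..m); left allele L, right R
        for b in range(0, m + 1):
            for left, right in itertools.product("AB", repeat=2):
                if left == right and 0 < b < m:
                    continue
                ok = all(matches(codes[k], left) for k in range(0, b))
                ok &= all(matches(codes[k], right) for k in range(b, m))
                if not ok:
                    continue
                for k in range(m - 1):
                    if k < b - 1:
                        allele = {left}
                    elif k == b - 1:
                        allele = {left, right}
                    else:
                        allele = {right}
                    if want in allele:
                        allowed.add(k)
    return allowed


def brute_delimit(lines: dict, markers: list, early_allele: str = "A"):
    """Intersection of per-line allowed intervals by exhaustive enumeration.

    ``lines``: mapping line -> (codes list, status).  Returns the set of
    allowed elementary interval indices.
    """
    allowed = set(range(len(markers) - 1))
    for codes, status in lines.values():
        allowed &= enumerate_locus_intervals(codes, status, early_allele)
    return allowed
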