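"""Genetic-map arithmetic for recombinant inbred line (RIL) populations.

Two closed-form transforms are provided:

* The **Kosambi mapping function**, which converts a per-meiosis recombination
  fraction ``r`` into a map distance ``d`` (centimorgans) while allowing for
  partial crossover interference::

      d = 100 * (1/4) * ln((1 + 2r) / (1 - 2r))          (cM)
      r = (1/2) * tanh(2 * d / 100)                       (inverse)

* The **Haldane–Waddington RIL correction**, which relates ``r`` to the
  recombinant-genotype fraction ``R`` actually observed among inbred lines.
  Repeated selfing gives every interval many chances to recombine, so the
  observed fraction exceeds ``r``.  At complete inbreeding (selfing to
  fixation)::

      R = 2r / (1 + 2r)        and inversely        r = R / (2 * (1 - R))

  A finite-generation variant is computed by iterating the exact two-locus
  selfing recursion on diplotype frequencies.

All public functions accept scalars or numpy arrays and return floats/arrays
accordingly.  Distances are centimorgans throughout; Morgans appear only
inside the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "kosambi_cm",
    "kosambi_r",
    "ril_R_from_r",
    "r_from_ril_R",
    "RecombEstimate",
]


def _asarray(x):
    a = np.asarray(x, dtype=float)
    return a, a.ndim == 0


def kosambi_cm(r):
    """Map distance in centimorgans for recombination fraction ``r``.

    Parameters
    ----------
    r : float or array-like
        Per-meiosis recombination fraction, ``0 <= r < 0.5``.

    Returns
    -------
    float or ndarray
        Kosambi map distance in cM; strictly increasing in ``r`` and
        diverging as ``r`` approaches 0.5.
    """
    a, scalar = _asarray(r)
    if np.any(a < 0) or np.any(a >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * a) / (1.0 - 2.0 * a))
    return float(d) if scalar else d


def kosambi_r(d_cm):
    """Recombination fraction for a Kosambi map distance in centimorgans.

    Exact inverse of :func:`kosambi_cm`; ``d_cm`` must be non-negative.
    """
    a, scalar = _asarray(d_cm)
    if np.any(a < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(a / 50.0)
    return float(r) if scalar else r


def _finite_selfing_R(r: float, generations: int) -> float:
    """Recombinant fraction among lines selfed to generation F_g.

    Exact two-locus diplotype recursion.  ``generations`` counts filial
    generations from the F1 (g = 1), so F6 means five rounds of selfing.
    The returned fraction is taken among lines homozygous at both loci,
    matching how recombinants are scored in genotype data (heterozygotes
    excluded).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    # Haplotypes over two loci: 0 = AB (parental), 1 = Ab, 2 = aB, 3 = ab.
    # Gametes from diplotype (h, k): parental h, k with prob (1-r)/2 each,
    # recombinants with prob r/2 each.
    def gametes(h: int, k: int) -> dict[int, float]:
        h1, h2 = h >> 1, h & 1
        k1, k2 = k >> 1, k & 1
        out: dict[int, float] = {}
        for hap, p in (
            (h, (1 - r) / 2),
            (k, (1 - r) / 2),
            ((h1 << 1) | k2, r / 2),
            ((k1 << 1) | h2, r / 2),
        ):
            out[hap] = out.get(hap, 0.0) + p
        return out

    # 16 ordered diplotype states; transition under selfing.
    T = np.zeros((16, 16))
    for h in range(4):
        for k in range(4):
            g = gametes(h, k)
            for a, pa in g.items():
                for b, pb in g.items():
                    T[4 * h + k, 4 * a + b] += pa * pb
    state = np.zeros(16)
    state[4 * 0 + 3] = 1.0  # F1 = AB/ab
    for _ in range(generations - 1):
        state = state @ T
    hom = [(h, h) for h in range(4)]
    p_hom = sum(state[4 * h + k] for h, k in hom)
    p_rec = state[4 * 1 + 1] + state[4 * 2 + 2]  # Ab/Ab and aB/aB
    if p_hom == 0:
        return 0.0
    return p_rec / p_hom


def ril_R_from_r(r, generations="infinite"):
    """Expected recombinant-genotype fraction among RILs for per-meiosis ``r``.

    ``generations="infinite"`` (selfing to fixation) uses the closed form
    ``2r / (1 + 2r)``.  An integer ``generations`` (filial generation, F1 = 1)
    iterates the exact selfing recursion and scores recombinants among lines
    homozygous at both loci.
    """
    a, scalar = _asarray(r)
    if np.any(a < 0) or np.any(a > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if generations == "infinite":
        R = 2.0 * a / (1.0 + 2.0 * a)
        return float(R) if scalar else R
    if not isinstance(generations, (int, np.integer)):
        raise ValueError(f"invalid generation specifier: {generations!r}")
    out = np.array([_finite_selfing_R(ri, int(generations)) for ri in np.atleast_1d(a)])
    return float(out[0]) if scalar else out.reshape(a.shape)


def r_from_ril_R(R_obs):
    """Per-meiosis recombination fraction from the observed RIL fraction.

    Inverse of the infinite-selfing correction: ``r = R / (2 (1 - R))``.
    """
    a, scalar = _asarray(R_obs)
    if np.any(a < 0) or np.any(a > 0.5):
        raise ValueError("observed recombinant fraction must lie in [0, 0.5]")
    r = a / (2.0 * (1.0 - a))
    return float(r) if scalar else r


@dataclass(frozen=True)
class RecombEstimate:
    """A mutually consistent (R_obs, r, d_cM) triple for one marker interval.

    ``r`` and ``d_cM`` always satisfy the Kosambi relation; ``R_obs`` is tied
    to ``r`` by the infinite-selfing RIL correction.
    """

    R_obs: float
    r: float
    d_cM: float

    @classmethod
    def from_R(cls, R_obs: float) -> "RecombEstimate":
        r = r_from_ril_R(R_obs)
        return cls(R_obs=float(R_obs), r=r, d_cM=kosambi_cm(r))

    @classmethod
    def from_r(cls, r: float) -> "RecombEstimate":
        return cls(R_obs=ril_R_from_r(r), r=float(r), d_cM=kosambi_cm(r))

    @classmethod
    def from_cm(cls, d_cM: float) -> "RecombEstimate":
        r = kosambi_r(d_cM)
        return cls(R_obs=ril_R_from_r(r), r=r, d_cM=float(d_cM))
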