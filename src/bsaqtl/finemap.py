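"""Recombinant-driven fine mapping of a single locus.

Given lines genotyped at an ordered panel of fine markers (codes ``A`` =
homozygous for the early parent's allele, ``B`` = homozygous late, ``H`` =
heterozygous), the locus is delimited by intersecting per-line constraints:

* a line whose progeny *segregate* for the trait must be heterozygous at the
  locus, so the locus lies in an interval compatible with heterozygosity in
  that line (touching an ``H`` call or a breakpoint between opposite
  homozygous calls);
* a line whose progeny are *fixed* must be homozygous at the locus for the
  allele matching its phenotype class, so the locus lies in an interval
  touching a call of that allele.

Each constraint is a boolean mask over the elementary intervals between
consecutive markers; the delimited region is the intersection, reported by
its flanking markers.  A single crossover per line per interval is assumed
(no double crossovers between adjacent markers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RecombinantLine",
    "IntervalResult",
    "InconsistentConstraintsError",
    "find_recombinants",
    "classify_progeny_segregation",
    "delimit_interval",
]

CODES = ("A", "B", "H")
STATUSES = ("segregating", "fixed_early", "fixed_late", "untested")


@dataclass
class RecombinantLine:
    """A line discordant at the flanking markers, with its fine genotypes."""

    line: str
    genotypes: pd.Series          # ordered fine markers -> 'A'/'B'/'H'/NA
    breakpoints: list[tuple[str, str]] = field(default_factory=list)
    status: str = "untested"

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"invalid progeny status {self.status!r}")


class InconsistentConstraintsError(ValueError):
    def __init__(self, lines):
        self.lines = list(lines)
        super().__init__(
            "recombinant constraints have empty intersection; conflicting "
            f"lines: {', '.join(self.lines)}")


@dataclass(frozen=True)
class IntervalResult:
    """Delimited locus interval with the constraints that produced it."""

    left_marker: str
    right_marker: str
    left_pos: int
    right_pos: int
    contiguous: bool
    constraints: dict[str, tuple[str, str]]  # line -> allowed (left, right)

    @property
    def span_bp(self) -> int:
        return self.right_pos - self.left_pos


def _breakpoints(genos: pd.Series) -> list[tuple[str, str]]:
    calls = [(m, c) for m, c in genos.items() if isinstance(c, str) and c in CODES]
    out = []
    for (m1, c1), (m2, c2) in zip(calls, calls[1:]):
        if c1 != c2:
            out.append((m1, m2))
    return out


def find_recombinants(genotypes: pd.DataFrame, left_marker: str,
                      right_marker: str) -> list[RecombinantLine]:
    """Lines whose calls at the two flanking markers differ.

    Any discordant combination (A/B, A/H, H/B, ...) counts; lines with a
    missing call at either flank are skipped with a log message.
    """
    out = []
    for line, row in genotypes.iterrows():
        a, b = row.get(left_marker), row.get(right_marker)
        if a not in CODES or b not in CODES:
            logger.info("line %s skipped: missing flanking-marker call", line)
            continue
        if a != b:
            out.append(RecombinantLine(line=str(line), genotypes=row,
                                       breakpoints=_breakpoints(row)))
    return out


def classify_progeny_segregation(progeny_phenotypes, early_mean: float,
                                 late_mean: float, min_n: int = 10,
                                 min_class: int = 3) -> str:
    """Classify a line's progeny as segregating or fixed.

    Progeny are split at the parental midpoint; the family is ``segregating``
    when both sides hold at least ``min_class`` members, otherwise fixed
    toward the majority side.  Fewer than ``min_n`` progeny -> ``untested``.
    """
    if early_mean == late_mean:
        raise ValueError("reference means must be distinct")
    y = np.asarray(progeny_phenotypes, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < min_n:
        return "untested"
    mid = (early_mean + late_mean) / 2.0
    early_side = np.sum(y < mid) if early_mean < late_mean else np.sum(y > mid)
    late_side = len(y) - early_side
    if early_side >= min_class and late_side >= min_class:
        return "segregating"
    return "fixed_early" if early_side >= late_side else "fixed_late"


def _allowed_intervals(codes: list, status: str, early_allele: str = "A"
                       ) -> np.ndarray:
    """Boolean mask over the m-1 elementary intervals for one line."""
    late_allele = "B" if early_allele == "A" else "A"
    m = len(codes)
    allowed = np.zeros(m - 1, dtype=bool)
    def known(c):
        return isinstance(c, str) and c in CODES
    for k in range(m - 1):
        c1, c2 = codes[k], codes[k + 1]
        if not known(c1) or not known(c2):
            allowed[k] = True  # missing call constrains nothing
            continue
        if status == "segregating":
            # het possible in the interval: an H call touches it, or the two
            # flanking homozygotes differ (single breakpoint inside).
            allowed[k] = (c1 == "H") or (c2 == "H") or (c1 != c2)
        else:
            want = early_allele if status == "fixed_early" else late_allele
            allowed[k] = (c1 == want) or (c2 == want)
    return allowed


def delimit_interval(recombinants: list[RecombinantLine],
                     markers: pd.DataFrame,
                     early_allele: str = "A") -> IntervalResult:
    """Intersect recombinant constraints into the minimal locus interval.

    ``markers``: DataFrame with columns ``marker`` and ``pos_bp`` in map
    order.  Lines with status ``untested`` are ignored.  The locus is treated
    as lying strictly between flanking markers; an empty intersection raises
    :class:`InconsistentConstraintsError` naming the conflicting lines.
    """
    names = markers["marker"].tolist()
    pos = markers["pos_bp"].to_numpy()
    m = len(names)
    if m < 2:
        raise ValueError("need at least two ordered markers")
    informative = [rl for rl in recombinants if rl.status != "untested"]
    if not informative:
        raise ValueError("no recombinant with a known progeny status")
    allowed = np.ones(m - 1, dtype=bool)
    masks = {}
    constraints = {}
    for rl in informative:
        codes = [rl.genotypes.get(n) for n in names]
        mask = _allowed_intervals(codes, rl.status, early_allele)
        masks[rl.line] = mask
        ks = np.nonzero(mask)[0]
        if len(ks):
            constraints[rl.line] = (names[ks[0]], names[ks[-1] + 1])
        else:
            constraints[rl.line] = ("-", "-")
        allowed &= mask
    if not allowed.any():
        # report the minimal set of lines whose masks pairwise conflict
        conflict = [ln for ln, msk in masks.items() if not (msk & allowed_any(masks, ln)).any()]
        raise InconsistentConstraintsError(conflict or list(masks))
    ks = np.nonzero(allowed)[0]
    contiguous = bool(np.all(np.diff(ks) == 1))
    left, right = int(ks[0]), int(ks[-1] + 1)
    return IntervalResult(
        left_marker=names[left], right_marker=names[right],
        left_pos=int(pos[left]), right_pos=int(pos[right]),
        contiguous=contiguous, constraints=constraints,
    )


def allowed_any(masks: dict, skip: str) -> np.ndarray:
    """Intersection of all masks except ``skip`` (for conflict reporting)."""
    out = None
    for ln, msk in masks.items():
        if ln == skip:
            continue
        out = msk.copy() if out is None else out & msk
    if out is None:
        return np.ones_like(next(iter(masks.values())))
    return out
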