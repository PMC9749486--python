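"""SNP-index / Delta(SNP-index) scan with permutation genome-wide thresholds.

For each retained biallelic site the SNP-index of a pool is the fraction of
its reads carrying the parent-B (late-flowering parent) allele; the contrast

    Delta = SNP-index(LF) - SNP-index(EF)

is near +1 where the late bulk is fixed for the parent-B allele and the early
bulk depleted of it, near 0 at unlinked sites.  Per-site Delta is smoothed by
a sliding window (mean over sites, default 1 Mb window / 10 kb step) and a
genome-wide significance threshold on |Delta| is obtained from the null
distribution of the genome-wide maximum of the windowed track.

Two null models are available for the threshold:

``"genedrop"`` (default)
    Re-simulates null bulks: for every replicate, ``n_EF + n_LF`` RIL genomes
    are dropped along the genetic map (two-state Markov chain with
    inter-site transition ``2r/(1+2r)``, the inbred-line recombinant
    fraction), split into two bulks, and re-sequenced at the *observed*
    per-site depths.  This reproduces both read sampling and the
    bulk-composition sampling variance shared along chromosomes, and is the
    simulation-convention threshold of QTL-seq-style analyses.

``"reads"``
    Redraws only the read counts, Binomial(observed depth, 0.5) in each pool.
    This is the textbook read-resampling null; it ignores bulk-composition
    variance and is kept for comparison and for data without genetic-map
    information.

Windows with fewer than ``min_sites`` contributing sites are masked.  Regions
are maximal runs of same-sign windows with |mean Delta| >= threshold, with
small gaps bridged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genmap import kosambi_r, ril_R_from_r
from .sites import parent_b_is_alt

__all__ = [
    "snp_index",
    "delta_snp_index",
    "index_track",
    "window_track",
    "permutation_threshold",
    "threshold_from_maxima",
    "call_regions",
    "Threshold",
    "RegionCall",
    "GeneDropNull",
    "genedrop_from_map",
    "genedrop_from_rate",
]


def snp_index(parent_b_reads, total_reads):
    """Fraction of a pool's reads carrying the parent-B allele.

    Sites with zero total depth yield NaN (missing), never 0: an uncovered
    site carries no information.
    """
    b = np.asarray(parent_b_reads, dtype=float)
    t = np.asarray(total_reads, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(t > 0, b / t, np.nan)
    return float(idx) if idx.ndim == 0 else idx


def delta_snp_index(index_lf, index_ef):
    """Late-bulk minus early-bulk SNP-index; NaN propagates."""
    d = np.asarray(index_lf, dtype=float) - np.asarray(index_ef, dtype=float)
    return float(d) if d.ndim == 0 else d


def index_track(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site SNP-index for both pools and their difference.

    Counts are oriented so that the counted allele is the one carried by
    parent B (decided per site from the parental read majorities).  Sites
    uncovered in either pool get NaN indices/Delta.
    """
    b_alt = parent_b_is_alt(sites)
    ef_b = np.where(b_alt, sites["ef_alt"], sites["ef_ref"]).astype(float)
    lf_b = np.where(b_alt, sites["lf_alt"], sites["lf_ref"]).astype(float)
    ef_t = (sites["ef_ref"] + sites["ef_alt"]).to_numpy(dtype=float)
    lf_t = (sites["lf_ref"] + sites["lf_alt"]).to_numpy(dtype=float)
    ef_i = snp_index(ef_b, ef_t)
    lf_i = snp_index(lf_b, lf_t)
    return pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(),
        "pos": sites["pos"].to_numpy(),
        "index_ef": ef_i,
        "index_lf": lf_i,
        "delta": delta_snp_index(lf_i, ef_i),
    })


class _Windower:
    """Sliding-window machinery shared by the observed track and the nulls.

    Holds, per chromosome, the step grid of window starts and a sparse
    averaging matrix mapping per-site values to window means over the sites
    falling in [start, start + window).  Rows for windows with fewer than
    ``min_sites`` sites are dropped (masked).
    """

    def __init__(self, chrom: np.ndarray, pos: np.ndarray, window_bp: int,
                 step_bp: int, min_sites: int):
        if step_bp > window_bp:
            raise ValueError("step must not exceed the window size")
        if step_bp <= 0 or window_bp <= 0:
            raise ValueError("window and step must be positive")
        self.window_bp, self.step_bp, self.min_sites = window_bp, step_bp, min_sites
        rows, cols = [], []
        frames = []
        offset = 0
        for c in dict.fromkeys(chrom):
            mask = chrom == c
            p = np.asarray(pos)[mask]
            site_idx = np.nonzero(mask)[0]
            n_win = int(np.max(p)) // step_bp + 1
            starts = np.arange(n_win, dtype=np.int64) * step_bp
            # windows containing site at p: start in ((p - window, p]] on grid
            lo = np.maximum((p - window_bp) // step_bp + 1, 0)
            hi = p // step_bp  # inclusive
            for j in range(len(p)):
                ks = np.arange(lo[j], hi[j] + 1)
                rows.append(offset + ks)
                cols.append(np.full(len(ks), site_idx[j]))
            frames.append(pd.DataFrame({
                "chrom": c, "start": starts, "end": starts + window_bp,
            }))
            offset += n_win
        self.windows = pd.concat(frames, ignore_index=True)
        n_windows, n_sites = offset, len(pos)
        r = np.concatenate(rows) if rows else np.array([], dtype=int)
        c_ = np.concatenate(cols) if cols else np.array([], dtype=int)
        m = sp.csr_matrix((np.ones(len(r)), (r, c_)), shape=(n_windows, n_sites))
        counts = np.asarray(m.sum(axis=1)).ravel()
        self.windows["n_sites"] = counts.astype(int)
        self.unmasked = counts >= min_sites
        inv = np.zeros(n_windows)
        inv[self.unmasked] = 1.0 / counts[self.unmasked]
        self.avg = sp.diags(inv[self.unmasked]) @ m[self.unmasked]

    def means(self, values: np.ndarray) -> np.ndarray:
        """Window means for per-site values; shape (..., n_unmasked)."""
        return (self.avg @ np.atleast_2d(values).T).T

    def frame(self, values: np.ndarray) -> pd.DataFrame:
        out = self.windows.copy()
        mean = np.full(len(out), np.nan)
        mean[self.unmasked] = self.avg @ values
        out["delta_mean"] = mean
        return out


def window_track(track: pd.DataFrame, window_bp: int = 1_000_000,
                 step_bp: int = 10_000, min_sites: int = 3) -> pd.DataFrame:
    """Sliding-window mean of per-site Delta.

    Sites with NaN Delta (uncovered in a pool) are excluded; windows with
    fewer than ``min_sites`` remaining sites are masked (NaN mean).  Returns
    one row per window on the step grid: ``chrom, start, end, n_sites,
    delta_mean``.
    """
    valid = track["delta"].notna().to_numpy()
    sub = track.loc[valid]
    w = _Windower(sub["chrom"].to_numpy(), sub["pos"].to_numpy(),
                  window_bp, step_bp, min_sites)
    return w.frame(sub["delta"].to_numpy())


@dataclass(frozen=True)
class Threshold:
    """Genome-wide |Delta| threshold from a permutation/simulation null."""

    value: float
    alpha: float
    n_perm: int
    null: str
    seed: int
    maxima: np.ndarray | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class GeneDropNull:
    """Genetic information needed by the gene-drop null.

    ``cm``: genetic position of every site in the table handed to
    :func:`permutation_threshold` (same order); ``bulk_sizes``: lines per
    (EF, LF) bulk; ``error_rate``: per-read allele error.
    """

    cm: np.ndarray
    bulk_sizes: tuple[int, int] = (30, 21)
    error_rate: float = 0.005


def genedrop_from_map(sites: pd.DataFrame, marker_map,
                      bulk_sizes=(30, 21), error_rate=0.005) -> GeneDropNull:
    """Genetic positions looked up from a marker map by (chrom, pos)."""
    mt = marker_map.table[["chrom", "pos_bp", "cm"]].rename(columns={"pos_bp": "pos"})
    merged = sites[["chrom", "pos"]].merge(mt, on=["chrom", "pos"], how="left")
    if merged["cm"].isna().any():
        raise ValueError("some sites have no genetic position on the marker map")
    return GeneDropNull(cm=merged["cm"].to_numpy(), bulk_sizes=tuple(bulk_sizes),
                        error_rate=error_rate)


def genedrop_from_rate(sites: pd.DataFrame, cm_per_mb: float = 2.0,
                       bulk_sizes=(30, 21), error_rate=0.005) -> GeneDropNull:
    """Genetic positions from a constant recombination rate (cM per Mb)."""
    return GeneDropNull(cm=sites["pos"].to_numpy(dtype=float) * cm_per_mb / 1e6,
                        bulk_sizes=tuple(bulk_sizes), error_rate=error_rate)


def threshold_from_maxima(maxima: np.ndarray, alpha: float) -> float:
    """Upper (1 - alpha) empirical quantile of the replicate maxima."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.quantile(np.asarray(maxima, dtype=float), 1.0 - alpha,
                             method="higher"))


def _null_maxima_reads(w: _Windower, ef_tot, lf_tot, n_perm, rng,
                       chunk=250) -> np.ndarray:
    maxima = []
    for k in range(0, n_perm, chunk):
        nk = min(chunk, n_perm - k)
        ef_b = rng.binomial(ef_tot, 0.5, size=(nk, len(ef_tot)))
        lf_b = rng.binomial(lf_tot, 0.5, size=(nk, len(lf_tot)))
        delta = lf_b / lf_tot - ef_b / ef_tot
        maxima.append(np.max(np.abs(w.means(delta)), axis=1))
    return np.concatenate(maxima)


def _drop_lines(chrom: np.ndarray, cm: np.ndarray, n_lines: int,
                rng) -> np.ndarray:
    """Null RIL genotype states (0/1) along the map for ``n_lines`` genomes."""
    states = np.empty((n_lines, len(cm)), dtype=np.int8)
    for c in dict.fromkeys(chrom):
        idx = np.nonzero(chrom == c)[0]
        R = ril_R_from_r(kosambi_r(np.diff(cm[idx])))
        m = len(idx)
        steps = np.empty((n_lines, m), dtype=np.int8)
        steps[:, 0] = rng.random(n_lines, dtype=np.float32) < 0.5
        if m > 1:
            steps[:, 1:] = rng.random((n_lines, m - 1), dtype=np.float32) < R
        states[:, idx] = np.cumsum(steps, axis=1, dtype=np.int64) & 1
    return states


def _null_maxima_genedrop(w: _Windower, chrom, ef_tot, lf_tot, n_perm, rng,
                          gd: GeneDropNull, chunk=250) -> np.ndarray:
    n_ef, n_lf = gd.bulk_sizes
    e = gd.error_rate
    maxima = []
    for k in range(0, n_perm, chunk):
        nk = min(chunk, n_perm - k)
        states = _drop_lines(chrom, gd.cm, nk * (n_ef + n_lf), rng)
        states = states.reshape(nk, n_ef + n_lf, -1)
        f_ef = states[:, :n_ef].mean(axis=1)
        f_lf = states[:, n_ef:].mean(axis=1)
        p_ef = f_ef * (1 - e) + (1 - f_ef) * e
        p_lf = f_lf * (1 - e) + (1 - f_lf) * e
        ef_b = rng.binomial(ef_tot, p_ef)
        lf_b = rng.binomial(lf_tot, p_lf)
        delta = lf_b / lf_tot - ef_b / ef_tot
        maxima.append(np.max(np.abs(w.means(delta)), axis=1))
    return np.concatenate(maxima)


def permutation_threshold(sites: pd.DataFrame, window_bp: int = 1_000_000,
                          step_bp: int = 10_000, min_sites: int = 3,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, null: str = "genedrop",
                          genedrop: GeneDropNull | None = None,
                          keep_maxima: bool = False) -> Threshold:
    """Genome-wide threshold on the windowed |Delta| track.

    For each of ``n_perm`` replicates, null read counts are generated at the
    observed per-pool depths (see module docstring for the two null models),
    the windowed |Delta| track is recomputed on the same grid and its
    genome-wide maximum recorded; the threshold is the empirical
    ``(1 - alpha)`` quantile of the maxima.  Deterministic given ``seed``.
    """
    ef_tot = (sites["ef_ref"] + sites["ef_alt"]).to_numpy(dtype=np.int64)
    lf_tot = (sites["lf_ref"] + sites["lf_alt"]).to_numpy(dtype=np.int64)
    valid = (ef_tot > 0) & (lf_tot > 0)
    if not valid.any():
        raise ValueError("no sites covered in both pools")
    chrom = sites["chrom"].to_numpy()[valid]
    pos = sites["pos"].to_numpy()[valid]
    w = _Windower(chrom, pos, window_bp, step_bp, min_sites)
    if not w.unmasked.any():
        raise ValueError("all windows masked; lower min_sites or widen windows")
    rng = np.random.default_rng(seed)
    if null == "reads":
        maxima = _null_maxima_reads(w, ef_tot[valid], lf_tot[valid], n_perm, rng)
    elif null == "genedrop":
        if genedrop is None:
            raise ValueError("genedrop null requires a GeneDropNull configuration")
        gd = GeneDropNull(cm=np.asarray(genedrop.cm)[valid],
                          bulk_sizes=genedrop.bulk_sizes,
                          error_rate=genedrop.error_rate)
        maxima = _null_maxima_genedrop(w, chrom, ef_tot[valid], lf_tot[valid],
                                       n_perm, rng, gd)
    else:
        raise ValueError(f"unknown null model {null!r}")
    return Threshold(value=threshold_from_maxima(maxima, alpha), alpha=alpha,
                     n_perm=n_perm, null=null, seed=seed,
                     maxima=maxima if keep_maxima else None)


@dataclass(frozen=True)
class RegionCall:
    """A candidate QTL region: run of significant same-sign windows."""

    chrom: str
    start: int            # bp, first window start (0-based half-open with end)
    end: int              # bp, last window end
    sign: int             # +1 = parent-B allele enriched in the late bulk
    peak_delta: float     # signed window mean at the peak
    peak_pos: int         # midpoint of the peak window
    n_windows: int

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "start": int(self.start), "end": int(self.end),
            "sign": int(self.sign), "peak_delta": float(self.peak_delta),
            "peak_pos": int(self.peak_pos), "n_windows": int(self.n_windows),
        }


def call_regions(windows: pd.DataFrame, threshold: float | Threshold,
                 merge_gap: int = 1,
                 merge_span_bp: int = 10_000_000) -> list[RegionCall]:
    """Candidate regions from a windowed track and a threshold.

    A region is a maximal run of unmasked windows with |mean Delta| >=
    threshold and a common sign; runs separated by at most ``merge_gap``
    non-qualifying windows (on the step grid) are bridged.  Same-sign
    regions on a chromosome whose spans lie within ``merge_span_bp`` of each
    other are then coalesced: with bulks of a few dozen lines the
    bulk-composition noise is correlated over tens of centimorgans, so
    supra-threshold excursions closer than the method's resolution
    (default 10 Mb, ~20 cM at typical rates) are one candidate region, not
    two.  Set ``merge_span_bp=0`` to keep raw runs.
    """
    thr = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    step = None
    regions: list[RegionCall] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        if len(starts) > 1:
            step = int(np.min(np.diff(starts)))
        mean = sub["delta_mean"].to_numpy()
        ok = np.isfinite(mean) & (np.abs(mean) >= thr)
        if not ok.any():
            continue
        sign = np.sign(mean)
        idx = starts // (step if step else max(starts.max(), 1))
        q = np.nonzero(ok)[0]
        run: list[int] = [q[0]]
        for j in q[1:]:
            gap = idx[j] - idx[run[-1]] - 1
            if gap <= merge_gap and sign[j] == sign[run[-1]]:
                run.append(j)
            else:
                regions.append(_make_region(chrom, sub, run))
                run = [j]
        regions.append(_make_region(chrom, sub, run))
    return _coalesce(regions, merge_span_bp)


def _coalesce(regions: list[RegionCall], merge_span_bp: int) -> list[RegionCall]:
    if merge_span_bp <= 0:
        return regions
    out: list[RegionCall] = []
    for r in sorted(regions, key=lambda r: (str(r.chrom), r.start)):
        if (out and r.chrom == out[-1].chrom and r.sign == out[-1].sign
                and r.start - out[-1].end < merge_span_bp):
            prev = out[-1]
            peak, pos = ((prev.peak_delta, prev.peak_pos)
                         if abs(prev.peak_delta) >= abs(r.peak_delta)
                         else (r.peak_delta, r.peak_pos))
            out[-1] = RegionCall(chrom=prev.chrom, start=prev.start,
                                 end=max(prev.end, r.end), sign=prev.sign,
                                 peak_delta=peak, peak_pos=pos,
                                 n_windows=prev.n_windows + r.n_windows)
        else:
            out.append(r)
    return out


def _make_region(chrom, sub: pd.DataFrame, run: list[int]) -> RegionCall:
    mean = sub["delta_mean"].to_numpy()
    peak_j = run[int(np.argmax(np.abs(mean[run])))]
    start = int(sub["start"].to_numpy()[run[0]])
    end = int(sub["end"].to_numpy()[run[-1]])
    return RegionCall(
        chrom=chrom, start=start, end=end,
        sign=int(np.sign(mean[peak_j])),
        peak_delta=float(mean[peak_j]),
        peak_pos=int((sub["start"].to_numpy()[peak_j]
                      + sub["end"].to_numpy()[peak_j]) // 2),
        n_windows=len(run),
    )


def regions_to_bed(regions: list[RegionCall], path) -> None:
    """Write calls as BED (0-based half-open) with the peak |Delta| as score."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = f"region{i + 1}"
            strand = "+" if r.sign > 0 else "-"
            fh.write(f"{r.chrom}\t{max(r.start, 0)}\t{r.end}\t{name}\t"
                     f"{abs(r.peak_delta):.4f}\t{strand}\n")
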