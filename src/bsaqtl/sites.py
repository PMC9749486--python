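"""Pooled-count site tables: VCF/TSV I/O and site-retention filters.

The canonical in-memory container is a pandas DataFrame with one row per
biallelic site and columns::

    chrom, pos, vclass, indel_len, qual,
    pA_ref, pA_alt, pB_ref, pB_alt, ef_ref, ef_alt, lf_ref, lf_alt

``pos`` is 1-based (VCF convention); ``*_ref``/``*_alt`` are read depths
supporting the REF and ALT alleles in the two parents and the early-/late-
flowering pools.  Which allele belongs to which parent is decided from the
parental counts (majority allele), not assumed.

Filters implement the retention rules used before SNP-index computation:
parents homozygous for different alleles, minimum pool depth and site
quality, indel length cap and (cohort mode) minor-allele-frequency floor.
Each filter returns the retained table plus a removal log in which every
removed site carries exactly one reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "chrom", "pos", "vclass", "indel_len", "qual",
    "pA_ref", "pA_alt", "pB_ref", "pB_alt",
    "ef_ref", "ef_alt", "lf_ref", "lf_alt",
]

SAMPLES = ("parentA", "parentB", "EF", "LF")


class SiteFormatError(ValueError):
    """Malformed pooled-count input (missing sample, missing AD field...)."""


@dataclass
class LoadedSites:
    sites: pd.DataFrame
    n_multiallelic: int = 0


@dataclass
class FilterResult:
    """Retained sites plus a per-site removal log (one reason code each)."""

    sites: pd.DataFrame
    removed: pd.DataFrame  # columns: chrom, pos, reason

    @property
    def reason_counts(self) -> dict:
        return self.removed["reason"].value_counts().to_dict()


def _check_table(df: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteFormatError(f"site table missing columns {missing}")


def parent_b_is_alt(df: pd.DataFrame) -> np.ndarray:
    """True where parent-B's majority allele is ALT (parent-A then REF)."""
    return (df["pB_alt"].to_numpy() >= df["pB_ref"].to_numpy())


# ---------------------------------------------------------------------------
# VCF / TSV I/O


def write_pool_tsv(df: pd.DataFrame, path) -> None:
    _check_table(df)
    df[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pool_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_table(df)
    return df


def _alleles(vclass: str, indel_len: int) -> tuple[str, str]:
    if vclass == "SNP" or indel_len == 0:
        return "A", "T"
    return "A" + "C" * int(indel_len), "A"  # deletion of indel_len bases


def write_pool_vcf(df: pd.DataFrame, path, samples=SAMPLES) -> None:
    """Write the site table as an uncompressed four-sample VCF (GT:AD).

    Parental GT calls are derived from the parental read majorities so that a
    reader can re-assign alleles to parents; pools are emitted as ``./.`` with
    allele depths only.
    """
    _check_table(df)
    b_alt = parent_b_is_alt(df)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        for chrom in dict.fromkeys(df["chrom"]):
            end = int(df.loc[df["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={end}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, row in enumerate(df.itertuples(index=False)):
            ref, alt = _alleles(row.vclass, row.indel_len)
            gt_a = "1/1" if not b_alt[i] else "0/0"
            gt_b = "1/1" if b_alt[i] else "0/0"
            cols = [
                str(row.chrom), str(int(row.pos)), ".", ref, alt,
                f"{float(row.qual):g}", "PASS", ".", "GT:AD",
                f"{gt_a}:{int(row.pA_ref)},{int(row.pA_alt)}",
                f"{gt_b}:{int(row.pB_ref)},{int(row.pB_alt)}",
                f"./.:{int(row.ef_ref)},{int(row.ef_alt)}",
                f"./.:{int(row.lf_ref)},{int(row.lf_alt)}",
            ]
            fh.write("\t".join(cols) + "\n")


def read_pool_vcf(path, samples=SAMPLES) -> LoadedSites:
    """Parse a four-sample pooled VCF into the canonical site table.

    Biallelic records only; multiallelic records are skipped and counted.
    Raises :class:`SiteFormatError` if a named sample or the AD field is
    missing, naming the offending record where possible.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    present = list(vcf.samples)
    missing = [s for s in samples if s not in present]
    if missing:
        raise SiteFormatError(f"VCF lacks required samples {missing}; found {present}")
    order = [present.index(s) for s in samples]
    rows = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise SiteFormatError(f"record {v.CHROM}:{v.POS} has no AD field")
        ad = np.clip(ad, 0, None)  # cyvcf2 encodes missing as negative
        ref, alt = v.REF, v.ALT[0]
        indel_len = abs(len(ref) - len(alt))
        vclass = "SNP" if indel_len == 0 else "INDEL"
        (pa, pb, ef, lf) = (ad[j] for j in order)
        rows.append((v.CHROM, v.POS, vclass, indel_len,
                     float(v.QUAL) if v.QUAL is not None else 0.0,
                     int(pa[0]), int(pa[1]), int(pb[0]), int(pb[1]),
                     int(ef[0]), int(ef[1]), int(lf[0]), int(lf[1])))
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return LoadedSites(sites=df, n_multiallelic=n_multi)


# ---------------------------------------------------------------------------
# Filters


def _result(df: pd.DataFrame, keep: np.ndarray, reasons: np.ndarray) -> FilterResult:
    removed = df.loc[~keep, ["chrom", "pos"]].copy()
    removed["reason"] = reasons[~keep]
    return FilterResult(sites=df.loc[keep].reset_index(drop=True),
                        removed=removed.reset_index(drop=True))


def filter_parent_informative(df: pd.DataFrame, min_parent_depth: int = 10,
                              max_minor_share: float = 0.1) -> FilterResult:
    """Keep sites where both parents are homozygous for *different* alleles.

    Homozygosity is scored at read level: parental depth >= ``min_parent_depth``
    and minor-allele read share <= ``max_minor_share``.
    """
    _check_table(df)
    pa_tot = (df["pA_ref"] + df["pA_alt"]).to_numpy(dtype=float)
    pb_tot = (df["pB_ref"] + df["pB_alt"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa_minor = np.minimum(df["pA_ref"], df["pA_alt"]).to_numpy() / pa_tot
        pb_minor = np.minimum(df["pB_ref"], df["pB_alt"]).to_numpy() / pb_tot
    depth_ok = (pa_tot >= min_parent_depth) & (pb_tot >= min_parent_depth)
    hom_ok = (pa_minor <= max_minor_share) & (pb_minor <= max_minor_share)
    a_allele = df["pA_alt"].to_numpy() > df["pA_ref"].to_numpy()
    b_allele = df["pB_alt"].to_numpy() > df["pB_ref"].to_numpy()
    poly = a_allele != b_allele
    keep = depth_ok & hom_ok & poly
    reasons = np.where(~depth_ok, "parent_low_depth",
                       np.where(~hom_ok, "parent_heterozygous", "parents_monomorphic"))
    return _result(df, keep, reasons)


def filter_quality(df: pd.DataFrame, min_depth: int = 10,
                   min_quality: float = 100.0) -> FilterResult:
    """Keep sites with total depth >= ``min_depth`` in *each* pool and site
    quality >= ``min_quality`` (both boundaries inclusive)."""
    _check_table(df)
    if min_depth < 0 or min_quality < 0:
        raise ValueError("thresholds must be non-negative")
    ef_tot = (df["ef_ref"] + df["ef_alt"]).to_numpy()
    lf_tot = (df["lf_ref"] + df["lf_alt"]).to_numpy()
    depth_ok = (ef_tot >= min_depth) & (lf_tot >= min_depth)
    qual_ok = df["qual"].to_numpy() >= min_quality
    keep = depth_ok & qual_ok
    reasons = np.where(~depth_ok, "pool_low_depth", "low_quality")
    return _result(df, keep, reasons)


def filter_variant_class(df: pd.DataFrame, maf_min: float | None = None,
                         indel_max_len: int = 20,
                         maf: np.ndarray | None = None) -> FilterResult:
    """Drop indels longer than ``indel_max_len`` bp and, when a cohort
    minor-allele frequency is supplied, SNPs with MAF < ``maf_min``.

    ``maf`` may be an array aligned with ``df`` or a column named ``maf`` in
    the table.  Requesting the MAF filter without frequencies is an error:
    pooled bulks alone cannot provide a cohort MAF.
    """
    _check_table(df)
    indel_ok = ~((df["vclass"].to_numpy() == "INDEL")
                 & (df["indel_len"].to_numpy() > indel_max_len))
    maf_ok = np.ones(len(df), dtype=bool)
    if maf_min is not None:
        if maf is None:
            if "maf" not in df.columns:
                raise ValueError("MAF filter requested but no cohort frequencies given")
            maf = df["maf"].to_numpy()
        maf = np.asarray(maf, dtype=float)
        maf_ok = ~((df["vclass"].to_numpy() == "SNP") & (maf < maf_min))
    keep = indel_ok & maf_ok
    reasons = np.where(~indel_ok, "indel_too_long", "low_maf")
    return _result(df, keep, reasons)


def apply_filter_chain(df: pd.DataFrame, min_parent_depth: int = 10,
                       max_minor_share: float = 0.1, min_depth: int = 10,
                       min_quality: float = 100.0, maf_min: float | None = None,
                       indel_max_len: int = 20) -> FilterResult:
    """Full retention chain: parent-informative, depth/quality, variant class."""
    r1 = filter_parent_informative(df, min_parent_depth, max_minor_share)
    r2 = filter_quality(r1.sites, min_depth, min_quality)
    r3 = filter_variant_class(r2.sites, maf_min, indel_max_len)
    removed = pd.concat([r1.removed, r2.removed, r3.removed], ignore_index=True)
    return FilterResult(sites=r3.sites, removed=removed)
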