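"""End-to-end orchestration: simulate -> filter -> scan -> map -> fine-map.

Every stage is a plain function over the library API that reads/writes the
package's text formats (TSV/VCF/BED/JSON) and returns its in-memory result,
so the same code path serves the CLI, the examples and the tests.  A run
directory always receives a ``manifest.json`` recording the resolved
parameters and seeds; re-running from the same manifest reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import linkage, scan, simulate, sites

__all__ = ["simulate_bsa_inputs", "bsa_scan_pipeline", "linkage_pipeline",
           "run_all", "null_false_positive_rate", "BsaScanResult"]


@dataclass
class SimulatedExperiment:
    config: simulate.CrossConfig
    population: simulate.Population
    ef: simulate.BulkSpec
    lf: simulate.BulkSpec
    site_table: pd.DataFrame


@dataclass
class BsaScanResult:
    track: pd.DataFrame
    windows: pd.DataFrame
    threshold: scan.Threshold
    regions: list


def simulate_bsa_inputs(config: simulate.CrossConfig,
                        seed: int | None = None) -> SimulatedExperiment:
    """Simulate the cross, phenotypes, bulks and the pooled site table."""
    seed = config.seed if seed is None else seed
    pop = simulate.simulate_cross(config, seed=seed)
    pop = simulate.assign_phenotypes(pop, config, seed=seed)
    ef, lf = simulate.select_bulks(pop.phenotypes, config.n_early, config.n_late)
    table = simulate.build_site_table(pop, ef, lf, config, seed=seed)
    return SimulatedExperiment(config=config, population=pop, ef=ef, lf=lf,
                               site_table=table)


def bsa_scan_pipeline(site_table: pd.DataFrame, *, window_bp: int = 1_000_000,
                      step_bp: int = 10_000, min_sites: int = 3,
                      n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                      null: str = "genedrop",
                      genedrop: scan.GeneDropNull | None = None,
                      merge_gap: int = 1,
                      filter_kwargs: dict | None = None) -> BsaScanResult:
    """Filter sites, build the Delta track, threshold it and call regions."""
    kept = sites.apply_filter_chain(site_table, **(filter_kwargs or {})).sites
    track = scan.index_track(kept)
    windows = scan.window_track(track, window_bp, step_bp, min_sites)
    if null == "genedrop" and genedrop is not None:
        # align the genedrop cM vector with the filtered table
        genedrop = scan.GeneDropNull(
            cm=_align_cm(site_table, kept, genedrop.cm),
            bulk_sizes=genedrop.bulk_sizes, error_rate=genedrop.error_rate)
    thr = scan.permutation_threshold(kept, window_bp, step_bp, min_sites,
                                     n_perm=n_perm, alpha=alpha, seed=seed,
                                     null=null, genedrop=genedrop)
    regions = scan.call_regions(windows, thr, merge_gap=merge_gap)
    return BsaScanResult(track=track, windows=windows, threshold=thr,
                         regions=regions)


def _align_cm(full: pd.DataFrame, kept: pd.DataFrame, cm: np.ndarray) -> np.ndarray:
    key = pd.DataFrame({"chrom": full["chrom"], "pos": full["pos"], "cm": cm})
    merged = kept[["chrom", "pos"]].merge(key, on=["chrom", "pos"], how="left")
    return merged["cm"].to_numpy()


def scan_simulated(exp: SimulatedExperiment, *, n_perm: int = 1000,
                   alpha: float = 0.05, seed: int | None = None,
                   null: str = "genedrop", **kwargs) -> BsaScanResult:
    """BSA scan of a simulated experiment with the map-derived gene-drop null."""
    cfg = exp.config
    gd = scan.genedrop_from_map(exp.site_table, cfg.marker_map,
                                bulk_sizes=(cfg.n_early, cfg.n_late),
                                error_rate=cfg.error_rate)
    return bsa_scan_pipeline(exp.site_table, n_perm=n_perm, alpha=alpha,
                             seed=cfg.seed + 101 if seed is None else seed,
                             null=null, genedrop=gd, **kwargs)


@dataclass
class LinkageResult:
    groups: list[list[str]]
    maps: list[pd.DataFrame]
    scan: pd.DataFrame
    threshold: linkage.LodThreshold
    significant: pd.DataFrame


def linkage_pipeline(genotypes: pd.DataFrame, phenotypes: pd.Series, *,
                     p_crit: float = 0.001, n_perm: int = 1000,
                     alpha: float = 0.05, floor: float = 2.5,
                     seed: int = 0) -> LinkageResult:
    """Group, order and map markers, then scan with a permutation threshold."""
    R, P = linkage.linkage_matrices(genotypes)
    groups = linkage.group_markers(P, p_crit=p_crit, R=R)
    maps = []
    for g in groups:
        if len(g) < 2:
            maps.append(pd.DataFrame({"marker": g, "R_obs": np.nan, "r": np.nan,
                                      "interval_cm": np.nan, "cum_cm": 0.0}))
            continue
        order, _ = linkage.order_markers(R.loc[g, g])
        maps.append(linkage.build_map(order, R))
    result = linkage.marker_scan(genotypes, phenotypes)
    thr = linkage.lod_threshold(genotypes, phenotypes, n_perm=n_perm,
                                alpha=alpha, floor=floor, seed=seed)
    sig = result[result["lod"] >= thr.value]
    return LinkageResult(groups=groups, maps=maps, scan=result, threshold=thr,
                         significant=sig)


# ---------------------------------------------------------------------------
# Directory-level runs (used by the CLI)


def _write_manifest(out_dir: Path, stage: str, params: dict) -> None:
    path = out_dir / "manifest.json"
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest[stage] = params
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_simulate(preset: str, seed: int, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = _preset(preset, seed)
    exp = simulate_bsa_inputs(config)
    simulate.write_genotypes_tsv(exp.population, out / "genotypes.tsv")
    simulate.write_phenotypes_tsv(exp.population, out / "phenotypes.tsv")
    config.marker_map.table.to_csv(out / "marker_map.tsv", sep="\t", index=False)
    sites.write_pool_tsv(exp.site_table, out / "sites.tsv")
    sites.write_pool_vcf(exp.site_table, out / "sites.vcf")
    (out / "bulks.json").write_text(json.dumps({
        "EF": list(exp.ef.members), "LF": list(exp.lf.members)}, indent=2) + "\n")
    params = {"preset": preset, "seed": seed, "n_lines": config.n_lines,
              "generations": config.generations, "n_early": config.n_early,
              "n_late": config.n_late, "depth": config.depth,
              "error_rate": config.error_rate, "mu": config.mu,
              "sigma": config.sigma,
              "qtls": [(q.chrom, q.cm, q.effect) for q in config.qtls]}
    _write_manifest(out, "simulate", params)
    return params


def run_filter(sites_path: str | Path, out_dir: str | Path,
               maf_min: float | None = None, **kwargs) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites_path = Path(sites_path)
    if not sites_path.exists():
        raise FileNotFoundError(f"missing input: {sites_path}")
    if sites_path.suffix == ".vcf":
        table = sites.read_pool_vcf(sites_path).sites
    else:
        table = sites.read_pool_tsv(sites_path)
    res = sites.apply_filter_chain(table, maf_min=maf_min, **kwargs)
    sites.write_pool_tsv(res.sites, out / "filtered.tsv")
    report = {"input_sites": int(len(table)), "retained": int(len(res.sites)),
              "removed_by_reason": {k: int(v) for k, v in res.reason_counts.items()}}
    (out / "filter_report.json").write_text(json.dumps(report, indent=2) + "\n")
    _write_manifest(out, "filter", {"sites": str(sites_path),
                                    "maf_min": maf_min, **kwargs})
    return report


def run_scan(filtered_path: str | Path, out_dir: str | Path, *,
             seed: int = 0, n_perm: int = 1000, alpha: float = 0.05,
             window_bp: int = 1_000_000, step_bp: int = 10_000,
             min_sites: int = 3, merge_gap: int = 1, null: str = "genedrop",
             marker_map_path: str | Path | None = None,
             cm_per_mb: float = 2.0, bulk_sizes=(30, 21),
             error_rate: float = 0.005) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    filtered_path = Path(filtered_path)
    if not filtered_path.exists():
        raise FileNotFoundError(
            f"missing input: {filtered_path} (run the filter stage first)")
    kept = sites.read_pool_tsv(filtered_path)
    gd = None
    if null == "genedrop":
        if marker_map_path is not None:
            mm = simulate.MarkerMap(pd.read_csv(marker_map_path, sep="\t"))
            gd = scan.genedrop_from_map(kept, mm, bulk_sizes, error_rate)
        else:
            gd = scan.genedrop_from_rate(kept, cm_per_mb, bulk_sizes, error_rate)
    track = scan.index_track(kept)
    windows = scan.window_track(track, window_bp, step_bp, min_sites)
    thr = scan.permutation_threshold(kept, window_bp, step_bp, min_sites,
                                     n_perm=n_perm, alpha=alpha, seed=seed,
                                     null=null, genedrop=gd)
    regions = scan.call_regions(windows, thr, merge_gap=merge_gap)
    track.to_csv(out / "track.tsv", sep="\t", index=False)
    windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    scan.regions_to_bed(regions, out / "regions.bed")
    report = {"threshold": thr.value, "alpha": alpha, "n_perm": n_perm,
              "null": null, "seed": seed,
              "regions": [r.to_dict() for r in regions]}
    (out / "scan_report.json").write_text(json.dumps(report, indent=2) + "\n")
    _write_manifest(out, "scan", {"filtered": str(filtered_path), "seed": seed,
                                  "n_perm": n_perm, "alpha": alpha,
                                  "window_bp": window_bp, "step_bp": step_bp,
                                  "min_sites": min_sites, "null": null,
                                  "merge_gap": merge_gap})
    return report


def run_linkage(genotypes_path: str | Path, phenotypes_path: str | Path,
                out_dir: str | Path, *, markers: list[str] | None = None,
                seed: int = 0, n_perm: int = 1000, alpha: float = 0.05,
                floor: float = 2.5) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in (genotypes_path, phenotypes_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")
    genos = simulate.read_genotypes_tsv(genotypes_path)
    if markers:
        genos = genos[markers]
    phenos = simulate.read_phenotypes_tsv(phenotypes_path)
    res = linkage_pipeline(genos, phenos, n_perm=n_perm, alpha=alpha,
                           floor=floor, seed=seed)
    pd.concat(res.maps, keys=range(len(res.maps)), names=["group"]) \
        .reset_index(level=0).to_csv(out / "linkage_map.tsv", sep="\t", index=False)
    res.scan.to_csv(out / "marker_scan.tsv", sep="\t", index=False)
    report = {"lod_threshold": res.threshold.value,
              "permutation_quantile": res.threshold.quantile,
              "floor": res.threshold.floor, "alpha": alpha, "n_perm": n_perm,
              "seed": seed, "n_groups": len(res.groups),
              "significant_markers": res.significant["marker"].tolist()}
    (out / "linkage_report.json").write_text(json.dumps(report, indent=2) + "\n")
    _write_manifest(out, "linkage", {"genotypes": str(genotypes_path),
                                     "phenotypes": str(phenotypes_path),
                                     "seed": seed, "n_perm": n_perm,
                                     "alpha": alpha, "floor": floor})
    return report


def _preset(name: str, seed: int) -> simulate.CrossConfig:
    if name in ("study", "study_cross"):
        return simulate.study_cross(seed)
    if name == "null":
        return simulate.null_cross(seed)
    raise ValueError(f"unknown preset {name!r}")


def null_false_positive_rate(n_replicates: int = 200, seed: int = 0, *,
                             n_perm: int = 1000, alpha: float = 0.05,
                             scan_kwargs: dict | None = None) -> dict:
    """Fraction of null-preset genomes yielding >= 1 region call.

    Each replicate simulates a fresh no-QTL cross, bulks the phenotypic
    tails, sequences the pools and runs the full scan with its own gene-drop
    threshold; used for genome-wide type-I calibration.
    """
    hits = 0
    for i in range(n_replicates):
        exp = simulate_bsa_inputs(simulate.null_cross(seed + 1000 * i + 1))
        res = scan_simulated(exp, n_perm=n_perm, alpha=alpha,
                             **(scan_kwargs or {}))
        hits += bool(res.regions)
    return {"replicates": n_replicates, "alpha": alpha,
            "false_positive_fraction": hits / n_replicates, "seed": seed}


def run_all(preset: str, seed: int, out_dir: str | Path, *,
            n_perm: int = 1000, alpha: float = 0.05,
            replicates: int = 1) -> dict:
    """Seeded end-to-end run; with ``replicates > 1`` on the null preset,
    summarises the empirical false-positive fraction instead."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if replicates > 1:
        if preset != "null":
            raise ValueError("replicated runs are for the null preset")
        summary = null_false_positive_rate(replicates, seed, n_perm=n_perm,
                                           alpha=alpha)
        (out / "null_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        _write_manifest(out, "run-all", {"preset": preset, "seed": seed,
                                         "replicates": replicates,
                                         "n_perm": n_perm, "alpha": alpha})
        return summary
    run_simulate(preset, seed, out)
    run_filter(out / "sites.tsv", out)
    cfg = _preset(preset, seed)
    report = run_scan(out / "filtered.tsv", out, seed=seed + 101, n_perm=n_perm,
                      alpha=alpha, marker_map_path=out / "marker_map.tsv",
                      bulk_sizes=(cfg.n_early, cfg.n_late),
                      error_rate=cfg.error_rate)
    lmarkers = simulate.linkage_subset(cfg.marker_map)
    lreport = run_linkage(out / "genotypes.tsv", out / "phenotypes.tsv", out,
                          markers=lmarkers, seed=seed + 202, n_perm=n_perm,
                          alpha=alpha)
    _write_manifest(out, "run-all", {"preset": preset, "seed": seed,
                                     "n_perm": n_perm, "alpha": alpha,
                                     "replicates": replicates})
    return {"scan": report, "linkage": lreport}
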