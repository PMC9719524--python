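"""End-to-end orchestration: structure analysis, cluster split, per-cluster
sex-linkage scans, association statistics, and a consolidated JSON report.

The stage order mirrors the analysis the package automates: a whole-cohort
sex-linkage pre-scan supplies the loci to exclude from the structure stage,
PCA (plus 2-means on the leading components when no cluster labels are given)
splits the cohort, each cluster is scanned separately with auto-strict
handling of small cohorts, and candidate loci are summarised with Hamming
distances and trend tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import association, structure
from .io import (
    SampleSheet, SnpMatrix, PaMatrix,
    check_samples_resolvable, export_fasta,
    read_pa_csv, read_sample_sheet, read_snp_csv,
    write_pa_csv, write_sample_sheet, write_snp_csv,
)
from .sexlinkage import SexLinkCriteria, scan
from .simulate import SimConfig, SimDataset, simulate_dataset

log = logging.getLogger("sexlinkscan")

CLUSTER_GIVEN = "GIVEN"
CLUSTER_FROM_PCA = "FROM_PCA"


@dataclass
class PipelineConfig:
    """Either file inputs (snp/pa/samples paths) or a SimConfig, plus options."""

    snp_path: Optional[str] = None
    pa_path: Optional[str] = None
    samples_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    criteria: SexLinkCriteria = field(default_factory=SexLinkCriteria)
    cluster_mode: str = CLUSTER_GIVEN
    outdir: Optional[str] = None
    seed: int = 0
    catt_permutations: int = 0

    def __post_init__(self):
        has_paths = self.snp_path is not None
        if has_paths == (self.sim is not None):
            raise ValueError("set exactly one of input paths / sim config")
        if self.cluster_mode not in (CLUSTER_GIVEN, CLUSTER_FROM_PCA):
            raise ValueError("cluster_mode must be GIVEN or FROM_PCA")


def _filter_log(stage: str, n_in: int, n_out: int, counts: list) -> None:
    entry = {"stage": stage, "n_in": int(n_in), "n_out": int(n_out),
             "n_dropped": int(n_in - n_out)}
    counts.append(entry)
    log.info("%s: %d in, %d retained, %d dropped",
             stage, n_in, n_out, n_in - n_out)


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        ds = simulate_dataset(config.sim)
        return ds.snp, ds.pa, ds.sheet
    snp = read_snp_csv(config.snp_path)
    pa = read_pa_csv(config.pa_path) if config.pa_path else None
    sheet = read_sample_sheet(config.samples_path)
    check_samples_resolvable(snp, sheet)
    if pa is not None:
        check_samples_resolvable(pa, sheet)
    return snp, pa, sheet


def _assign_clusters(snp: SnpMatrix, sheet: SampleSheet, sexlink_ids,
                     mode: str, seed: int, counts_log: list):
    """Cluster labels aligned with snp.sample_ids, plus structure outputs."""
    auto = structure.filter_autosomal_strict(snp, sexlink_ids)
    _filter_log("strict_autosomal_filter", snp.n_loci, auto.n_loci, counts_log)
    pca = structure.pca_scores(auto)
    given = sheet.cluster_of(snp.sample_ids)
    if mode == CLUSTER_GIVEN and not pd.isna(given).any():
        labels = np.asarray(given).astype(int)
        source = "given"
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed % (2**31))
        labels = km.fit_predict(pca.scores.iloc[:, :2].to_numpy()) + 1
        source = "pca_kmeans"
    return labels, pca, auto, source


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    rng_seed = config.seed
    counts_log: list = []
    snp, pa, sheet = _load_inputs(config)
    log.info("loaded %d SNP loci, %s PA loci, %d samples",
             snp.n_loci, pa.n_loci if pa is not None else "no", snp.n_samples)

    # whole-cohort pre-scan: supplies sex-linked loci to exclude from structure
    pre = scan(snp, pa, sheet, config.criteria)
    pre_ids = pre.reported()["locus_id"].tolist()
    n_total = snp.n_loci + (pa.n_loci if pa is not None else 0)
    _filter_log("prescan_sexlinked_flagged", n_total,
                n_total - len(pre_ids), counts_log)

    labels, pca, auto, cluster_source = _assign_clusters(
        snp, sheet, pre_ids, config.cluster_mode, rng_seed, counts_log)

    report = {
        "seed": rng_seed,
        "n_samples": int(snp.n_samples),
        "cluster_source": cluster_source,
        "prescan_summary": pre.summary,
        "pca_explained_variance": [round(float(v), 6)
                                   for v in pca.explained_variance_ratio[:5]],
        "clusters": {},
        "filters": counts_log,
    }

    uniq, cnt = np.unique(labels, return_counts=True)
    if len(uniq) >= 2 and (cnt >= 2).all():
        report["fst"] = structure.pairwise_fst(auto, labels).to_dict("records")
        report["nei"] = structure.nei_distance(auto, labels).to_dict("records")
        report["within_cluster_distance"] = {
            str(k): (None if np.isnan(v) else round(v, 6))
            for k, v in structure.mean_within_cluster_distance(auto, labels).items()
        }
        am = structure.amova(auto, labels, permutations=99, seed=rng_seed)
        report["amova"] = {
            "table": am.table.round(4).to_dict("index"),
            "p_between_clusters": am.p_between_clusters,
            "p_within": am.p_within,
        }

    scan_tables = {}
    for cl in uniq:
        sel = snp.sample_ids[labels == cl]
        snp_c = snp.subset_samples(sel)
        pa_c = pa.subset_samples(sel) if pa is not None else None
        sheet_c = SampleSheet(
            sheet.table[sheet.table["sample_id"].isin(set(sel))].copy())
        try:
            res = scan(snp_c, pa_c, sheet_c, config.criteria)
        except ValueError as e:
            report["clusters"][str(cl)] = {"error": str(e)}
            continue
        rep = res.reported()
        entry = {"n_samples": int(len(sel)), "summary": res.summary}
        snp_ids = rep[rep["marker_type"] == "SNP"]["locus_id"].tolist()
        pa_ids = rep[rep["marker_type"] == "PA"]["locus_id"].tolist()
        if snp_ids:
            dm = association.hamming_matrix(snp_c, snp_ids)
            gs = association.group_distance_summary(dm, sheet_c)
            entry["snp_distance"] = {
                "within_males": _r(gs.mean_within_males),
                "within_females": _r(gs.mean_within_females),
                "between_sexes": _r(gs.mean_between),
            }
            tests = association.catt_scan(
                snp_c, sheet_c, snp_ids,
                permutations=config.catt_permutations, seed=rng_seed)
            valid_p = tests["p_asymptotic"].dropna()
            comb = association.combined_trend_test(snp_c, sheet_c, snp_ids)
            entry["catt"] = {
                "n_loci": int(len(tests)),
                "median_p": _r(float(valid_p.median())) if len(valid_p) else None,
                "min_p": _r(float(valid_p.min())) if len(valid_p) else None,
                "combined_pc1_chi2": _r(comb.chi2),
                "combined_pc1_p": _r(comb.p_asymptotic),
            }
        if pa_ids:
            dm = association.hamming_matrix(pa_c, pa_ids)
            gs = association.group_distance_summary(dm, sheet_c)
            entry["pa_distance"] = {
                "within_males": _r(gs.mean_within_males),
                "within_females": _r(gs.mean_within_females),
                "between_sexes": _r(gs.mean_between),
            }
        report["clusters"][str(cl)] = entry
        scan_tables[str(cl)] = (res, snp_ids)

    if config.outdir:
        _write_outputs(Path(config.outdir), report, snp, scan_tables, pca)
    return report


def _r(x, nd: int = 6):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return round(float(x), nd)


def _write_outputs(outdir: Path, report: dict, snp: SnpMatrix,
                   scan_tables: dict, pca) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    pca.scores.round(6).to_csv(outdir / "pca_scores.csv")
    all_candidates = []
    for cl, (res, snp_ids) in scan_tables.items():
        res.results.to_csv(outdir / f"scan_cluster_{cl}.csv", index=False)
        all_candidates.extend(snp_ids)
    cand = [l for l in dict.fromkeys(all_candidates)
            if "trimmed_sequence" in snp.meta.columns]
    if cand:
        export_fasta(snp, cand, outdir / "candidates.fasta")
    log.info("report written to %s", outdir / "report.json")


def write_simulated_dataset(ds: SimDataset, outdir) -> dict:
    """Write a simulated dataset's four CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp": outdir / "snp.csv", "pa": outdir / "pa.csv",
        "samples": outdir / "samples.csv", "truth": outdir / "truth.csv",
    }
    write_snp_csv(ds.snp, paths["snp"])
    write_pa_csv(ds.pa, paths["pa"])
    write_sample_sheet(ds.sheet, paths["samples"])
    ds.truth.to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}
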