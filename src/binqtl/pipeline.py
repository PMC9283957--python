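"""End-to-end orchestration of the simulated genotype-to-gene pipeline.

`run_pipeline` executes simulate -> correct -> binmap -> qtl -> (gwas) ->
stats -> triage with one declarative configuration, writes every stage's
tables under an output directory, and returns a manifest (also written as
JSON) recording parameters, seeds, per-stage outputs and their digests —
enough to reproduce the run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binmap, genocorrect, io, mlmgwas, qtlscan, quantstats, simpop, triage

logger = logging.getLogger("binqtl")


@dataclass
class RunConfig:
    """Stage toggles plus every stage parameter, pre-filled with the study
    defaults (window 15/11, 10 kb + p<0.001 bin filters, 1 cM step / 10 cM
    window / 5 cofactors / permutation alpha 0.05, MAF 0.05, 1/nSNP
    threshold)."""

    seed: int = 1
    outdir: str = "pipeline_out"
    # stage toggles
    do_gwas: bool = True
    do_multi_env: bool = False
    # simulation
    sim: simpop.SimConfig = field(default_factory=simpop.SimConfig)
    n_chromosomes: int = 2
    chrom_bp: int = 20_000_000
    chrom_cm: float = 80.0
    snps_per_chrom: int = 2000
    # correction
    window: genocorrect.WindowRule = field(default_factory=genocorrect.WindowRule)
    # bin filters
    min_bin_len_bp: int = 10_000
    seg_alpha: float = 0.001
    # scan
    scan: qtlscan.ScanSettings = field(default_factory=qtlscan.ScanSettings)
    # gwas
    maf_min: float = 0.05


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the toggled stages; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.sim.seed = cfg.seed
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "window": asdict(cfg.window),
            "min_bin_len_bp": cfg.min_bin_len_bp,
            "seg_alpha": cfg.seg_alpha,
            "scan": asdict(cfg.scan),
            "maf_min": cfg.maf_min,
            "sim": {
                "n_ril": cfg.sim.n_ril,
                "n_self_generations": cfg.sim.n_self_generations,
                "error": cfg.sim.genotyping_error_rate,
                "missing": cfg.sim.missing_rate,
                "n_environments": cfg.sim.n_environments,
                "target_h2": cfg.sim.target_h2,
                "qtl": [q._asdict() for q in cfg.sim.qtl_spec],
            },
        },
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], t0: float, **extra) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "outputs": {k: str(p) for k, p in files.items()},
            "digests": {k: _digest(p) for k, p in files.items()},
            **extra,
        }
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    # -- simulate -----------------------------------------------------------
    t0 = time.time()
    gmap = simpop.uniform_map(
        cfg.n_chromosomes, cfg.chrom_bp, cfg.chrom_cm, cfg.snps_per_chrom
    )
    calls, truth = simpop.simulate_ril_population(gmap, cfg.sim)
    pheno = simpop.simulate_phenotypes(truth, calls, cfg.sim)
    files = {
        "calls_vcf": out / "ril_calls.vcf",
        "pheno": out / "ril_phenotypes.tsv",
        "truth": out / "ril_truth.json",
    }
    io.write_vcf(calls, files["calls_vcf"])
    io.write_phenotypes(pheno, files["pheno"])
    io.write_truth_json(truth, files["truth"])
    record("simulate", files, t0, n_ril=cfg.sim.n_ril, n_snps=calls.n_markers)

    # -- correct ------------------------------------------------------------
    t0 = time.time()
    corrected = genocorrect.slide_correct(calls, cfg.window)
    report = genocorrect.correction_report(calls, corrected)
    files = {"corrected_vcf": out / "ril_corrected.vcf", "report": out / "corrections.tsv"}
    io.write_vcf(corrected, files["corrected_vcf"])
    report.to_csv(files["report"], sep="\t", index=False)
    record("correct", files, t0, n_changed=int(report["count"].sum()) if len(report) else 0)

    # -- binmap -------------------------------------------------------------
    t0 = time.time()
    bps = binmap.detect_breakpoints(corrected)
    bins = binmap.build_bins(corrected, bps)
    retained, rejects = binmap.filter_bins(bins, cfg.min_bin_len_bp, cfg.seg_alpha)
    groups = binmap.assemble_map(retained)
    summary = binmap.map_summary(groups)
    files = {
        "bins": out / "bins.tsv",
        "map": out / "linkage_map.tsv",
        "map_summary": out / "map_summary.tsv",
        "rejects": out / "bin_rejects.tsv",
    }
    binmap.bins_table(retained).to_csv(files["bins"], sep="\t", index=False)
    map_rows = []
    for g in groups:
        for b, cm in zip(g.bins, g.cm):
            map_rows.append({"group": g.id, "start": b.start, "end": b.end, "cm": round(cm, 4)})
    pd.DataFrame(map_rows).to_csv(files["map"], sep="\t", index=False)
    summary["per_group"].to_csv(files["map_summary"], sep="\t", index=False)
    rejects.to_csv(files["rejects"], sep="\t", index=False)
    record("binmap", files, t0, n_bins=len(retained), total_cm=summary["genome"]["total_cm"])

    # -- qtl ----------------------------------------------------------------
    t0 = time.time()
    env1 = pheno[pheno["environment"] == pheno["environment"].iloc[0]]
    y = env1.groupby("individual", sort=False)["value"].mean().reindex(calls.samples)
    engine = qtlscan._ScanEngine(groups, cfg.scan)
    scan = qtlscan.cim_scan(groups, y.to_numpy(), cfg.scan, environment="E1", _engine=engine)
    thr, _ = qtlscan.permutation_threshold(
        groups, y.to_numpy(), cfg.scan, seed=cfg.seed, _engine=engine
    )
    scan.threshold = thr
    records = qtlscan.call_qtl(scan, thr, cfg.scan)
    files = {"scan": out / "qtl_scan.tsv", "qtl": out / "qtl_records.tsv"}
    pd.DataFrame(
        {"group": scan.group, "cm": scan.cm, "lod": scan.lod, "add": scan.add, "pve": scan.pve}
    ).to_csv(files["scan"], sep="\t", index=False)
    qtlscan.qtl_table(records).to_csv(files["qtl"], sep="\t", index=False)
    qtl_extra = {"threshold": thr, "n_qtl": len(records)}
    if cfg.do_multi_env and cfg.sim.n_environments > 1:
        joint = qtlscan.multi_env_scan(groups, pheno, cfg.scan, samples=calls.samples)
        files["joint_scan"] = out / "qtl_scan_joint.tsv"
        pd.DataFrame(
            {
                "group": joint.group,
                "cm": joint.cm,
                "lod": joint.lod,
                "pve_add": joint.pve,
                "pve_int": joint.pve_interaction,
            }
        ).to_csv(files["joint_scan"], sep="\t", index=False)
    record("qtl", files, t0, **qtl_extra)

    # -- gwas ---------------------------------------------------------------
    if cfg.do_gwas:
        t0 = time.time()
        panel, labels = simpop.simulate_structured_panel(cfg.sim)
        filtered = mlmgwas.maf_filter(panel, cfg.maf_min)
        ppheno = simpop.simulate_polygenic_phenotype(filtered, h2=0.5, seed=cfg.seed)
        K = mlmgwas.kinship(filtered)
        assoc = mlmgwas.emmax_assoc(ppheno, filtered, K)
        p_star, neglog = mlmgwas.significance_threshold(filtered.n_markers)
        assoc.threshold_p = p_star
        curve = mlmgwas.ld_decay(filtered, max_dist=500_000, bin_width=10_000)
        files = {
            "assoc": out / "gwas_assoc.tsv",
            "kinship": out / "kinship.tsv",
            "ld": out / "ld_decay.tsv",
        }
        assoc.table.to_csv(files["assoc"], sep="\t", index=False)
        pd.DataFrame(K.values, index=K.samples, columns=K.samples).to_csv(files["kinship"], sep="\t")
        pd.DataFrame(
            {"dist_bp": curve.bin_centers_bp, "mean_r2": curve.mean_r2, "n_pairs": curve.n_pairs}
        ).to_csv(files["ld"], sep="\t", index=False)
        record(
            "gwas", files, t0,
            n_snps=filtered.n_markers, threshold_p=p_star, neglog10_threshold=neglog,
            n_hits=int((assoc.table["p"] < p_star).sum()),
        )

    # -- stats --------------------------------------------------------------
    t0 = time.time()
    summ = quantstats.summarize_trait(env1["value"])
    rows = [{"environment": "E1", **summ.__dict__}]
    files = {"trait_summary": out / "trait_summary.tsv"}
    extra = {}
    if cfg.sim.n_environments > 1:
        blup = quantstats.blup_lines(pheno)
        files["blup"] = out / "blup.tsv"
        blup.rename_axis("individual").reset_index().to_csv(files["blup"], sep="\t", index=False)
        if cfg.sim.n_replicates > 1:
            vc = quantstats.anova_varcomp(pheno)
            extra["h2"] = vc.h2
    pd.DataFrame(rows).to_csv(files["trait_summary"], sep="\t", index=False)
    record("stats", files, t0, **extra)

    # -- triage -------------------------------------------------------------
    t0 = time.time()
    fx = simpop.make_triage_fixture()
    chrom, lo, hi = simpop.CANDIDATE_INTERVAL
    in_interval = triage.genes_in_interval(fx.genes, chrom, lo, hi)
    recs = triage.annotate_genes(in_interval, fx.expression, fx.de_stats, fx.variants, fx.synteny)
    verdicts = triage.triage_genes(recs, syntenic_region_has_qtl=False)
    files = {"verdicts": out / "triage_verdicts.tsv"}
    triage.verdict_table(verdicts).to_csv(files["verdicts"], sep="\t", index=False)
    record(
        "triage", files, t0,
        n_genes=len(verdicts),
        n_retained=sum(v.verdict == "retained" for v in verdicts),
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
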