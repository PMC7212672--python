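"""End-to-end orchestration: simulate -> demux -> qc -> dea/signature ->
score/classify/correct -> kbet/variance, driven by one config and one seed.

Every stage writes its artifacts under the output directory in the
MTX-triplet + CSV convention so any stage can be re-run or swapped for an
external tool, and the run report collects the headline metrics.
"""

from __future__ import annotations

import json
import logging
import os
import sys
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from timedrift import io as tio
from timedrift.containers import ConfigError, NormalizedMatrix
from timedrift.demux import clr_normalize, demultiplex_barcodes
from timedrift.dea import define_signature, wilcoxon_dea
from timedrift.mixing import kbet, pc_variance_fraction, variance_r2
from timedrift.qc import QcThresholds, filter_cells, filter_genes, \
    mito_mask_from_names, size_factor_normalize
from timedrift.score import (
    _pca_embed,
    bootstrap_silhouette,
    fit_classifier,
    module_score,
    predict_auc,
    regress_out_score,
)
from timedrift.sim import SimConfig, simulate_counts, simulate_hto

log = logging.getLogger("timedrift")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    One global ``seed`` feeds every stochastic stage; stage-specific streams
    are derived from it with fixed offsets so stages stay reproducible in
    isolation.
    """

    out_dir: str = "timedrift_run"
    seed: int = 0
    # stage toggles
    do_demux: bool = True
    do_bootstrap: bool = False
    # simulation
    sim: dict = field(default_factory=dict)
    hto: dict = field(
        default_factory=lambda: dict(fg_mean=200.0, bg_mean=5.0,
                                     dispersion=10.0, doublet_rate=0.05,
                                     negative_rate=0.02)
    )
    # qc
    qc: dict = field(
        default_factory=lambda: dict(min_counts=0, max_counts=float("inf"),
                                     min_genes=0, max_mito=1.0,
                                     min_cells_per_gene=3)
    )
    # signature thresholds
    min_abs_logfc: float = 0.25
    max_adj_p: float = 0.001
    min_expr: float = 0.0
    # scoring
    n_bins: int = 25
    n_ctrl: int = 100
    # mixing
    kbet_k: int | None = None
    kbet_n_test: int = 500
    n_pcs: int = 10
    # bootstrap
    bootstrap_n_cells: int = 300
    bootstrap_reps: int = 25

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ConfigError(f"unknown config keys: {sorted(stray)}")
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s: FAILED", name)
                raise
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written as ``report.json`` and
    ``report.txt`` under ``config.out_dir``). A stage failure aborts the run
    with the failing stage named; artifacts of completed stages remain on
    disk.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    fh = logging.FileHandler(os.path.join(config.out_dir, "run.log"))
    log.addHandler(fh)
    report: dict = {"seed": config.seed, "stages": {}}

    try:
        # --- simulate ------------------------------------------------------
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        counts, truth = _stage("simulate")(simulate_counts)(sim_cfg)
        tio.write_counts(counts, os.path.join(config.out_dir, "counts"))
        truth.genes.to_csv(os.path.join(config.out_dir, "truth_genes.csv"))
        report["stages"]["simulate"] = {
            "n_genes": counts.n_genes, "n_cells": counts.n_cells,
            "conditions": list(sim_cfg.conditions),
        }

        # --- demux (label recovery on matched HTO data) --------------------
        if config.do_demux:
            n_htos = len(sim_cfg.conditions)
            hto, hto_truth = _stage("demux:simulate")(simulate_hto)(
                n_barcodes=counts.n_cells, n_htos=n_htos,
                seed=config.seed + 1, **config.hto,
            )
            clr = clr_normalize(hto)
            demux = _stage("demux")(demultiplex_barcodes)(
                clr, k=n_htos, seed=config.seed + 2
            )
            demux.to_frame().to_csv(os.path.join(config.out_dir, "demux_calls.csv"))
            demux.thresholds.to_csv(
                os.path.join(config.out_dir, "demux_thresholds.csv")
            )
            singlets = hto_truth.barcodes["kind"] == "singlet"
            acc = float(
                (demux.calls[singlets.values]
                 == hto_truth.barcodes.loc[singlets, "identity"]).mean()
            )
            report["stages"]["demux"] = {
                "n_htos": n_htos,
                "singlet_accuracy": acc,
                "n_multiplets_called": int((demux.calls == "multiplet").sum()),
                "n_negatives_called": int((demux.calls == "negative").sum()),
            }

        # --- qc + normalize ------------------------------------------------
        qc_kwargs = dict(config.qc)
        min_cells_per_gene = int(qc_kwargs.pop("min_cells_per_gene", 0))
        thr = QcThresholds(min_cells_per_gene=min_cells_per_gene, **qc_kwargs)
        mito = mito_mask_from_names(counts.gene_names)
        filtered, qc_report = _stage("qc")(filter_cells)(counts, thr, mito)
        filtered = filter_genes(filtered, min_cells_per_gene)
        norm = size_factor_normalize(filtered)
        with open(os.path.join(config.out_dir, "qc_report.json"), "w") as f:
            json.dump(qc_report, f, indent=2)
        report["stages"]["qc"] = {
            "n_cells_kept": filtered.n_cells, "n_genes_kept": filtered.n_genes,
        }

        # --- signature on the training donor -------------------------------
        donors = pd.unique(norm.cell_meta["donor"])
        train_donor = donors[0]
        test_donor = donors[1] if len(donors) > 1 else donors[0]
        train = norm.subset_cells((norm.cell_meta["donor"] == train_donor).values)
        test = norm.subset_cells((norm.cell_meta["donor"] == test_donor).values)

        dea = _stage("dea")(wilcoxon_dea)(
            train, train.cell_meta["affected"].values
        )
        dea.to_csv(os.path.join(config.out_dir, "dea.tsv"), sep="\t")
        sig = define_signature(
            dea, config.min_abs_logfc, config.max_adj_p, config.min_expr
        )
        sig.to_csv(os.path.join(config.out_dir, "signature.tsv"), sep="\t")
        report["stages"]["signature"] = {"n_genes": int(len(sig))}

        # --- score / classify / correct on the test donor -------------------
        if len(sig) == 0:
            report["headline"] = {"n_signature_genes": 0}
            raise ConfigError("empty signature; downstream stages skipped")
        score_train = _stage("score:train")(module_score)(
            train, sig.index, config.n_bins, config.n_ctrl, seed=config.seed + 3
        )
        model = fit_classifier(score_train, train.cell_meta["affected"].values)
        score_test = module_score(
            test, sig.index, config.n_bins, config.n_ctrl, seed=config.seed + 3
        )
        auc, roc = predict_auc(
            model, score_test, test.cell_meta["affected"].values
        )
        pd.DataFrame({
            "score": score_test,
            "prob_biased": model.predict_proba(score_test),
        }).to_csv(os.path.join(config.out_dir, "scores_test.csv"))

        corrected = _stage("correct")(regress_out_score)(
            test, score_test.values, test.cell_meta["cell_type"].values
        )

        # --- mixing before/after -------------------------------------------
        emb_before = _pca_embed(test.values, config.n_pcs, seed=config.seed)
        emb_after = _pca_embed(corrected, config.n_pcs, seed=config.seed)
        time_labels = test.cell_meta["time_h"].values
        kb_before = _stage("kbet")(kbet)(
            emb_before, time_labels, k=config.kbet_k,
            n_test=config.kbet_n_test, seed=config.seed + 4,
        )
        kb_after = kbet(
            emb_after, time_labels, k=config.kbet_k,
            n_test=config.kbet_n_test, seed=config.seed + 4,
        )

        corrected_nm = NormalizedMatrix(
            corrected, test.gene_names, test.cell_meta, test.size_factors
        )
        r2_time = variance_r2(test, time_labels)
        r2_time_after = variance_r2(corrected_nm, time_labels)
        pcvar_time = pc_variance_fraction(
            test, time_labels, n_pcs=config.n_pcs, seed=config.seed
        )

        report["headline"] = {
            "n_signature_genes": int(len(sig)),
            "train_auc": float(model.train_auc),
            "test_auc": float(auc),
            "kbet_acceptance_before": kb_before.acceptance_rate,
            "kbet_acceptance_after": kb_after.acceptance_rate,
            "median_r2_time_before": float(r2_time.median()),
            "median_r2_time_after": float(r2_time_after.median()),
            "pc_variance_fraction_time": pcvar_time,
        }

        # --- bootstrap silhouette ------------------------------------------
        if config.do_bootstrap:
            boot = _stage("bootstrap")(bootstrap_silhouette)(
                test, score_test.values, test.cell_meta["affected"].values,
                test.cell_meta["cell_type"].values,
                n_cells=config.bootstrap_n_cells, reps=config.bootstrap_reps,
                n_pcs=config.n_pcs, seed=config.seed + 5,
            )
            boot.to_csv(os.path.join(config.out_dir, "bootstrap.csv"), index=False)
            report["stages"]["bootstrap"] = {
                "n_rows": int(len(boot)),
                "mean_silhouette_before": float(boot["silhouette_before"].mean()),
                "mean_silhouette_after": float(boot["silhouette_after"].mean()),
            }
    finally:
        with open(os.path.join(config.out_dir, "report.json"), "w") as f:
            json.dump(report, f, indent=2, default=str)
        with open(os.path.join(config.out_dir, "report.txt"), "w") as f:
            f.write(_render_report(report))
        log.removeHandler(fh)
        fh.close()
    return report


def _render_report(report: dict) -> str:
    lines = [f"timedrift run (seed={report.get('seed')})", ""]
    for stage, info in report.get("stages", {}).items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
    if "headline" in report:
        lines.append("[headline]")
        for k, v in report["headline"].items():
            lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"
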