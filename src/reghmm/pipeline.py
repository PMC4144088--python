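"""End-to-end orchestration: prep -> fit/select -> analyze -> predict.

Every stage writes plain-text artifacts under the configured output
directory, and a JSON manifest records parameters, seeds, stage completion
and output-file hashes so a run can be audited and reproduced.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, prediction, preprocess, state_analysis
from .io import (RunConfig, read_annotation_labels, read_bedgraph,
                 read_gene_table, read_mask_bed, read_matrix, write_matrix)
from .types import FeatureMatrix

logger = logging.getLogger(__name__)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash,
                "stages": {}, "outputs": {}}

    def done(stage: str, t0: float, **extra) -> None:
        manifest["stages"][stage] = {"complete": True,
                                     "seconds": round(time.time() - t0, 3), **extra}
        logger.info("stage %s complete (%.1fs)", stage, time.time() - t0)

    # ---- prep -------------------------------------------------------------
    t0 = time.time()
    if config.genes is None:
        raise ValueError("config.genes is required")
    genes = read_gene_table(config.genes)
    if config.features:
        fm = read_matrix(config.features)
        id_to_row = {g: i for i, g in enumerate(fm.gene_ids)}
        order = [id_to_row[g.accession] for g in genes if g.accession in id_to_row]
        genes = [g for g in genes if g.accession in id_to_row]
        fm = fm.subset(order)
    elif config.signal:
        mask = read_mask_bed(config.mask) if config.mask else None
        tracks = {mark: read_bedgraph(path) for mark, path in config.signal.items()}
        fm = preprocess.build_feature_matrix(tracks, genes, config.span,
                                             config.window, mask=mask)
    else:
        raise ValueError("either config.features or config.signal is required")

    genes, fm, report = preprocess.filter_genes(genes, fm)
    fm = preprocess.standardize_features(fm, seed=int(rng.integers(2**31 - 1)))
    X = fm.values
    y = np.array([g.expression for g in genes])
    d = core.distances_from_genes(genes)
    cond = preprocess.condition_number(X)
    write_matrix(fm, out / "features.tsv")
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    done("prep", t0, n_genes=len(genes), condition_number=cond)

    # ---- fit / select ------------------------------------------------------
    t0 = time.time()
    if config.n_states is not None:
        chosen_M = config.n_states
        scores = []
    else:
        chosen_M, score_list = core.select_num_states(
            X, y, d, config.M_range, D=config.D, n_restarts=config.restarts,
            seed=int(rng.integers(2**31 - 1)))
        scores = [s.to_dict() for s in score_list]
    fit = core.fit_em(X, y, d, chosen_M, D=config.D, n_restarts=config.restarts,
                      seed=int(rng.integers(2**31 - 1)))
    fit = core.relabel_by_r2(fit, X, y)
    mix = core.fit_mixture_no_markov(X, y, chosen_M, n_restarts=config.restarts,
                                     seed=int(rng.integers(2**31 - 1)))
    fit_json = {"fit": fit.to_dict(), "bic_table": scores, "chosen_M": chosen_M,
                "mixture_no_markov_bic": mix.bic, "config_hash": config.config_hash}
    (out / "fit.json").write_text(json.dumps(fit_json, indent=2))
    states_df = pd.DataFrame({
        "gene_id": [g.accession for g in genes],
        "viterbi_state": fit.viterbi_path,
        **{f"posterior_{m + 1}": fit.gamma[:, m] for m in range(chosen_M)},
    })
    states_df.to_csv(out / "states.tsv", sep="\t", index=False)
    done("fit", t0, chosen_M=chosen_M, bic=fit.bic, mixture_bic=mix.bic,
         n_iterations=fit.n_iterations)

    # ---- analyze -----------------------------------------------------------
    t0 = time.time()
    fits, combined_r2, all_r2 = state_analysis.per_state_ols(X, y, fit.viterbi_path)
    summary = {
        "per_state": [f.to_dict() for f in fits],
        "combined_r2": combined_r2,
        "all_r2": all_r2,
        "config_hash": config.config_hash,
    }
    signed = state_analysis.signed_r2_per_variable(X, y, fit.viterbi_path)
    signed.columns = fm.column_names
    signed.to_csv(out / "signed_r2.tsv", sep="\t")
    if chosen_M >= 2:
        means_tbl = state_analysis.compare_state_means(X, fit.viterbi_path,
                                                       alpha=config.alpha)
        means_tbl["variable"] = fm.column_names
        means_tbl.to_csv(out / "mean_comparison.tsv", sep="\t", index=False)
        if fits[0].n > X.shape[1] + 1 and fits[1].n > X.shape[1] + 1:
            coef_tbl = state_analysis.compare_state_coefficients(
                fits[0], fits[1], alpha=config.alpha)
            coef_tbl.to_csv(out / "coefficient_comparison.tsv", sep="\t", index=False)
        enrich = {}
        gene_ids = [g.accession for g in genes]
        for name, path in config.annotations.items():
            df = read_annotation_labels(path)
            if "value" in df.columns:
                id_to_val = dict(zip(df["gene_id"].astype(str), df["value"]))
                labels = np.array([id_to_val.get(g, 0) for g in gene_ids])
                tab = state_analysis.table_from_labels(fit.viterbi_path, labels)
                enrich[name] = state_analysis.enrichment_test(tab).to_dict()
                enrich[name]["covariate_effect"] = state_analysis.add_binary_covariate(
                    X, y, fit.viterbi_path, labels)
            elif "label" in df.columns:
                scan, meta = state_analysis.go_frequency_scan(df, gene_ids,
                                                              fit.viterbi_path)
                scan.to_csv(out / f"go_scan_{name}.tsv", sep="\t", index=False)
                enrich[name] = {"scan": f"go_scan_{name}.tsv", **meta}
        summary["enrichment"] = enrich
    (out / "state_summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    done("analyze", t0, combined_r2=combined_r2, all_r2=all_r2)

    # ---- predict -----------------------------------------------------------
    t0 = time.time()
    reports = prediction.kfold_evaluate(
        genes, X, y, k=config.kfold, M=chosen_M, D=config.D,
        n_restarts=max(2, config.restarts // 4),
        seed=int(rng.integers(2**31 - 1)))
    (out / "crossval.json").write_text(json.dumps(_jsonable(reports), indent=2))
    done("predict", t0)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _file_hash(f)
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
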