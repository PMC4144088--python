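#!/usr/bin/env python
"""Characterize the decoded states.

Per-state regressions (R^2, the combined fit and the single pooled
regression), signed per-variable R^2, Bonferroni-corrected mean and
coefficient comparisons between states, CpG-label enrichment with the
added-covariate analysis, and the resampling R^2 tests against known truth.
Writes tables under results/states/.
"""
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from reghmm import state_analysis as sa
from reghmm.io import read_gene_table, read_matrix
from reghmm.pipeline import _jsonable

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "states"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = read_gene_table(ROOT / "scratch" / "data" / "genes.bed")
    fm = read_matrix(ROOT / "scratch" / "prep" / "features.tsv")
    states_df = pd.read_csv(ROOT / "scratch" / "fit" / "states.tsv", sep="\t")
    path = states_df["viterbi_state"].to_numpy()
    keep = set(fm.gene_ids)
    genes = [g for g in genes if g.accession in keep]
    X = fm.values
    y = np.array([g.expression for g in genes])

    fits, combined, single = sa.per_state_ols(X, y, path)
    print("per-state regressions:")
    for f in fits:
        print(f"  state {f.state}: n={f.n}  R^2={f.r_squared:.4f}  "
              f"intercept={f.intercept:.3f}")
    print(f"  combined (y on per-state fitted values): R^2={combined:.4f}")
    print(f"  single pooled regression:               R^2={single:.4f}")

    signed = sa.signed_r2_per_variable(X, y, path)
    signed.columns = fm.column_names
    signed.to_csv(OUT / "signed_r2.tsv", sep="\t")
    top = signed.loc["state_1"].abs().idxmax()
    print(f"strongest single predictor in state 1: {top} "
          f"(signed R^2 = {signed.loc['state_1', top]:.3f})")

    means = sa.compare_state_means(X, path)
    means["variable"] = fm.column_names
    means.to_csv(OUT / "mean_comparison.tsv", sep="\t", index=False)
    print(f"predictor means differing after Bonferroni: "
          f"{int(means['significant'].sum())}/{len(means)}")

    coefs = sa.compare_state_coefficients(fits[0], fits[1])
    coefs.to_csv(OUT / "coefficient_comparison.tsv", sep="\t", index=False)
    print(f"coefficients differing after Bonferroni: "
          f"{int(coefs['significant'].sum())}/{len(coefs)} "
          f"(intercept difference {coefs.loc[0, 'difference']:+.3f})")

    ann = pd.read_csv(ROOT / "scratch" / "data" / "annotations.tsv", sep="\t")
    id_to_cpg = dict(zip(ann["gene_id"], ann["cpg"]))
    label = np.array([id_to_cpg[g.accession] for g in genes])
    tab = sa.table_from_labels(path, label)
    enr = sa.enrichment_test(tab)
    print(f"CpG-label enrichment: proportions "
          f"{enr.proportions[0]:.2f} vs {enr.proportions[1]:.2f}, "
          f"chi-square p = {enr.pvalue:.3g}")
    cov = sa.add_binary_covariate(X, y, path, label)

    # resampling tests: decoded state 1 vs state 2 R^2 difference, and the
    # CpG-positive genes' R^2 against random same-size gene sets
    idx1 = np.flatnonzero(path == 1)
    idx2 = np.flatnonzero(path == 2)
    diff = sa.r2_difference_simtest(idx1, idx2, X, y, n_reps=1000, seed=SEED)
    print(f"R^2 difference between states: {diff.observed:.4f}, "
          f"resampling p = {diff.pvalue:.3f}")
    sub = np.flatnonzero(label == 1)
    ext = sa.r2_extremity_simtest(sub, np.arange(len(y)), X, y, n_reps=1000,
                                  side="smaller", seed=SEED + 1)
    print(f"CpG-positive subset R^2 = {ext.observed:.4f}; null range "
          f"[{ext.null_min:.4f}, {ext.null_max:.4f}], smaller-side p = "
          f"{ext.pvalue:.3f}")

    (OUT / "summary.json").write_text(json.dumps(_jsonable({
        "per_state": [f.to_dict() for f in fits],
        "combined_r2": combined, "single_r2": single,
        "cpg_enrichment": enr.to_dict(), "cpg_covariate": cov,
        "r2_difference_test": diff.to_dict(),
        "cpg_extremity_test": ext.to_dict()}), indent=2))


if __name__ == "__main__":
    main()
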