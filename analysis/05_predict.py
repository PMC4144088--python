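#!/usr/bin/env python
"""Held-out prediction by five-fold cross-validation.

Each fold trains the two-state model, assigns test genes to states from
their predictor profiles (phi p_1(z) vs (1-phi) p_2(z)) and predicts
expression with the assigned state's regression; performance is the R^2 of
regressing true on predicted expression, against the single-pooled-model
baseline.  Writes results/predict/crossval.json.
"""
import json
import sys
from pathlib import Path

import numpy as np

from reghmm import core, prediction
from reghmm.io import read_gene_table, read_matrix
from reghmm.pipeline import _jsonable

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "predict"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = read_gene_table(ROOT / "scratch" / "data" / "genes.bed")
    fm = read_matrix(ROOT / "scratch" / "prep" / "features.tsv")
    keep = set(fm.gene_ids)
    genes = [g for g in genes if g.accession in keep]
    y = np.array([g.expression for g in genes])

    reports = prediction.kfold_evaluate(genes, fm.values, y, k=5, M=2,
                                        n_restarts=3, seed=SEED)
    print(f"five-fold cross-validation ({reports[0]['n_train']} train / "
          f"{reports[0]['n_test']} test genes per fold):")
    s1, s2, single = [], [], []
    for r in reports:
        r2s = r["test"]["r2_by_state"]
        print(f"  fold {r['fold']}: state-1 R^2 = {r2s.get(1)}, "
              f"state-2 R^2 = {r2s.get(2)}, single-model R^2 = "
              f"{r['r2_single_model']:.4f}")
        if r2s.get(1) is not None:
            s1.append(r2s[1])
        if r2s.get(2) is not None:
            s2.append(r2s[2])
        single.append(r["r2_single_model"])
    print(f"means: state-1 {np.mean(s1):.4f}, state-2 {np.mean(s2):.4f}, "
          f"single model {np.mean(single):.4f}")
    (OUT / "crossval.json").write_text(json.dumps(_jsonable(reports), indent=2))


if __name__ == "__main__":
    main()
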