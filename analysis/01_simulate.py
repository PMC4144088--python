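#!/usr/bin/env python
"""Generate the synthetic study dataset.

Emulates the structure the model targets: 17020 genes on one chromosome with
irregular spacing, a hidden two-state path whose persistence decays with
inter-gene distance (D = 4000 bp), seven histone-mark predictors in ten
200 bp windows around each TSS (70 columns), state-specific linear
expression responses (intercepts 0.25 / 1.15, within-state R^2 0.7 / 0.4)
and a CpG-island-like label biased by state (rates 0.59 / 0.70).

Writes the fixture (genes.bed, predictors.tsv, true_states.tsv,
annotations.tsv, spec.yaml) plus a one-mark bedGraph signal track under
scratch/data/ (bulky generated inputs are kept out of results/).
"""
import sys
from pathlib import Path

import numpy as np

from reghmm import synthetic

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

MARKS = ("H3K4me1", "H3K4me2", "H3K4me3", "H3K9me3", "H3K20me3",
         "H3K27me3", "H3K36me3")


def main() -> None:
    spec = synthetic.make_two_state_spec(n_genes=17020, p=70, marks=MARKS, seed=SEED)
    ds = synthetic.generate_dataset(spec)
    paths = synthetic.write_fixture(ds, OUT)

    # a raw signal track for the windowing demonstration in 02, on a
    # well-spaced demo gene set so every window has its own signal level
    demo = synthetic.gen_positions(300, distance_law=("fixed", 5000), seed=SEED)
    from reghmm.io import write_gene_table

    for g in demo:
        g.expression = 0.0
    write_gene_table(demo, OUT / "demo_genes.bed")
    track, oracle = synthetic.gen_signal_track(demo, seed=SEED + 1)
    track.to_csv(OUT / "H3K4me3.bedgraph", sep="\t", header=False, index=False)
    np.savetxt(OUT / "H3K4me3_window_oracle.tsv", oracle, delimiter="\t")

    d = ds.distances[1:]
    print(f"wrote {len(paths) + 2} files to {OUT}")
    print(f"genes: {len(ds.genes)} on {spec.chrom}; predictors: "
          f"{ds.predictors.n_features} columns ({len(MARKS)} marks x 10 windows)")
    print(f"inter-gene distances: median {np.median(d):.0f} bp, "
          f"range {d.min():.0f}-{d.max():.0f} bp")
    print(f"hidden states: {np.mean(ds.true_states == 1):.1%} in state 1; "
          f"CpG label rate {ds.annotations['cpg'].mean():.2f}")


if __name__ == "__main__":
    main()
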