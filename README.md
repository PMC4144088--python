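# reghmm — regression hidden Markov model for heterogeneous gene regulation

Histone-modification levels around a gene's transcription start site (TSS)
predict its expression, but not every gene obeys the same relationship:
constitutively expressed genes, for instance, can be highly expressed while
their promoter chromatin explains little of their expression variance.
`reghmm` is for statistical genomicists who want to *segment* genes into
latent regulatory states defined by that relationship, rather than fit one
genome-wide regression.

## The model

Genes are ordered along each chromosome. The observation at gene *t* is
O_t = (x_t, y_t): p standardized histone-mark window averages (by default
7 marks × ten 200 bp windows on TSS ± 1 kb, p = 70) and the expression
level. Given a hidden state q_t = i,

    y_t | x_t, q_t = i  ~  N(β_i0 + x_tᵀ β_i, σ_i²),

a mixture of linear regressions whose labels follow a Markov chain. Because
neighbouring genes share regulatory context only when they are close, the
transition matrix between genes d bp apart decays toward a baseline
stochastic matrix P:

    A(d) = e^(−d/D) I + (1 − e^(−d/D)) P,      D = 4000 bp by default.

Fitting is Baum–Welch EM (scaled forward–backward, weighted-least-squares
M-step, multiple restarts), decoding is Viterbi, and the number of states
maximizes BIC = L − 0.5·N_M·ln T. An order-free mixture of regressions is
available as the no-Markov baseline, and a held-out prediction mode assigns
test genes to states from their chromatin profiles alone
(φ·p₁(z) vs (1−φ)·p₂(z)) before predicting expression. Downstream
characterization covers per-state R², signed per-variable R², Bonferroni-
corrected mean/coefficient comparisons, Yates-corrected chi-square
enrichment of binary gene labels, added-covariate analysis, and two
resampling tests on R². See `docs/methods.md` for the full account.

## Worked example

The analysis is organised as numbered drivers over the library; each reads
the previous step's outputs (bulky intermediates under `scratch/`, tables
under `results/`):

```bash
python analysis/01_simulate.py            # synthetic study dataset, T=17020
python analysis/02_preprocess.py          # windowing, standardization, filters
python analysis/03_fit_select.py          # BIC selection + fit + no-Markov
python analysis/04_characterize_states.py # state characterization
python analysis/05_predict.py             # five-fold held-out prediction
```

`01` draws 17020 genes on one chromosome with log-uniform inter-gene gaps
(10²–10⁶ bp), a hidden two-state path from the distance kernel, 70
predictor columns, expression with state intercepts 0.25 / 1.15 and
within-state R² ≈ 0.7 / 0.4, and a CpG-island-like label at rates
0.59 / 0.70. `03` then prints (seed 0):

```
BIC by number of states:
  M=1: loglik  -26598.15  BIC  -26948.87
  M=2: loglik  -25387.76  BIC  -26103.81 <- max
  M=3: loglik  -25097.17  BIC  -26188.29
regHMM BIC -26103.81 vs no-Markov mixture BIC -26290.46 (advantage +186.65)
```

BIC recovers the generating two-state structure, and the distance-dependent
Markov chain is worth ~187 BIC points over the order-free mixture — the
spatial persistence of regulatory state is real signal, not bookkeeping.
`04` characterizes the decoded states:

```
per-state regressions:
  state 1: n=9148  R^2=0.8487  intercept=0.198
  state 2: n=7872  R^2=0.4871  intercept=0.715
  combined (y on per-state fitted values): R^2=0.6717
  single pooled regression:               R^2=0.5037
CpG-label enrichment: proportions 0.62 vs 0.68, chi-square p = 2.33e-20
R^2 difference between states: 0.3616, resampling p = 0.000
```

— a strong-association state and a weak one with the larger intercept, the
two-relationship description explaining more variance than any single
regression (0.67 vs 0.50), and the state-biased CpG label recovered by the
enrichment test. (Decoded-state R² values are selection-inflated relative
to the generating 0.7/0.4: Viterbi assigns each gene to the state that
explains it best.) `05` closes with held-out prediction:

```
means: state-1 0.5415, state-2 0.3467, single model 0.4987
```

predicting strong-state genes better than one pooled regression, while
weak-state genes stay hard to predict from chromatin — the point of the
segmentation.

A `reghmm` console script exposes the same stages
(`simulate`, `prep`, `fit`, `select`, `analyze`, `predict`, `crossval`,
`run`) for shell use; `reghmm run --config run.yaml` executes the whole
pipeline with a manifest.

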