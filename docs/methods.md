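# Methods

## The model

`reghmm` segments genes, ordered along each chromosome, into latent
regulatory states defined by *how* promoter-proximal chromatin predicts
expression, not by the chromatin level itself. The observation at gene
t is O_t = (x_t, y_t): a vector of p standardized histone-modification
window averages and a scalar expression level. Conditional on the hidden
state q_t = i the emission density is a state-specific linear regression,

    b_i(O_t) = N(y_t ; β_{i0} + x_tᵀβ_i, σ_i²),

and the marginal density of x_t is left unmodelled (p(x|q) = 1), so states
are identified purely by the regression relationship — coefficients,
intercept and residual variance. The model is therefore a mixture of linear
regressions whose mixture labels follow a Markov chain.

Genes are unequally spaced, and the spatial coupling of regulation should
fade with distance. The transition matrix applied between adjacent genes
d bp apart interpolates between perfect persistence and a baseline
stochastic matrix P = (p_ij):

    A(d) = e^(−d/D) I + (1 − e^(−d/D)) P.

At d = 0 the state carries over with probability 1; as d → ∞ the chain
mixes according to P; larger D extends the range of persistence. D is a
predetermined constant (default 4000 bp, matching the idea that genes
within a few kb share regulatory context); P, the regression parameters,
the residual variances and the initial distribution π are estimated.
Each chromosome is an independent chain restarted from π.

### Estimation

Fitting is by Baum–Welch EM:

* **E-step** — scaled forward–backward recursions over the non-homogeneous
  chain give the exact marginal log-likelihood, per-gene posteriors
  γ_t(i), and expected transition counts ξ_t(i,j).
* **M-step** — β_i is the γ(·,i)-weighted least-squares fit of y on [1, X];
  σ_i² the γ-weighted mean squared residual (floored at 1e−6 to prevent
  degenerate collapse, which is logged); π the normalized posterior at
  chain starts. The baseline matrix P appears inside the mixture
  A(d) = eI + (1−e)P, so its expected complete-data log-likelihood has no
  closed-form maximizer; we treat the branch indicator (carry-over vs P)
  as an additional latent variable. Conditional on an observed (i→j)
  transition the P-branch probability is 1 for i ≠ j and
  (1−e)p_ii / (e + (1−e)p_ii) for i = j; P is re-estimated from the
  reweighted expected counts. This nested-EM update is a generalized EM
  step, so the likelihood is still monotone (asserted to 1e−8 in tests).

Default convergence: relative log-likelihood change below 1e−6 or 500
iterations; 20 independent restarts by default (random state assignment
followed by per-state OLS; an expression-quantile split initializer is also
available), keeping the restart with the best final log-likelihood.
Decoding is by Viterbi in log space, ties broken toward the lower state
index. For reporting, states are relabelled by descending within-state R²
so "State 1" is always the stronger-association state.

### Model selection

The number of states maximizes BIC in the form L − 0.5·N_M·ln T (larger is
better), with the free-parameter count

    N_M = M(p+1) + M + M(M−1) + (M−1)

(coefficients, variances, baseline transitions, initial probabilities).
L is the marginal log-likelihood by default; a flag substitutes the
Viterbi-path joint likelihood for users who read L_M(O,q) literally.
The no-Markov baseline — an independent mixture of regressions with
mixing weights in place of the transition structure — is fitted by the
same EM machinery and its BIC (N = M(p+1) + M + (M−1)) is directly
comparable; when all rows of P are equal and distances are large the two
models coincide, which the tests exploit as an equivalence check.

## Preprocessing

Signal tracks (bedGraph) are averaged over non-overlapping 200 bp windows
covering TSS ± 1 kb (10 windows per mark; 7 marks give the canonical
70-column design). Coordinates are 0-based half-open: the span is
[tss−1000, tss+1000), windows [tss−1000+200k, tss−800+200k). Window
offsets are oriented in the direction of transcription — offset −1000 is
always the most upstream window — so a minus-strand row is the reverse of
the plus-strand row under the same signal; this makes per-offset effects
comparable across strands. Windows overlapping a masked interval, or
running past a chromosome end, are flagged rather than silently truncated.

Each column is standardized by mapping ranks to standard-normal quantiles,
rank r of n → Φ⁻¹((r − 0.5)/n); the −0.5 offset avoids infinite endpoint
quantiles. Ties are broken beforehand, once, by adding N(0, 0.01)
disturbances (sd 0.1) under a recorded seed. The transform is monotone and
idempotent to rank precision.

Gene filtering applies an ordered rule list — unmatched annotation, strand
mismatch, any masked window, zero expression, duplicate TSS — and reports
telescoping counts. The duplicate-TSS rule keeps the record with the
highest expression (the choice is not dictated by anything upstream; any
deterministic choice works, and this one is stated so results are
reproducible). Multicollinearity is diagnosed by the condition number
√(λ_max/λ_min) of XᵀX with the conventional cutoff 30.

## Downstream state characterization

* Per-state OLS with R²; the "combined" R² regresses y on the
  concatenation of per-state fitted values, the "all" R² is a single
  pooled regression — the gap between them is the value of the two-
  relationship description.
* Signed per-variable R²: squared Pearson correlation times the sign of
  the slope, per predictor and state.
* Mean comparisons between states use Welch t-tests, coefficient
  comparisons z-tests on β̂₁ⱼ − β̂₂ⱼ with SE = √(se₁ⱼ² + se₂ⱼ²); both are
  Bonferroni-corrected (denominators: number of predictors, respectively
  number of coefficients including the intercept).
* 2×2 enrichment of binary gene labels uses the chi-square test **with
  Yates continuity correction** by default. The dialect matters: on the
  published housekeeping table (192/10211 vs 239/6809) the corrected test
  gives p = 4.693·10⁻¹¹ and on the TATA table (1200/10211 vs 629/6809)
  p = 2.42·10⁻⁷, exactly the printed values, whereas the uncorrected
  statistic gives ≈3.4·10⁻¹¹ / ≈2.1·10⁻⁷. Uncorrected and Fisher-exact
  variants are available by flag. Annotation-frequency scans test each
  label carried by more than 10 genes per state (two-proportion
  chi-square, Bonferroni over tested labels) and report unannotated genes.
* Adding a binary covariate (e.g. CpG-island overlap) refits each state
  with the extra column and reports ΔR², the new intercept, the label
  coefficient with a nested-model F-test, and a z-test comparing the
  label's effect across states.
* Two resampling tests on R²: (i) the difference test splits the pooled
  gene set repeatedly into the observed group sizes and counts splits with
  an absolute R² difference at least the observed one (non-strict, no
  +1 smoothing; p has resolution 1/replicates, default 1000); (ii) the
  extremity test draws random same-size gene sets from a universe and
  counts null R² on the requested side of the observed value, reporting
  the null minimum/maximum alongside.

## Held-out prediction

States of test genes (whose expression is unknown) cannot be decoded, so
each training state m is summarized by the sample mean and covariance of
its predictors and the decoded proportion φ; a test gene with predictors z
is assigned to State 1 iff φ·p₁(z) > (1−φ)·p₂(z) (ties and the general-M
case resolve to the higher state index) and its expression predicted by
the assigned state's regression. Covariances are ridged by
1e−6·trace(V)/p when ill-conditioned. Evaluation is the R² of regressing
true on predicted expression (with intercept), per state and overall,
under k-fold cross-validation (default 5) with gene-wise random folds;
removing a fold breaks adjacency, so training chains use distances between
retained neighbours.

## The synthetic-data generator

The generator emulates the joint structure the analysis assumes: gene
positions with irregular gaps (log-uniform over 10²–10⁶ bp by default,
spanning the orders of magnitude seen between real genes on one
chromosome), a hidden state path drawn from the distance-dependent kernel,
state-conditional multivariate-normal predictors (AR(1) correlation within
a mark, independent marks), expression from the state's regression, and
state-biased Bernoulli labels. The canonical two-state configuration uses
intercepts 0.25 / 1.15, within-state R² 0.7 / 0.4, a 0.5 baseline stay
probability, D = 4000 bp, and a CpG-like label at rates 0.59 / 0.70 —
the headline constants of the study design. Default test size is M = 2
states with one mark × 10 windows; the full 7-mark, 70-column layout is
available by configuration.

What it does **not** emulate: read-level noise, RPKM computation,
peak shapes, long-range enhancer effects, non-normal predictor marginals
(the generator produces data already on the standardized scale the model
consumes), or inter-chromosomal structure. Passing tests therefore
demonstrate correctness of the estimator and pipeline under the model's
own assumptions, not robustness to the full messiness of real ChIP-seq.

### The recovery configuration

Parameter-recovery, model-selection and Markov-advantage experiments use a
deliberately *well-separated* variant (`make_recovery_spec`): opposed slope
directions, state-2 signal variance 2 (the R² targets pin only the ratio of
residual to signal variance, not the scale), and dense geometry (log-uniform
gaps over 10²–10⁴ bp, mostly below D, so persistence is strong). Under this
configuration the Viterbi decoding ceiling *at the true parameters* is
about 93%, computed from the model before any fitting; an estimator-
correctness experiment needs that ceiling comfortably above its assertion
threshold, otherwise it measures the difficulty of the decoding problem
rather than the quality of the estimator. Under the study-realistic
defaults (correlated slope profiles, sparse geometry) the ceiling is ≈78%,
a property of the configuration, not of the fit.

## Numerical choices

* Forward–backward uses per-step scaling; Viterbi runs in log space.
* σ² floor 1e−6; near-empty states in the weighted regression get a tiny
  ridge (1e−8·total weight) and are logged.
* EM stops on relative log-likelihood change < 1e−6 or 500 iterations
  (validation experiments cap overfitted candidates at 120–150 iterations:
  on a nearly flat likelihood the trimmed tail moves BIC by far less than
  the parameter penalty separating candidate state counts).
* Quantile standardization jitters only when ties are present.
* All randomness flows from a single seed through named substreams; every
  randomized routine is bit-reproducible given its seed.

## Problem sizes in the validation battery

Oracle equivalence: 200 random instances with T ≤ 8, M ≤ 3 against full
path enumeration. EM monotonicity: 50 random fits at T = 300. Recovery:
10 replicates at T = 2000, p = 10, 5 restarts. BIC selection: 10
replicates each of two-state and one-state data, candidates M ∈ {1,2,3}.
Markov advantage: 10 replicates. Resampling calibration: 200 meta-
replicates of 1000-replicate tests on 140 homogeneous genes. The
analysis-narrative scripts run the full 7-mark, 70-column design at the
study's gene count (T = 17020); at a few thousand genes the second state's
75-parameter BIC penalty is not yet repaid by the likelihood gain, so the
study-scale T is what makes the two-state structure detectable — itself a
useful illustration of BIC's conservatism.

## Known limitations

* D is fixed, not estimated; the exponential-mixture kernel is one of
  several forms with the right limits, and conclusions about the range of
  persistence inherit its shape.
* BIC with p = 70 predictors is conservative at small T (see above).
* The emission model ignores p(x|q); if predictor profiles alone carry
  state information (they do, by construction, in the prediction step),
  the HMM does not use it during fitting.
* The resampling R² tests condition on the decoded states; decoding error
  propagates into them unquantified.
* Label-switching is resolved by the within-state-R² convention, which can
  be unstable when states have nearly equal R².
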