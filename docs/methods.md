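# Methods

## Problem and model

`mindrisk` classifies tabular student-cohort records into three mental-health
risk levels (Low / Medium / High) with a hybrid architecture designed to be
intrinsically interpretable. A record is ten features: four emotional scales
(anxiety 0–21, depression 0–27, stress 0–10, social support 0–10), three
behavioral measures (productivity 0–10, sleep hours, physical-activity
days/week) and three demographics (age, gender, employment status).

The forward pass, for one normalized record x ∈ R^10:

1. **Feature tokenization.** Each scalar feature value is mapped to a
   d-dimensional token, token_i = x_i·w_i + b_i with learned per-feature
   vectors (d = 32 by default). This is the standard trick for making
   self-attention well defined over tabular features.
2. **Feature self-attention.** Multi-head scaled dot-product self-attention
   over the 10 tokens (softmax((QKᵀ)/√d_h)V per head), with residual
   connections and a ReLU feed-forward sublayer, stacked `n_layers` times.
   The output A_T captures feature–feature interactions (e.g. anxiety and
   depression reinforcing each other). No layer normalization: at this
   width and with z-scored inputs training is stable without it, and
   omitting it keeps the gradient path elementary.
3. **Positional-psychological encoding.** Features are ordered Emotional →
   Behavioral → Demographic ("order3"; two alternative orderings are
   provided) and a per-position scalar addend sin(i / 10^{2i/d}) (0-based i)
   is added to every component of token i. Note the base is 10, not the
   canonical 10000, and there is no cosine pair; the conventional
   sine/cosine encoding is available via `canonical_pe=True` for
   comparison.
4. **LSTM over the ordered tokens.** A standard LSTM (zero initial state)
   reads the 10 position-encoded tokens as a sequence; its final hidden
   state h_T summarizes the "emotional → behavioral" progression.
5. **Cross-attention attribution (CAAL).** Per head: each attended token is
   scored against the LSTM summary, score_i = (A_T W_F)_i · (h_T W_L), and
   the scores are softmaxed over the 10 features, giving a simplex
   attribution vector A_C. The context aggregates the **raw** tokens,
   c = Σ_i A_C[i]·(tokens W_F)_i. Scoring uses the attended tokens (the
   transformer branch steers the attribution) while aggregation uses the
   raw tokens, because post-attention tokens are mixtures of all features:
   aggregating them lets the network place attention mass on arbitrary
   positions without affecting the loss, which makes A_C meaningless as an
   attribution map. With the raw-token value path, position i's
   contribution to the context is a function of feature i's value only, so
   attention mass must sit on features that matter. Head contexts are
   concatenated; fusion with h_T is concatenation (default) or addition
   through a projection.
6. **Risk head.** A softmax over three classes on the fused vector.

**Loss.** Categorical cross-entropy (nats) plus an attribution-sharpness
regularizer: λ_XAI times the mean Shannon entropy (bits) of the A_C heads,
λ_XAI = 0.1 by default (0 disables it; large values verifiably sharpen
attribution at some cost in accuracy). Probabilities are clamped at 1e-12
inside the log.

**Training.** Mini-batch gradient descent on all parameters; plain SGD is
the default update rule and Adam is available (`optimizer="adam"`) and is
what the worked examples use. Initialization is seeded Glorot-uniform.
15% of the training rows are held out (stratified) for checkpoint
selection: the returned parameters are those of the best
validation-accuracy epoch, with early stopping after 10 epochs without
improvement (max 60 epochs). The CAAL projections W_F, W_L start at 0.25×
Glorot scale (residual-branch-style small init, in the spirit of
ReZero/Fixup): with full-scale init the context path's early gradients
interfere with the recurrent branch, costing both accuracy and
attribution faithfulness; with small init the LSTM path fits first and
the attribution layer refines on top. Everything runs in float64 on a
hand-written
reverse-mode autodiff core (`mindrisk.autodiff`) — a compact tensor-graph
engine whose gradients are validated against central finite differences at
relative 1e-3 in the test suite.

**Ablation ladder.** `variant=` selects: `lstm` (E1, bare sequence model),
`lstm_attn` (E2, + additive temporal attention pooling), `transformer`
(E3, attention branch + mean pool), `early_fusion` (E4, concat pooled
branches), `dual_attn` (E5, separate additive attention per branch),
`caal` (E6, full model). All variants share the tokenizer, training loop
and evaluation harness.

## Preprocessing and labeling

- Missing continuous values → median imputation; categoricals → fixed
  alphabetical integer codes (persisted with the model).
- Z-scaling per continuous feature with mean/SD fitted on the training
  split only (population SD); encoded categoricals are not scaled.
- Risk labels: composite = mean of z-scored anxiety and depression;
  Low/Medium/High by the composite's empirical 1/3 and 2/3 quantiles
  (strict inequalities; ties at a cut go to the lower class). Exact
  tertiles are used — the conventional "33rd/67th percentile" phrasing is
  treated as tertile language, since only exact tertiles give balanced
  classes (within one record of n/3 for distinct composites).
- Stratified 80/20 split, deterministic given the seed. Labels are
  assigned on the full cohort (the tertiles are a property of the dataset)
  before splitting; imputation for labeling also runs on the full cohort.

## Entropy screening

Continuous features are discretized into k = 10 quantile bins (quantile
rather than equal-width so skew does not starve bins); already-discrete
features keep their categories. Per feature we report the marginal Shannon
entropy H(f) = −Σ p(v) log₂ p(v) and the conditional label entropy
H(Y|X) = Σ_v p(v) H(Y|X=v), both in bits (base configurable). Features
with H(f) below 0.9·log₂(k) are marked "stable", otherwise "uncertain";
the marks are reported metadata and drop nothing — the classifier's
tokenizer and attribution contracts are defined over the fixed ten-feature
schema, so feature exclusion is deliberately out of scope. Entropies are
computed on the training split.

## Explanations

- **Model-side:** A_C averaged over heads and samples, renormalized,
  gives a global importance profile; per-instance maps are exposed.
- **Local surrogate (LIME-family):** 500 Gaussian perturbations around the
  instance (SD = the feature's training SD; categoricals resampled
  uniformly from their codes), the model queried for the probability of
  its predicted class, and a linear surrogate fitted by weighted least
  squares with exponential-kernel proximity weights of width 0.75·√m on
  scale-standardized distance. Reported per instance: surrogate weights
  (in original feature units, so thresholds stay legible), local fidelity
  R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² (defined 0 for constant outputs), signed
  contribution totals C± = Σ_{±w_i>0} w_i x_i, and the ranked |w_i x_i|
  profile. Top-k (k = 5) sets across instances yield a mean pairwise
  Jaccard stability score. Singular surrogate designs fall back to a
  1e-6 ridge.

## Evaluation and statistics

Accuracy and per-class precision/recall/F1 come from the confusion matrix
with macro averaging (classes are balanced by construction). Reliability
curves use 10 equal-width probability bins, one-vs-rest per class.
Predictive entropy (bits) and confidence get centered rolling means
(window 50).

The validation battery implements five tests from their textbook formulas
(p-values from scipy distributions): one-way ANOVA (between/within sum of
squares), Pearson χ², Wilcoxon signed-rank W = Σ sgn(d_i)R_i (exact
enumeration by dynamic programming for n ≤ 25 without ties, otherwise
normal approximation with tie correction), Friedman
χ²_F = 12/(Nk(k+1))·ΣR_j² − 3N(k+1), and Diebold–Mariano
DM = d̄/√(LRV/T) with the long-run variance from autocovariances truncated
at lag horizon−1 (a truncated estimate can be non-positive; that case is
flagged degenerate rather than reported). Per-sample loss for DM is
cross-entropy. The per-feature battery runs ANOVA (continuous) or χ²
(categorical) against predicted classes, a leave-one-feature-out DM
(feature frozen at its training mean at prediction time, masked-model loss
vs full-model loss), plus cohort-level Wilcoxon (predicted vs true codes)
and a Friedman test of conditional-entropy feature ranks across CV folds.
No multiple-testing correction is applied by default.

## Synthetic cohorts

One latent distress factor z ~ N(0,1) per record drives the continuous
features: anxiety = clip(10 + 5sz + ε, 0, 21), depression =
clip(13 + 7sz + ε, 0, 27), productivity = clip(6 − 2sz + ε, 0, 10),
stress = clip(5 + 2sz + ε, 0, 10), social support = clip(6 − sz + ε, 0, 10),
sleep = clip(7 − 0.5sz + ε, 3, 12), with s = signal_strength (default 0.8)
and ε ~ N(0, noise_sd). Physical activity, age, gender and employment are
independent of z. Scales put clinically styled thresholds (anxiety > 11,
depression > 23) in the upper tails. Labels come from the tertile rule
above; clipping (not resampling) keeps the draw a deterministic transform
of the seeded randomness. Missingness is MCAR on the continuous features.
`ground_truth` returns the planted informative set and loading order, used
as the oracle for attribution and entropy-ranking tests.

**Interaction plant.** With `interaction_mode="anxiety_x_productivity"`
the label composite gains 1.5 · z_anx · (−z_prod) — the anxiety ×
productivity interaction proper, whose positive direction is jointly high
anxiety with low productivity. A rectified product was rejected: it is
co-monotone with the additive composite (relabeling under 5% of rows), so
a linear model fits it almost perfectly and the plant cannot probe model
capacity. Interaction experiments run at signal_strength 0.3
(`INTERACTION_SIGNAL`): at the default 0.8 the shared latent factor makes
anxiety and productivity nearly collinear (r ≈ −0.83) and the product
degenerates into a monotone function of the main effect. At 0.3 a
multinomial logistic baseline reaches ≈ 64% while the full model exceeds
95%, a clean capacity separation.

**What the generator does not emulate.** Real survey data has discrete
Likert scales, informative missingness, measurement error correlated
across instruments, and no single latent factor; class labels there are
not a deterministic function of the features. Passing tests demonstrate
that the pipeline recovers structure it was designed to recover under the
declared conditions — not clinical validity on real cohorts.

## Problem sizes and numerical choices

Desk-scale defaults keep every experiment on one CPU: token width 32,
2 attention layers of 4 heads, feed-forward width 64, 64 LSTM units,
2 CAAL heads of width 32, batch 64, ≤ 60 epochs on cohorts of n = 2000
(80/20 split). Several widths sit below the published search grid
({256, 512} feed-forward etc.); `ModelConfig.off_grid()` lists them.
Softmax is computed with max-shift stabilization; probabilities are
clamped at 1e-12 inside logs; attention-weight and attribution simplex
contracts are asserted at 1e-6. Ties in quantile binning collapse
duplicate edges; a constant feature yields a single bin with a warning.

## Known limitations

- Attribution from attention is identifiable here only because the
  context uses the raw-token value path; with redundant features (anxiety
  and depression correlate ~0.95 at default signal) the top-2 recovery is
  still occasionally displaced by another signal-bearing feature.
- The Wilcoxon exact path requires tie-free ranks; heavy ties push it to
  the normal approximation regardless of n.
- The positional addend as specified (base 10, sine only) is nearly zero
  for i ≥ 4 at d = 32, so ordering information mostly distinguishes the
  first few positions; the canonical encoding is available when position
  information matters more.
- Training is full-batch-deterministic given a seed but not reproducible
  across BLAS implementations at the bit level.
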