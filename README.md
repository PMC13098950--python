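# mindrisk

Interpretable three-level mental-health risk classification for student
cohorts, built around a hybrid tabular architecture: per-feature
tokenization with multi-head self-attention over the features, an LSTM
reading the features as a psychologically ordered sequence (Emotional →
Behavioral → Demographic), and a **cross-attention attribution layer
(CAAL)** that fuses the two branches while emitting, for every
prediction, a softmax-normalized per-feature attribution map. Around the
classifier the package provides entropy-based feature screening,
LIME-style local surrogate explanations with fidelity/stability metrics,
calibration and predictive-entropy diagnostics, a five-test statistical
validation battery, and a synthetic cohort generator with planted signal
so everything is testable end to end without any external dataset.

Intended users: researchers in computational mental-health screening and
interpretable tabular deep learning who want a transparent, CPU-only,
fully seeded reference implementation.

## The model

For a normalized record x ∈ R^10, with learned per-feature vectors w_i, b_i:

    tokens_i = x_i · w_i + b_i                                (tokenization)
    A_T      = SelfAttention(tokens)                          (feature interactions)
    x_PE(i)  = tokens_i + sin(i / 10^(2i/d))                  (psychological ordering)
    h_T      = LSTM(x_PE)                                     (sequential dynamics)
    A_C      = softmax_i((A_T W_F)_i · (h_T W_L))             (attribution map)
    c        = Σ_i A_C[i] · (tokens W_F)_i                    (attributed context)
    ŷ        = softmax([c ; h_T] W_O + b_O)                   (risk probabilities)

Training minimizes cross-entropy plus λ_XAI times the Shannon entropy of
A_C (an attribution-sharpness regularizer). The ablation ladder
E1 (bare LSTM) … E6 (full model) is available through a single
`variant=` switch. Everything runs in float64 on a small built-in
reverse-mode autodiff engine; gradients are finite-difference-checked in
the test suite. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from mindrisk import (GeneratorSpec, generate, prepare, SplitSpec,
                      RiskNetworkClassifier, uncertainty_scores,
                      caal_attribution)

cohort = generate(GeneratorSpec(n=2000, seed=1))        # planted cohort
train, test = prepare(cohort, SplitSpec(0.2, seed=1))   # label, split, z-scale

print(uncertainty_scores(train).nsmallest(3).round(3))
# depression      0.279
# anxiety         0.324
# stress_level    0.947      <- lower H(Y|X) = more predictive

model = RiskNetworkClassifier(optimizer="adam", learning_rate=2e-3,
                              max_epochs=30, random_state=1)
model.fit(train.feature_matrix(), train.label_codes())
acc = (model.predict(test.feature_matrix()) == test.label_codes()).mean()
print(round(acc, 3))
# 0.992

gi = caal_attribution(model, test.feature_matrix(), test.feature_order)
print(gi.scores.sort_values(ascending=False).head(3).round(3))
# depression      0.513
# anxiety         0.196
# stress_level    0.092
```

The entropy screen and the model's own attribution map both single out
the two features that drive the planted labels (anxiety and depression);
the accuracy is high because the synthetic labels are a deterministic
function of the features.

Command-line equivalents:

```bash
mindrisk simulate --n 2000 --seed 1 --out cohort.csv
mindrisk train --data cohort.csv --variant E6 --seed 1 --out model.npz
mindrisk evaluate --model model.npz --data cohort.csv --seed 1
mindrisk explain --model model.npz --data cohort.csv --row 17 --seed 1
```

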