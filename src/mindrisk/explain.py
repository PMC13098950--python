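"""Instance-level and global model explanations.

Two complementary routes: the model's own cross-attention attribution maps
(averaged into a global importance profile), and a model-agnostic local
surrogate in the LIME family — perturb around an instance, query the model,
fit a proximity-weighted linear surrogate, and summarize it with local
fidelity R^2, signed contribution totals C+/C- and a top-k feature-set
stability score.  Surrogates are fitted and reported in original
(un-normalized) feature units so thresholds stay legible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExplanationBundle:
    """Local surrogate explanation for one instance."""

    instance_id: int
    feature_names: list[str]
    surrogate_weights: np.ndarray
    surrogate_intercept: float
    local_fidelity: float
    c_plus: float
    c_minus: float
    #: (feature, signed contribution w_i * x_i) sorted by |contribution| desc
    top_features: list[tuple[str, float]] = field(default_factory=list)

    def top_set(self, k: int = 5) -> frozenset:
        return frozenset(name for name, _ in self.top_features[:k])

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "weights": dict(zip(self.feature_names, self.surrogate_weights.tolist())),
            "intercept": self.surrogate_intercept,
            "local_fidelity_r2": self.local_fidelity,
            "c_plus": self.c_plus,
            "c_minus": self.c_minus,
            "top_features": self.top_features,
        }


@dataclass
class GlobalImportance:
    """Nonnegative per-feature scores summing to 1."""

    scores: pd.Series
    method: str  # "caal" | "lime-aggregate"

    def ranking(self) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# model-side attribution


def caal_attribution(model, X, feature_names=None) -> GlobalImportance:
    """Global importance from the attribution maps: mean A_C over heads and
    samples, renormalized to sum to 1."""
    ac = model.attribution(X)  # (n, heads, m)
    mean = ac.mean(axis=(0, 1))
    mean = mean / mean.sum()
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(len(mean))]
    return GlobalImportance(
        scores=pd.Series(mean, index=list(feature_names)), method="caal"
    )


# ---------------------------------------------------------------------------
# LIME-style local surrogate


def local_fidelity(y_model, y_surrogate) -> float:
    """R^2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2; defined 0 when the
    model outputs have no variance."""
    y = np.asarray(y_model, dtype=float)
    yhat = np.asarray(y_surrogate, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # constant model outputs accumulate O(eps) variance in floating point
    if ss_tot <= y.size * (1e-12 * max(1.0, float(np.abs(y).max()))) ** 2:
        logger.info("constant model outputs; local fidelity defined as 0")
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def contribution_scores(weights, values) -> tuple[float, float]:
    """C+ = sum_{w_i>0} w_i x_i and C- = sum_{w_i<0} w_i x_i."""
    w = np.asarray(weights, dtype=float)
    x = np.asarray(values, dtype=float)
    contrib = w * x
    return float(contrib[w > 0].sum()), float(contrib[w < 0].sum())


def stability_score(feature_sets) -> float:
    """Mean pairwise Jaccard index over all unordered pairs of top-k sets."""
    sets = [frozenset(s) for s in feature_sets]
    if len(sets) < 2:
        raise ValueError("need at least two feature sets")
    total, n_pairs = 0.0, 0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            union = sets[i] | sets[j]
            if not union:
                logger.info("empty set pair; Jaccard defined as 0")
                jac = 0.0
            else:
                jac = len(sets[i] & sets[j]) / len(union)
            total += jac
            n_pairs += 1
    return total / n_pairs


def lime_explain(
    predict_fn,
    instance,
    feature_names,
    scales,
    categorical_values: dict[int, np.ndarray] | None = None,
    n_perturb: int = 500,
    kernel_width: float | None = None,
    seed: int = 0,
    instance_id: int = 0,
) -> ExplanationBundle:
    """Fit a proximity-weighted linear surrogate around one instance.

    ``predict_fn`` maps an (n, m) array in original feature units to the
    model's probability for the class it predicts at ``instance``.
    Continuous features are perturbed with Gaussian noise of SD ``scales``;
    features listed in ``categorical_values`` are resampled uniformly from
    their observed codes.  Proximity weights use an exponential kernel on
    scale-standardized Euclidean distance with width 0.75 * sqrt(m).
    Deterministic given ``seed``.
    """
    x0 = np.asarray(instance, dtype=float)
    m = x0.size
    if n_perturb < 50:
        raise ValueError("n_perturb must be at least 50")
    scales = np.asarray(scales, dtype=float)
    rng = np.random.default_rng(seed)
    X = x0 + rng.normal(0.0, 1.0, size=(n_perturb, m)) * scales
    if categorical_values:
        for j, codes in categorical_values.items():
            X[:, j] = rng.choice(np.asarray(codes, dtype=float), size=n_perturb)
    X[0] = x0  # anchor the neighborhood on the instance itself

    y = np.asarray(predict_fn(X), dtype=float)
    if kernel_width is None:
        kernel_width = 0.75 * math.sqrt(m)
    safe = np.where(scales > 0, scales, 1.0)
    dist = np.sqrt(np.sum(((X - x0) / safe) ** 2, axis=1))
    w = np.exp(-(dist**2) / kernel_width**2)

    design = np.column_stack([np.ones(n_perturb), X])
    sw = np.sqrt(w)
    A = design * sw[:, None]
    b = y * sw
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        logger.info("singular surrogate design; ridge fallback (1e-6)")
        gram = gram + 1e-6 * np.eye(gram.shape[0])
    coef = np.linalg.solve(gram, A.T @ b)
    intercept, weights = float(coef[0]), coef[1:]

    y_surr = design @ coef
    r2 = local_fidelity(y, y_surr)
    c_plus, c_minus = contribution_scores(weights, x0)
    contrib = weights * x0
    order = np.argsort(-np.abs(contrib))
    top = [(feature_names[i], float(contrib[i])) for i in order]
    return ExplanationBundle(
        instance_id=instance_id,
        feature_names=list(feature_names),
        surrogate_weights=weights,
        surrogate_intercept=intercept,
        local_fidelity=r2,
        c_plus=c_plus,
        c_minus=c_minus,
        top_features=top,
    )


def aggregate_lime(bundles, feature_names=None) -> GlobalImportance:
    """Global importance: mean |w_i x_i| per feature, normalized to sum 1."""
    if not bundles:
        raise ValueError("need at least one bundle")
    if feature_names is None:
        feature_names = bundles[0].feature_names
    acc = np.zeros(len(feature_names))
    for b in bundles:
        contrib = dict(b.top_features)
        acc += np.array([abs(contrib.get(f, 0.0)) for f in feature_names])
    acc /= len(bundles)
    total = acc.sum()
    if total > 0:
        acc = acc / total
    return GlobalImportance(
        scores=pd.Series(acc, index=list(feature_names)), method="lime-aggregate"
    )


# ---------------------------------------------------------------------------
# cohort-level convenience


def explain_cohort_instance(
    model,
    train_cohort,
    row_values: np.ndarray,
    n_perturb: int = 500,
    seed: int = 0,
    instance_id: int = 0,
) -> ExplanationBundle:
    """LIME explanation of one un-normalized record against a fitted model.

    ``train_cohort`` must carry normalization stats (perturbation scales =
    training SDs; the model is queried through the same normalization).
    """
    from . import schema

    stats = train_cohort.normalization_stats
    if stats is None:
        raise ValueError("train_cohort has no fitted normalization stats")
    names = train_cohort.feature_order
    scales = np.array(
        [stats[f][1] if f in stats else 0.0 for f in names]
    )
    cat_vals = {
        i: np.array(sorted(schema.CATEGORY_CODES[f].values()), dtype=float)
        for i, f in enumerate(names)
        if f in schema.CATEGORICAL
    }

    def to_normalized(X):
        Z = np.array(X, dtype=float)
        for i, f in enumerate(names):
            if f in stats:
                mean, sd = stats[f]
                Z[:, i] = (Z[:, i] - mean) / sd if sd > 0 else Z[:, i] - mean
        return Z

    x0 = np.asarray(row_values, dtype=float)
    target_class = int(model.predict_proba(to_normalized(x0[None, :])).argmax())

    def predict_fn(X):
        return model.predict_proba(to_normalized(X))[:, target_class]

    return lime_explain(
        predict_fn,
        x0,
        names,
        scales,
        categorical_values=cat_vals,
        n_perturb=n_perturb,
        seed=seed,
        instance_id=instance_id,
    )
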