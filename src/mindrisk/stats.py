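"""Performance metrics, calibration/uncertainty diagnostics, and the
statistical validation battery.

The five validation tests (one-way ANOVA, Pearson chi-square, Wilcoxon
signed-rank, Friedman, Diebold–Mariano) are computed from their textbook
sum-of-squares / rank formulas, with p-values from the corresponding scipy
reference distributions.  They are deliberately independent of the scipy
test functions so the latter can serve as cross-checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import schema

logger = logging.getLogger(__name__)


@dataclass
class StatTestResult:
    name: str  # anova | chi2 | wilcoxon | friedman | dm
    statistic: float
    p_value: float
    df: float | tuple | None = None
    flag: str = ""


# ---------------------------------------------------------------------------
# classification metrics


@dataclass
class MetricsReport:
    labels: list
    confusion_matrix: np.ndarray
    accuracy: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    flags: list[str]

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "accuracy": self.accuracy,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
            }
        )


def compute_metrics(y_true, y_pred, labels=None) -> MetricsReport:
    """Accuracy and per-class precision/recall/F1 from the confusion matrix.

    Precision_c = TP/(TP+FP), Recall_c = TP/(TP+FN), F1_c their harmonic
    mean; macro scores are unweighted class means.  A class absent from
    ``y_true`` gets recall 0 and is flagged.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    if labels is None:
        labels = (
            list(schema.LABELS)
            if set(np.unique(y_true)) <= set(schema.LABELS)
            else sorted(set(y_true) | set(y_pred))
        )
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    flags = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    for i, lab in enumerate(labels):
        if cm[i].sum() == 0:
            flags.append(f"class {lab!r} absent from y_true; recall reported as 0")
    return MetricsReport(
        labels=list(labels),
        confusion_matrix=cm,
        accuracy=float(tp.sum() / cm.sum()),
        precision_per_class=precision,
        recall_per_class=recall,
        f1_per_class=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# calibration and uncertainty


@dataclass
class CalibrationReport:
    """One-vs-rest reliability curves per class (empty bins omitted)."""

    n_bins: int
    per_class: dict  # class index -> dict(bin_center, mean_prob, freq, count)


def calibration_curve(y_true, y_prob, n_bins: int = 10) -> CalibrationReport:
    """Reliability curves over equal-width probability bins, one per class."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    per_class = {}
    for c in range(y_prob.shape[1]):
        p = y_prob[:, c]
        hit = (y_true == c).astype(float)
        # rightmost bin closed so p=1 is counted
        idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
        centers, mean_prob, freq, count = [], [], [], []
        for b in range(n_bins):
            mask = idx == b
            if not mask.any():
                continue
            centers.append((edges[b] + edges[b + 1]) / 2)
            mean_prob.append(float(p[mask].mean()))
            freq.append(float(hit[mask].mean()))
            count.append(int(mask.sum()))
        per_class[c] = {
            "bin_center": np.array(centers),
            "mean_prob": np.array(mean_prob),
            "freq": np.array(freq),
            "count": np.array(count),
        }
    return CalibrationReport(n_bins=n_bins, per_class=per_class)


@dataclass
class UncertaintyReport:
    entropy: np.ndarray  # bits, per sample
    confidence: np.ndarray  # max class probability
    rolling_entropy: np.ndarray
    rolling_confidence: np.ndarray
    cumulative_accuracy: np.ndarray | None


def uncertainty_curves(y_prob, window: int = 50, y_true=None) -> UncertaintyReport:
    """Predictive entropy/confidence with centered rolling means."""
    if window < 1:
        raise ValueError("window must be >= 1")
    p = np.asarray(y_prob, dtype=float)
    ent = -np.sum(p * np.log2(np.maximum(p, 1e-300)), axis=1)
    conf = p.max(axis=1)
    roll = lambda x: (  # noqa: E731
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    cum = None
    if y_true is not None:
        correct = (p.argmax(axis=1) == np.asarray(y_true, dtype=int)).astype(float)
        cum = np.cumsum(correct) / np.arange(1, len(correct) + 1)
    return UncertaintyReport(
        entropy=ent,
        confidence=conf,
        rolling_entropy=roll(ent),
        rolling_confidence=roll(conf),
        cumulative_accuracy=cum,
    )


# ---------------------------------------------------------------------------
# statistical validation tests


def anova_oneway(values, groups) -> StatTestResult:
    """One-way ANOVA F = (SSb/dfb) / (SSw/dfw)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two members")
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb = len(levels) - 1
    dfw = len(values) - len(levels)
    if ssw == 0.0:
        logger.warning("zero within-group variance; F infinite")
        return StatTestResult("anova", math.inf, 0.0, (dfb, dfw), flag="ssw=0")
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return StatTestResult("anova", float(F), p, (dfb, dfw))


def chi_square(x, y) -> StatTestResult:
    """Pearson chi-square of association from the x-by-y contingency table."""
    table = pd.crosstab(np.asarray(x), np.asarray(y)).to_numpy(dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if np.any(expected == 0):
        r, c = np.argwhere(expected == 0)[0]
        raise ValueError(f"expected count 0 in cell ({r}, {c})")
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return StatTestResult("chi2", stat, p, df)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the sum of positive ranks by dynamic
    programming over all 2^n sign assignments (integer ranks, no ties)."""
    r = np.rint(ranks).astype(int)
    total = int(r.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for rank in r:
        shifted = np.zeros_like(dist)
        shifted[rank:] = dist[: total + 1 - rank]
        dist = dist + shifted
    dist /= dist.sum()
    w = int(round(w_plus))
    p = 2.0 * min(dist[: w + 1].sum(), dist[w:].sum())
    return float(min(p, 1.0))


def wilcoxon_signed_rank(x, y) -> StatTestResult:
    """Signed-rank statistic W = sum sgn(d_i) R_i over nonzero differences.

    Exact p by enumeration for n <= 25 without rank ties, otherwise a
    normal approximation (with tie correction).  All-zero differences give
    a degenerate result (W = 0, p = 1).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.warning("all paired differences are zero; degenerate test")
        return StatTestResult("wilcoxon", 0.0, 1.0, 0, flag="all-zero differences")
    ranks = sps.rankdata(np.abs(d))
    W = float(np.sum(np.sign(d) * ranks))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        _, counts = np.unique(ranks, return_counts=True)
        var_w = n * (n + 1) * (2 * n + 1) / 6.0 - np.sum(counts**3 - counts) / 12.0
        z = W / math.sqrt(var_w) if var_w > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
    return StatTestResult("wilcoxon", W, p, n)


def friedman_test(data, pre_ranked: bool = False) -> StatTestResult:
    """Friedman chi-square over N blocks x k treatments.

    chi2_F = 12 / (N k (k+1)) * sum_j R_j^2 - 3 N (k+1), with R_j the
    column rank sums (ranks computed within each block, average on ties,
    unless ``pre_ranked``).  p from chi-square with k-1 df.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an N x k matrix with k >= 2")
    N, k = data.shape
    ranks = data if pre_ranked else np.apply_along_axis(sps.rankdata, 1, data)
    R = ranks.sum(axis=0)
    stat = 12.0 / (N * k * (k + 1)) * float(np.sum(R**2)) - 3.0 * N * (k + 1)
    p = float(sps.chi2.sf(stat, k - 1))
    return StatTestResult("friedman", float(stat), p, k - 1)


def diebold_mariano(loss_a, loss_b, horizon: int = 1) -> StatTestResult:
    """Diebold–Mariano comparison of two per-sample loss series.

    d_t = loss_a_t - loss_b_t; DM = dbar / sqrt(LRV / T), where the
    long-run variance LRV = gamma_0 + 2 sum_{k<h} gamma_k truncates the
    autocovariances at lag ``horizon`` - 1.  Two-sided normal p.
    """
    a = np.asarray(loss_a, dtype=float)
    b = np.asarray(loss_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 10:
        raise ValueError("need aligned loss series of length >= 10")
    d = a - b
    T = len(d)
    dbar = d.mean()
    dc = d - dbar
    lrv = float(np.dot(dc, dc)) / T
    for k in range(1, horizon):
        gamma = float(np.dot(dc[:-k], dc[k:])) / T
        lrv += 2.0 * gamma
    if lrv <= 0:
        logger.warning("non-positive long-run variance; degenerate DM test")
        return StatTestResult("dm", 0.0, 1.0, T, flag="degenerate variance")
    stat = dbar / math.sqrt(lrv / T)
    p = float(2.0 * sps.norm.sf(abs(stat)))
    return StatTestResult("dm", float(stat), p, T)


# ---------------------------------------------------------------------------
# per-feature significance battery


def feature_significance_battery(
    model,
    train_cohort,
    test_cohort,
    n_folds: int = 3,
) -> pd.DataFrame:
    """Per-feature discriminative significance against model predictions.

    Continuous features: one-way ANOVA of feature values across predicted
    classes.  Categorical features: chi-square of association with the
    predicted class.  Per-feature Diebold–Mariano: cross-entropy loss of
    the model with the feature neutralized (set to its training mean)
    versus the full model.  Two cohort-level diagnostics ride along in
    ``DataFrame.attrs``: a Wilcoxon signed-rank of encoded predicted vs
    true labels and a Friedman test of conditional-entropy feature ranks
    across ``n_folds`` folds of the training split.
    """
    from .entropy import uncertainty_scores
    from .cohort import Cohort

    names = test_cohort.feature_order
    X = test_cohort.feature_matrix()
    y = test_cohort.label_codes()
    proba = model.predict_proba(X)
    pred = proba.argmax(axis=1)
    full_loss = -np.log(np.maximum(proba[np.arange(len(y)), y], 1e-12))

    rows = []
    for j, feat in enumerate(names):
        vals = X[:, j]
        is_cat = feat in schema.CATEGORICAL
        anova_stat = anova_p = chi2_stat = chi2_p = np.nan
        if is_cat:
            res = chi_square(vals, pred)
            chi2_stat, chi2_p = res.statistic, res.p_value
        else:
            res = anova_oneway(vals, pred)
            anova_stat, anova_p = res.statistic, res.p_value
        X_masked = X.copy()
        X_masked[:, j] = vals.mean()
        proba_m = model.predict_proba(X_masked)
        masked_loss = -np.log(np.maximum(proba_m[np.arange(len(y)), y], 1e-12))
        dm = diebold_mariano(masked_loss, full_loss)
        rows.append(
            {
                "feature": feat,
                "anova_F": anova_stat,
                "anova_p": anova_p,
                "chi2": chi2_stat,
                "chi2_p": chi2_p,
                "dm": dm.statistic,
                "dm_p": dm.p_value,
            }
        )
    out = pd.DataFrame(rows)

    wil = wilcoxon_signed_rank(pred.astype(float), y.astype(float))
    out.attrs["wilcoxon"] = wil

    rng = np.random.default_rng(0)
    idx = rng.permutation(len(train_cohort))
    folds = np.array_split(idx, n_folds)
    rank_rows = []
    for fold in folds:
        sub = Cohort(
            df=train_cohort.df.iloc[np.sort(fold)].reset_index(drop=True),
            feature_order=list(train_cohort.feature_order),
        )
        scores = uncertainty_scores(sub).reindex(names).to_numpy()
        rank_rows.append(sps.rankdata(scores))
    out.attrs["friedman"] = friedman_test(np.asarray(rank_rows), pre_ranked=True)
    return out
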