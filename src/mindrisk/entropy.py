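"""Entropy-based feature screening.

Two quantities per feature: the marginal Shannon entropy of its discretized
distribution (high entropy = volatile, "uncertain" feature; low entropy =
"stable"), and the conditional entropy H(Y|X) of the risk label given the
discretized feature (low = predictive).  Entropies are in bits by default
and should be computed on the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon

from . import schema
from .cohort import Cohort

DEFAULT_BINS = 10
#: marginal-entropy threshold for the stable/uncertain mark, as a fraction
#: of the maximum log2(k) achievable with k quantile bins
DEFAULT_THRESHOLD_FRACTION = 0.9


@dataclass
class EntropyReport:
    """Per-feature entropy summary."""

    feature_name: str
    marginal_entropy: float
    conditional_entropy: float
    mark: str  # "stable" | "uncertain"
    bin_edges: np.ndarray
    bin_probs: np.ndarray


def discretize(values, k: int = DEFAULT_BINS):
    """Quantile-bin a vector into at most ``k`` bins.

    Returns ``(bin_edges, assignment)`` where ``assignment`` is an integer
    bin index per value.  Already-discrete inputs with at most ``k``
    distinct values are kept as their own categories (edges = the sorted
    distinct values).  A constant vector collapses to a single bin with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    distinct = np.unique(values)
    if distinct.size == 1:
        warnings.warn("all values identical; single bin", stacklevel=2)
        return distinct, np.zeros(values.shape, dtype=int)
    if distinct.size <= k:
        return distinct, np.searchsorted(distinct, values)
    binned, edges = pd.qcut(values, q=k, retbins=True, labels=False, duplicates="drop")
    return edges, np.asarray(binned, dtype=int)


def marginal_entropy(bin_probs, base: float = 2.0) -> float:
    """Shannon entropy -sum p log p of a probability vector (0 log 0 = 0)."""
    p = np.asarray(bin_probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    return float(_shannon(p, base=base))


def conditional_entropy(feature_bins, labels, base: float = 2.0) -> float:
    """H(Y|X) = sum_v p(v) H(Y | X=v) from exact joint counts."""
    x = np.asarray(feature_bins)
    y = np.asarray(labels)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    joint = pd.crosstab(x, y).to_numpy(dtype=float)
    n = joint.sum()
    h = 0.0
    for row in joint:
        nv = row.sum()
        if nv > 0:
            h += (nv / n) * _shannon(row / nv, base=base)
    return float(h)


def label_entropy(labels, base: float = 2.0) -> float:
    """Marginal entropy H(Y) of a class vector."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    return marginal_entropy(counts / counts.sum(), base=base)


def mark_features(
    reports: list[EntropyReport], threshold: float
) -> list[EntropyReport]:
    """Apply the stable/uncertain rule: stable iff H(f) < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for r in reports:
        r.mark = "stable" if r.marginal_entropy < threshold else "uncertain"
    return reports


def screen(
    cohort: Cohort,
    k: int = DEFAULT_BINS,
    threshold: float | None = None,
    base: float = 2.0,
) -> list[EntropyReport]:
    """Entropy report for every feature in the cohort's feature order.

    ``threshold`` defaults to 0.9 * log2(k).  Marks are reported metadata;
    nothing is dropped here.
    """
    if cohort.labels is None:
        raise ValueError("cohort must be labeled before entropy screening")
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRACTION * np.log2(k) / np.log2(base)
    y = cohort.label_codes()
    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are fine here
        for feat in cohort.feature_order:
            vals = cohort.df[feat]
            if feat in schema.CATEGORICAL and not pd.api.types.is_numeric_dtype(vals):
                vals = vals.map(schema.CATEGORY_CODES[feat])
            edges, bins = discretize(vals.to_numpy(dtype=float), k=k)
            counts = np.bincount(bins)
            probs = counts[counts > 0] / counts.sum()
            reports.append(
                EntropyReport(
                    feature_name=feat,
                    marginal_entropy=marginal_entropy(probs, base=base),
                    conditional_entropy=conditional_entropy(bins, y, base=base),
                    mark="",
                    bin_edges=edges,
                    bin_probs=probs,
                )
            )
    return mark_features(reports, threshold)


def uncertainty_scores(cohort: Cohort, k: int = DEFAULT_BINS) -> pd.Series:
    """Per-feature conditional entropy H(Y|X); ascending = most predictive."""
    reports = screen(cohort, k=k)
    return pd.Series(
        {r.feature_name: r.conditional_entropy for r in reports},
        name="conditional_entropy",
    )


def report_frame(reports: list[EntropyReport]) -> pd.DataFrame:
    """Reports as a DataFrame (feature, marginal, conditional, mark)."""
    return pd.DataFrame(
        {
            "feature": [r.feature_name for r in reports],
            "marginal_entropy": [r.marginal_entropy for r in reports],
            "conditional_entropy": [r.conditional_entropy for r in reports],
            "mark": [r.mark for r in reports],
        }
    )
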