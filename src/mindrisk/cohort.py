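"""Cohort loading, encoding, normalization, labeling and splitting.

A :class:`Cohort` wraps a pandas DataFrame holding the ten schema features
(plus an optional risk label) together with the active feature ordering and
any normalization statistics fitted on a training split.  All leakage-prone
statistics (imputation medians, z-score means/SDs, percentile cut points)
are fitted on training rows only and applied unchanged to held-out rows.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import schema

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A file or frame does not conform to the cohort schema."""


@dataclass
class SplitSpec:
    """Stratified train/test split specification."""

    test_fraction: float = 0.2
    seed: int = 0
    stratify_on: str = schema.LABEL_COLUMN

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction}"
            )


@dataclass
class Cohort:
    """Tabular cohort: records, feature ordering and normalization state."""

    df: pd.DataFrame
    feature_order: list[str] = field(
        default_factory=lambda: list(schema.ORDERINGS[schema.DEFAULT_ORDERING])
    )
    #: per-feature (mean, sd) fitted on the training split; None until fitted
    normalization_stats: dict[str, tuple[float, float]] | None = None
    #: medians used for imputation, fitted on the training split
    imputation_medians: dict[str, float] | None = None
    #: tertile cut points of the label composite (fitted where labels assigned)
    label_cuts: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> pd.Series | None:
        if schema.LABEL_COLUMN in self.df.columns:
            return self.df[schema.LABEL_COLUMN]
        return None

    def feature_matrix(self) -> np.ndarray:
        """Features as an (n, 10) float array in ``feature_order``."""
        return self.df[self.feature_order].to_numpy(dtype=float)

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes 0=Low, 1=Medium, 2=High."""
        lab = self.labels
        if lab is None:
            raise ValueError("cohort has no label column")
        return lab.map({name: i for i, name in enumerate(schema.LABELS)}).to_numpy()

    def sidecar(self) -> dict:
        """JSON-serializable record of fitted statistics and encodings."""
        return {
            "feature_order": self.feature_order,
            "normalization_stats": self.normalization_stats,
            "imputation_medians": self.imputation_medians,
            "label_cuts": self.label_cuts,
            "category_codes": schema.CATEGORY_CODES,
        }


def read_cohort(path) -> Cohort:
    """Read a schema-conformant CSV into a :class:`Cohort`.

    The header must contain all ten schema columns; the label column is
    optional and extra columns are passed through untouched.  Unparseable
    numerics and out-of-set categorical values are rejected with the row
    index and offending value.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: file contains no records")
    missing = [c for c in schema.FEATURES if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in schema.CONTINUOUS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: column {col!r} has unparseable value "
                f"{df.loc[bad[0], col]!r} at row {bad[0]}"
            )
        df[col] = coerced
    for col in schema.CATEGORICAL:
        if pd.api.types.is_numeric_dtype(df[col]):
            continue  # already encoded
        allowed = set(schema.CATEGORY_CODES[col])
        vals = df[col].astype(str).str.strip()
        bad = df.index[df[col].notna() & ~vals.isin(allowed)]
        if len(bad):
            raise SchemaError(
                f"{path}: column {col!r} has value {df.loc[bad[0], col]!r} "
                f"at row {bad[0]}; allowed: {sorted(allowed)}"
            )
        df[col] = vals.where(df[col].notna())
    if schema.LABEL_COLUMN in df.columns:
        bad = df.index[~df[schema.LABEL_COLUMN].isin(schema.LABELS)]
        if len(bad):
            raise SchemaError(
                f"{path}: label {df.loc[bad[0], schema.LABEL_COLUMN]!r} at "
                f"row {bad[0]}; allowed: {schema.LABELS}"
            )
    return Cohort(df=df)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort back to CSV (schema column order, label last)."""
    cols = list(schema.FEATURES)
    if schema.LABEL_COLUMN in cohort.df.columns:
        cols.append(schema.LABEL_COLUMN)
    extra = [c for c in cohort.df.columns if c not in cols]
    cohort.df[cols + extra].to_csv(path, index=False)


def write_sidecar(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.sidecar(), fh, indent=2)


def impute_and_encode(
    cohort: Cohort, medians: dict[str, float] | None = None
) -> Cohort:
    """Fill missing continuous values and integer-encode categoricals.

    Missing continuous entries are replaced by the training-split median of
    the feature (fitted here when ``medians`` is None, i.e. when the cohort
    is the training split).  Gender and employment are mapped to their fixed
    alphabetical integer codes.
    """
    df = cohort.df.copy()
    fitted = dict(medians) if medians is not None else {}
    for col in schema.CONTINUOUS:
        if col not in fitted:
            med = df[col].median()
            if np.isnan(med):
                raise ValueError(f"feature {col!r} entirely missing; median undefined")
            fitted[col] = float(med)
        df[col] = df[col].fillna(fitted[col])
    for col in schema.CATEGORICAL:
        codes = schema.CATEGORY_CODES[col]
        if not pd.api.types.is_numeric_dtype(df[col]):
            mode = df[col].mode()
            fill = mode.iloc[0] if len(mode) else next(iter(codes))
            df[col] = df[col].fillna(fill).map(codes).astype(float)
        else:
            df[col] = df[col].fillna(float(pd.to_numeric(df[col]).median()))
    return replace(cohort, df=df, imputation_medians=fitted)


def fit_normalization(cohort: Cohort) -> dict[str, tuple[float, float]]:
    """Per-feature (mean, sd) of the continuous features (population sd)."""
    stats: dict[str, tuple[float, float]] = {}
    for col in schema.CONTINUOUS:
        x = cohort.df[col].to_numpy(dtype=float)
        stats[col] = (float(np.mean(x)), float(np.std(x)))
    return stats


def normalize(
    cohort: Cohort, stats: dict[str, tuple[float, float]] | None = None
) -> Cohort:
    """Z-scale continuous features with training-split statistics.

    When ``stats`` is None the cohort is treated as the training split and
    the statistics are fitted here.  Encoded categoricals are left as their
    integer codes.  A zero-variance feature is centered only, with a
    warning.
    """
    if stats is None:
        stats = fit_normalization(cohort)
    df = cohort.df.copy()
    for col in schema.CONTINUOUS:
        mean, sd = stats[col]
        if sd == 0.0:
            warnings.warn(
                f"feature {col!r} has zero variance; centered only", stacklevel=2
            )
            df[col] = df[col] - mean
        else:
            df[col] = (df[col] - mean) / sd
    return replace(cohort, df=df, normalization_stats=dict(stats))


def composite_score(
    cohort: Cohort, stats: dict[str, tuple[float, float]] | None = None
) -> np.ndarray:
    """Distress composite: mean of z-scored anxiety and depression."""
    parts = []
    for col in ("anxiety", "depression"):
        x = cohort.df[col].to_numpy(dtype=float)
        if stats is not None and col in stats:
            mean, sd = stats[col]
        else:
            mean, sd = float(np.mean(x)), float(np.std(x))
        parts.append((x - mean) / sd if sd > 0 else x - mean)
    return np.mean(parts, axis=0)


def assign_percentile_labels(
    cohort: Cohort,
    composite: np.ndarray | None = None,
    cuts: tuple[float, float] | None = None,
) -> Cohort:
    """Assign Low/Medium/High labels by tertiles of the distress composite.

    The composite defaults to the mean of z-scored anxiety and depression.
    Cut points are the empirical 1/3 and 2/3 quantiles; a row is Low iff
    its composite is strictly below the lower cut, High iff strictly above
    the upper cut, Medium otherwise (ties at a cut go to the lower class).
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 rows to place percentile cuts")
    if composite is None:
        composite = composite_score(cohort, cohort.normalization_stats)
    composite = np.asarray(composite, dtype=float)
    if cuts is None:
        q1, q2 = np.quantile(composite, [1.0 / 3.0, 2.0 / 3.0])
        cuts = (float(q1), float(q2))
    q1, q2 = cuts
    if q1 == q2:
        warnings.warn(
            "degenerate composite: percentile cuts coincide; labels collapse",
            stacklevel=2,
        )
    labels = np.where(
        composite < q1, "Low", np.where(composite > q2, "High", "Medium")
    )
    df = cohort.df.copy()
    df[schema.LABEL_COLUMN] = labels
    return replace(cohort, df=df, label_cuts=cuts)


def stratified_split(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Deterministic stratified split into (train, test) cohorts.

    Per-class test counts land within one record of ``class_count *
    test_fraction``; train and test are disjoint and exhaustive.
    """
    strat = cohort.df[spec.stratify_on]
    counts = strat.value_counts()
    if (counts < 2).any():
        tiny = counts[counts < 2].index.tolist()
        raise ValueError(f"class(es) {tiny} have fewer than 2 members; cannot split")
    idx_train, idx_test = train_test_split(
        cohort.df.index.to_numpy(),
        test_size=spec.test_fraction,
        random_state=spec.seed,
        stratify=strat.to_numpy(),
    )
    make = lambda idx: replace(  # noqa: E731
        cohort, df=cohort.df.loc[np.sort(idx)].reset_index(drop=True)
    )
    return make(idx_train), make(idx_test)


def order_features(cohort: Cohort, ordering_name: str) -> Cohort:
    """Set the cohort's active feature permutation by name (idempotent)."""
    return replace(cohort, feature_order=schema.ordering(ordering_name))


def prepare(
    cohort: Cohort,
    spec: SplitSpec | None = None,
    ordering_name: str = schema.DEFAULT_ORDERING,
) -> tuple[Cohort, Cohort]:
    """Full preprocessing pipeline: encode, label, split, normalize, order.

    Imputation and encoding run on the full cohort (labels need complete
    anxiety/depression values), labels are assigned on the full cohort (the
    composite's tertiles are a property of the whole dataset), then the
    split is stratified on them and the z-score statistics are fitted on
    the training rows only and applied unchanged to the test rows.
    """
    spec = spec or SplitSpec()
    encoded = impute_and_encode(cohort)
    if encoded.labels is None:
        labeled = assign_percentile_labels(encoded)
    else:
        labeled = encoded
    train, test = stratified_split(labeled, spec)
    train = normalize(train)
    test = normalize(test, stats=train.normalization_stats)
    return order_features(train, ordering_name), order_features(test, ordering_name)
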