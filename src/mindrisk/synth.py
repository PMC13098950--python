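"""Synthetic student-cohort generator with a planted distress signal.

Each record is driven by a single latent distress factor ``z`` (standard
normal).  Emotional scales load positively on ``z`` (anxiety, depression,
stress), protective/behavioral scales load negatively (productivity, social
support, sleep), and demographics are independent of ``z``.  Labels come
from tertiles of the normalized anxiety+depression composite, so the
informative features — and hence the expected importance ranking — are
known by construction, which is what makes attribution and entropy-ranking
tests possible without any external dataset.

Scales are chosen so clinically styled thresholds (anxiety above ~11,
depression above ~23) fall in the upper tail of the generated marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .cohort import Cohort, assign_percentile_labels, composite_score

#: loading of each continuous feature on the latent distress factor, at
#: signal_strength 1.0 (scaled linearly by ``signal_strength``)
DEFAULT_LOADINGS = {
    "anxiety": 5.0,
    "depression": 7.0,
    "productivity": -2.0,
    "stress_level": 2.0,
    "social_support": -1.0,
    "sleep_hours": -0.5,
}

#: feature means at z = 0
_BASELINES = {
    "anxiety": 10.0,
    "depression": 13.0,
    "productivity": 6.0,
    "stress_level": 5.0,
    "social_support": 6.0,
    "sleep_hours": 7.0,
}

_CLIP = {
    "anxiety": (0.0, 21.0),
    "depression": (0.0, 27.0),
    "productivity": (0.0, 10.0),
    "stress_level": (0.0, 10.0),
    "social_support": (0.0, 10.0),
    "sleep_hours": (3.0, 12.0),
}

_GENDER_P = {"female": 0.46, "male": 0.46, "non-binary": 0.05, "prefer-not-to-say": 0.03}
_EMPLOYMENT_P = {"student": 0.70, "employed": 0.20, "unemployed": 0.10}

#: weight of the planted anxiety-x-productivity interaction in the label
#: composite; set so the interaction term's variance is comparable to the
#: additive emotional composite's
INTERACTION_WEIGHT = 1.5

#: latent-factor strength used for interaction-planted cohorts: the shared
#: distress factor correlates anxiety and productivity, and at high signal
#: their product degenerates into a monotone function of the additive
#: composite; a weak factor keeps the planted interaction genuinely
#: cross-feature
INTERACTION_SIGNAL = 0.3


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic cohort."""

    n: int = 2000
    seed: int = 0
    #: loading of the latent distress factor on the emotional features
    signal_strength: float = 0.8
    #: "none" or "anxiety_x_productivity" (label composite gains a term that
    #: requires jointly high anxiety and low productivity)
    interaction_mode: str = "none"
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    #: optional per-feature loading override (features absent -> loading 0)
    loadings: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.interaction_mode not in ("none", "anxiety_x_productivity"):
            raise ValueError(f"unknown interaction_mode {self.interaction_mode!r}")

    def effective_loadings(self) -> dict[str, float]:
        base = self.loadings if self.loadings is not None else DEFAULT_LOADINGS
        return {f: base.get(f, 0.0) for f in _BASELINES}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def generate(spec: GeneratorSpec) -> Cohort:
    """Draw a labeled cohort under the given study conditions.

    Deterministic given ``spec.seed``.  Missing values (MCAR) are masked
    only in the continuous features, after label assignment.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.n)
    loadings = spec.effective_loadings()
    cols: dict[str, np.ndarray] = {}
    for feat, base in _BASELINES.items():
        eps = rng.normal(0.0, spec.noise_sd, spec.n)
        raw = base + spec.signal_strength * loadings[feat] * z + eps
        lo, hi = _CLIP[feat]
        cols[feat] = np.clip(raw, lo, hi)
    cols["physical_activity_days"] = rng.integers(0, 8, spec.n).astype(float)
    cols["age"] = rng.integers(18, 61, spec.n).astype(float)
    cols["gender"] = rng.choice(
        list(_GENDER_P), p=list(_GENDER_P.values()), size=spec.n
    )
    cols["employment"] = rng.choice(
        list(_EMPLOYMENT_P), p=list(_EMPLOYMENT_P.values()), size=spec.n
    )
    df = pd.DataFrame(cols)[schema.FEATURES]
    cohort = Cohort(df=df)

    composite = composite_score(cohort)
    if spec.interaction_mode == "anxiety_x_productivity":
        # signed product: the anxiety x productivity interaction proper,
        # whose positive direction is jointly high anxiety / low
        # productivity; unlike a rectified product it is not co-monotone
        # with the additive composite, so the label genuinely needs it
        z_anx = _zscore(df["anxiety"].to_numpy())
        z_prod = _zscore(df["productivity"].to_numpy())
        composite = composite + INTERACTION_WEIGHT * z_anx * (-z_prod)
    cohort = assign_percentile_labels(cohort, composite=composite)

    if spec.missing_rate > 0:
        mask = rng.random((spec.n, len(_BASELINES))) < spec.missing_rate
        df = cohort.df.copy()
        for j, feat in enumerate(_BASELINES):
            df.loc[mask[:, j], feat] = np.nan
        cohort = Cohort(
            df=df, feature_order=cohort.feature_order, label_cuts=cohort.label_cuts
        )
    return cohort


@dataclass
class GroundTruth:
    """What the generator planted, for use as a test oracle."""

    informative: list[str] = field(default_factory=list)
    #: informative features ordered by |loading|, largest first
    importance_order: list[str] = field(default_factory=list)
    interaction_pair: tuple[str, str] | None = None


def ground_truth(spec: GeneratorSpec) -> GroundTruth:
    """Informative feature set and expected importance ranking."""
    loadings = spec.effective_loadings()
    if spec.signal_strength == 0.0:
        informative: list[str] = []
    else:
        informative = [f for f, w in loadings.items() if w != 0.0]
    order = sorted(informative, key=lambda f: -abs(loadings[f]))
    pair = None
    if spec.interaction_mode == "anxiety_x_productivity":
        pair = ("anxiety", "productivity")
        for f in pair:
            if f not in informative:
                informative.append(f)
    return GroundTruth(
        informative=informative, importance_order=order, interaction_pair=pair
    )
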