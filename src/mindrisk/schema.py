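"""Canonical feature schema for the student-cohort risk pipeline.

Every record carries ten psychological, behavioral and demographic
attributes plus an optional three-level risk label.  All modules agree on
the names, closed category sets and block structure defined here; feature
positions are 0-based everywhere.
"""

from __future__ import annotations

# Emotional block: direct psychological state indicators.
EMOTIONAL = ["anxiety", "depression", "stress_level", "social_support"]
# Behavioral block: outward expressions / lifestyle correlates.
BEHAVIORAL = ["productivity", "sleep_hours", "physical_activity_days"]
# Demographic block: background attributes.
DEMOGRAPHIC = ["age", "gender", "employment"]

#: The ten schema features in storage order (CSV column order).
FEATURES = EMOTIONAL + BEHAVIORAL + DEMOGRAPHIC

CONTINUOUS = [
    "anxiety",
    "depression",
    "stress_level",
    "social_support",
    "productivity",
    "sleep_hours",
    "physical_activity_days",
    "age",
]
CATEGORICAL = ["gender", "employment"]

LABEL_COLUMN = "risk"
LABELS = ["Low", "Medium", "High"]
N_CLASSES = 3

# Closed category sets with fixed alphabetical integer codes, persisted with
# any fitted model so encodings are stable across runs.
GENDER_CODES = {"female": 0, "male": 1, "non-binary": 2, "prefer-not-to-say": 3}
EMPLOYMENT_CODES = {"employed": 0, "student": 1, "unemployed": 2}
CATEGORY_CODES = {"gender": GENDER_CODES, "employment": EMPLOYMENT_CODES}

#: Expected value ranges (used by the generator's clipping contract and by
#: input validation; continuous scales are instrument-style score ranges).
RANGES = {
    "anxiety": (0.0, 21.0),
    "depression": (0.0, 27.0),
    "productivity": (0.0, 10.0),
    "social_support": (0.0, 10.0),
    "sleep_hours": (0.0, 14.0),
    "stress_level": (0.0, 10.0),
    "physical_activity_days": (0, 7),
    "age": (18, 80),
}

# Named feature orderings.  The proposed ordering places emotional features
# first so the sequence model reads distress indicators before their
# behavioral and demographic context.
ORDERINGS = {
    "order1": DEMOGRAPHIC + BEHAVIORAL + EMOTIONAL,
    "order2": BEHAVIORAL + EMOTIONAL + DEMOGRAPHIC,
    "order3": EMOTIONAL + BEHAVIORAL + DEMOGRAPHIC,
}
DEFAULT_ORDERING = "order3"


def ordering(name: str) -> list[str]:
    """Return the named feature permutation.

    Raises
    ------
    ValueError
        If ``name`` is not one of ``order1``, ``order2``, ``order3``.
    """
    try:
        return list(ORDERINGS[name])
    except KeyError:
        raise ValueError(
            f"unknown ordering {name!r}; expected one of {sorted(ORDERINGS)}"
        ) from None
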