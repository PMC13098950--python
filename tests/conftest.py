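import numpy as np
import pytest

from mindrisk import cohort as cohort_mod
from mindrisk import synth
from mindrisk.estimators import RiskNetworkClassifier

TINY_NET = dict(
    d_token=8,
    n_heads=2,
    n_layers=1,
    ffn_dim=8,
    lstm_units=8,
    attention_dim=4,
    caal_heads=2,
    dropout=0.0,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small default-signal cohort (anxiety/depression drive the labels)."""
    return synth.generate(synth.GeneratorSpec(n=400, seed=7))


@pytest.fixture(scope="session")
def planted_split(planted_cohort):
    return cohort_mod.prepare(planted_cohort, cohort_mod.SplitSpec(0.2, 7))


@pytest.fixture(scope="session")
def tiny_model(planted_split):
    """A small trained full model shared by explanation/battery tests."""
    train, _ = planted_split
    model = RiskNetworkClassifier(
        **TINY_NET,
        optimizer="adam",
        learning_rate=5e-3,
        max_epochs=15,
        patience=15,
        random_state=7,
    )
    model.fit(train.feature_matrix(), train.label_codes())
    return model
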