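"""Scikit-learn estimator interface to the risk network.

:class:`RiskNetworkClassifier` wraps the network's training loop behind the
standard ``fit`` / ``predict`` / ``predict_proba`` contract so it composes
with sklearn pipelines, cross-validation and model selection.  Inputs are
the (n, 10) matrix of normalized feature values in the active feature
ordering (the :mod:`mindrisk.cohort` pipeline produces exactly that).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_array, check_X_y

from . import network
from .network import ModelConfig, TrainState


class RiskNetworkClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid attention/LSTM risk classifier with ablation variants.

    Parameters mirror :class:`mindrisk.network.ModelConfig`; ``variant``
    selects a rung of the ablation ladder (``lstm``, ``lstm_attn``,
    ``transformer``, ``early_fusion``, ``dual_attn``, ``caal``; the aliases
    ``E1``..``E6`` are accepted).  ``validation_fraction`` of the training
    rows is held out (stratified) for checkpoint selection and early
    stopping.

    Fitted attributes
    -----------------
    params_ : dict of named parameter tensors
    train_state_ : TrainState with per-epoch curves and best epoch
    classes_ : array of class codes seen in ``y``
    """

    def __init__(
        self,
        variant: str = "caal",
        d_token: int = 32,
        n_heads: int = 4,
        n_layers: int = 2,
        ffn_dim: int = 64,
        lstm_units: int = 64,
        attention_dim: int = 32,
        caal_heads: int = 2,
        fusion: str = "concat",
        dropout: float = 0.1,
        lambda_xai: float = 0.1,
        learning_rate: float = 1e-2,
        batch_size: int = 64,
        max_epochs: int = 60,
        patience: int = 10,
        optimizer: str = "sgd",
        validation_fraction: float = 0.15,
        canonical_pe: bool = False,
        random_state: int = 0,
    ):
        self.variant = variant
        self.d_token = d_token
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.ffn_dim = ffn_dim
        self.lstm_units = lstm_units
        self.attention_dim = attention_dim
        self.caal_heads = caal_heads
        self.fusion = fusion
        self.dropout = dropout
        self.lambda_xai = lambda_xai
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.optimizer = optimizer
        self.validation_fraction = validation_fraction
        self.canonical_pe = canonical_pe
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(
            d_token=self.d_token,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            ffn_dim=self.ffn_dim,
            lstm_units=self.lstm_units,
            attention_dim=self.attention_dim,
            caal_heads=self.caal_heads,
            fusion=self.fusion,
            dropout=self.dropout,
            lambda_xai=self.lambda_xai,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            optimizer=self.optimizer,
            seed=self.random_state,
            canonical_pe=self.canonical_pe,
        )

    def fit(self, X, y) -> "RiskNetworkClassifier":
        X, y = check_X_y(X, y, dtype=np.float64)
        if X.shape[1] != network.N_FEATURES:
            raise ValueError(
                f"expected {network.N_FEATURES} features, got {X.shape[1]}"
            )
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        config = self._config()
        if self.validation_fraction > 0 and len(X) >= 20:
            from sklearn.model_selection import train_test_split

            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y_idx,
                test_size=self.validation_fraction,
                random_state=self.random_state,
                stratify=y_idx,
            )
        else:
            X_tr, y_tr, X_val, y_val = X, y_idx, None, None
        self.params_, self.train_state_ = network.train(
            X_tr, y_tr, X_val, y_val, config, self.variant
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise NotFittedError("call fit before using this estimator")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = check_array(X, dtype=np.float64)
        proba = network.predict_proba(X, self.params_, self._config(), self.variant)
        if len(self.classes_) < network.N_CLASSES:
            proba = proba[:, : len(self.classes_)]
            proba = proba / proba.sum(axis=1, keepdims=True)
        return proba

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # ------------------------------------------------------------------
    def forward_trace(self, X) -> dict:
        """Evaluation-mode forward pass returning intermediate tensors."""
        self._check_fitted()
        X = check_array(X, dtype=np.float64)
        return network.forward(X, self.params_, self._config(), self.variant)

    def attribution(self, X) -> np.ndarray:
        """Per-instance attribution maps A_C, shape (n, heads, m).

        Only defined for the full model (variant ``caal``).
        """
        trace = self.forward_trace(X)
        if trace["A_C"] is None:
            raise ValueError(f"variant {self.variant!r} has no attribution layer")
        return trace["A_C"].data

    def parameter_count(self) -> int:
        self._check_fitted()
        return network.param_count(self.params_)

    def training_curves(self):
        """Per-epoch train/validation loss, accuracy and entropy."""
        self._check_fitted()
        return self.train_state_.curves_frame()

    def save(self, path, extra: dict | None = None) -> None:
        self._check_fitted()
        ex = dict(extra or {})
        ex["classes"] = [int(c) if isinstance(c, (np.integer, int)) else str(c) for c in self.classes_]
        network.save_checkpoint(path, self.params_, self._config(), self.variant, ex)

    @classmethod
    def load(cls, path) -> "RiskNetworkClassifier":
        params, config, variant, extra = network.load_checkpoint(path)
        est = cls(
            variant=variant,
            d_token=config.d_token,
            n_heads=config.n_heads,
            n_layers=config.n_layers,
            ffn_dim=config.ffn_dim,
            lstm_units=config.lstm_units,
            attention_dim=config.attention_dim,
            caal_heads=config.caal_heads,
            fusion=config.fusion,
            dropout=config.dropout,
            lambda_xai=config.lambda_xai,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            patience=config.patience,
            optimizer=config.optimizer,
            canonical_pe=config.canonical_pe,
            random_state=config.seed,
        )
        est.params_ = params
        est.classes_ = np.asarray(extra.get("classes", [0, 1, 2]))
        est.train_state_ = TrainState()
        est.n_features_in_ = network.N_FEATURES
        return est


def build_variant(variant_id: str, **kwargs) -> RiskNetworkClassifier:
    """Construct an ablation-ladder classifier by variant id (E1..E6 or name)."""
    name = network.VARIANTS.get(variant_id, variant_id)
    if name not in network.VARIANT_NAMES:
        raise ValueError(f"unknown variant {variant_id!r}")
    return RiskNetworkClassifier(variant=name, **kwargs)
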