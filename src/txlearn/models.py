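"""Outcome risk classifiers: the transformer (primary) and the baselines.

All models satisfy one contract: ``fit(encoded_cohort, y)`` then
``predict_proba(encoded_cohort) -> probabilities in [0, 1]`` aligned with
the input rows. The transformer and LSTM consume the padded sequences;
the logistic and gradient-boosted baselines consume a bag-of-token count
representation concatenated with the static covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier, XGBRegressor

from .encoding import EncodedCohort
from .nn import (
    LSTMConfig,
    LSTMNet,
    TransformerConfig,
    TransformerNet,
    predict_proba_batched,
    train_network,
)


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return y


class _CheckpointMixin:
    """Checkpointing for the sequence models: the config and the parameter
    arrays are serialised together so a reload reproduces predictions
    bit for bit."""

    def save(self, path) -> None:
        import pickle
        from pathlib import Path

        if self.net is None:
            raise RuntimeError("cannot checkpoint an unfitted model")
        payload = {
            "kind": type(self).__name__,
            "config": self.config,
            "state": self.net.state(),
            "vocab_size": self._fitted_vocab_size,
            "n_static": self._n_static,
        }
        Path(path).write_bytes(pickle.dumps(payload))

    @classmethod
    def load(cls, path):
        import pickle
        from pathlib import Path

        payload = pickle.loads(Path(path).read_bytes())
        if payload["kind"] != cls.__name__:
            raise ValueError(
                f"checkpoint holds a {payload['kind']}, not a {cls.__name__}"
            )
        model = cls(payload["config"])
        model._build_net(payload["vocab_size"], payload["n_static"])
        model.net.load_state(payload["state"])
        return model


class TransformerRiskModel(_CheckpointMixin):
    """Primary sequence classifier; see :mod:`txlearn.nn.transformer`."""

    def __init__(self, config: TransformerConfig | None = None):
        self.config = config or TransformerConfig()
        self.net: TransformerNet | None = None
        self.log = None
        self._n_static: int | None = None
        self._fitted_vocab_size: int | None = None

    def _build_net(self, vocab_size: int, n_static: int) -> None:
        self._n_static = n_static
        self._fitted_vocab_size = vocab_size
        self.net = TransformerNet(vocab_size, n_static, self.config)

    def fit(self, enc: EncodedCohort, y) -> "TransformerRiskModel":
        y = _check_labels(y)
        L = enc.token_ids.shape[1]
        if self.config.max_len != L:
            self.config = replace(self.config, max_len=L)
        self._build_net(enc.vocab_size, enc.static_features.shape[1])
        self.log = train_network(
            self.net, enc.token_ids, enc.day_offsets, enc.padding_mask,
            enc.static_features, y, self.config,
        )
        return self

    def predict_proba(self, enc: EncodedCohort) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("model is not fitted")
        if enc.vocab_size != self._fitted_vocab_size:
            raise ValueError("vocabulary mismatch between training and scoring")
        return predict_proba_batched(
            self.net, enc.token_ids, enc.day_offsets, enc.padding_mask,
            enc.static_features,
        )


class LSTMRiskModel(_CheckpointMixin):
    """Recurrent baseline over the same encoded sequences."""

    def __init__(self, config: LSTMConfig | None = None):
        self.config = config or LSTMConfig()
        self.net: LSTMNet | None = None
        self.log = None
        self._n_static: int | None = None
        self._fitted_vocab_size: int | None = None

    def _build_net(self, vocab_size: int, n_static: int) -> None:
        self._n_static = n_static
        self._fitted_vocab_size = vocab_size
        self.net = LSTMNet(vocab_size, n_static, self.config)

    def fit(self, enc: EncodedCohort, y) -> "LSTMRiskModel":
        y = _check_labels(y)
        self._build_net(enc.vocab_size, enc.static_features.shape[1])
        self.log = train_network(
            self.net, enc.token_ids, enc.day_offsets, enc.padding_mask,
            enc.static_features, y, self.config,
        )
        return self

    def predict_proba(self, enc: EncodedCohort) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("model is not fitted")
        if enc.vocab_size != self._fitted_vocab_size:
            raise ValueError("vocabulary mismatch between training and scoring")
        return predict_proba_batched(
            self.net, enc.token_ids, enc.day_offsets, enc.padding_mask,
            enc.static_features,
        )


def _tabular(enc: EncodedCohort) -> np.ndarray:
    return np.hstack([np.log1p(enc.bag_of_tokens()), enc.static_features])


class LogisticRiskModel:
    """Logistic regression on log(1 + token counts) + static covariates."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
        self._vocab_size: int | None = None

    def fit(self, enc: EncodedCohort, y) -> "LogisticRiskModel":
        self.clf.fit(_tabular(enc), _check_labels(y))
        self._vocab_size = enc.vocab_size
        return self

    def predict_proba(self, enc: EncodedCohort) -> np.ndarray:
        if self._vocab_size is None:
            raise RuntimeError("model is not fitted")
        if enc.vocab_size != self._vocab_size:
            raise ValueError("vocabulary mismatch between training and scoring")
        if len(enc) == 0:
            return np.zeros(0)
        return self.clf.predict_proba(_tabular(enc))[:, 1]


class BoostedTreesRiskModel:
    """Gradient-boosted trees on the same tabular representation."""

    def __init__(self, n_estimators: int = 200, max_depth: int = 4,
                 learning_rate: float = 0.1, seed: int = 0):
        self.clf = XGBClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            learning_rate=learning_rate, random_state=seed,
            n_jobs=1, tree_method="hist", verbosity=0,
        )
        self._vocab_size: int | None = None

    def fit(self, enc: EncodedCohort, y) -> "BoostedTreesRiskModel":
        self.clf.fit(_tabular(enc), _check_labels(y))
        self._vocab_size = enc.vocab_size
        return self

    def predict_proba(self, enc: EncodedCohort) -> np.ndarray:
        if self._vocab_size is None:
            raise RuntimeError("model is not fitted")
        if enc.vocab_size != self._vocab_size:
            raise ValueError("vocabulary mismatch between training and scoring")
        if len(enc) == 0:
            return np.zeros(0)
        return self.clf.predict_proba(_tabular(enc))[:, 1].astype(float)


class FunctionRiskModel:
    """Risk model wrapping a fixed function of the encoded inputs; used to
    freeze hand-specified outcome surfaces in algebra checks."""

    def __init__(self, fn):
        self.fn = fn

    def fit(self, enc, y):
        return self

    def predict_proba(self, enc: EncodedCohort) -> np.ndarray:
        return np.asarray([self.fn(enc.subset([i])) for i in range(len(enc))],
                          dtype=float).ravel()


MODEL_KINDS = {
    "transformer": TransformerRiskModel,
    "lstm": LSTMRiskModel,
    "logistic": LogisticRiskModel,
    "boosted_trees": BoostedTreesRiskModel,
}


def make_risk_model(kind: str, **kwargs):
    """Factory for the RiskModel contract: transformer, lstm, logistic or
    boosted_trees."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(MODEL_KINDS)}")
    if kind == "transformer":
        return TransformerRiskModel(TransformerConfig(**kwargs))
    if kind == "lstm":
        return LSTMRiskModel(LSTMConfig(**kwargs))
    return MODEL_KINDS[kind](**kwargs)


__all__ = [
    "TransformerRiskModel", "LSTMRiskModel", "LogisticRiskModel",
    "BoostedTreesRiskModel", "FunctionRiskModel", "make_risk_model",
    "TransformerConfig", "LSTMConfig", "XGBRegressor",
]
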