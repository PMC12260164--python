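"""X-learner meta-algorithm around any risk model.

Three stages per drug:

1. Outcome surfaces: fit mu0 on controls (T=0) and mu1 on treated (T=1),
   each predicting the 180-day outcome probability from the encoded
   sequence + statics (with the index drug's own tokens removed upstream).
2. Imputed individual effects: for treated patients
   D1_i = Y_i - mu0(x_i); for controls D0_j = mu1(x_j) - Y_j.
3. Effect surfaces and propensity: regress D1 on x over the treated
   (tau1), D0 on x over the controls (tau0), fit the propensity g(x), and
   combine

       tau_hat(x) = g(x) * tau0(x) + (1 - g(x)) * tau1(x)

   so each arm's effect surface is weighted by how unlike that arm the
   patient is — the standard X-learner weighting. The ATE is the uniform
   mean of tau_hat over the evaluation population (the propensity
   weighting already lives inside tau_hat); its dispersion is reported as
   the SD of the tau_hat distribution, with median and IQR alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from xgboost import XGBRegressor

from .encoding import EncodedCohort


@dataclass
class XLearnerConfig:
    min_arm_size: int = 25
    propensity_clip: float = 0.01
    seed: int = 0
    effect_n_estimators: int = 200
    effect_max_depth: int = 3
    effect_learning_rate: float = 0.05


def effect_features(enc: EncodedCohort) -> np.ndarray:
    """Tabular features for the effect surfaces and the propensity model:
    statics plus log(1 + token counts) per code-system-agnostic bag."""
    bag = enc.bag_of_tokens()
    total = bag.sum(axis=1, keepdims=True)
    return np.hstack([enc.static_features, np.log1p(bag), np.log1p(total)])


class _XGBEffectRegressor:
    def __init__(self, cfg: XLearnerConfig):
        self.reg = XGBRegressor(
            n_estimators=cfg.effect_n_estimators,
            max_depth=cfg.effect_max_depth,
            learning_rate=cfg.effect_learning_rate,
            random_state=cfg.seed, n_jobs=1, tree_method="hist", verbosity=0,
        )

    def fit(self, enc: EncodedCohort, d: np.ndarray):
        self.reg.fit(effect_features(enc), d)
        return self

    def predict(self, enc: EncodedCohort) -> np.ndarray:
        return self.reg.predict(effect_features(enc)).astype(float)


class _LogisticPropensity:
    def __init__(self, cfg: XLearnerConfig):
        self.clip = cfg.propensity_clip
        self.clf = LogisticRegression(max_iter=2000, random_state=cfg.seed)

    def fit(self, enc: EncodedCohort, t: np.ndarray):
        self.clf.fit(effect_features(enc), t)
        return self

    def predict(self, enc: EncodedCohort) -> np.ndarray:
        g = self.clf.predict_proba(effect_features(enc))[:, 1]
        return np.clip(g, self.clip, 1 - self.clip)


@dataclass
class ITEResult:
    patient_ids: np.ndarray
    tau_hat: np.ndarray
    g: np.ndarray
    tau0: np.ndarray
    tau1: np.ndarray
    drug: str = ""

    def summary(self) -> dict[str, float]:
        q1, med, q3 = np.percentile(self.tau_hat, [25, 50, 75])
        return {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3)}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "drug": self.drug,
                "tau_hat": self.tau_hat,
                "g": self.g,
                "tau0": self.tau0,
                "tau1": self.tau1,
            }
        )


@dataclass
class ATEResult:
    drug: str
    ate: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float
    n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class XLearner:
    """Fitted X-learner for one drug."""

    drug: str
    mu0: object
    mu1: object
    tau0: object
    tau1: object
    propensity: object
    config: XLearnerConfig
    imputed_d1: np.ndarray = field(default=None, repr=False)
    imputed_d0: np.ndarray = field(default=None, repr=False)


def impute_effects(y: np.ndarray, t: np.ndarray, mu0_hat: np.ndarray,
                   mu1_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stage-2 imputations: D1 over the treated, D0 over the controls.

    mu0_hat are control-surface predictions for the *treated* patients;
    mu1_hat are treated-surface predictions for the *controls*.
    """
    d1 = y[t == 1] - mu0_hat
    d0 = mu1_hat - y[t == 0]
    return d1, d0


def fit_xlearner(
    enc: EncodedCohort,
    t: np.ndarray,
    y: np.ndarray,
    base_model_factory,
    config: XLearnerConfig | None = None,
    drug: str = "",
    tau_regressor_factory=None,
    propensity_factory=None,
) -> XLearner:
    """Fit all five sub-models.

    ``base_model_factory()`` must return a fresh RiskModel for each outcome
    surface. Frozen surfaces (for algebra checks) can be supplied through
    the optional factories.
    """
    config = config or XLearnerConfig()
    t = np.asarray(t).astype(int).ravel()
    y = np.asarray(y).astype(int).ravel()
    if len(enc) != len(t) or len(enc) != len(y):
        raise ValueError("enc, t and y must be row-aligned")
    idx1, idx0 = np.where(t == 1)[0], np.where(t == 0)[0]
    for name, idx in (("treated", idx1), ("control", idx0)):
        if len(idx) < config.min_arm_size:
            raise ValueError(
                f"{name} arm has {len(idx)} patients "
                f"(< min_arm_size={config.min_arm_size})"
            )
    enc1, enc0 = enc.subset(idx1), enc.subset(idx0)

    mu0 = base_model_factory().fit(enc0, y[idx0])
    mu1 = base_model_factory().fit(enc1, y[idx1])

    d1, d0 = impute_effects(y, t, mu0.predict_proba(enc1), mu1.predict_proba(enc0))

    make_tau = tau_regressor_factory or (lambda: _XGBEffectRegressor(config))
    tau1 = make_tau().fit(enc1, d1)
    tau0 = make_tau().fit(enc0, d0)
    make_g = propensity_factory or (lambda: _LogisticPropensity(config))
    g = make_g().fit(enc, t)

    return XLearner(drug, mu0, mu1, tau0, tau1, g, config, d1, d0)


def estimate_ite(xl: XLearner, enc: EncodedCohort) -> ITEResult:
    """Per-patient tau_hat = g * tau0 + (1 - g) * tau1, clipped to [-1, 1]."""
    g = np.asarray(xl.propensity.predict(enc), dtype=float)
    tau0 = np.asarray(xl.tau0.predict(enc), dtype=float)
    tau1 = np.asarray(xl.tau1.predict(enc), dtype=float)
    tau_hat = np.clip(g * tau0 + (1.0 - g) * tau1, -1.0, 1.0)
    return ITEResult(enc.patient_ids, tau_hat, g, tau0, tau1, xl.drug)


def estimate_ate(ite: ITEResult, weighting: str = "uniform") -> ATEResult:
    """Population ATE: the mean of tau_hat (the propensity weighting is
    already inside tau_hat), with SD/median/IQR dispersion."""
    if weighting not in ("uniform", "propensity_combination"):
        raise ValueError("weighting must be 'uniform' or 'propensity_combination'")
    if len(ite.tau_hat) == 0:
        raise ValueError("cannot average an empty ITE set")
    s = ite.summary()
    return ATEResult(
        ite.drug,
        float(np.mean(ite.tau_hat)),
        float(np.std(ite.tau_hat)),
        s["median"],
        s["iqr_low"],
        s["iqr_high"],
        len(ite.tau_hat),
    )
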