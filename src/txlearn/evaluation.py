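"""Predictive and causal evaluation.

* 5-fold cross-validated classification metrics (accuracy, F1, AUPRC),
  with the vocabulary and static scaler rebuilt inside each training fold.
* Paired drug-vs-drug ITE comparisons: Wilcoxon signed-rank (zeros
  dropped, mid-ranks for ties, continuity-corrected normal approximation
  for larger samples, exact enumeration for small ones), effect size
  r = |Z| / sqrt(n nonzero pairs) banded as Small / Moderate / Large, and
  Cohen's d with an asymptotic confidence interval.
* Subgroup ITE summaries across age bands, sex and SIMD deciles.
* Ground-truth recovery metrics (bias, RMSE, PEHE, Spearman rank
  correlation) for simulation studies.

AUPRC is trapezoidal integration over the step precision-recall curve,
anchored at (recall 0, precision at the strictest threshold); for a
constant no-skill score this reduces to the outcome prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold

from .cohort import age_band
from .encoding import StaticScaler, build_vocabulary, encode_cohort
from .records import LabeledPatient, WaveDefinition

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# classification metrics
# --------------------------------------------------------------------------


def pr_curve_points(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at every distinct score threshold, predicting
    positive when score >= threshold, ordered by increasing recall."""
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.sum() == 0:
        raise ValueError("AUPRC is undefined without positive labels")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    npred = np.arange(1, len(y) + 1)
    # last index of each distinct threshold block
    last = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    recall = tp[last] / y.sum()
    precision = tp[last] / npred[last]
    return recall, precision


def auprc(y_true, scores) -> float:
    """Area under the precision-recall curve by trapezoidal integration,
    anchored at (0, precision of the strictest threshold)."""
    recall, precision = pr_curve_points(y_true, scores)
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(p, r))


@dataclass
class ClassificationMetrics:
    accuracy: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    auprc: list[float] = field(default_factory=list)

    def add(self, acc: float, f1v: float, ap: float) -> None:
        self.accuracy.append(acc)
        self.f1.append(f1v)
        self.auprc.append(ap)

    def mean_sd(self) -> dict[str, tuple[float, float]]:
        return {
            m: (float(np.mean(v)), float(np.std(v)))
            for m, v in (("accuracy", self.accuracy), ("f1", self.f1),
                         ("auprc", self.auprc))
        }

    def frame(self, model: str = "", wave: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": model,
                "wave": wave,
                "fold": np.arange(len(self.accuracy)),
                "accuracy": self.accuracy,
                "f1": self.f1,
                "auprc": self.auprc,
            }
        )


def score_fold(y_true, scores, threshold: float = 0.5) -> tuple[float, float, float]:
    y_pred = (np.asarray(scores) >= threshold).astype(int)
    return (
        float(accuracy_score(y_true, y_pred)),
        float(f1_score(y_true, y_pred, zero_division=0)),
        auprc(y_true, scores),
    )


def cross_validate(
    cohort: list[LabeledPatient],
    wave: WaveDefinition,
    model_factory,
    k: int = 5,
    seed: int = 0,
    max_len: int = 64,
    min_count: int = 1,
    threshold: float = 0.5,
    max_redraws: int = 5,
) -> ClassificationMetrics:
    """Stratified k-fold CV of a risk model on a labelled cohort.

    The vocabulary and the static scaler are rebuilt on each fold's
    training patients only, so fold-test codes unseen in training map
    to UNK.
    """
    y = np.array([lp.y for lp in cohort])
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    metrics = ClassificationMetrics()
    for attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 and y[te].sum() > 0
               for tr, te in splits):
            break
        logger.warning("single-class fold drawn; re-drawing folds")
    else:
        raise ValueError("could not draw k folds with both classes present")
    for tr, te in splits:
        train = [cohort[i] for i in tr]
        test = [cohort[i] for i in te]
        vocab = build_vocabulary(train, min_count=min_count, wave=wave)
        scaler = StaticScaler().fit(train)
        enc_tr = encode_cohort(train, wave, vocab, max_len, scaler)
        enc_te = encode_cohort(test, wave, vocab, max_len, scaler)
        model = model_factory()
        model.fit(enc_tr, y[tr])
        scores = model.predict_proba(enc_te)
        metrics.add(*score_fold(y[te], scores, threshold))
    return metrics


# --------------------------------------------------------------------------
# paired ITE comparison
# --------------------------------------------------------------------------

EFFECT_SIZE_BANDS = ((0.5, "Large"), (0.3, "Moderate"), (0.1, "Small"))


def effect_size_magnitude(r: float) -> str:
    """Band an effect size r: Small [0.1, 0.3), Moderate [0.3, 0.5),
    Large [0.5, inf); below 0.1 is Negligible."""
    if r < 0:
        raise ValueError("effect size r must be non-negative")
    for cut, label in EFFECT_SIZE_BANDS:
        if r >= cut:
            return label
    return "Negligible"


def wilcoxon_signed_rank(
    diffs: np.ndarray, exact_max_n: int = 25
) -> tuple[float, float, float, int]:
    """Signed-rank test on paired differences.

    Zero differences are dropped; ties get mid-ranks. For n <= exact_max_n
    (and no ties) the exact null distribution is used for the p-value;
    otherwise the normal approximation with tie correction and continuity
    correction. Returns (W_plus, Z, p, n_nonzero). Z always comes from the
    normal approximation so the effect size r = |Z|/sqrt(n) is defined
    uniformly.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction to the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        return w_plus, 0.0, 1.0, n
    cc = 0.5 * np.sign(w_plus - mean_w)
    z = (w_plus - mean_w - cc) / np.sqrt(var_w)
    has_ties = len(tie_counts) < n
    if n <= exact_max_n and not has_ties:
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
        p = float(res.pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, float(z), min(p, 1.0), n


def cohens_d(a: np.ndarray, b: np.ndarray, alpha: float = 0.05):
    """Standardised mean difference (pooled SD) with an asymptotic CI."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0:
        return 0.0, (0.0, 0.0)
    d = (a.mean() - b.mean()) / sp
    se = np.sqrt((na + nb) / (na * nb) + d * d / (2.0 * (na + nb)))
    zc = stats.norm.ppf(1 - alpha / 2)
    return float(d), (float(d - zc * se), float(d + zc * se))


@dataclass
class PairedComparisonResult:
    drug_a: str
    drug_b: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    w_statistic: float
    z: float
    p_value: float
    r: float
    magnitude: str
    cohens_d: float
    d_ci: tuple[float, float]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug_a": self.drug_a,
                    "drug_b": self.drug_b,
                    "median_a": self.median_a,
                    "iqr_a_low": self.iqr_a[0],
                    "iqr_a_high": self.iqr_a[1],
                    "median_b": self.median_b,
                    "iqr_b_low": self.iqr_b[0],
                    "iqr_b_high": self.iqr_b[1],
                    "cohens_d": self.cohens_d,
                    "d_ci_low": self.d_ci[0],
                    "d_ci_high": self.d_ci[1],
                    "r": self.r,
                    "magnitude": self.magnitude,
                }
            ]
        )


def paired_ite_comparison(
    ite_a: np.ndarray,
    ite_b: np.ndarray,
    drug_a: str = "A",
    drug_b: str = "B",
) -> PairedComparisonResult:
    """Compare two drugs' ITE vectors over the same patients, same order."""
    a = np.asarray(ite_a, float).ravel()
    b = np.asarray(ite_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired ITE vectors must have equal length")
    w, z, p, n_nonzero = wilcoxon_signed_rank(a - b)
    r = abs(z) / np.sqrt(n_nonzero) if n_nonzero else 0.0
    d, ci = cohens_d(a, b)
    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return PairedComparisonResult(
        drug_a, drug_b,
        float(qa[1]), (float(qa[0]), float(qa[2])),
        float(qb[1]), (float(qb[0]), float(qb[2])),
        w, z, p, float(r), effect_size_magnitude(float(r)), d, ci,
    )


# --------------------------------------------------------------------------
# subgroup summaries
# --------------------------------------------------------------------------


def subgroup_ite_summaries(
    ite_values: np.ndarray,
    patients,
    covariate: str = "age_band",
) -> pd.DataFrame:
    """Median/IQR (and a density bandwidth) of ITEs per subgroup of one
    covariate, plus the maximum pairwise difference of subgroup medians
    (the between-group dispersion statistic)."""
    getters = {
        "age_band": lambda p: age_band(p.age),
        "sex": lambda p: p.sex,
        "simd": lambda p: p.simd_decile,
    }
    if covariate not in getters:
        raise ValueError(f"unknown covariate {covariate!r}")
    get = getters[covariate]
    tau = np.asarray(ite_values, float).ravel()
    if len(tau) != len(patients):
        raise ValueError("ITE vector and patient list must align")
    groups: dict = {}
    for v, lp in zip(tau, patients):
        p = lp.patient if isinstance(lp, LabeledPatient) else lp
        groups.setdefault(get(p), []).append(v)
    rows = []
    medians = []
    for level in sorted(groups, key=str):
        vals = np.array(groups[level])
        if len(vals) == 0:
            logger.warning("empty subgroup %s omitted", level)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        # Silverman bandwidth: the scale a kernel density plot would use
        bw = 0.9 * min(vals.std(ddof=1) if len(vals) > 1 else 0.0,
                       (q3 - q1) / 1.349 if q3 > q1 else np.inf)
        bw = 0.0 if not np.isfinite(bw) else bw * len(vals) ** (-0.2)
        medians.append(med)
        rows.append((covariate, str(level), len(vals), med, q1, q3, bw))
    df = pd.DataFrame(
        rows, columns=["covariate", "level", "n", "median", "iqr_low",
                       "iqr_high", "kde_bandwidth"]
    )
    df.attrs["median_dispersion"] = (
        float(max(medians) - min(medians)) if medians else 0.0
    )
    return df


def plot_subgroup_densities(ite_values, patients, covariate="age_band",
                            path=None):
    """Conditional density plot of the ITE distribution per subgroup level
    (one curve per level); written to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    getters = {
        "age_band": lambda p: age_band(p.age),
        "sex": lambda p: p.sex,
        "simd": lambda p: p.simd_decile,
    }
    get = getters[covariate]
    tau = np.asarray(ite_values, float).ravel()
    groups: dict = {}
    for v, lp in zip(tau, patients):
        p = lp.patient if isinstance(lp, LabeledPatient) else lp
        groups.setdefault(get(p), []).append(v)
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(tau.min() - 0.02, tau.max() + 0.02, 200)
    for level in sorted(groups, key=str):
        vals = np.asarray(groups[level])
        if len(vals) < 2 or np.ptp(vals) == 0:
            continue
        kde = stats.gaussian_kde(vals)
        ax.plot(grid, kde(grid), label=str(level))
    ax.set_xlabel("individual treatment effect (risk difference)")
    ax.set_ylabel("density")
    ax.legend(title=covariate, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# --------------------------------------------------------------------------
# ground-truth recovery
# --------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    bias: float
    rmse: float
    pehe: float
    rank_correlation: float


def recovery_report(tau_hat: np.ndarray, tau_star: np.ndarray) -> RecoveryMetrics:
    """Simulation-only scorecard of estimated vs true individual effects."""
    th = np.asarray(tau_hat, float).ravel()
    ts = np.asarray(tau_star, float).ravel()
    if th.shape != ts.shape or len(th) == 0:
        raise ValueError("tau_hat and ground truth must be equal-length, non-empty")
    err = th - ts
    bias = float(err.mean())
    pehe = float(np.sqrt((err**2).mean()))
    if np.ptp(ts) == 0 or np.ptp(th) == 0:
        rho = 0.0 if np.ptp(ts) or np.ptp(th) else 1.0
    else:
        rho = float(stats.spearmanr(th, ts).statistic)
    return RecoveryMetrics(bias, pehe, pehe, rho)
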