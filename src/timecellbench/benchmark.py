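"""Ground-truth benchmarking: confusion metrics, Otsu thresholding,
score/prediction correlations, ROC analysis, concordance and
parameter-sensitivity slopes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ALGORITHMS",
    "SCORE_COLUMNS",
    "ConfusionCounts",
    "MetricSet",
    "RocResult",
    "concordance_classify",
    "concordance_sweep",
    "confusion",
    "metrics",
    "otsu_threshold",
    "parameter_sensitivity",
    "prediction_correlations",
    "roc_and_threshold",
    "score_correlations",
]

# Fixed column order for the ten classifiers and four base scores.
ALGORITHMS = ("tiMean", "tiBoot", "tiBoth", "tiMean-O", "tiBase-O",
              "r2bMean", "r2bBoot", "r2bBase-O", "peqBase", "peqBase-O")
BOOTSTRAP_ALGORITHMS = ("tiMean", "tiBoot", "tiBoth", "r2bMean", "r2bBoot")
SCORE_COLUMNS = ("tiMean_score", "tiBase_score", "r2bBase_score", "peqBase_score")


# ---------------------------------------------------------------------------
# Confusion counts and derived metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred, truth) -> ConfusionCounts:
    """Count true/false positives/negatives of a Boolean prediction list."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


@dataclass
class MetricSet:
    recall: float
    precision: float
    f1: float
    accuracy: float
    degenerate: bool = False   # some denominator was zero; affected metrics are 0


def metrics(c: ConfusionCounts) -> MetricSet:
    """Recall, precision, F1 (harmonic mean) and accuracy from counts.

    Zero denominators yield a metric of 0 with the ``degenerate`` flag set,
    so batch outputs never carry NaN.
    """
    degenerate = False

    def _ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    recall = _ratio(c.tp, c.tp + c.fn)
    precision = _ratio(c.tp, c.tp + c.fp)
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate = True
    accuracy = _ratio(c.tp + c.tn, c.total)
    return MetricSet(recall=recall, precision=precision, f1=f1,
                     accuracy=accuracy, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Otsu's threshold
# ---------------------------------------------------------------------------

def otsu_threshold(scores, n_bins: int = 256) -> float:
    """Between-class-variance-maximising threshold of a score distribution.

    Scores are min-max normalised to [0, 1] and histogrammed into
    ``n_bins`` bins; the threshold maximising the between-class variance
    is returned on the original scale.  A zero-variance input returns
    ``+inf`` (every score classifies negative): no threshold separates a
    constant distribution.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    lo, hi = scores.min(), scores.max()
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("scores must be finite")
    if hi == lo:
        return np.inf
    norm = (scores - lo) / (hi - lo)
    hist, edges = np.histogram(norm, bins=n_bins, range=(0.0, 1.0))
    w = hist / hist.sum()
    mu = (edges[:-1] + edges[1:]) / 2.0
    omega0 = np.cumsum(w)
    omega1 = 1.0 - omega0
    m0 = np.cumsum(w * mu)
    m_total = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / omega0
        mu1 = (m_total - m0) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    k = int(np.argmax(sigma_b[:-1]))  # last bin cannot split the data
    t = edges[k + 1]                  # classify: score > threshold
    return float(lo + t * (hi - lo))


# ---------------------------------------------------------------------------
# Correlation matrices
# ---------------------------------------------------------------------------

def score_correlations(table: pd.DataFrame,
                       columns=SCORE_COLUMNS) -> pd.DataFrame:
    """Pairwise Pearson correlations between pooled analog score columns."""
    return table.loc[:, list(columns)].astype(float).corr(method="pearson")


def prediction_correlations(table: pd.DataFrame,
                            columns=ALGORITHMS) -> pd.DataFrame:
    """Pairwise Pearson correlations between Boolean prediction lists
    (cast to 0/1).  Zero-variance columns yield NaN entries."""
    return table.loc[:, list(columns)].astype(float).corr(method="pearson")


# ---------------------------------------------------------------------------
# ROC / logistic thresholding
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    best_threshold: float        # Youden's J maximiser over score thresholds
    glm_params: np.ndarray       # logistic fit: intercept, slope on score


def roc_and_threshold(scores, truth) -> RocResult:
    """ROC curve over all score thresholds, AUC and the ideal threshold.

    The truth labels are regressed on the score with a binomial GLM
    (logistic link); the reported best threshold maximises TPR - FPR.
    """
    from sklearn.metrics import roc_curve, auc as _auc
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(truth.astype(int), scores)
    area = float(_auc(fpr, tpr))
    best = float(thr[np.argmax(tpr - fpr)])
    X = sm.add_constant(scores)
    glm = sm.GLM(truth.astype(float), X, family=sm.families.Binomial())
    params = np.asarray(glm.fit().params)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=area,
                     best_threshold=best, glm_params=params)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance_classify(pred_table, threshold: int) -> np.ndarray:
    """Consensus call: positive iff >= ``threshold`` algorithms agree.

    ``pred_table`` is an ``n_algorithms x n_cells`` Boolean array or a
    DataFrame whose algorithm columns follow :data:`ALGORITHMS`.
    """
    if isinstance(pred_table, pd.DataFrame):
        votes = pred_table.loc[:, list(ALGORITHMS)].to_numpy(dtype=bool).sum(axis=1)
    else:
        arr = np.asarray(pred_table, dtype=bool)
        votes = arr.sum(axis=0)
    n_algs = len(ALGORITHMS) if isinstance(pred_table, pd.DataFrame) else arr.shape[0]
    if not (1 <= threshold <= n_algs):
        raise ValueError(f"threshold must be in [1, {n_algs}]")
    return votes >= threshold


def concordance_sweep(pred_table, truth) -> pd.DataFrame:
    """F1/precision/recall of the consensus call at every threshold 1..N."""
    if isinstance(pred_table, pd.DataFrame):
        n_algs = len(ALGORITHMS)
    else:
        n_algs = np.asarray(pred_table).shape[0]
    rows = []
    for k in range(1, n_algs + 1):
        m = metrics(confusion(concordance_classify(pred_table, k), truth))
        rows.append({"threshold": k, "f1": m.f1, "precision": m.precision,
                     "recall": m.recall, "accuracy": m.accuracy})
    return pd.DataFrame(rows)


def best_concordance_threshold(pred_table, truth) -> int:
    """Concordance threshold maximising F1 (lowest threshold wins ties)."""
    sweep = concordance_sweep(pred_table, truth)
    return int(sweep.loc[sweep["f1"].idxmax(), "threshold"])


# ---------------------------------------------------------------------------
# Parameter sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    parameter: str
    algorithm: str
    levels: np.ndarray
    slope: float
    p_value: float
    rmse: float
    significant: bool           # p < 0.01, per-slope test


def parameter_sensitivity(results: pd.DataFrame, parameter: str = "",
                          alpha: float = 0.01) -> list[SensitivityResult]:
    """OLS slope of F1 against parameter level, per algorithm.

    ``results`` needs columns ``algorithm``, ``level``, ``f1`` (one row per
    algorithm x level x seed).  Requires >= 2 distinct levels and >= 2
    replicates per level.  The two-sided p-value tests slope == 0; no
    multiple-testing correction is applied.
    """
    import statsmodels.api as sm

    required = {"algorithm", "level", "f1"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    out: list[SensitivityResult] = []
    for alg, grp in results.groupby("algorithm", sort=False):
        levels = np.sort(grp["level"].unique())
        if levels.size < 2:
            raise ValueError(f"algorithm {alg!r}: need >= 2 parameter levels")
        if grp.groupby("level").size().min() < 2:
            raise ValueError(f"algorithm {alg!r}: need >= 2 replicates per level")
        X = sm.add_constant(grp["level"].to_numpy(dtype=float))
        fit = sm.OLS(grp["f1"].to_numpy(dtype=float), X).fit()
        slope = float(fit.params[1])
        p = float(fit.pvalues[1])
        rmse = float(np.sqrt(np.mean(fit.resid ** 2)))
        out.append(SensitivityResult(parameter=parameter, algorithm=str(alg),
                                     levels=levels, slope=slope, p_value=p,
                                     rmse=rmse, significant=p < alpha))
    return out
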