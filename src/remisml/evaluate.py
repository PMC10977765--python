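"""Performance metrics pooled across imputations by Rubin's rules.

Seven metrics are reported per model: sensitivity, specificity, PPV, NPV,
accuracy, balanced accuracy and ROC-AUC, with remitter as the positive
class.  For the internal-CV (training) role, repeat-level metrics are
averaged within each imputation, and the M per-imputation estimates are
combined by Rubin's rules: W = mean within-imputation variance, B =
between-imputation sample variance, T = W + (1 + 1/M) B, se = sqrt(T), Wald
95% CI = estimate +/- 1.96 se.  For the external (testing) role the SE of
proportion-type metrics is the sd of the M values over sqrt(M), and the AUC
uses bootstrap within-imputation variance (1000 resamples) inside Rubin's
rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "PooledEstimate",
    "confusion_metrics",
    "auc",
    "rubin_pool",
    "testing_se",
    "bootstrap_auc_se",
    "performance_table",
    "render_performance",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "balanced_accuracy", "auc")


class EvaluationError(ValueError):
    pass


@dataclass
class PooledEstimate:
    """Rubin-combined estimate with within/between/total variance."""

    estimate: float
    W: float
    B: float
    T: float
    se: float
    ci95: tuple[float, float]
    M: int


def confusion_metrics(labels: np.ndarray, hard_predictions: np.ndarray) -> dict[str, float]:
    """The six confusion-matrix metrics; remitter (1) is the positive class.

    A zero denominator (e.g. no predicted positives for PPV) yields NaN for
    that metric rather than 0.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(hard_predictions, dtype=float)
    if y.shape != p.shape:
        raise EvaluationError("labels and predictions are misaligned")
    tp = float(np.sum((y == 1) & (p == 1)))
    tn = float(np.sum((y == 0) & (p == 0)))
    fp = float(np.sum((y == 0) & (p == 1)))
    fn = float(np.sum((y == 1) & (p == 0)))

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Rank-based ROC-AUC; tied scores contribute 1/2 per pair."""
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUC undefined for single-class labels")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def rubin_pool(estimates, variances, M: int | None = None) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise EvaluationError("estimates and variances must have equal length")
    if M is None:
        M = len(est)
    if M < 2 or len(est) != M:
        raise EvaluationError("Rubin pooling needs M >= 2 matching inputs")
    q = float(np.mean(est))
    W = float(np.mean(var))
    B = float(np.var(est, ddof=1))
    T = W + (1.0 + 1.0 / M) * B
    se = math.sqrt(T)
    return PooledEstimate(
        estimate=q, W=W, B=B, T=T, se=se, ci95=(q - 1.96 * se, q + 1.96 * se), M=M
    )


def testing_se(values, mode: str = "sqrt_n") -> float:
    """Spread of the M per-imputation testing metrics.

    ``sqrt_n`` (default) is the standard error of the mean, sd/sqrt(M); the
    ``n`` mode divides the sd by M instead.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise EvaluationError("need at least 2 values")
    sd = float(np.std(v, ddof=1))
    if mode == "sqrt_n":
        return sd / math.sqrt(len(v))
    if mode == "n":
        return sd / len(v)
    raise EvaluationError("mode must be 'sqrt_n' or 'n'")


def bootstrap_auc_se(
    labels, probabilities, n_boot: int = 1000, seed: int = 0
) -> float:
    """SD of the AUC over participant-level bootstrap resamples.

    Resamples that draw a single class are redrawn; seed-deterministic.
    """
    if n_boot < 2:
        raise EvaluationError("n_boot must be >= 2")
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUC undefined for single-class labels")
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) == 2:
                break
        else:  # pragma: no cover - pathological label composition
            raise EvaluationError("could not draw a two-class bootstrap resample")
        aucs[b] = roc_auc_score(y[idx], p[idx])
    return float(np.std(aucs, ddof=1))


# --------------------------------------------------------------------------
# pooled performance tables
# --------------------------------------------------------------------------

def _metric_denominator(metric: str, y: np.ndarray, hard: np.ndarray) -> float:
    n = len(y)
    if metric == "sensitivity":
        return float(np.sum(y == 1))
    if metric == "specificity":
        return float(np.sum(y == 0))
    if metric == "ppv":
        return float(np.sum(hard == 1))
    if metric == "npv":
        return float(np.sum(hard == 0))
    return float(n)


def _within_variance(metric: str, value: float, y: np.ndarray, hard: np.ndarray) -> float:
    """Binomial within-imputation variance p(1-p)/n for proportion metrics."""
    if math.isnan(value):
        return float("nan")
    if metric == "balanced_accuracy":
        vs = _within_variance("sensitivity", value, y, hard)
        vp = _within_variance("specificity", value, y, hard)
        return (vs + vp) / 4.0
    den = _metric_denominator(metric, y, hard)
    if den <= 0:
        return float("nan")
    return value * (1.0 - value) / den


def performance_table(
    prediction_set: pd.DataFrame,
    role: str,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
    testing_se_mode: str = "sqrt_n",
) -> pd.DataFrame:
    """One row per model x metric with the pooled estimate, SE and 95% CI.

    ``role='outer_test'`` pools internal-CV results: metrics are computed per
    (imputation, repeat) over that repeat's out-of-fold predictions, averaged
    over repeats within imputation, then Rubin-pooled across imputations.
    ``role='external_test'`` pools the per-imputation external predictions
    with sd/sqrt(M) SEs (bootstrap-within-variance Rubin pooling for AUC).
    Imputations on which a metric is undefined are excluded from its pooling.
    """
    sub = prediction_set[prediction_set["role"] == role]
    if sub.empty:
        raise EvaluationError(f"no predictions with role {role!r}")
    rows = []
    for model, df_model in sub.groupby("model", sort=False):
        per_imp: dict[str, list[float]] = {m: [] for m in METRICS}
        per_imp_var: dict[str, list[float]] = {m: [] for m in METRICS}
        for m, df_imp in df_model.groupby("imputation"):
            rep_metrics: dict[str, list[float]] = {k: [] for k in METRICS}
            for _, df_rep in df_imp.groupby("repeat"):
                y = df_rep["y_true"].to_numpy(dtype=float)
                prob = df_rep["prob"].to_numpy(dtype=float)
                hard = (prob >= threshold).astype(float)
                cm = confusion_metrics(y, hard)
                for k, v in cm.items():
                    rep_metrics[k].append(v)
                try:
                    rep_metrics["auc"].append(auc(y, prob))
                except EvaluationError:
                    rep_metrics["auc"].append(float("nan"))
            # participant-level aggregation for within-imputation variance
            mean_prob = df_imp.groupby("participant")[["prob", "y_true"]].mean()
            y_all = mean_prob["y_true"].to_numpy(dtype=float)
            hard_all = (mean_prob["prob"].to_numpy(dtype=float) >= threshold).astype(float)
            for k in METRICS:
                vals = np.asarray(rep_metrics[k], dtype=float)
                est = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
                per_imp[k].append(est)
                if k == "auc":
                    if math.isnan(est) or len(np.unique(y_all)) < 2:
                        per_imp_var[k].append(float("nan"))
                    else:
                        se_b = bootstrap_auc_se(
                            y_all, mean_prob["prob"].to_numpy(dtype=float),
                            n_boot=n_boot, seed=seed,
                        )
                        per_imp_var[k].append(se_b**2)
                else:
                    per_imp_var[k].append(_within_variance(k, est, y_all, hard_all))
        for k in METRICS:
            est = np.asarray(per_imp[k], dtype=float)
            var = np.asarray(per_imp_var[k], dtype=float)
            ok = ~np.isnan(est)
            if ok.sum() < 2:
                rows.append((model, k, float(np.nanmean(est)), float("nan"),
                             float("nan"), float("nan")))
                continue
            est, var = est[ok], var[ok]
            if role == "external_test" and k != "auc":
                point = float(np.mean(est))
                se = testing_se(est, mode=testing_se_mode)
            else:
                var = np.where(np.isnan(var), np.nanmean(var) if not np.all(np.isnan(var)) else 0.0, var)
                pooled = rubin_pool(est, var, M=len(est))
                point, se = pooled.estimate, pooled.se
            rows.append((model, k, point, se, point - 1.96 * se, point + 1.96 * se))
    return pd.DataFrame(
        rows, columns=["model", "metric", "estimate", "se", "ci_lo", "ci_hi"]
    )


def render_performance(table: pd.DataFrame) -> str:
    """Fixed-width 'estimate (se)' rendering, one row per model."""
    wide = table.pivot(index="model", columns="metric", values=["estimate", "se"])
    lines = ["model".ljust(22) + "".join(m.ljust(18) for m in METRICS)]
    for model in wide.index:
        cells = []
        for m in METRICS:
            est = wide.loc[model, ("estimate", m)]
            se = wide.loc[model, ("se", m)]
            cells.append(f"{est:.4f} ({se:.4f})".ljust(18))
        lines.append(str(model).ljust(22) + "".join(cells))
    return "\n".join(lines)
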