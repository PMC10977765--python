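"""Imputation-averaged subgroup ROC curves and k-sample ROC comparison.

For each subgroup, a ROC curve is computed per imputed dataset on a shared
descending threshold grid, then sensitivity and specificity are averaged
across imputations at fixed thresholds, along with the mean AUC.  Groups
are compared per imputation with an L1-type statistic — the sum over groups
of the integrated absolute difference between the group ROC and the pooled
ROC — whose null distribution comes from permuting group membership; the
resulting M dependent p-values are combined with the harmonic mean p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "AveragedROC",
    "HMPResult",
    "averaged_roc",
    "compare_roc_k",
    "harmonic_mean_p",
    "subgroup_roc_report",
    "default_threshold_grid",
]

logger = logging.getLogger(__name__)


class ROCStatsError(ValueError):
    pass


def default_threshold_grid(step: float = 1e-4) -> np.ndarray:
    """Descending thresholds 1 -> 0, prefixed with an above-one sentinel.

    The sentinel guarantees the (0, 0) corner of the curve even when some
    predicted probability equals 1.
    """
    grid = np.arange(1.0, -step / 2, -step)
    return np.concatenate(([1.0 + step], grid))


@dataclass
class AveragedROC:
    """Mean ROC across imputations at fixed thresholds for one subgroup."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    subgroup: str = ""
    n_imputations: int = 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fpr": 1.0 - self.specificity,
                "sensitivity": self.sensitivity,
            }
        )


@dataclass
class HMPResult:
    """Harmonic-mean combination of L dependent p-values."""

    p_values: np.ndarray
    weights: np.ndarray
    combined: float


def _sens_spec_at(labels: np.ndarray, probs: np.ndarray, thresholds: np.ndarray):
    pred = probs[None, :] >= thresholds[:, None]
    pos = labels == 1
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    tp = (pred & pos[None, :]).sum(axis=1)
    fp = (pred & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos if n_pos else np.full(len(thresholds), np.nan)
    spec = (n_neg - fp) / n_neg if n_neg else np.full(len(thresholds), np.nan)
    return sens, spec


def averaged_roc(
    labels_per_imputation: Sequence[np.ndarray],
    probs_per_imputation: Sequence[np.ndarray],
    thresholds: np.ndarray | None = None,
    subgroup: str = "",
) -> AveragedROC:
    """Average per-imputation ROC curves at fixed thresholds.

    Per imputation, sensitivity and specificity are computed at every grid
    threshold (predicted positive when probability >= threshold) along with
    the AUC; curves and AUCs are then averaged across imputations.
    Imputations whose labels contain a single class are skipped with a
    warning.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    sens_list, spec_list, aucs = [], [], []
    for m, (y, p) in enumerate(zip(labels_per_imputation, probs_per_imputation)):
        y = np.asarray(y, dtype=float)
        p = np.asarray(p, dtype=float)
        if len(np.unique(y)) < 2:
            logger.warning("subgroup %r: single-class labels in imputation %d; skipped", subgroup, m)
            continue
        sens, spec = _sens_spec_at(y, p, thresholds)
        sens_list.append(sens)
        spec_list.append(spec)
        aucs.append(roc_auc_score(y, p))
    if not aucs:
        raise ROCStatsError(f"subgroup {subgroup!r} has no imputation with both classes")
    return AveragedROC(
        thresholds=thresholds,
        sensitivity=np.mean(sens_list, axis=0),
        specificity=np.mean(spec_list, axis=0),
        auc=float(np.mean(aucs)),
        subgroup=subgroup,
        n_imputations=len(aucs),
    )


# --------------------------------------------------------------------------
# k-sample ROC comparison (L1-type statistic, permutation null)
# --------------------------------------------------------------------------

def _roc_on_grid(labels: np.ndarray, scores: np.ndarray, fpr_grid: np.ndarray) -> np.ndarray:
    """Empirical ROC as a right-continuous step function on an FPR grid."""
    fpr, tpr, _ = roc_curve(labels, scores)
    idx = np.searchsorted(fpr, fpr_grid, side="right") - 1
    return tpr[np.clip(idx, 0, len(tpr) - 1)]


def _l1_statistic(groups, fpr_grid: np.ndarray) -> float:
    all_y = np.concatenate([y for y, _ in groups])
    all_s = np.concatenate([s for _, s in groups])
    pooled = _roc_on_grid(all_y, all_s, fpr_grid)
    stat = 0.0
    for y, s in groups:
        stat += float(np.trapezoid(np.abs(_roc_on_grid(y, s, fpr_grid) - pooled), fpr_grid))
    return stat


def compare_roc_k(
    groups: Sequence[tuple[np.ndarray, np.ndarray]],
    n_permutations: int = 999,
    seed: int = 0,
    grid_points: int = 201,
) -> tuple[float, float]:
    """Permutation test for equality of k >= 2 independent ROC curves.

    The statistic sums, over groups, the integrated absolute difference on
    the FPR grid between the group ROC and the ROC pooled over all groups.
    Group membership is permuted among participants (label-score pairs stay
    together); the p-value uses the add-one convention
    (1 + #{permuted >= observed}) / (1 + n_permutations).

    Returns (statistic, p_value).
    """
    if len(groups) < 2:
        raise ROCStatsError("need k >= 2 groups")
    groups = [(np.asarray(y, dtype=float), np.asarray(s, dtype=float)) for y, s in groups]
    for y, _ in groups:
        if len(np.unique(y)) < 2:
            raise ROCStatsError("every group needs both classes")
    fpr_grid = np.linspace(0.0, 1.0, grid_points)
    observed = _l1_statistic(groups, fpr_grid)

    sizes = [len(y) for y, _ in groups]
    all_y = np.concatenate([y for y, _ in groups])
    all_s = np.concatenate([s for _, s in groups])
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(all_y))
        ok = True
        perm_groups = []
        for g in range(len(sizes)):
            idx = perm[bounds[g]:bounds[g + 1]]
            y_g = all_y[idx]
            if len(np.unique(y_g)) < 2:
                ok = False
                break
            perm_groups.append((y_g, all_s[idx]))
        if not ok:
            count += 1  # degenerate permutation treated as extreme (conservative)
            continue
        if _l1_statistic(perm_groups, fpr_grid) >= observed:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return observed, float(p)


def harmonic_mean_p(p_values, weights=None) -> HMPResult:
    """Combined p = (sum w_i) / (sum w_i / p_i); equal weights by default.

    With w_i = 1/L this is the harmonic mean of the p-values.  The raw
    combination is reported without the asymptotically-exact tail
    correction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ROCStatsError("p_values must be a non-empty 1-D sequence")
    if np.any(p <= 0) or np.any(p > 1):
        raise ROCStatsError("all p-values must lie in (0, 1]")
    if weights is None:
        w = np.full(len(p), 1.0 / len(p))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w < 0):
            raise ROCStatsError("weights must be non-negative and match p_values")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ROCStatsError("weights must sum to 1")
    combined = float(w.sum() / np.sum(w / p))
    return HMPResult(p_values=p, weights=w, combined=combined)


def plot_averaged_roc(curves: Mapping[str, AveragedROC], path=None, title: str = ""):
    """Plot one or more averaged ROC curves (sensitivity vs 1-specificity)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(1.0 - curve.specificity, curve.sensitivity,
                label=f"{label} (AUC {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


# --------------------------------------------------------------------------
# subgroup report
# --------------------------------------------------------------------------

def subgroup_roc_report(
    prediction_set: pd.DataFrame,
    groupings: Mapping[str, pd.Series],
    model: str,
    role: str = "external_test",
    thresholds: np.ndarray | None = None,
    min_group_size: int = 10,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, dict]:
    """Averaged ROC per subgroup level plus an HMP-combined comparison p.

    ``groupings`` maps a grouping name (e.g. sex, site, treatment arm,
    median-split baseline severity) to a per-participant level Series.  For
    each grouping the report contains one :class:`AveragedROC` per level,
    the per-imputation k-sample comparison p-values, and their harmonic-mean
    combination (omitted for single-level groupings).  Levels smaller than
    ``min_group_size`` are dropped with a warning.
    """
    if thresholds is None:
        thresholds = default_threshold_grid(1e-3)
    sub = prediction_set[
        (prediction_set["role"] == role) & (prediction_set["model"] == model)
    ]
    if sub.empty:
        raise ROCStatsError(f"no predictions for model {model!r} with role {role!r}")
    imputations = sorted(sub["imputation"].unique())
    report: dict[str, dict] = {}
    for gname, assignment in groupings.items():
        levels = []
        for level in pd.unique(assignment.dropna()):
            ids = assignment.index[assignment == level]
            if len(ids) < min_group_size:
                logger.warning(
                    "grouping %r: level %r below minimum size %d; dropped",
                    gname, level, min_group_size,
                )
                continue
            levels.append((str(level), set(ids)))
        curves = {}
        per_imp_data: dict[int, list] = {m: [] for m in imputations}
        for level, ids in levels:
            labels_list, probs_list = [], []
            for m in imputations:
                df = sub[(sub["imputation"] == m) & (sub["participant"].isin(ids))]
                df = df.groupby("participant")[["prob", "y_true"]].mean()
                y = df["y_true"].to_numpy(dtype=float)
                p = df["prob"].to_numpy(dtype=float)
                labels_list.append(y)
                probs_list.append(p)
                per_imp_data[m].append((y, p))
            curves[level] = averaged_roc(
                labels_list, probs_list, thresholds=thresholds,
                subgroup=f"{gname}={level}",
            )
        entry: dict = {"curves": curves}
        if len(levels) >= 2:
            p_values = []
            for m in imputations:
                ok_groups = [
                    (y, p) for y, p in per_imp_data[m] if len(np.unique(y)) == 2
                ]
                if len(ok_groups) < 2:
                    continue
                _, p_m = compare_roc_k(
                    ok_groups, n_permutations=n_permutations,
                    seed=int(np.random.SeedSequence([seed, m]).generate_state(1)[0] % (2**31 - 1)),
                )
                p_values.append(p_m)
            entry["per_imputation_p"] = p_values
            entry["hmp"] = harmonic_mean_p(p_values) if p_values else None
        report[gname] = entry
    return report
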