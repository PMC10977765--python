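"""Feature pruning, filtering, cross-study harmonization, standardization.

Order of use in the pipeline: prune redundant imaging measures by average
Spearman correlation across brain regions, drop degenerate / sparse /
high-missingness features, restrict both studies to their shared feature
set, and (after imputation, per train/test pair) z-score the continuous
features with training-partition statistics only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cohort import CohortTable

__all__ = [
    "FilterReport",
    "StandardizationParams",
    "prune_correlated_measures",
    "filter_features",
    "harmonize_features",
    "standardize",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A measure is not present for every region, or schemas conflict."""


class HarmonizationError(ValueError):
    """Same feature name with conflicting kind or bounds across studies."""


@dataclass
class FilterReport:
    """Outcome of a filtering step: dropped names with reasons, retained names.

    ``dropped`` maps feature name -> reason in {single_category, small_count,
    high_missingness, correlated_measure, redundant}.
    """

    dropped: dict[str, str]
    retained: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.dropped) & set(self.retained)
        if overlap:
            raise ValueError(f"features both dropped and retained: {sorted(overlap)}")

    @property
    def all_features(self) -> set[str]:
        return set(self.dropped) | set(self.retained)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"dropped": self.dropped, "retained": self.retained}, indent=1)
        )


@dataclass
class StandardizationParams:
    """Per-feature centering/scaling statistics from the training partition.

    sigma uses the population denominator (n, not n-1).
    """

    mu: pd.Series
    sigma: pd.Series

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mu": self.mu.to_dict(), "sigma": self.sigma.to_dict()}, indent=1)
        )


# --------------------------------------------------------------------------
# imaging measure pruning
# --------------------------------------------------------------------------

def prune_correlated_measures(
    imaging: pd.DataFrame,
    measure_labels: Mapping[str, tuple[str, str]],
    threshold: float = 0.7,
) -> FilterReport:
    """Drop whole imaging measures whose region-averaged |Spearman rho| is high.

    For each pair of measures, Spearman's rank correlation is computed per
    region between the two measures' region columns and |rho| is averaged
    across regions.  Measures are then retained greedily in canonical (sorted)
    order: a measure is kept only if its average |rho| with every
    already-kept measure is below ``threshold``.  All region-level features
    of a dropped measure are dropped (reason ``correlated_measure``).

    Parameters
    ----------
    imaging : DataFrame
        Participants x imaging-feature values (may contain NaN).
    measure_labels : mapping
        feature name -> (measure, region).  Every measure must cover the
        same region set.
    """
    by_measure: dict[str, dict[str, str]] = {}
    for feat, (measure, region) in measure_labels.items():
        if feat not in imaging.columns:
            raise SchemaError(f"labeled feature {feat!r} absent from imaging block")
        by_measure.setdefault(measure, {})[region] = feat
    measures = sorted(by_measure)
    region_sets = {m: set(by_measure[m]) for m in measures}
    regions = sorted(region_sets[measures[0]])
    for m in measures:
        if region_sets[m] != set(regions):
            raise SchemaError(f"measure {m!r} does not cover the common region set")
    if len(imaging.dropna(how="any")) < 2 and len(imaging) < 2:
        raise SchemaError("need at least 2 participants with observed values")

    def avg_abs_rho(m1: str, m2: str) -> float:
        rhos = []
        for r in regions:
            a = imaging[by_measure[m1][r]]
            b = imaging[by_measure[m2][r]]
            ok = a.notna() & b.notna()
            if ok.sum() < 2:
                raise SchemaError(
                    f"fewer than 2 joint observations for measures {m1!r}/{m2!r} in region {r!r}"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant columns -> rho undefined
                rho = spearmanr(a[ok], b[ok]).statistic
            rhos.append(0.0 if np.isnan(rho) else abs(float(rho)))
        return float(np.mean(rhos))

    kept: list[str] = []
    dropped_measures: list[str] = []
    for m in measures:  # canonical order, keep-first
        if all(avg_abs_rho(m, k) < threshold for k in kept):
            kept.append(m)
        else:
            dropped_measures.append(m)

    dropped = {
        by_measure[m][r]: "correlated_measure" for m in dropped_measures for r in regions
    }
    retained = [c for c in imaging.columns if c not in dropped]
    return FilterReport(dropped=dropped, retained=retained)


# --------------------------------------------------------------------------
# degenerate / sparse / missing feature filters
# --------------------------------------------------------------------------

def filter_features(table: CohortTable, missing_threshold: float = 0.2) -> FilterReport:
    """Drop single-category, small-count and high-missingness features.

    Reasons, in priority order per feature:

    - ``single_category``: one unique observed value (any kind);
    - ``small_count``: categorical/ordinal/binary feature with any observed
      category counting <= 3;
    - ``high_missingness``: missing fraction above ``missing_threshold``.
    """
    dropped: dict[str, str] = {}
    n = table.n
    for meta in table.features:
        col = table.values[meta.name]
        observed = col.dropna()
        if len(observed) and observed.nunique() == 1:
            dropped[meta.name] = "single_category"
            continue
        if meta.kind in ("ordinal_integer", "binary", "categorical") and len(observed):
            counts = observed.value_counts()
            if (counts <= 3).any():
                dropped[meta.name] = "small_count"
                continue
        if n and col.isna().mean() > missing_threshold:
            dropped[meta.name] = "high_missingness"
    retained = [f.name for f in table.features if f.name not in dropped]
    return FilterReport(dropped=dropped, retained=retained)


def apply_filter(table: CohortTable, report: FilterReport) -> CohortTable:
    """Restrict a cohort to the features a :class:`FilterReport` retained."""
    return table.restrict_features([n for n in table.feature_names if n in set(report.retained)])


# --------------------------------------------------------------------------
# cross-study harmonization
# --------------------------------------------------------------------------

def harmonize_features(a: CohortTable, b: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Restrict both cohorts to their shared features, in sorted column order.

    Features sharing a name but disagreeing on kind or bounds raise
    :class:`HarmonizationError`; participant rows are unchanged.
    """
    shared = sorted(set(a.feature_names) & set(b.feature_names))
    for name in shared:
        fa, fb = a.feature_index[name], b.feature_index[name]
        if (fa.kind, fa.lower, fa.upper) != (fb.kind, fb.lower, fb.upper):
            raise HarmonizationError(
                f"feature {name!r} has conflicting kind/bounds across studies"
            )
    return a.restrict_features(shared), b.restrict_features(shared)


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

def standardize(
    train: CohortTable, test: CohortTable | None = None
) -> tuple[CohortTable, CohortTable | None, StandardizationParams]:
    """z-score continuous features with training-partition statistics.

    mu and sigma come from the training partition only (sigma with
    population denominator n); the test partition is transformed with the
    same parameters.  Non-continuous features pass through untouched.
    Zero-variance training columns map to all zeros in both partitions (a
    warning is logged).
    """
    cont = [f.name for f in train.features if f.kind == "continuous"]
    mu = train.values[cont].mean()
    sigma = train.values[cont].std(ddof=0)
    degenerate = sigma.index[sigma == 0].tolist()
    if degenerate:
        logger.warning("zero-variance training columns mapped to 0: %s", degenerate)

    def transform(t: CohortTable) -> CohortTable:
        vals = t.values.copy()
        if cont:
            z = (vals[cont] - mu) / sigma.replace(0.0, np.nan)
            z[degenerate] = 0.0
            vals[cont] = z
        return t.with_values(vals)

    params = StandardizationParams(mu=mu, sigma=sigma)
    return transform(train), (transform(test) if test is not None else None), params


def standardize_frames(
    X_train: pd.DataFrame,
    X_test: pd.DataFrame | None,
    continuous: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Frame-level variant of :func:`standardize` used inside CV folds."""
    mu = X_train[continuous].mean()
    sigma = X_train[continuous].std(ddof=0)
    safe = sigma.replace(0.0, np.nan)

    def tr(X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        if continuous:
            z = (out[continuous] - mu) / safe
            out[continuous] = z.fillna(0.0) if (sigma == 0).any() else z
        return out

    return tr(X_train), (tr(X_test) if X_test is not None else None)
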