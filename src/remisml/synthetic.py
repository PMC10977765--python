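"""Synthetic multi-study, multi-site clinical-trial cohorts.

The generator emulates the structure of small antidepressant trials with
structural-MRI morphometrics and questionnaire items: a block of correlated
continuous imaging features (measures x brain regions), bounded ordinal
questionnaire items driven by a latent severity factor, clinical/demographic
covariates, per-site mean offsets on the imaging block (scanner/site
heterogeneity), and a latent linear outcome model that maps to a week-8
HDRS-17 total — remission is that total being <= 7.

The outcome depends on the *biological* imaging values before the site offset
is added, so the offset acts as pure measurement shift: internally a model can
learn the signal, but transferring it to a cohort measured with different
offsets degrades discrimination.  This is the mechanism behind the
internal-vs-external generalization experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .cohort import HDRS17_MAX, CohortTable, FeatureMeta, derive_remission

__all__ = [
    "SyntheticConfig",
    "FactorDefinition",
    "generate_cohort",
    "inject_missingness",
    "compute_hdrs_factors",
    "derive_remission",
    "hdrs_factor_definition",
    "HDRS_FACTOR_ITEMS",
    "apat_like_config",
    "embarc_like_config",
]

DEFAULT_MEASURES = ("thickness", "grayvol", "foldind", "meancurv")


class SyntheticConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SyntheticConfig:
    """Configuration of one generated study cohort.

    Defaults emulate the single-site trial arm of the analysis: 85
    participants, 4 imaging measures x 68 regions (272 imaging features), 24
    HDRS items (0-2) + 16 QIDS items (0-3) + severity totals, five clinical
    covariates, ~37% remission prevalence, sparse feature missingness and
    ~8% missing week-8 outcomes under a severity-dependent (MAR) mechanism.
    """

    study_label: str = "STUDY_A"
    n_per_site: int | Sequence[int] = 85
    n_sites: int = 1
    n_imaging_measures: int = 4
    n_imaging_regions: int = 68
    n_hdrs_items: int = 24
    n_qids_items: int = 16
    n_clinical: int = 5
    signal_features: Mapping[str, float] | None = None  # None -> 5 default imaging signals
    signal_effect: float = 0.8  # effect size per default signal feature (latent SD units)
    severity_effect: float = 0.5  # latent baseline-severity effect on the outcome
    site_shift_magnitude: float = 0.0
    within_block_correlation: float = 0.3  # cross-measure corr within a region
    item_severity_loading: float = 0.6
    target_prevalence: float = 0.37
    hdrs_scale: float = 4.0  # latent-to-HDRS points conversion
    missing_rate_features: float = 0.01
    missing_rate_outcome: float = 0.08
    missingness_mechanism: str = "MAR"  # or "MCAR"
    age_mean: float = 28.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.site_counts()
        if any(c < 0 for c in counts):
            raise SyntheticConfigError("participant counts must be non-negative")
        if self.n_sites < 1:
            raise SyntheticConfigError("n_sites must be >= 1")
        for name in ("target_prevalence", "missing_rate_features", "missing_rate_outcome"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise SyntheticConfigError("within_block_correlation must lie in [0, 1)")
        if self.site_shift_magnitude < 0:
            raise SyntheticConfigError("site_shift_magnitude must be non-negative")
        if self.missingness_mechanism not in ("MCAR", "MAR"):
            raise SyntheticConfigError("missingness_mechanism must be MCAR or MAR")
        if self.signal_features is not None:
            for k, v in self.signal_features.items():
                if not math.isfinite(v):
                    raise SyntheticConfigError(f"effect size for {k!r} must be finite")

    def site_counts(self) -> list[int]:
        if isinstance(self.n_per_site, (int, np.integer)):
            return [int(self.n_per_site)] * self.n_sites
        counts = [int(c) for c in self.n_per_site]
        if len(counts) != self.n_sites:
            raise SyntheticConfigError("n_per_site list length must equal n_sites")
        return counts

    # ---------------------------------------------------------------- schema
    def imaging_names(self) -> list[str]:
        measures = list(DEFAULT_MEASURES)
        while len(measures) < self.n_imaging_measures:
            measures.append(f"measure{len(measures) + 1:02d}")
        measures = measures[: self.n_imaging_measures]
        return [
            f"{m}_region{r + 1:02d}"
            for m in measures
            for r in range(self.n_imaging_regions)
        ]

    def default_signal(self) -> dict[str, float]:
        """Five imaging features in distinct regions carry the outcome signal."""
        if self.signal_features is not None:
            return dict(self.signal_features)
        names = self.imaging_names()
        k = min(5, len(names), self.n_imaging_regions)
        measure = DEFAULT_MEASURES[0] if self.n_imaging_measures else None
        picked = [f"{measure}_region{r + 1:02d}" for r in range(k)] if measure else []
        return {name: self.signal_effect for name in picked}

    def feature_schema(self) -> list[FeatureMeta]:
        feats: list[FeatureMeta] = [
            FeatureMeta(n, "continuous", group="imaging") for n in self.imaging_names()
        ]
        for i in range(self.n_hdrs_items):
            feats.append(
                FeatureMeta(f"hdrs_{i + 1:02d}", "ordinal_integer", 0, 2, "questionnaire")
            )
        for i in range(self.n_qids_items):
            feats.append(
                FeatureMeta(f"qids_{i + 1:02d}", "ordinal_integer", 0, 3, "questionnaire")
            )
        if self.n_hdrs_items:
            feats.append(
                FeatureMeta("hdrs_baseline_total", "continuous", group="questionnaire")
            )
        clinical = [
            FeatureMeta("age", "continuous", group="clinical"),
            FeatureMeta("education_years", "ordinal_integer", 8, 22, "clinical"),
            FeatureMeta("sex_female", "binary", 0, 1, "clinical"),
            FeatureMeta("treatment_ssri", "binary", 0, 1, "clinical"),
            FeatureMeta("bmi", "continuous", group="clinical"),
        ]
        feats.extend(clinical[: self.n_clinical])
        return feats

    # ------------------------------------------------------------------ yaml
    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if d["signal_features"] is not None:
            d["signal_features"] = dict(d["signal_features"])
        if not isinstance(d["n_per_site"], (int, np.integer)):
            d["n_per_site"] = list(d["n_per_site"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def apat_like_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Single-site cohort shaped like the 85-participant discovery trial."""
    base = dict(
        study_label="APAT_SYN",
        n_per_site=85,
        n_sites=1,
        missing_rate_outcome=7 / 85,
        missing_rate_features=0.01,
        age_mean=25.0,
        target_prevalence=0.372,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def embarc_like_config(seed: int = 1, **overrides) -> SyntheticConfig:
    """Four-site cohort shaped like the 197-participant validation trial."""
    base = dict(
        study_label="EMBARC_SYN",
        n_per_site=(50, 49, 49, 49),
        n_sites=4,
        missing_rate_outcome=50 / 197,
        missing_rate_features=0.02,
        site_shift_magnitude=1.0,
        age_mean=34.0,
        target_prevalence=0.374,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _signal_variance(config: SyntheticConfig, signal: Mapping[str, float]) -> float:
    """Exact variance of the imaging-signal term under the generative model.

    Imaging features are unit-variance with correlation rho between measures
    of the same region and zero otherwise, so beta' Sigma beta is available in
    closed form.
    """
    rho = config.within_block_correlation
    items = list(signal.items())
    var = 0.0
    for i, (ni, bi) in enumerate(items):
        var += bi * bi
        ri = ni.rsplit("_region", 1)[-1]
        for nj, bj in items[i + 1:]:
            if nj.rsplit("_region", 1)[-1] == ri:
                var += 2.0 * rho * bi * bj
    return var


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw one complete (no missingness) cohort from the generative model.

    Deterministic in ``config`` including ``config.seed``.  The marginal
    remission prevalence matches ``target_prevalence`` by construction: the
    latent outcome score is exactly Gaussian with known variance, so the
    remission threshold is placed at its ``target_prevalence`` quantile
    analytically.
    """
    for name in signal_names_outside_imaging(config):
        raise SyntheticConfigError(
            f"signal feature {name!r} is not an imaging feature of this schema"
        )
    rng = np.random.default_rng(config.seed)
    counts = config.site_counts()
    n = int(sum(counts))
    schema = config.feature_schema()
    names = [f.name for f in schema]

    # Site offsets are drawn first so that, at a fixed seed, scaling
    # site_shift_magnitude rescales the same offset pattern (monotone shifts).
    imaging = config.imaging_names()
    offsets = rng.standard_normal((config.n_sites, len(imaging)))

    site_labels = np.repeat(
        [f"{config.study_label}_site{j + 1}" for j in range(config.n_sites)], counts
    )
    site_idx = np.repeat(np.arange(config.n_sites), counts)
    ids = pd.Index(
        [f"{config.study_label}_p{i + 1:04d}" for i in range(n)], name="participant_id"
    )

    cols: dict[str, np.ndarray] = {}

    # imaging block: region latent shared across measures
    rho = config.within_block_correlation
    n_reg = config.n_imaging_regions
    region_latent = rng.standard_normal((n, n_reg))
    true_imaging: dict[str, np.ndarray] = {}
    for j, name in enumerate(imaging):
        r = j % n_reg
        eps = rng.standard_normal(n)
        t = math.sqrt(rho) * region_latent[:, r] + math.sqrt(1.0 - rho) * eps
        true_imaging[name] = t
        cols[name] = t + config.site_shift_magnitude * offsets[site_idx, j]

    # questionnaire block: latent severity drives bounded ordinal items
    severity = rng.standard_normal(n)
    lam = config.item_severity_loading
    for f in schema:
        if f.group != "questionnaire" or f.kind != "ordinal_integer":
            continue
        latent = lam * severity + math.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
        levels = int(f.upper - f.lower) + 1
        cuts = ndtri(np.arange(1, levels) / levels)
        cols[f.name] = (latent[:, None] > cuts[None, :]).sum(axis=1).astype(float) + f.lower

    if "hdrs_baseline_total" in names:
        item_cols = [f"hdrs_{i + 1:02d}" for i in range(config.n_hdrs_items)]
        cols["hdrs_baseline_total"] = sum(cols[c] for c in item_cols)

    # clinical block
    arm = np.where(rng.random(n) < 0.5, "active", "placebo") if n else np.array([], dtype=object)
    clinical_draws = {
        "age": np.clip(config.age_mean + 10.0 * rng.standard_normal(n), 18, 70),
        "education_years": np.clip(np.round(15 + 2.5 * rng.standard_normal(n)), 8, 22),
        "sex_female": (rng.random(n) < 0.64).astype(float),
        "treatment_ssri": (arm == "active").astype(float),
        "bmi": np.clip(25 + 4.0 * rng.standard_normal(n), 15, 45),
    }
    for f in schema:
        if f.group == "clinical":
            cols[f.name] = clinical_draws[f.name]

    # latent outcome: biology (pre-shift imaging) + baseline severity + noise
    signal = config.default_signal()
    score = np.zeros(n)
    for name, beta in signal.items():
        score += beta * true_imaging[name]
    score += config.severity_effect * severity
    score += rng.standard_normal(n)
    sigma = math.sqrt(_signal_variance(config, signal) + config.severity_effect**2 + 1.0)
    if config.target_prevalence in (0.0, 1.0):
        tau = -math.inf if config.target_prevalence == 0.0 else math.inf
    else:
        tau = sigma * float(ndtri(config.target_prevalence))
    d = config.hdrs_scale * (score - tau)
    hdrs8 = np.clip(np.floor(8.0 + d), 0, HDRS17_MAX)

    values = pd.DataFrame({name: cols[name] for name in names}, index=ids, dtype=float)
    return CohortTable(
        values=values,
        features=schema,
        study=config.study_label,
        site=pd.Series(site_labels, index=ids, name="site", dtype=object),
        arm=pd.Series(arm, index=ids, name="arm", dtype=object),
        hdrs17_week8=pd.Series(hdrs8, index=ids, name="hdrs17_week8", dtype=float),
    )


def signal_names_outside_imaging(config: SyntheticConfig) -> list[str]:
    if config.signal_features is None:
        return []
    imaging = set(config.imaging_names())
    return [n for n in config.signal_features if n not in imaging]


# --------------------------------------------------------------------------
# missingness
# --------------------------------------------------------------------------

def inject_missingness(table: CohortTable, config: SyntheticConfig) -> CohortTable:
    """Blank out feature cells and week-8 outcomes; the input is unchanged.

    MCAR blanks cells independently at the configured rates.  MAR keeps
    feature cells MCAR but makes *outcome* missingness depend on observed
    baseline severity through a logistic model whose intercept is calibrated
    so the realized mean missingness probability equals the configured rate.
    """
    out = table.copy()
    rng = np.random.default_rng([config.seed, 104729])
    n, p = out.values.shape
    if n == 0:
        return out
    if config.missing_rate_features > 0 and p > 0:
        mask = rng.random((n, p)) < config.missing_rate_features
        vals = out.values.to_numpy(copy=True)
        vals[mask] = np.nan
        out.values.iloc[:, :] = vals

    rate = config.missing_rate_outcome
    if rate <= 0:
        return out
    if rate >= 1 or config.missingness_mechanism == "MCAR":
        prob = np.full(n, rate)
    else:
        severity = _severity_proxy(out)
        z = (severity - np.nanmean(severity)) / (np.nanstd(severity) or 1.0)
        z = np.nan_to_num(z)

        def mean_rate(a: float) -> float:
            return float(np.mean(expit(a + z))) - rate

        a = brentq(mean_rate, -30, 30)
        prob = expit(a + z)
    drop = rng.random(n) < prob
    hdrs = out.hdrs17_week8.to_numpy(copy=True)
    hdrs[drop] = np.nan
    out.hdrs17_week8 = pd.Series(hdrs, index=out.participants, name="hdrs17_week8")
    return out


def _severity_proxy(table: CohortTable) -> np.ndarray:
    if "hdrs_baseline_total" in table.feature_index:
        return table.values["hdrs_baseline_total"].to_numpy(dtype=float)
    cont = [f.name for f in table.features if f.kind == "continuous"]
    if cont:
        return table.values[cont[0]].to_numpy(dtype=float)
    return np.zeros(table.n)


# --------------------------------------------------------------------------
# HDRS factor scores
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorDefinition:
    """One HDRS symptom factor: its items and fixed per-item loadings."""

    factor_id: str
    item_names: tuple[str, ...]
    loadings: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.item_names) != len(self.loadings):
            raise ValueError("item_names and loadings must have equal length")
        if any(l < 0 for l in self.loadings):
            raise ValueError("loadings must be non-negative")


# Published fixed loadings for the five HDRS symptom factors (Milak et al.,
# 2005, as used in the source trials).  The printed F4 load-weighted-sum
# formula uses item 19 in place of item 09; both variants are exposed.
HDRS_FACTOR_ITEMS: dict[str, tuple[tuple[str, float], ...]] = {
    "F1": (
        ("HDRS_01", 0.59),
        ("HDRS_02", 0.46),
        ("HDRS_03", 0.67),
        ("HDRS_08", 0.44),
        ("HDRS_22", 0.41),
        ("HDRS_23", 0.65),
        ("HDRS_24", 0.79),
    ),
    "F2": (
        ("HDRS_07", 0.42),
        ("HDRS_12", 0.84),
        ("HDRS_14", 0.50),
        ("HDRS_16", 0.74),
    ),
    "F3": (
        ("HDRS_17", 0.74),
        ("HDRS_19", 0.41),
        ("HDRS_20", 0.68),
        ("HDRS_21", 0.68),
    ),
    "F4": (
        ("HDRS_19", 0.74),
        ("HDRS_10", 0.62),
        ("HDRS_11", 0.52),
        ("HDRS_15", 0.68),
    ),
    "F5": (
        ("HDRS_04", 0.74),
        ("HDRS_05", 0.83),
        ("HDRS_06", 0.59),
    ),
}


def hdrs_factor_definition(factor_id: str, f4_variant: str = "printed") -> FactorDefinition:
    """Return a factor definition; ``f4_variant`` selects the F4 first item.

    ``"printed"`` follows the published formula exactly (item 19);
    ``"item09"`` substitutes item 09, matching the factor's item listing.
    """
    items = HDRS_FACTOR_ITEMS[factor_id]
    if factor_id == "F4" and f4_variant == "item09":
        items = (("HDRS_09", items[0][1]),) + items[1:]
    elif factor_id == "F4" and f4_variant != "printed":
        raise ValueError("f4_variant must be 'printed' or 'item09'")
    return FactorDefinition(
        factor_id=factor_id,
        item_names=tuple(n for n, _ in items),
        loadings=tuple(l for _, l in items),
    )


class MissingItemError(KeyError):
    """A required HDRS item is absent from the provided scores."""


def compute_hdrs_factors(
    items: Mapping[str, float], definition: FactorDefinition
) -> tuple[float, float]:
    """Arithmetic sum and load-weighted sum of one HDRS factor.

    ``arithmetic_sum`` is the plain sum of the factor's item scores;
    ``load_weighted_sum`` weights each item by its published loading.
    """
    scores = []
    for name in definition.item_names:
        if name not in items:
            raise MissingItemError(name)
        scores.append(float(items[name]))
    arithmetic = float(sum(scores))
    weighted = float(sum(l * s for l, s in zip(definition.loadings, scores)))
    return arithmetic, weighted
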