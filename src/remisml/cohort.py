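"""Cohort containers: participants x features with metadata and missingness.

A :class:`CohortTable` is the in-memory unit the whole pipeline operates on —
a numeric participant-by-feature grid (``NaN`` marks missing), a typed feature
schema (:class:`FeatureMeta`), and per-participant trial metadata (study, site,
treatment arm, week-8 HDRS-17 outcome).  Remission is never stored: it is
always derived from the week-8 score (total <= 7 -> remitter) so the two can
never disagree.

On disk a cohort is one CSV (participant metadata columns + feature columns,
missing as empty cells) plus a JSON sidecar holding the feature schema.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FeatureMeta",
    "CohortTable",
    "REMITTER",
    "NON_REMITTER",
    "derive_remission",
    "derive_remission_series",
    "read_cohort",
    "write_cohort",
]

REMITTER = "remitter"
NON_REMITTER = "non_remitter"
REMISSION_CUTOFF = 7  # HDRS-17 total <= 7 at week 8
HDRS17_MAX = 52

FEATURE_KINDS = ("continuous", "ordinal_integer", "binary", "categorical")
FEATURE_GROUPS = ("imaging", "questionnaire", "clinical")

_META_COLUMNS = ("participant_id", "study", "site", "arm", "hdrs17_week8")


class CohortError(ValueError):
    """Invalid cohort construction or schema violation."""


@dataclass(frozen=True)
class FeatureMeta:
    """Schema entry for one feature.

    Parameters
    ----------
    name : str
        Unique feature name within a cohort.
    kind : {"continuous", "ordinal_integer", "binary", "categorical"}
    lower, upper : float or None
        Bounds; ordinal_integer features must have finite integer bounds
        with lower < upper.
    group : {"imaging", "questionnaire", "clinical"}
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    group: str = "clinical"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise CohortError(f"unknown feature kind {self.kind!r}")
        if self.group not in FEATURE_GROUPS:
            raise CohortError(f"unknown feature group {self.group!r}")
        if self.kind == "ordinal_integer":
            if self.lower is None or self.upper is None:
                raise CohortError(f"ordinal feature {self.name!r} needs finite bounds")
            if not (
                math.isfinite(self.lower)
                and math.isfinite(self.upper)
                and float(self.lower).is_integer()
                and float(self.upper).is_integer()
                and self.lower < self.upper
            ):
                raise CohortError(
                    f"ordinal feature {self.name!r} needs integer bounds with lower < upper"
                )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "lower": self.lower,
            "upper": self.upper,
            "group": self.group,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMeta":
        return cls(
            name=d["name"],
            kind=d["kind"],
            lower=d.get("lower"),
            upper=d.get("upper"),
            group=d.get("group", "clinical"),
        )


def derive_remission(hdrs17_week8: float | int | None) -> str | float:
    """Map a week-8 HDRS-17 total to a remission label.

    <= 7 -> ``"remitter"``; > 7 -> ``"non_remitter"``; missing -> ``NaN``.
    Scores must be non-negative integers within [0, 52] when observed.
    """
    if hdrs17_week8 is None or (
        isinstance(hdrs17_week8, float) and math.isnan(hdrs17_week8)
    ):
        return float("nan")
    score = float(hdrs17_week8)
    if not score.is_integer() or score < 0 or score > HDRS17_MAX:
        raise CohortError(f"invalid week-8 HDRS-17 score {hdrs17_week8!r}")
    return REMITTER if score <= REMISSION_CUTOFF else NON_REMITTER


def derive_remission_series(scores: pd.Series) -> pd.Series:
    """Vectorized :func:`derive_remission` over a Series of week-8 totals."""
    return scores.map(derive_remission)


@dataclass
class CohortTable:
    """Participants x features grid with trial metadata.

    ``values`` is a float DataFrame indexed by participant id with one column
    per feature (NaN = missing).  ``site``, ``arm`` and ``hdrs17_week8`` are
    Series aligned to the same index.  Remission labels are derived, not
    stored (see :meth:`remission`).
    """

    values: pd.DataFrame
    features: list[FeatureMeta]
    study: str
    site: pd.Series
    arm: pd.Series
    hdrs17_week8: pd.Series
    feature_index: dict[str, FeatureMeta] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise CohortError("duplicate feature names")
        if list(self.values.columns) != names:
            raise CohortError("values columns must match feature schema order")
        for s, label in ((self.site, "site"), (self.arm, "arm"), (self.hdrs17_week8, "hdrs17_week8")):
            if not s.index.equals(self.values.index):
                raise CohortError(f"{label} index does not match participants")
        observed = self.hdrs17_week8.dropna()
        bad = observed[(observed < 0) | (observed > HDRS17_MAX) | (observed % 1 != 0)]
        if len(bad):
            raise CohortError("week-8 HDRS-17 scores must be integers in [0, 52]")
        # bounded ordinal values must respect their bounds where observed
        for f in self.features:
            if f.kind == "ordinal_integer":
                col = self.values[f.name].dropna()
                if len(col) and ((col < f.lower) | (col > f.upper)).any():
                    raise CohortError(f"observed values of {f.name!r} violate bounds")
        object.__setattr__(self, "feature_index", {f.name: f for f in self.features})

    # ------------------------------------------------------------------ views
    @property
    def participants(self) -> pd.Index:
        return self.values.index

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def remission(self) -> pd.Series:
        """Per-participant remission label derived from the week-8 score."""
        return derive_remission_series(self.hdrs17_week8).rename("remission")

    @property
    def remission_binary(self) -> pd.Series:
        """1 = remitter, 0 = non-remitter, NaN = unknown."""
        rem = self.remission
        return rem.map({REMITTER: 1.0, NON_REMITTER: 0.0}).astype(float)

    def features_in_group(self, group: str) -> list[str]:
        return [f.name for f in self.features if f.group == group]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any() or self.hdrs17_week8.isna().any())

    # ------------------------------------------------------------- operations
    def copy(self) -> "CohortTable":
        return CohortTable(
            values=self.values.copy(),
            features=list(self.features),
            study=self.study,
            site=self.site.copy(),
            arm=self.arm.copy(),
            hdrs17_week8=self.hdrs17_week8.copy(),
        )

    def restrict_features(self, names: Sequence[str]) -> "CohortTable":
        missing = [n for n in names if n not in self.feature_index]
        if missing:
            raise CohortError(f"unknown features {missing}")
        return CohortTable(
            values=self.values.loc[:, list(names)].copy(),
            features=[self.feature_index[n] for n in names],
            study=self.study,
            site=self.site,
            arm=self.arm,
            hdrs17_week8=self.hdrs17_week8,
        )

    def restrict_participants(self, ids: Iterable) -> "CohortTable":
        ids = list(ids)
        return CohortTable(
            values=self.values.loc[ids].copy(),
            features=list(self.features),
            study=self.study,
            site=self.site.loc[ids].copy(),
            arm=self.arm.loc[ids].copy(),
            hdrs17_week8=self.hdrs17_week8.loc[ids].copy(),
        )

    def with_values(self, values: pd.DataFrame, hdrs17_week8: pd.Series | None = None) -> "CohortTable":
        return CohortTable(
            values=values,
            features=list(self.features),
            study=self.study,
            site=self.site,
            arm=self.arm,
            hdrs17_week8=self.hdrs17_week8 if hdrs17_week8 is None else hdrs17_week8,
        )

    def same_schema(self, other: "CohortTable") -> bool:
        return self.features == other.features and self.participants.equals(other.participants)


def concat_cohorts(tables: Sequence[CohortTable], study: str | None = None) -> CohortTable:
    """Stack cohorts row-wise; schemas must be identical."""
    first = tables[0]
    for t in tables[1:]:
        if t.features != first.features:
            raise CohortError("cannot concatenate cohorts with different schemas")
    return CohortTable(
        values=pd.concat([t.values for t in tables]),
        features=list(first.features),
        study=study if study is not None else "+".join(t.study for t in tables),
        site=pd.concat([t.site for t in tables]),
        arm=pd.concat([t.arm for t in tables]),
        hdrs17_week8=pd.concat([t.hdrs17_week8 for t in tables]),
    )


# ---------------------------------------------------------------------- I/O

def write_cohort(table: CohortTable, csv_path: str | Path) -> Path:
    """Write a cohort as CSV plus a JSON feature-metadata sidecar.

    Missing values are written as empty cells.  The sidecar path is the CSV
    path with a ``.features.json`` suffix.
    """
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        {
            "participant_id": table.participants,
            "study": table.study,
            "site": table.site.values,
            "arm": table.arm.values,
            "hdrs17_week8": table.hdrs17_week8.values,
        }
    )
    frame = pd.concat([frame.reset_index(drop=True), table.values.reset_index(drop=True)], axis=1)
    frame.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".features.json")
    sidecar.write_text(json.dumps([f.to_dict() for f in table.features], indent=1))
    return sidecar


def read_cohort(csv_path: str | Path) -> CohortTable:
    """Inverse of :func:`write_cohort`."""
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".features.json")
    features = [FeatureMeta.from_dict(d) for d in json.loads(sidecar.read_text())]
    frame = pd.read_csv(csv_path)
    frame = frame.set_index("participant_id")
    studies = frame["study"].unique()
    if len(studies) != 1:
        raise CohortError("cohort CSV must contain a single study label")
    values = frame[[f.name for f in features]].astype(float)
    return CohortTable(
        values=values,
        features=features,
        study=str(studies[0]),
        site=frame["site"].astype(str),
        arm=frame["arm"].astype(str),
        hdrs17_week8=frame["hdrs17_week8"].astype(float),
    )
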