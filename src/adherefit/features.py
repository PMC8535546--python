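"""Clustering features computed from the first 90 days of a daily series.

Eighteen features per user: the mean daily workout seconds of each of the
three training months, the number of missed (zero-activity) days in each
month, and the mean daily seconds of each of the twelve 7-day weeks.
Months are fixed 30-day blocks (days 1-30, 31-60, 61-90); weeks are fixed
7-day blocks covering days 1-84, so days 85-90 contribute to month 3 only.

"Missed" days are days with zero accumulated seconds inside the block; the
app prescribes no schedule, so inactivity is the only observable skip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sessions_io import DailySeries, TRAIN_DAYS

__all__ = [
    "FEATURE_NAMES",
    "PRESETS",
    "FeatureVector",
    "CohortScaler",
    "extract_features",
    "feature_matrix",
    "select_preset",
    "preset_names",
]

_MONTHS = ("first", "second", "third")

#: Canonical order of the 18 features (also the CSV export column order).
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"mean_{m}_month" for m in _MONTHS)
    + tuple(f"missed_{m}_month" for m in _MONTHS)
    + tuple(f"mean_week_{w}" for w in range(1, 13))
)

#: Feature subsets evaluated in the study, by name.
PRESETS: dict[str, tuple[str, ...]] = {
    "month_means": tuple(f"mean_{m}_month" for m in _MONTHS),
    "missed_months": tuple(f"missed_{m}_month" for m in _MONTHS),
    "weeks": tuple(f"mean_week_{w}" for w in range(1, 13)),
    # missed months + month means + weeks 8-11
    "combined": tuple(f"missed_{m}_month" for m in _MONTHS)
    + tuple(f"mean_{m}_month" for m in _MONTHS)
    + tuple(f"mean_week_{w}" for w in range(8, 12)),
}


@dataclass(frozen=True)
class FeatureVector:
    """The 18 per-user clustering features, keyed by canonical name."""

    user_id: str
    values: dict[str, float]

    def as_array(self, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def extract_features(series: DailySeries) -> FeatureVector:
    """Compute the 18 features from days 1-90 of ``series``.

    Only the training window is touched; month 4 never leaks into the
    clustering stage.
    """
    days = np.asarray(series.day_values, dtype=float)[:TRAIN_DAYS]
    if len(days) != TRAIN_DAYS:
        raise ValueError(f"need at least {TRAIN_DAYS} days, got {len(days)}")
    values: dict[str, float] = {}
    for m, name in enumerate(_MONTHS):
        block = days[30 * m : 30 * (m + 1)]
        values[f"mean_{name}_month"] = float(block.mean())
        values[f"missed_{name}_month"] = float(np.count_nonzero(block == 0.0))
    for w in range(12):
        block = days[7 * w : 7 * (w + 1)]
        values[f"mean_week_{w + 1}"] = float(block.mean())
    return FeatureVector(user_id=series.user_id, values=values)


def feature_matrix(cohort: list[DailySeries]) -> pd.DataFrame:
    """All 18 features for a cohort, one row per user, canonical columns."""
    rows = [extract_features(s) for s in cohort]
    return pd.DataFrame(
        [[fv.values[n] for n in FEATURE_NAMES] for fv in rows],
        index=pd.Index([s.user_id for s in cohort], name="user_id"),
        columns=list(FEATURE_NAMES),
    )


@dataclass
class CohortScaler:
    """Cohort-level z-scoring statistics for a feature subset.

    Constant features (sd = 0) map to 0 rather than dividing by zero.
    """

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame, names: tuple[str, ...]) -> "CohortScaler":
        sub = table[list(names)].to_numpy(dtype=float)
        return cls(
            names=tuple(names),
            mean=sub.mean(axis=0),
            sd=sub.std(axis=0, ddof=0),
        )

    def transform(self, x: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd > 0, self.sd, 1.0)
        out = (np.asarray(x, dtype=float) - self.mean) / sd
        return np.where(self.sd > 0, out, 0.0)


def preset_names(preset: str) -> tuple[str, ...]:
    try:
        return PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown feature preset {preset!r}; expected one of {sorted(PRESETS)}"
        ) from None


def select_preset(
    fv: FeatureVector,
    preset: str,
    standardize: bool = False,
    scaler: CohortScaler | None = None,
) -> np.ndarray:
    """Return a preset's features as a vector in fixed documented order.

    If ``standardize`` is true a fitted :class:`CohortScaler` (supplying
    cohort means/sds) must be provided.  The clustering defaults reason in
    raw seconds, so standardisation is off by default.
    """
    names = preset_names(preset)
    x = fv.as_array(names)
    if standardize:
        if scaler is None:
            raise ValueError("standardize=True requires a fitted CohortScaler")
        if tuple(scaler.names) != names:
            raise ValueError("scaler was fitted for a different preset")
        x = scaler.transform(x)
    return x
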