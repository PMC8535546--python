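"""The cluster-conditioned ensemble framework, as model/results objects.

:class:`AdherenceFramework` is built from a cohort of 120-day daily series.
``fit`` (i) clusters users on features of their first 90 days, (ii) grid-
searches a per-user one-step forecaster on each user's 90-day training
window (month 4 is never shown to any model), and (iii) groups the winning
regressors into one ensemble per cluster.  The returned
:class:`AdherenceResults` predicts a new user's fourth month as the
elementwise mean of the forecasts of the ensemble their cluster selects,
binarised into adherent / non-adherent by the evaluation rule.

A ``"none"`` clustering mode exposes the single-ensemble baseline (no
clustering stage).  When a cluster is empty or affinity propagation did not
converge (sentinel -1), prediction degrades gracefully to the global
ensemble of all members.

Leave-one-user-out evaluation excludes only the held-out user's own
ensemble member; the clustering fit is shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering as cl
from .evaluation import DEFAULT_TAU, confusion, metrics, predicted_label, true_label
from .features import CohortScaler, extract_features, feature_matrix, preset_names
from .regressors import TrainedRegressor, default_grid, forecast_recursive, grid_search_user
from .sessions_io import DailySeries, PERIOD_DAYS, TRAIN_DAYS

__all__ = [
    "KMeansConfig",
    "BirchConfig",
    "APConfig",
    "NoClusteringConfig",
    "RegressorConfig",
    "EnsembleMember",
    "AdherenceFramework",
    "AdherenceResults",
    "train_framework",
    "predict_month4",
    "loo_evaluate",
]


# -- configuration ----------------------------------------------------------

@dataclass(frozen=True)
class KMeansConfig:
    k: int = 4
    max_iter: int = 300
    n_restarts: int = 10

    def fit(self, X: np.ndarray, seed: int):
        return cl.kmeans_fit(X, self.k, max_iter=self.max_iter,
                             n_restarts=self.n_restarts, seed=seed)


@dataclass(frozen=True)
class BirchConfig:
    threshold: float = 0.1
    branching: int = 50
    n_global_clusters: int = 4

    def fit(self, X: np.ndarray, seed: int):
        del seed  # BIRCH insertion order is the data order; no randomness
        return cl.birch_fit(X, threshold=self.threshold, branching=self.branching,
                            n_global_clusters=self.n_global_clusters)


@dataclass(frozen=True)
class APConfig:
    damping: float = 0.7
    preference: float | str = "median"
    max_iter: int = 200
    convergence_iter: int = 15

    def fit(self, X: np.ndarray, seed: int):
        del seed  # message passing is deterministic
        return cl.ap_fit(X, damping=self.damping, preference=self.preference,
                         max_iter=self.max_iter, convergence_iter=self.convergence_iter)


@dataclass(frozen=True)
class NoClusteringConfig:
    """Single-ensemble baseline: every user in cluster 0, no clustering fit."""

    def fit(self, X: np.ndarray, seed: int):
        return None


_CLUSTERING_BY_NAME = {
    "kmeans": KMeansConfig,
    "birch": BirchConfig,
    "ap": APConfig,
    "none": NoClusteringConfig,
}


def clustering_config(spec) -> object:
    """Coerce a name or config object into a clustering config."""
    if isinstance(spec, str):
        try:
            return _CLUSTERING_BY_NAME[spec]()
        except KeyError:
            raise ValueError(
                f"unknown clustering {spec!r}; expected one of {sorted(_CLUSTERING_BY_NAME)}"
            ) from None
    return spec


@dataclass(frozen=True)
class RegressorConfig:
    """Which forecaster family to grid-search per user."""

    kind: str = "svr"  # 'svr' | 'lstm'
    grid: tuple | None = None  # None -> the family's default grid

    def __post_init__(self):
        if self.kind not in ("svr", "lstm"):
            raise ValueError(f"unknown regressor kind {self.kind!r}")

    def resolved_grid(self) -> list:
        return list(self.grid) if self.grid is not None else default_grid(self.kind)


# -- model / results --------------------------------------------------------

@dataclass
class EnsembleMember:
    """One trained per-user forecaster, tagged with its source user's cluster."""

    user_id: str
    cluster_id: int
    regressor: TrainedRegressor


class AdherenceFramework:
    """Adherence-prediction model over a cohort of 120-day daily series.

    Parameters
    ----------
    cohort
        Users' :class:`~adherefit.sessions_io.DailySeries`, each of length
        120.  Only days 1-90 are used for fitting.
    clustering
        ``"kmeans" | "birch" | "ap" | "none"`` or a config dataclass.
    regressor
        ``"svr" | "lstm"`` or a :class:`RegressorConfig`.
    preset
        Feature subset for clustering (``missed_months`` by default — the
        skipped-days features that separate behavioural groups best).
    standardize
        z-score features with cohort statistics before clustering.
    tau
        Seconds/month threshold binarising a forecast into adherent.
    """

    def __init__(
        self,
        cohort: Sequence[DailySeries],
        clustering="kmeans",
        regressor="svr",
        preset: str = "missed_months",
        standardize: bool = False,
        tau: float = DEFAULT_TAU,
    ):
        cohort = list(cohort)
        if not cohort:
            raise ValueError("cohort must be non-empty")
        for s in cohort:
            if len(s) != PERIOD_DAYS:
                raise ValueError(
                    f"user {s.user_id!r}: series length {len(s)} != {PERIOD_DAYS}"
                )
        self.cohort = cohort
        self.clustering = clustering_config(clustering)
        self.regressor = (
            RegressorConfig(kind=regressor) if isinstance(regressor, str) else regressor
        )
        self.preset = preset
        preset_names(preset)  # validate early
        self.standardize = standardize
        self.tau = float(tau)

    def fit(self, seed: int = 0, progress: bool = False) -> "AdherenceResults":
        """Fit clustering and all per-user regressors; returns results."""
        names = preset_names(self.preset)
        table = feature_matrix(self.cohort)
        scaler = CohortScaler.fit(table, names) if self.standardize else None
        X = table[list(names)].to_numpy(dtype=float)
        if scaler is not None:
            X = np.vstack([scaler.transform(row) for row in X])
        cluster_model = self.clustering.fit(X, seed=seed)
        labels = _training_labels(cluster_model, X)
        grid = self.regressor.resolved_grid()
        members: list[EnsembleMember] = []
        fitted_labels: dict[str, int] = {}
        for i, series in enumerate(self.cohort):
            if progress:
                print(f"  training user {i + 1}/{len(self.cohort)} ({series.user_id})")
            train = series.day_values[:TRAIN_DAYS]
            try:
                reg = grid_search_user(train, self.regressor.kind, grid, seed=seed + i)
            except ValueError as exc:
                warnings.warn(
                    f"user {series.user_id!r} excluded from ensembles: {exc}",
                    stacklevel=2,
                )
                continue
            members.append(EnsembleMember(series.user_id, int(labels[i]), reg))
            fitted_labels[series.user_id] = int(labels[i])
        if not members:
            raise ValueError("no user passed the regressor preconditions")
        return AdherenceResults(
            model=self,
            cluster_model=cluster_model,
            scaler=scaler,
            members=members,
            seed=seed,
        )


def _training_labels(cluster_model, X: np.ndarray) -> np.ndarray:
    if cluster_model is None:
        return np.zeros(len(X), dtype=int)
    return np.asarray(cluster_model.labels, dtype=int)


class AdherenceResults:
    """Fitted framework: clustering + per-cluster ensembles of regressors."""

    def __init__(self, model, cluster_model, scaler, members, seed):
        self.model = model
        self.cluster_model = cluster_model
        self.scaler = scaler
        self.members = list(members)
        self.seed = seed
        self.ensembles: dict[int, list[EnsembleMember]] = {}
        for m in self.members:
            self.ensembles.setdefault(m.cluster_id, []).append(m)

    # -- prediction -------------------------------------------------------

    def _features(self, first_90_days: np.ndarray) -> np.ndarray:
        history = np.asarray(first_90_days, dtype=float).ravel()
        if len(history) < TRAIN_DAYS:
            raise ValueError(f"need {TRAIN_DAYS} days of history, got {len(history)}")
        fv = extract_features(DailySeries("new", history[:TRAIN_DAYS]))
        x = fv.as_array(preset_names(self.model.preset))
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return x

    def assign(self, first_90_days) -> int:
        """Cluster id for a new user's first-90-day history (-1 sentinel when
        affinity propagation never converged)."""
        if self.cluster_model is None:
            return 0
        return cl.assign_cluster(self.cluster_model, self._features(first_90_days))

    def _select_ensemble(self, cluster_id: int, exclude: str | None = None):
        members = self.ensembles.get(cluster_id, [])
        members = [m for m in members if m.user_id != exclude]
        if not members:  # empty cluster or -1 sentinel: global fallback
            members = [m for m in self.members if m.user_id != exclude]
        return members

    def predict_month4(self, first_90_days, exclude_user: str | None = None) -> np.ndarray:
        """Elementwise-mean 30-day forecast of the selected cluster ensemble."""
        history = np.asarray(first_90_days, dtype=float).ravel()[:TRAIN_DAYS]
        members = self._select_ensemble(self.assign(history), exclude=exclude_user)
        forecasts = np.vstack(
            [forecast_recursive(m.regressor, history, horizon=30) for m in members]
        )
        return forecasts.mean(axis=0)

    def predict_label(self, first_90_days) -> str:
        return predicted_label(self.predict_month4(first_90_days), tau=self.model.tau)

    # -- evaluation -------------------------------------------------------

    def leave_one_out(self, progress: bool = False) -> "LOOReport":
        """Score every cohort user with their own ensemble member excluded.

        Each user's month 4 is predicted from the cluster ensemble built
        from the remaining users' models, then labelled against the ground
        truth of their held-out fourth month.
        """
        cohort = self.model.cohort
        if len(cohort) < 2:
            raise ValueError("leave-one-out evaluation needs a cohort of at least 2")
        by_user = {m.user_id: m for m in self.members}
        # member forecasts are reusable across evaluations: cache by
        # (member, evaluated user)
        rows = []
        fc_cache: dict[tuple[str, str], np.ndarray] = {}

        def member_forecast(m: EnsembleMember, series: DailySeries) -> np.ndarray:
            key = (m.user_id, series.user_id)
            if key not in fc_cache:
                fc_cache[key] = forecast_recursive(
                    m.regressor, series.day_values[:TRAIN_DAYS], horizon=30
                )
            return fc_cache[key]

        for i, series in enumerate(cohort):
            if progress:
                print(f"  evaluating user {i + 1}/{len(cohort)} ({series.user_id})")
            own = by_user.get(series.user_id)
            cluster_id = own.cluster_id if own is not None else self.assign(series.day_values[:TRAIN_DAYS])
            members = self._select_ensemble(cluster_id, exclude=series.user_id)
            forecasts = np.vstack([member_forecast(m, series) for m in members])
            pred = forecasts.mean(axis=0)
            rows.append(
                {
                    "user_id": series.user_id,
                    "cluster": cluster_id,
                    "predicted_total_s": float(pred.sum()),
                    "true_label": true_label(series),
                    "predicted_label": predicted_label(pred, tau=self.model.tau),
                }
            )
        return LOOReport(pd.DataFrame(rows))

    # -- reporting --------------------------------------------------------

    @property
    def n_clusters(self) -> int:
        return len(self.ensembles)

    def summary(self) -> str:
        lines = [
            "Adherence ensemble framework",
            "=" * 42,
            f"cohort size           {len(self.model.cohort)}",
            f"clustering            {type(self.model.clustering).__name__}",
            f"feature preset        {self.model.preset}"
            + (" (standardized)" if self.scaler is not None else ""),
            f"regressor             {self.model.regressor.kind}"
            f" (grid of {len(self.model.regressor.resolved_grid())})",
            f"adherence tau         {self.model.tau:g} s/month",
            f"clusters / ensembles  {self.n_clusters}",
        ]
        for cid in sorted(self.ensembles):
            ms = self.ensembles[cid]
            maes = [m.regressor.train_mae for m in ms]
            lines.append(
                f"  cluster {cid:>3}: {len(ms):>4} members, "
                f"median train MAE {np.median(maes):8.1f} s"
            )
        return "\n".join(lines)

    def plot_forecast(self, first_90_days, true_month4=None, ax=None):
        """Plot a user's 90-day history and the 30-day ensemble forecast."""
        import matplotlib.pyplot as plt

        history = np.asarray(first_90_days, dtype=float).ravel()[:TRAIN_DAYS]
        pred = self.predict_month4(history)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(np.arange(1, TRAIN_DAYS + 1), history, color="tab:red", label="months 1-3")
        days4 = np.arange(TRAIN_DAYS + 1, TRAIN_DAYS + 31)
        ax.plot(days4, pred, color="tab:blue", label="forecast month 4")
        if true_month4 is not None:
            ax.plot(days4, np.asarray(true_month4, dtype=float), color="tab:purple",
                    alpha=0.6, label="actual month 4")
        ax.set_xlabel("day")
        ax.set_ylabel("workout seconds")
        ax.legend(loc="best")
        return ax

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialise the fitted bundle (joblib) to ``path``."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "AdherenceResults":
        import joblib

        return joblib.load(path)


@dataclass
class LOOReport:
    """Leave-one-out results table plus derived classification metrics."""

    table: pd.DataFrame

    @property
    def confusion(self):
        return confusion(list(self.table["true_label"]), list(self.table["predicted_label"]))

    @property
    def metrics(self):
        return metrics(self.confusion)

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    @property
    def majority_baseline(self) -> float:
        """Accuracy of always predicting the most frequent true class."""
        counts = self.table["true_label"].value_counts()
        return float(counts.max() / counts.sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# -- functional wrappers ----------------------------------------------------

def train_framework(cohort, clustering="kmeans", regressor="svr",
                    preset: str = "missed_months", seed: int = 0,
                    standardize: bool = False, tau: float = DEFAULT_TAU) -> AdherenceResults:
    """Build and fit an :class:`AdherenceFramework` in one call."""
    return AdherenceFramework(
        cohort, clustering=clustering, regressor=regressor, preset=preset,
        standardize=standardize, tau=tau,
    ).fit(seed=seed)


def predict_month4(results: AdherenceResults, first_90_days) -> np.ndarray:
    return results.predict_month4(first_90_days)


def loo_evaluate(cohort, clustering="kmeans", regressor="svr",
                 preset: str = "missed_months", seed: int = 0,
                 standardize: bool = False, tau: float = DEFAULT_TAU) -> LOOReport:
    """Fit the framework and run leave-one-user-out evaluation."""
    return train_framework(
        cohort, clustering=clustering, regressor=regressor, preset=preset,
        seed=seed, standardize=standardize, tau=tau,
    ).leave_one_out()
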