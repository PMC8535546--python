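"""Seedable synthetic cohorts of fitness-app users.

Each simulated user follows one of four behavioural archetypes mirroring
the groups that clustering recovers on real cohorts:

* ``steady``    — about one session every two days across all three months;
* ``declining`` — moderate activity in month 1 that tapers off;
* ``ramping``   — low activity in month 1 that grows in months 2-3;
* ``inactive``  — very little activity throughout.

A day in months 1-3 is active with the archetype's per-month probability;
active days draw their accumulated seconds from a log-normal distribution
(positive and right-skewed, like real session logs whose daily standard
deviation far exceeds the mean).  Adherent users remain active in month 4
with a continuation probability (at least one active day is enforced);
non-adherent users have an all-zero fourth month, so generated labels are
recoverable exactly by the adherence rule.

The defaults aim at a cohort whose daily means sit in the 300-400 s band
and whose month-1 per-user means mass in the (0, 300] and (300, 1800]
second bins, with an adherent fraction of 112/246.  Which users are
adherent is drawn with archetype-dependent propensities, reflecting that
recent training frequency is strongly predictive of continuation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sessions_io import DailySeries, PERIOD_DAYS, TRAIN_DAYS
from .evaluation import ADHERENT, NON_ADHERENT

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "DEFAULT_ARCHETYPES",
    "simulate_user",
    "simulate_cohort",
    "cohort_sessions_csv",
    "cohort_truth_frame",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One behavioural template.

    ``month_probs`` are the daily session probabilities for months 1-3;
    ``continuation_prob`` the daily session probability in month 4 for an
    adherent user; ``duration_median``/``duration_sigma`` parameterise the
    log-normal active-day seconds; ``adherence_propensity`` weights the
    draw of which users end up adherent.
    """

    name: str
    month_probs: tuple[float, float, float]
    continuation_prob: float
    duration_median: float = 800.0
    duration_sigma: float = 0.5
    adherence_propensity: float = 0.5

    def __post_init__(self) -> None:
        probs = (*self.month_probs, self.continuation_prob)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"archetype {self.name!r}: probabilities must be in [0, 1]")
        if self.duration_median <= 0 or self.duration_sigma < 0:
            raise ValueError(f"archetype {self.name!r}: invalid duration parameters")


DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("steady", (0.50, 0.50, 0.50), 0.45, adherence_propensity=0.95),
    ArchetypeSpec("declining", (0.60, 0.25, 0.10), 0.10, adherence_propensity=0.08),
    ArchetypeSpec("ramping", (0.10, 0.35, 0.60), 0.55, adherence_propensity=0.92),
    ArchetypeSpec("inactive", (0.05, 0.05, 0.05), 0.10, adherence_propensity=0.02),
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings."""

    n_users: int = 246
    archetypes: tuple[ArchetypeSpec, ...] = DEFAULT_ARCHETYPES
    mixture_weights: tuple[float, ...] = (0.30, 0.30, 0.20, 0.20)
    adherent_fraction: float = 112 / 246
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ValueError("n_users must be non-negative")
        if len(self.mixture_weights) != len(self.archetypes):
            raise ValueError("one mixture weight per archetype required")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0.0 <= self.adherent_fraction <= 1.0:
            raise ValueError("adherent_fraction must be in [0, 1]")


def _draw_durations(rng: np.random.Generator, arch: ArchetypeSpec, size: int) -> np.ndarray:
    return rng.lognormal(mean=np.log(arch.duration_median), sigma=arch.duration_sigma, size=size)


def _stratified_archetypes(rng: np.random.Generator, weights: np.ndarray, n: int) -> np.ndarray:
    """Archetype indices with exact mixture proportions (largest-remainder
    apportionment), randomly ordered.

    The cohort composition is a study condition, so it is realised exactly
    — like the adherent count — rather than drawn multinomially; randomness
    stays in which user gets which archetype and in their activity patterns.
    """
    ideal = weights * n
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(-(ideal - counts)):
        if counts.sum() == n:
            break
        counts[i] += 1
    idx = np.repeat(np.arange(len(weights)), counts)
    return idx[rng.permutation(n)]


def _sample_exact_size(rng: np.random.Generator, weights: np.ndarray, m: int) -> np.ndarray:
    """Fixed-size sample whose inclusion probabilities are proportional to
    ``weights`` (capped at 1), via systematic PPS sampling.

    Sequential weighted draws without replacement would flatten the designed
    per-archetype adherence rates once the high-weight pool is exhausted;
    systematic sampling realises pi_i = min(1, c * w_i) exactly while
    keeping the sample size fixed at ``m``.
    """
    n = len(weights)
    if m <= 0:
        return np.zeros(n, dtype=bool)
    if m >= n:
        return np.ones(n, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(n)
    capped = np.zeros(n, dtype=bool)
    c = 0.0
    for _ in range(n):  # iteratively cap weights whose pi would exceed 1
        free = ~capped
        c = (m - capped.sum()) / w[free].sum()
        newly = free & (c * w >= 1.0)
        if not newly.any():
            break
        capped |= newly
    pi = np.where(capped, 1.0, np.minimum(1.0, c * w))
    order = rng.permutation(n)
    csum = np.cumsum(pi[order])
    points = rng.random() + np.arange(m)
    chosen = order[np.searchsorted(csum, points, side="left")]
    flags = np.zeros(n, dtype=bool)
    flags[chosen] = True
    return flags


def simulate_user(
    arch: ArchetypeSpec,
    adherent: bool,
    rng: np.random.Generator,
    user_id: str = "u0",
) -> tuple[DailySeries, str, str]:
    """Simulate one 120-day series; returns (series, label, archetype name)."""
    values = np.zeros(PERIOD_DAYS, dtype=float)
    for m, p in enumerate(arch.month_probs):
        active = rng.random(30) < p
        values[30 * m : 30 * (m + 1)][active] = _draw_durations(rng, arch, int(active.sum()))
    if adherent:
        active = rng.random(30) < arch.continuation_prob
        if not active.any():
            active[rng.integers(30)] = True  # adherence means >= 1 active day
        values[TRAIN_DAYS:][active] = _draw_durations(rng, arch, int(active.sum()))
        label = ADHERENT
    else:
        label = NON_ADHERENT  # month 4 left all-zero
    return DailySeries(user_id=user_id, day_values=values), label, arch.name


def simulate_cohort(config: CohortConfig) -> list[tuple[DailySeries, str, str]]:
    """Simulate a whole cohort, reproducibly for a given seed.

    The realised adherent count is round(adherent_fraction * n); the
    adherent set is drawn without replacement with probability proportional
    to each user's archetype adherence propensity.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    if n == 0:
        return []
    arch_idx = _stratified_archetypes(rng, np.asarray(config.mixture_weights), n)
    n_adherent = round(config.adherent_fraction * n)
    propensity = np.array(
        [config.archetypes[i].adherence_propensity for i in arch_idx], dtype=float
    )
    adherent_flags = _sample_exact_size(rng, propensity, n_adherent)
    width = len(str(max(n - 1, 1)))
    out = []
    for u in range(n):
        arch = config.archetypes[arch_idx[u]]
        out.append(simulate_user(arch, bool(adherent_flags[u]), rng, user_id=f"u{u:0{width}d}"))
    return out


def cohort_sessions_csv(cohort: list[tuple[DailySeries, str, str]], start_date: str = "2021-01-01") -> str:
    """Emit a cohort as a sessions CSV in the standard dialect, one finished
    session per active day, so the file pipeline can be driven end to end."""
    base = pd.Timestamp(start_date)
    buf = io.StringIO()
    buf.write("user_id,start_time,duration_s,finished\n")
    for series, _label, _arch in cohort:
        days = np.flatnonzero(series.day_values > 0)
        if len(days) == 0:
            # one zero-second finished session anchors otherwise-empty users
            buf.write(f"{series.user_id},{base.date()}T12:00:00,0.0,true\n")
            continue
        anchor = base
        if days[0] != 0:
            # zero-second session pins the anchor date so day indices round-trip
            buf.write(f"{series.user_id},{anchor.date()}T12:00:00,0.0,true\n")
        for d in days:
            ts = (anchor + pd.Timedelta(days=int(d))).date()
            buf.write(f"{series.user_id},{ts}T12:00:00,{series.day_values[d]:.6f},true\n")
    return buf.getvalue()


def cohort_truth_frame(cohort: list[tuple[DailySeries, str, str]]) -> pd.DataFrame:
    """Ground-truth table: user_id, label, archetype."""
    return pd.DataFrame(
        [(s.user_id, label, arch) for s, label, arch in cohort],
        columns=["user_id", "label", "archetype"],
    )
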