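"""Larval developmental-timing analysis on dropout diets.

Cohorts of (nominally 40) eggs are seeded per replicate tube; new pupae are
scored daily until day 30.  The endpoint is D50 — the day by which half of
the finally emerged pupae of a replicate have entered metamorphosis —
estimated by fitting a cumulative-logistic curve to the cumulative
pupariation fraction, with deterministic linear interpolation as fallback.

Quality rules follow the screen design: replicates with egg-to-pupa survival
below 25% are excluded (larvae are cannibalistic; siblings become a nutrient
source), and a condition counts as "failed to develop" when the mean
survival of its replicates is below 25%.

Group comparisons use a Kruskal–Wallis test followed by post hoc Dunn tests
against the designated control (the complete-diet condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

ASSOCIATIONS = ("GF", "Ap", "Lp", "Ap_HK", "Lp_HK")

SURVIVAL_CUTOFF = 0.25
CENSOR_DAY = 30

#: Sentinel for replicates in which no pupa ever emerged.
CENSORED = float("nan")


@dataclass(frozen=True)
class Condition:
    medium: str
    association: str

    def __post_init__(self) -> None:
        if self.association not in ASSOCIATIONS:
            raise ValueError(f"bad association {self.association!r}")

    def __str__(self) -> str:
        return f"{self.medium}/{self.association}"


@dataclass
class PupariationRecord:
    """Daily new-pupae counts for one replicate tube."""

    condition: Condition
    replicate: str
    n_eggs: int
    daily_pupae: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_eggs <= 0:
            raise ValueError("n_eggs must be positive")
        for day, count in self.daily_pupae.items():
            if not (1 <= day <= CENSOR_DAY):
                raise ValueError(f"day {day} outside 1..{CENSOR_DAY}")
            if count < 0:
                raise ValueError("daily pupae counts must be >= 0")
        if self.total_pupae > self.n_eggs:
            raise ValueError("more pupae than eggs")

    @property
    def total_pupae(self) -> int:
        return sum(self.daily_pupae.values())

    @property
    def survival(self) -> float:
        return self.total_pupae / self.n_eggs

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """(days, cumulative counts) over days with at least one new pupa."""
        days = np.array(sorted(d for d, c in self.daily_pupae.items() if c > 0), dtype=float)
        counts = np.cumsum([self.daily_pupae[int(d)] for d in days])
        return days, counts.astype(float)


@dataclass
class D50Result:
    condition: Condition
    d50s: list[float]
    n_replicates_used: int
    developed: bool
    survival: float

    @property
    def mean(self) -> float:
        if not self.developed or not self.d50s:
            return CENSORED
        return float(np.mean(self.d50s))

    @property
    def sem(self) -> float:
        if not self.developed or len(self.d50s) < 2:
            return CENSORED
        return float(np.std(self.d50s, ddof=1) / math.sqrt(len(self.d50s)))


def _logistic_cdf(t: np.ndarray, d50: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - d50) / scale))


def interpolate_d50(days: np.ndarray, cum_fraction: np.ndarray) -> float:
    """Deterministic fallback: linear interpolation of the first 50% crossing."""
    idx = int(np.argmax(cum_fraction >= 0.5))
    if cum_fraction[idx] == 0.5 or idx == 0:
        return float(days[idx])
    d0, d1 = days[idx - 1], days[idx]
    f0, f1 = cum_fraction[idx - 1], cum_fraction[idx]
    return float(d0 + (0.5 - f0) / (f1 - f0) * (d1 - d0))


def compute_d50(record: PupariationRecord, force_interpolation: bool = False) -> float:
    """D50 of one replicate, in days; NaN (censored) when no pupa emerged.

    The cumulative pupariation fraction — of the finally emerged count, not
    of seeded eggs, so delayed-but-developed replicates keep a defined D50 —
    is fitted with a two-parameter logistic CDF; the fit falls back to linear
    interpolation when it cannot converge.
    """
    if record.total_pupae == 0:
        return CENSORED
    days, cum = record.cumulative()
    frac = cum / record.total_pupae
    if len(days) == 1:
        return float(days[0])  # degenerate step: every pupa on one day
    interp = interpolate_d50(days, frac)
    if force_interpolation:
        return interp
    lo, hi = float(days[0]), float(days[-1])
    try:
        popt, _ = optimize.curve_fit(
            _logistic_cdf, days, frac,
            p0=(interp, 1.0),
            bounds=((lo, 1e-6), (hi, 50.0)),
            maxfev=2000,
        )
        return float(popt[0])
    except (RuntimeError, ValueError):
        return interp


def apply_exclusions(
    records: Sequence[PupariationRecord], survival_cutoff: float = SURVIVAL_CUTOFF
) -> tuple[list[PupariationRecord], dict[Condition, bool]]:
    """Drop low-survival replicates; decide per-condition development.

    A replicate is excluded when its egg-to-pupa survival is below the cutoff
    (< 25%, i.e. fewer than 10 of 40 eggs).  A condition is marked
    developed=False when the *pre-exclusion* mean survival of its replicates
    is below the cutoff.  Idempotent.
    """
    kept = [r for r in records if r.survival >= survival_cutoff]
    verdicts: dict[Condition, bool] = {}
    by_condition: dict[Condition, list[PupariationRecord]] = {}
    for r in records:
        by_condition.setdefault(r.condition, []).append(r)
    for cond, reps in by_condition.items():
        n_eggs = {r.n_eggs for r in reps}
        if len(n_eggs) != 1:
            raise ValueError(f"replicates of {cond} disagree on n_eggs: {sorted(n_eggs)}")
        verdicts[cond] = float(np.mean([r.survival for r in reps])) >= survival_cutoff
    return kept, verdicts


def summarize_condition(records: Sequence[PupariationRecord], survival_cutoff: float = SURVIVAL_CUTOFF) -> list[D50Result]:
    """Per-condition D50 summary after exclusion; censored replicates never
    contribute to means."""
    kept, verdicts = apply_exclusions(records, survival_cutoff)
    by_condition: dict[Condition, list[PupariationRecord]] = {}
    for r in kept:
        by_condition.setdefault(r.condition, []).append(r)
    all_conditions: dict[Condition, list[PupariationRecord]] = {}
    for r in records:
        all_conditions.setdefault(r.condition, []).append(r)
    out = []
    for cond in all_conditions:
        reps = by_condition.get(cond, [])
        d50s = [compute_d50(r) for r in reps]
        d50s = [d for d in d50s if not math.isnan(d)]
        survival = float(np.mean([r.survival for r in all_conditions[cond]]))
        out.append(
            D50Result(
                condition=cond,
                d50s=d50s,
                n_replicates_used=len(d50s),
                developed=verdicts[cond] and bool(d50s),
                survival=survival,
            )
        )
    return out


def classify_requirement(
    dropout_condition: D50Result, complete_condition: D50Result, p_value: float, alpha: float = 0.05
) -> str:
    """Nutrient requirement of the larvae for the dropped component.

    ``essential`` — larvae fail to develop without it; ``limiting`` —
    development succeeds but is significantly slower than on the complete
    diet; ``dispensable`` — development at the complete-diet rate.
    """
    if not complete_condition.developed:
        raise ValueError("complete-diet reference condition did not develop; cannot classify")
    if not dropout_condition.developed:
        return "essential"
    if p_value < alpha and dropout_condition.mean > complete_condition.mean:
        return "limiting"
    return "dispensable"


def _dunn_z(values: Sequence[float], labels: Sequence[str], group_a: str, group_b: str) -> float:
    """Dunn's post hoc z-statistic on pooled ranks, with tie correction."""
    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values)
    n = len(values)
    labels = np.asarray(labels)
    ra = ranks[labels == group_a]
    rb = ranks[labels == group_b]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb))
    if var <= 0:
        return 0.0
    return float((ra.mean() - rb.mean()) / math.sqrt(var))


def compare_to_control(
    groups: Mapping[str, Sequence[float]],
    control: str,
    adjust: str = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal–Wallis across all groups, then Dunn tests vs the control.

    Returns one row per non-control group with the Dunn z, the raw two-sided
    p, and the adjusted p (``adjust`` is any method name accepted by
    ``statsmodels.stats.multitest.multipletests``, or ``"none"``).  Groups of
    size < 2 are flagged not testable.  Deterministic.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    testable = {name: len(vals) >= 2 for name, vals in groups.items()}
    usable = {name: np.asarray(vals, float) for name, vals in groups.items() if testable[name]}
    if testable[control] and len(usable) >= 2:
        kw_h, kw_p = stats.kruskal(*usable.values())
    else:
        kw_h, kw_p = math.nan, math.nan
    # classic Dunn: one joint ranking over all testable groups
    pooled = np.concatenate(list(usable.values())) if usable else np.array([])
    labels = np.concatenate([[name] * len(v) for name, v in usable.items()]) if usable else np.array([])
    rows = []
    for name, vals in groups.items():
        if name == control:
            continue
        if not (testable[name] and testable[control]):
            rows.append({"group": name, "n": len(vals), "z": math.nan, "p_raw": math.nan, "testable": False})
            continue
        z = _dunn_z(pooled, labels, name, control)
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group": name, "n": len(vals), "z": z, "p_raw": p, "testable": True})
    df = pd.DataFrame(rows)
    if adjust == "none" or df.empty:
        df["p_adj"] = df["p_raw"]
    else:
        from statsmodels.stats.multitest import multipletests

        mask = df["testable"].to_numpy()
        adj = np.full(len(df), math.nan)
        if mask.any():
            adj[mask] = multipletests(df.loc[mask, "p_raw"], alpha=alpha, method=adjust)[1]
        df["p_adj"] = adj
    df.attrs["kruskal_h"] = float(kw_h)
    df.attrs["kruskal_p"] = float(kw_p)
    return df


def correlate_load_vs_d50(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Pearson product–moment correlation between log10 bacterial load and D50.

    Raises on fewer than 3 finite pairs or zero variance in either variable.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (load, d50) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(r), float(p)


def read_pupariation_csv(path) -> list[PupariationRecord]:
    """Read ``medium,association,replicate,n_eggs,day,new_pupae`` rows."""
    df = pd.read_csv(path)
    expected = ["medium", "association", "replicate", "n_eggs", "day", "new_pupae"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"pupariation csv missing columns {missing}")
    records = []
    for (med, assoc, rep, n_eggs), grp in df.groupby(["medium", "association", "replicate", "n_eggs"], sort=True):
        daily = {int(d): int(c) for d, c in zip(grp["day"], grp["new_pupae"]) if c > 0}
        records.append(
            PupariationRecord(
                condition=Condition(medium=med, association=assoc),
                replicate=str(rep), n_eggs=int(n_eggs), daily_pupae=daily,
            )
        )
    return records


def load_d50_table(path) -> pd.DataFrame:
    """Load a per-replicate D50 table: ``medium,association,replicate,d50``.

    Used to recompute per-condition mean D50 from published per-replicate
    source data when such a file is available; this package does not ship
    one.
    """
    df = pd.read_csv(path)
    expected = ["medium", "association", "replicate", "d50"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"d50 table missing columns {missing}")
    return df.groupby(["medium", "association"])["d50"].agg(["mean", "sem", "count"]).reset_index()
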