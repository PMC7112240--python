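"""Bacterial growth-screen summarization.

Plate-reader OD600 time series (72 h, one reading every 30 min in the
reference protocol) are reduced to the maximal optical density reached
(OD_Max), averaged over replicates, and turned into a categorical growth
call per (organism, medium).  Static cultures scored by end-point CFU counts
are summarized as log10 fold change over the inoculum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROWTH_CATEGORIES = ("growth", "reduced", "none")

#: OD above baseline below which a culture is called "none".
DEFAULT_NONE_MARGIN = 0.05
#: Fraction of the complete-medium OD_Max below which growth is "reduced".
DEFAULT_REDUCED_FRACTION = 0.25


@dataclass
class GrowthCurve:
    """A blank-corrected OD600 time series for one replicate well."""

    organism: str
    medium: str
    times: np.ndarray  # hours
    od: np.ndarray
    regime: str = "agitated"  # or "static"
    replicate: str = "1"
    blank_corrected: bool = True
    #: number of negative readings clipped to 0 during correction
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.regime not in ("agitated", "static"):
            raise ValueError(f"bad regime {self.regime!r}")
        if self.times.shape != self.od.shape or self.times.size < 2:
            raise ValueError("times and od must be equal-length arrays with >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            neg = int(np.sum(self.od < 0))
            self.od = np.clip(self.od, 0.0, None)
            self.n_clipped += neg

    @classmethod
    def from_raw(cls, organism: str, medium: str, times: Sequence[float], od: Sequence[float], **kw) -> "GrowthCurve":
        """Blank-correct by subtracting the t=0 reading (no dedicated blank
        wells in the reference protocol)."""
        od = np.asarray(od, dtype=float)
        return cls(organism=organism, medium=medium, times=np.asarray(times, float), od=od - od[0],
                   blank_corrected=True, **kw)


@dataclass(frozen=True)
class CfuMeasurement:
    organism: str
    medium: str
    regime: str
    time: float
    cfu: float
    unit: str = "CFU/mL"
    replicate: str = "1"
    inoculum: float = 1e4

    def __post_init__(self) -> None:
        if self.cfu < 0:
            raise ValueError("cfu must be >= 0")
        if self.inoculum <= 0:
            raise ValueError("inoculum must be > 0")


@dataclass(frozen=True)
class GrowthCall:
    organism: str
    medium: str
    od_max: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in GROWTH_CATEGORIES:
            raise ValueError(f"bad growth category {self.category!r}")
        if self.od_max < 0:
            raise ValueError("od_max must be >= 0")


def od_max(curve: GrowthCurve) -> float:
    """Maximal blank-corrected OD over the series."""
    return float(np.max(curve.od))


def summarize_od_max(curves: Iterable[GrowthCurve]) -> float:
    """Per-condition summary: arithmetic mean of replicate maxima."""
    maxima = [od_max(c) for c in curves]
    if not maxima:
        raise ValueError("no curves to summarize")
    return float(np.mean(maxima))


def classify_growth(
    od_max_value: float,
    baseline: float = 0.0,
    complete_ref: float = 1.0,
    none_margin: float = DEFAULT_NONE_MARGIN,
    reduced_fraction: float = DEFAULT_REDUCED_FRACTION,
) -> str:
    """Categorical call from a condition's mean OD_Max.

    ``none`` if the culture never exceeded ``baseline + none_margin``;
    ``reduced`` below ``reduced_fraction`` of the same organism's OD_Max on
    the complete medium; ``growth`` otherwise.  The thresholds are this
    pipeline's (configurable) operationalization of the verbal categories
    "fails to grow" / "grows poorly".
    """
    if complete_ref <= baseline:
        raise ValueError("complete_ref must exceed baseline")
    if od_max_value <= baseline + none_margin:
        return "none"
    if od_max_value < reduced_fraction * complete_ref:
        return "reduced"
    return "growth"


def cfu_fold_change(m: CfuMeasurement, inoculum: float | None = None) -> tuple[float, bool]:
    """log10(cfu / inoculum); a zero count is floored at -log10(inoculum)
    (i.e. one detectable cell against the inoculum) and flagged censored.

    Returns ``(log10_fold_change, censored)``.
    """
    inoc = m.inoculum if inoculum is None else inoculum
    if inoc <= 0:
        raise ValueError("inoculum must be > 0")
    if m.cfu == 0:
        return (-math.log10(inoc), True)
    return (math.log10(m.cfu / inoc), False)


def read_od_csv(path) -> list[GrowthCurve]:
    """Read long-format OD data: ``organism,medium,regime,replicate,time_h,od600``."""
    df = pd.read_csv(path)
    expected = ["organism", "medium", "regime", "replicate", "time_h", "od600"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"OD csv missing columns {missing}")
    curves = []
    for (org, med, regime, rep), grp in df.groupby(["organism", "medium", "regime", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                organism=org, medium=med, regime=regime, replicate=str(rep),
                times=grp["time_h"].to_numpy(), od=grp["od600"].to_numpy(),
            )
        )
    return curves


def read_cfu_csv(path, inoculum: float = 1e4) -> list[CfuMeasurement]:
    """Read CFU data: ``organism,medium,regime,replicate,time,unit,cfu``."""
    df = pd.read_csv(path)
    expected = ["organism", "medium", "regime", "replicate", "time", "unit", "cfu"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"CFU csv missing columns {missing}")
    return [
        CfuMeasurement(
            organism=r.organism, medium=r.medium, regime=r.regime, time=float(r.time),
            cfu=float(r.cfu), unit=r.unit, replicate=str(r.replicate), inoculum=inoculum,
        )
        for r in df.itertuples()
    ]


def screen_growth_calls(curves: Sequence[GrowthCurve], complete_medium: str = "HD",
                        none_margin: float = DEFAULT_NONE_MARGIN,
                        reduced_fraction: float = DEFAULT_REDUCED_FRACTION) -> pd.DataFrame:
    """Summarize a whole screen: per (organism, regime, medium) mean OD_Max and
    category, referenced to that organism/regime's complete-medium OD_Max."""
    rows = []
    groups: dict[tuple[str, str, str], list[GrowthCurve]] = {}
    for c in curves:
        groups.setdefault((c.organism, c.regime, c.medium), []).append(c)
    refs = {
        (org, regime): summarize_od_max(cs)
        for (org, regime, med), cs in groups.items()
        if med == complete_medium
    }
    for (org, regime, med), cs in sorted(groups.items()):
        m = summarize_od_max(cs)
        ref = refs.get((org, regime))
        if ref is None:
            raise ValueError(f"no complete-medium ({complete_medium!r}) reference for {org}/{regime}")
        rows.append(
            {
                "organism": org, "regime": regime, "medium": med,
                "od_max": m, "n_replicates": len(cs),
                "category": classify_growth(m, 0.0, ref, none_margin, reduced_fraction),
            }
        )
    return pd.DataFrame(rows)


def text_heatmap(calls: pd.DataFrame, value: str = "category") -> str:
    """Plain-text heatmap of growth calls, media as rows, organisms as columns."""
    sym = {"growth": "##", "reduced": "+-", "none": "  "}
    pivot = calls.pivot_table(index="medium", columns=["organism", "regime"], values=value, aggfunc="first")
    lines = ["medium".ljust(22) + " ".join(f"{o}/{r}"[:12].ljust(12) for o, r in pivot.columns)]
    for med, row in pivot.iterrows():
        cells = []
        for v in row:
            cells.append((sym.get(v, str(v)) if isinstance(v, str) else "..").ljust(12))
        lines.append(str(med).ljust(22) + " ".join(cells))
    return "\n".join(lines)
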