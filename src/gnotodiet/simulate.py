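"""Synthetic-data generators for every pipeline stage.

Defaults emulate the reference screen design: cohorts of 40 eggs in 5
replicate tubes scored daily up to day 30, plate-reader OD600 curves sampled
every 30 min for 72 h, and inocula of 1e4 CFU.  Pupariation-day noise is
logistic — the D50 endpoint is defined on a cumulative-logistic curve, so
recovery tests are self-consistent — and a pupa observed on day *k* is one
whose latent pupariation time fell in (k-1, k] (daily scoring), which keeps
the cumulative fraction at day *k* an unbiased estimate of the latent CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compounds import Compound, CompoundRegistry
from .dev import CENSOR_DAY, Condition, PupariationRecord
from .growth import GrowthCurve
from .medium import Medium, MediumComponent
from .network import DEFAULT_BOOTSTRAP, Reaction, ReactionNetwork


@dataclass
class SimulationConfig:
    """Parameters for all generators; same seed ⇒ bit-identical outputs."""

    seed: int = 0
    # toy-network parameters
    n_compounds: int = 15
    n_reactions: int = 20
    # growth-curve parameters
    carrying_capacity: float = 1.2  # OD600 plateau (K)
    growth_rate: float = 0.25      # 1/h logistic rate
    lag_h: float = 8.0
    noise_sd: float = 0.01
    duration_h: float = 72.0
    sampling_min: float = 30.0
    # cohort parameters
    n_eggs: int = 40
    n_replicates: int = 5
    true_d50: float = 8.4
    logistic_scale: float = 1.0    # days; slope of the cumulative curve
    survival: float = 0.9
    censor_day: int = CENSOR_DAY

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.growth_rate < 0:
            raise ValueError("rates and noise must be >= 0")
        if not (0.0 <= self.survival <= 1.0):
            raise ValueError("survival must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ----------------------------------------------------------------- networks

def gen_network(
    config: SimulationConfig,
    targets: Sequence[tuple[str, str]] = (("T", "feasible"),),
) -> tuple[ReactionNetwork, CompoundRegistry, dict[str, str]]:
    """Random toy network with planted producibility ground truth.

    ``targets`` maps target compound ids to the verdict to plant: a unique
    bottleneck reaction producing the target is included (``feasible``),
    demoted to a secondary route (``limited``), or deleted (``impossible``).
    Returns ``(network, registry, truth)``.

    The random backbone connects intermediate compounds downstream of a seed
    pool ``S0..S4``; target compounds are produced only by their bottleneck,
    so the planted verdict is the ground truth by construction.
    """
    if not targets:
        raise ValueError("need at least one target nutrient")
    if self_check := [t for t, v in targets if v not in ("feasible", "limited", "impossible")]:
        raise ValueError(f"bad planted verdicts for {self_check}")
    if config.n_compounds < 6:
        raise ValueError("need at least 6 compounds (5 seeds + 1 intermediate)")
    rng = config.rng()
    seeds = [f"S{i}" for i in range(5)]
    intermediates = [f"C{i}" for i in range(config.n_compounds - 5)]
    pool = seeds + intermediates
    reactions: list[Reaction] = []
    for i in range(config.n_reactions):
        n_sub = int(rng.integers(1, 3))
        subs = list(rng.choice(pool, size=n_sub, replace=False))
        remaining = [c for c in pool if c not in subs]
        prods = list(rng.choice(remaining, size=1))
        reactions.append(
            Reaction(id=f"R{i}", substrates=frozenset(subs), products=frozenset(prods))
        )
    truth: dict[str, str] = {}
    for tid, planted in targets:
        # bottleneck substrates come from the seed pool, so the planted
        # verdict is exactly recoverable: the bottleneck is the unique
        # producer of the target and it can always fire
        n_sub = int(rng.integers(1, 3))
        subs = frozenset(rng.choice(seeds, size=n_sub, replace=False))
        if planted == "impossible":
            pass  # bottleneck deleted: no reaction produces the target
        else:
            route = "primary" if planted == "feasible" else "secondary"
            reactions.append(
                Reaction(id=f"bottleneck_{tid}", substrates=subs, products=frozenset({tid}), route=route)
            )
        truth[tid] = planted
    registry = CompoundRegistry(
        [Compound(id=c, name=c) for c in pool]
        + [Compound(id=t, name=t) for t, _ in targets]
        + [Compound(id=b, name=b) for b in DEFAULT_BOOTSTRAP]
    )
    net = ReactionNetwork(organism=f"toy{config.seed}", reactions=reactions, registry=registry)
    return net, registry, truth


def seed_medium_for(net_targets: Sequence[str], n_seeds: int = 5) -> Medium:
    """Medium whose components are the toy seed pool plus the targets (so a
    target can be 'dropped')."""
    comps = {
        cid: MediumComponent(compound_id=cid, concentration=1.0, unit="mM")
        for cid in [f"S{i}" for i in range(n_seeds)] + list(net_targets)
    }
    return Medium(name="toyHD", components=comps)


# -------------------------------------------------------------- growth curves

def gen_growth_curve(
    config: SimulationConfig, organism: str = "sim", medium: str = "HD",
    replicate: str = "1", regime: str = "agitated",
    rng: np.random.Generator | None = None,
) -> GrowthCurve:
    """Logistic OD600 curve with additive Gaussian noise, clipped at 0."""
    rng = config.rng() if rng is None else rng
    t = np.arange(0.0, config.duration_h + 1e-9, config.sampling_min / 60.0)
    k, r, lag = config.carrying_capacity, config.growth_rate, config.lag_h
    od = k / (1.0 + np.exp(-r * (t - lag - math.log(max(k, 1e-12)) / max(r, 1e-12))))
    od = od + rng.normal(0.0, config.noise_sd, size=t.shape)
    return GrowthCurve(
        organism=organism, medium=medium, regime=regime, replicate=replicate,
        times=t, od=np.clip(od, 0.0, None),
    )


def gen_cfu_series(config: SimulationConfig, rate_per_h: float, times_h: Sequence[float],
                  inoculum: float = 1e4) -> list[float]:
    """Deterministic exponential CFU counts ``inoculum * exp(r t)``."""
    return [inoculum * math.exp(rate_per_h * t) for t in times_h]


# ------------------------------------------------------------------ cohorts

def gen_pupariation(
    config: SimulationConfig, medium: str = "HD", association: str = "GF",
    rng: np.random.Generator | None = None,
) -> list[PupariationRecord]:
    """Replicate cohorts of daily pupariation counts.

    Per replicate: survivors ~ Binomial(n_eggs, survival); each survivor's
    latent pupariation time is logistic(true_d50, logistic_scale); observed
    day = ceil(time) (scored at the end of each day); pupae past the
    censoring day are never observed.
    """
    rng = config.rng() if rng is None else rng
    cond = Condition(medium=medium, association=association)
    records = []
    for rep in range(config.n_replicates):
        survivors = int(rng.binomial(config.n_eggs, config.survival))
        if config.logistic_scale > 0:
            times = rng.logistic(loc=config.true_d50, scale=config.logistic_scale, size=survivors)
        else:
            times = np.full(survivors, config.true_d50)
        days = np.ceil(np.maximum(times, 0.5)).astype(int)
        daily: dict[int, int] = {}
        for d in days:
            if 1 <= d <= config.censor_day:
                daily[int(d)] = daily.get(int(d), 0) + 1
        records.append(
            PupariationRecord(condition=cond, replicate=str(rep + 1), n_eggs=config.n_eggs, daily_pupae=daily)
        )
    return records
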