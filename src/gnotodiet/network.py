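"""Qualitative reaction networks and producibility (scope) inference.

The central question answered here: given an organism's reaction repertoire
and a medium, can the organism still produce nutrient X when X is removed
from the medium?  The computation is network *expansion*: starting from the
seed compounds (medium plus a bootstrap set of currency cofactors), reactions
fire whenever all their substrates are available, until a fixpoint.  This is
a purely qualitative, presence/absence semantics — no stoichiometry and no
flux — matching genome-level pathway-completeness reasoning.

Verdicts are three-valued, mirroring genome-annotation practice:

* ``feasible`` — a route using only primary-metabolism reactions exists;
* ``limited`` — a route exists but requires at least one reaction flagged as
  a secondary/derivative catalysis (e.g. producing Phe from L-arogenate via a
  promiscuous transaminase when prephenate dehydratase is missing);
* ``impossible`` — no route; for inorganic nutrients (metal ions) always
  ``impossible``, as elements cannot be synthesized.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .compounds import CompoundRegistry, UnknownCompoundError
from .medium import Medium

#: Default currency/cofactor compounds seeded into every expansion.  Network
#: expansion from a realistic seed otherwise stalls on the classic cofactor
#: bootstrapping problem (every reaction consuming ATP before ATP is made).
DEFAULT_BOOTSTRAP = frozenset(
    {"water", "proton", "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "coa", "phosphate", "ppi", "co2"}
)

VERDICTS = ("feasible", "limited", "impossible")


@dataclass(frozen=True)
class Reaction:
    """A directed (or reversible) qualitative reaction.

    ``route`` distinguishes primary metabolism (``"primary"``) from
    secondary/derivative catalysis (``"secondary"``); the flag is curated per
    reaction, not computed, because "limited biosynthesis" is an expert call.
    """

    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    ec: str = ""
    reversible: bool = False
    route: str = "primary"

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.id!r} needs non-empty substrates and products")
        if self.route not in ("primary", "secondary"):
            raise ValueError(f"reaction {self.id!r}: route must be primary or secondary")
        overlap = (self.substrates & self.products) - DEFAULT_BOOTSTRAP
        if overlap:
            raise ValueError(f"reaction {self.id!r}: substrates and products overlap: {sorted(overlap)}")


@dataclass
class ReactionNetwork:
    """An organism's reaction set plus its bootstrap (currency) compounds."""

    organism: str
    reactions: list[Reaction] = field(default_factory=list)
    bootstrap: frozenset[str] = DEFAULT_BOOTSTRAP
    registry: CompoundRegistry | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate reaction ids in network {self.organism!r}")
        if self.registry is not None:
            for r in self.reactions:
                self.registry.require(r.substrates | r.products, context=f"reaction {r.id!r}")

    def directed_reactions(self, routes: Iterable[str] = ("primary", "secondary")) -> list[Reaction]:
        """Expand reversible reactions into two directed firings."""
        allowed = set(routes)
        out: list[Reaction] = []
        for r in self.reactions:
            if r.route not in allowed:
                continue
            out.append(r)
            if r.reversible:
                out.append(
                    Reaction(
                        id=r.id + "__rev",
                        substrates=r.products,
                        products=r.substrates,
                        ec=r.ec,
                        reversible=False,
                        route=r.route,
                    )
                )
        return out


@dataclass(frozen=True)
class ProducibilityCall:
    """Per (organism, nutrient) verdict with a witness reaction list."""

    organism: str
    nutrient: str
    verdict: str
    witness: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"bad verdict {self.verdict!r}")
        if self.verdict == "impossible" and self.witness:
            raise ValueError("impossible verdict must carry an empty witness")
        if self.verdict in ("feasible", "limited") and not self.witness:
            raise ValueError(f"{self.verdict} verdict requires a witness")

    @property
    def can_synthesize(self) -> bool:
        return self.verdict != "impossible"


def expand_scope(network: ReactionNetwork, seeds: set[str], routes: Sequence[str] = ("primary", "secondary")) -> set[str]:
    """Least fixpoint of compound availability from ``seeds`` ∪ bootstrap.

    A directed reaction fires when all substrates are available, adding its
    products.  The result is iteration-order independent (it is the unique
    least fixpoint).  Unknown seed ids raise :class:`UnknownCompoundError`
    when the network carries a registry.
    """
    if network.registry is not None:
        network.registry.require(seeds, context="seeds")
    available = set(seeds) | set(network.bootstrap)
    pending = network.directed_reactions(routes)
    changed = True
    while changed:
        changed = False
        remaining = []
        for r in pending:
            if r.substrates <= available:
                if not r.products <= available:
                    available |= r.products
                    changed = True
            else:
                remaining.append(r)
        pending = remaining
    return available


def _witness(network: ReactionNetwork, seeds: set[str], target: str, routes: Sequence[str]) -> tuple[str, ...] | None:
    """Forward-expand recording which firing first produced each compound,
    then backward-trace a derivation of ``target``.

    Returns the witness reaction ids in firing order, ``()`` when the target
    is already a seed/bootstrap compound, and ``None`` when it is out of
    scope.
    """
    base = set(seeds) | set(network.bootstrap)
    if target in base:
        return ()
    available = set(base)
    producer: dict[str, Reaction] = {}  # compound -> firing that first made it
    order: dict[str, int] = {}  # reaction id -> firing rank
    pending = network.directed_reactions(routes)
    changed = True
    while changed:
        changed = False
        remaining = []
        for r in pending:
            if r.substrates <= available:
                new = r.products - available
                if new:
                    order.setdefault(r.id, len(order))
                    for p in new:
                        producer[p] = r
                    available |= new
                    changed = True
            else:
                remaining.append(r)
        pending = remaining
    if target not in available:
        return None
    used: set[str] = set()
    stack = [target]
    while stack:
        cpd = stack.pop()
        if cpd in base:
            continue
        r = producer[cpd]
        if r.id in used:
            continue
        used.add(r.id)
        stack.extend(r.substrates)
    ids = sorted(used, key=order.__getitem__)
    return tuple(rid.removesuffix("__rev") for rid in ids)


def assess_biosynthesis(network: ReactionNetwork, medium: Medium, nutrient: str) -> ProducibilityCall:
    """Can ``network``'s organism make ``nutrient`` on the medium lacking it?

    Seeds are the medium components minus the nutrient.  A primary-only route
    yields ``feasible`` (primary wins over any secondary route); a route
    needing secondary catalysis yields ``limited``; otherwise ``impossible``.
    Inorganic nutrients are always ``impossible``.
    """
    if nutrient not in medium.components:
        raise KeyError(f"nutrient {nutrient!r} is not a component of medium {medium.name!r}")
    if network.registry is not None and nutrient in network.registry:
        if not network.registry[nutrient].organic:
            return ProducibilityCall(network.organism, nutrient, "impossible")
    seeds = set(medium.components) - {nutrient}
    w = _witness(network, seeds, nutrient, routes=("primary",))
    if w is not None:
        if not w:  # nutrient is a bootstrap/currency compound: trivially available
            w = ("<bootstrap>",)
        return ProducibilityCall(network.organism, nutrient, "feasible", witness=w)
    w = _witness(network, seeds, nutrient, routes=("primary", "secondary"))
    if w is not None:
        return ProducibilityCall(network.organism, nutrient, "limited", witness=w)
    return ProducibilityCall(network.organism, nutrient, "impossible")


def capability_table(
    networks: Sequence[ReactionNetwork], medium: Medium, nutrients: Sequence[str]
) -> tuple[pd.DataFrame, dict[frozenset[str], list[str]]]:
    """Producibility calls for every (organism, nutrient), plus the Venn-style
    partition of nutrients by the subset of organisms able to make them.

    Returns ``(table, regions)`` where ``table`` has one row per call and
    ``regions`` maps each subset of organism labels (as a frozenset; the empty
    frozenset collects nutrients nobody can make) to a sorted nutrient list.
    A ``limited`` verdict counts as "can synthesize".
    """
    if not networks:
        raise ValueError("need at least one network")
    rows = []
    calls: dict[tuple[str, str], ProducibilityCall] = {}
    for net in networks:
        for nutrient in nutrients:
            call = assess_biosynthesis(net, medium, nutrient)
            calls[(net.organism, nutrient)] = call
            rows.append(
                {
                    "organism": net.organism,
                    "nutrient": nutrient,
                    "verdict": call.verdict,
                    "witness": ";".join(call.witness),
                }
            )
    table = pd.DataFrame(rows, columns=["organism", "nutrient", "verdict", "witness"])
    regions: dict[frozenset[str], list[str]] = {}
    for nutrient in nutrients:
        members = frozenset(
            net.organism for net in networks if calls[(net.organism, nutrient)].can_synthesize
        )
        regions.setdefault(members, []).append(nutrient)
    for v in regions.values():
        v.sort()
    return table, regions


def read_reaction_table(
    path: str | Path | io.TextIOBase, organism: str, registry: CompoundRegistry | None = None,
    bootstrap: frozenset[str] = DEFAULT_BOOTSTRAP,
) -> ReactionNetwork:
    """Read a TSV reaction table.

    Header: ``reaction_id ec reversible route substrates products`` with
    compound ids ``;``-separated inside the substrate/product cells.  ``#``
    starts a comment line.
    """
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "r", encoding="utf-8")
        close = True
    else:
        fh = path
    try:
        reactions: list[Reaction] = []
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["reaction_id", "ec", "reversible", "route", "substrates", "products"]
                if fields != expected:
                    raise ValueError(f"bad reaction header {fields!r}, expected {expected!r}")
                continue
            rid, ec, rev, route, subs, prods = fields
            reactions.append(
                Reaction(
                    id=rid,
                    ec=ec,
                    reversible=rev.lower() in ("true", "1", "yes"),
                    route=route,
                    substrates=frozenset(s for s in subs.split(";") if s),
                    products=frozenset(p for p in prods.split(";") if p),
                )
            )
        return ReactionNetwork(organism=organism, reactions=reactions, bootstrap=bootstrap, registry=registry)
    finally:
        if close:
            fh.close()
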