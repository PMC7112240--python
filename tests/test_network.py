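"""Scope expansion and producibility inference."""

import numpy as np
import pytest

from gnotodiet.compounds import Compound, CompoundRegistry, UnknownCompoundError
from gnotodiet.medium import Medium, MediumComponent
from gnotodiet.network import (
    DEFAULT_BOOTSTRAP,
    ProducibilityCall,
    Reaction,
    ReactionNetwork,
    assess_biosynthesis,
    capability_table,
    expand_scope,
)
from gnotodiet.simulate import SimulationConfig, gen_network, seed_medium_for


def brute_force_scope(network, seeds):
    """Independent oracle: re-scan every directed reaction until stable."""
    available = set(seeds) | set(network.bootstrap)
    while True:
        before = len(available)
        for r in network.directed_reactions():
            if r.substrates <= available:
                available |= r.products
        if len(available) == before:
            return available


def toy_net(reactions, bootstrap=frozenset()):
    return ReactionNetwork(organism="toy", reactions=reactions, bootstrap=bootstrap)


def random_net(seed, n_compounds=15, n_reactions=20):
    rng = np.random.default_rng(seed)
    pool = [f"X{i}" for i in range(n_compounds)]
    reactions = []
    for i in range(n_reactions):
        subs = list(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))
        remaining = [c for c in pool if c not in subs]
        prods = list(rng.choice(remaining, size=int(rng.integers(1, 3)), replace=False))
        reactions.append(
            Reaction(
                id=f"R{i}",
                substrates=frozenset(subs),
                products=frozenset(prods),
                reversible=bool(rng.random() < 0.3),
            )
        )
    return toy_net(reactions)


class TestExpandScope:
    def test_no_reactions_returns_seeds_plus_bootstrap(self):
        net = toy_net([], bootstrap=frozenset({"atp"}))
        assert expand_scope(net, {"A", "B"}) == {"A", "B", "atp"}

    def test_conjunctive_firing(self):
        net = toy_net([Reaction(id="r", substrates=frozenset("AB"), products=frozenset("C"))])
        assert "C" not in expand_scope(net, {"A"})
        assert "C" in expand_scope(net, {"A", "B"})

    def test_unknown_seed_named_in_error(self):
        reg = CompoundRegistry([Compound(id="A", name="A")])
        net = ReactionNetwork(organism="t", reactions=[], registry=reg, bootstrap=frozenset())
        with pytest.raises(UnknownCompoundError, match="nope"):
            expand_scope(net, {"nope"})

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_matches_brute_force_oracle(self, seed):
        net = random_net(seed)
        seeds = {f"X{i}" for i in range(5)}
        assert expand_scope(net, seeds) == brute_force_scope(net, seeds)

    @pytest.mark.parametrize("seed", range(1, 16))
    def test_monotone_in_seeds(self, seed):
        net = random_net(seed)
        small = {"X0", "X1"}
        assert expand_scope(net, small) <= expand_scope(net, small | {"X2", "X3"})

    @pytest.mark.parametrize("seed", range(1, 16))
    def test_idempotent(self, seed):
        net = random_net(seed)
        scope = expand_scope(net, {"X0", "X1", "X2"})
        assert expand_scope(net, scope) == scope


class TestAssessBiosynthesis:
    def test_dropout_scope_contained_in_complete_scope(self, networks, hd_medium):
        net = networks["Lp"]
        full = expand_scope(net, hd_medium.component_ids())
        for x in sorted(hd_medium.droppable_ids()):
            assert expand_scope(net, hd_medium.component_ids() - {x}) <= full

    def test_lp_phe_limited_via_arogenate_derivative(self, networks, hd_medium):
        call = assess_biosynthesis(networks["Lp"], hd_medium, "Phe")
        assert call.verdict == "limited"
        assert "phe_from_aro_sec" in call.witness

    def test_lp_bcaa_impossible(self, networks, hd_medium):
        for aa in ("Ile", "Leu", "Val"):
            call = assess_biosynthesis(networks["Lp"], hd_medium, aa)
            assert call.verdict == "impossible"
            assert call.witness == ()

    def test_metals_always_impossible(self, networks, hd_medium):
        for org in ("Dmel", "Ap", "Lp"):
            assert assess_biosynthesis(networks[org], hd_medium, "Zn").verdict == "impossible"

    def test_nutrient_not_in_medium_is_an_error(self, networks, hd_medium):
        with pytest.raises(KeyError):
            assess_biosynthesis(networks["Ap"], hd_medium, "caffeine")

    def test_primary_wins_over_secondary(self):
        """A nutrient with both a primary and a secondary route is feasible."""
        reactions = [
            Reaction(id="p", substrates=frozenset({"A"}), products=frozenset({"T"})),
            Reaction(id="s", substrates=frozenset({"A"}), products=frozenset({"T"}), route="secondary"),
        ]
        net = toy_net(reactions)
        med = Medium(
            name="m",
            components={
                c: MediumComponent(compound_id=c, concentration=1.0, unit="mM") for c in ("A", "T")
            },
        )
        call = assess_biosynthesis(net, med, "T")
        assert call.verdict == "feasible"
        assert call.witness == ("p",)

    def test_feasible_witness_uses_only_primary_routes(self, networks, hd_medium):
        net = networks["Lp"]
        by_id = {r.id: r for r in net.reactions}
        for nutrient in sorted(hd_medium.droppable_ids()):
            call = assess_biosynthesis(net, hd_medium, nutrient)
            if call.verdict == "feasible":
                assert all(by_id[w].route == "primary" for w in call.witness)
            elif call.verdict == "limited":
                assert any(by_id[w].route == "secondary" for w in call.witness)


class TestCapabilityTable:
    def test_venn_regions_match_screen_narrative(self, networks, hd_medium):
        _, regions = capability_table(
            list(networks.values()), hd_medium, sorted(hd_medium.droppable_ids())
        )
        assert "myoinositol" in regions[frozenset({"Dmel"})]
        assert "biotin" in regions[frozenset({"Ap"})]
        assert "Ile" in regions[frozenset({"Dmel", "Ap"})] or "Ile" in regions.get(frozenset({"Ap"}), [])

    def test_empty_nutrient_list(self, networks, hd_medium):
        table, regions = capability_table(list(networks.values()), hd_medium, [])
        assert table.empty and regions == {}

    def test_limited_counts_as_can_synthesize(self, networks, hd_medium):
        _, regions = capability_table([networks["Lp"]], hd_medium, ["Phe"])
        assert regions[frozenset({"Lp"})] == ["Phe"]


class TestPlantedAuxotrophies:
    @pytest.mark.parametrize("seed", range(1, 31))
    def test_planted_truth_recovered(self, seed):
        cfg = SimulationConfig(seed=seed)
        targets = [("T0", "feasible"), ("T1", "limited"), ("T2", "impossible")]
        net, _, truth = gen_network(cfg, targets)
        med = seed_medium_for([t for t, _ in targets])
        for tid, expected in truth.items():
            assert assess_biosynthesis(net, med, tid).verdict == expected


class TestInvariants:
    def test_reversible_reactions_fire_both_ways(self):
        net = toy_net([Reaction(id="r", substrates=frozenset("A"), products=frozenset("B"), reversible=True)])
        assert "A" in expand_scope(net, {"B"})

    def test_producibility_call_invariants(self):
        with pytest.raises(ValueError):
            ProducibilityCall("o", "n", "impossible", witness=("r1",))
        with pytest.raises(ValueError):
            ProducibilityCall("o", "n", "feasible", witness=())

    def test_substrate_product_overlap_rejected_outside_bootstrap(self):
        with pytest.raises(ValueError):
            Reaction(id="bad", substrates=frozenset({"A", "B"}), products=frozenset({"A"}))
        # currency compounds on both sides are tolerated
        Reaction(id="ok", substrates=frozenset({"A", "atp"}), products=frozenset({"B", "atp"}))
        assert "atp" in DEFAULT_BOOTSTRAP
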