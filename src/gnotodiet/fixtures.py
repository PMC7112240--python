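"""Packaged fixture data: FLYAA composition, curated networks, phenotypes.

The phenotype and producibility tables are hand-transcribed categorical
outcomes of the published gnotobiotic dropout screen of *Drosophila
melanogaster* larvae mono-associated with *Acetobacter pomorum* (Ap) and
*Lactiplantibacillus plantarum* (Lp); each cell carries a provenance string.
The reaction tables are curated synthetic toy networks built for this
package that reproduce the transcribed verdicts through scope expansion.
A SHA-256 manifest guards against silent fixture edits.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .compounds import CompoundRegistry, read_compound_registry
from .medium import Medium, read_medium
from .network import ReactionNetwork, read_reaction_table
from .reconcile import ReconciliationRecord

ORGANISMS = ("Dmel", "Ap", "Lp")
BACTERIA = ("Ap", "Lp")


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match the committed SHA-256 manifest."""


def _data_dir() -> Path:
    return Path(resources.files("gnotodiet").joinpath("data"))


def verify_manifest() -> None:
    data = _data_dir()
    manifest = (data / "MANIFEST.sha256").read_text(encoding="utf-8")
    for line in manifest.strip().splitlines():
        digest, name = line.split()
        actual = hashlib.sha256((data / name).read_bytes()).hexdigest()
        if actual != digest:
            raise FixtureIntegrityError(f"fixture file {name} has been modified (sha256 mismatch)")


def load_registry() -> CompoundRegistry:
    return read_compound_registry(_data_dir() / "compounds.tsv")


def load_flyaa_medium(liquid: bool = False) -> Medium:
    """The complete FLYAA holidic diet (solid by default)."""
    return read_medium(_data_dir() / "flyaa_medium.tsv", name="HD", liquid=liquid)


def load_network(organism: str, registry: CompoundRegistry | None = None) -> ReactionNetwork:
    if organism not in ORGANISMS:
        raise KeyError(f"no fixture network for organism {organism!r}")
    if registry is None:
        registry = load_registry()
    fname = {"Dmel": "reactions_dmel.tsv", "Ap": "reactions_ap.tsv", "Lp": "reactions_lp.tsv"}[organism]
    return read_reaction_table(_data_dir() / fname, organism=organism, registry=registry)


class PhenotypeTable:
    """Categorical screen outcomes keyed by (nutrient, actor, field)."""

    def __init__(self, df: pd.DataFrame) -> None:
        self.df = df
        self._cells = {
            (r.nutrient, r.actor, r.field): r.value for r in df.itertuples()
        }

    def get(self, nutrient: str, actor: str, field: str) -> str | None:
        return self._cells.get((nutrient, actor, field))

    def requirement(self, nutrient: str) -> str:
        v = self.get(nutrient, "GF", "requirement")
        if v is None:
            raise KeyError(f"no GF requirement entry for {nutrient!r}")
        return v

    def growth(self, nutrient: str, bacterium: str, regime: str = "agitated") -> str | None:
        return self.get(nutrient, bacterium, f"growth_{regime}")

    def rescues(self, nutrient: str, actor: str) -> bool | None:
        v = self.get(nutrient, actor, "rescue")
        if v is None:
            return None
        return v == "develops"

    def nutrients(self) -> list[str]:
        return sorted({r.nutrient for r in self.df.itertuples()})

    def essential_nutrients(self) -> list[str]:
        return sorted(n for n in self.nutrients() if self.requirement(n) == "essential")


def load_paper_fixture(verify: bool = True) -> tuple[PhenotypeTable, pd.DataFrame]:
    """The committed transcription of the screen outcomes.

    Returns ``(phenotypes, producibility)`` where producibility has columns
    ``organism, nutrient, verdict, provenance``.
    """
    if verify:
        verify_manifest()
    data = _data_dir()
    phen = PhenotypeTable(pd.read_csv(data / "phenotypes.csv"))
    prod = pd.read_csv(data / "producibility.csv")
    return phen, prod


def build_reconciliation_records(
    phenotypes: PhenotypeTable, producibility: pd.DataFrame, registry: CompoundRegistry | None = None
) -> list[ReconciliationRecord]:
    """Join fixture tables into per (nutrient, bacterium) records, classified."""
    from .reconcile import classify_records

    if registry is None:
        registry = load_registry()
    verdict = {(r.organism, r.nutrient): r.verdict for r in producibility.itertuples()}
    records = []
    for nutrient in phenotypes.nutrients():
        requirement = phenotypes.requirement(nutrient)
        is_metal = nutrient in registry and registry[nutrient].role == "metal"
        for bact in BACTERIA:
            rescues = phenotypes.rescues(nutrient, bact)
            if requirement == "essential" and rescues is None:
                raise KeyError(f"missing rescue cell for essential nutrient {nutrient!r} x {bact!r}")
            records.append(
                ReconciliationRecord(
                    nutrient=nutrient,
                    bacterium=bact,
                    predicted=verdict[(bact, nutrient)],
                    grows_without=phenotypes.growth(nutrient, bact),
                    rescues=bool(rescues) if rescues is not None else False,
                    requirement=requirement,
                    is_metal=is_metal,
                )
            )
    return classify_records(records)


def static_growth_calls(phenotypes: PhenotypeTable) -> dict[tuple[str, str], str]:
    """(nutrient, bacterium) -> static-regime growth category, where measured."""
    out = {}
    for r in phenotypes.df.itertuples():
        if r.field == "growth_static":
            out[(r.nutrient, r.actor)] = r.value
    return out
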