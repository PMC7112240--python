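"""Holidic-diet (HD) composition and single-component dropout media.

The complete FLYAA holidic diet is a fully chemically defined fly medium.
Screens remove exactly one droppable component at a time (``HDΔX``).  The
droppable set covers amino acids, vitamins, NALs, cholesterol, sucrose and
the metal ions; agar and the acetate buffer are never dropped (the buffer
doubles as a carbon source and the gelling agent is structural, not
nutritional).  A liquid variant omits agar and cholesterol.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

from .compounds import ROLES, CompoundRegistry

#: Ordering of role classes for stable dropout enumeration (heatmap row order).
ROLE_ORDER = {role: i for i, role in enumerate(ROLES)}


@dataclass(frozen=True)
class MediumComponent:
    compound_id: str
    concentration: float
    unit: str
    droppable: bool = True

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"component {self.compound_id!r}: concentration must be > 0")


@dataclass(frozen=True)
class Medium:
    """A named compound set with per-component concentration records.

    Concentrations are carried for bookkeeping but producibility inference is
    qualitative: only the component *set* seeds network expansion.
    """

    name: str
    components: dict[str, MediumComponent] = field(default_factory=dict)
    liquid: bool = False
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.liquid:
            for banned in ("agar", "cholesterol"):
                if banned in self.components:
                    raise ValueError(f"liquid medium {self.name!r} must omit {banned}")

    @property
    def is_complete(self) -> bool:
        return self.parent is None

    def component_ids(self) -> set[str]:
        return set(self.components)

    def droppable_ids(self) -> set[str]:
        return {cid for cid, comp in self.components.items() if comp.droppable}

    def dropout(self, component: str) -> "Medium":
        """Return a copy named ``ΔX`` lacking exactly ``component``."""
        if component not in self.components:
            raise KeyError(f"component {component!r} not present in medium {self.name!r}")
        if not self.components[component].droppable:
            raise KeyError(f"component {component!r} of medium {self.name!r} is not droppable")
        remaining = {cid: comp for cid, comp in self.components.items() if cid != component}
        return Medium(
            name=f"{self.name}Δ{component}",
            components=remaining,
            liquid=self.liquid,
            parent=self.name,
        )

    def with_component(self, component: MediumComponent) -> "Medium":
        """Return a copy with ``component`` (re-)added; used for round trips."""
        comps = dict(self.components)
        comps[component.compound_id] = component
        return Medium(name=self.name, components=comps, liquid=self.liquid, parent=self.parent)

    def to_liquid(self) -> "Medium":
        """Liquid version: omit agar and cholesterol from the recipe."""
        comps = {cid: c for cid, c in self.components.items() if cid not in ("agar", "cholesterol")}
        return Medium(name=self.name + "_liquid", components=comps, liquid=True, parent=self.parent)


def dropout(medium: Medium, component: str) -> Medium:
    """Functional alias for :meth:`Medium.dropout`."""
    return medium.dropout(component)


def enumerate_dropouts(medium: Medium, registry: CompoundRegistry | None = None) -> list[Medium]:
    """One dropout medium per droppable component of a complete medium.

    Ordering is stable: by role class (when a registry is supplied) then by
    compound id.
    """
    if not medium.is_complete:
        raise ValueError(f"medium {medium.name!r} is itself a dropout; enumerate from the complete medium")

    def key(cid: str) -> tuple[int, str]:
        if registry is not None and cid in registry:
            return (ROLE_ORDER[registry[cid].role], cid)
        return (len(ROLE_ORDER), cid)

    return [medium.dropout(cid) for cid in sorted(medium.droppable_ids(), key=key)]


def read_medium(path: str | Path | io.TextIOBase, name: str = "HD", liquid: bool = False) -> Medium:
    """Read a medium TSV: ``compound_id concentration unit droppable``."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "r", encoding="utf-8")
        close = True
    else:
        fh = path
    try:
        components: dict[str, MediumComponent] = {}
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["compound_id", "concentration", "unit", "droppable"]
                if fields != expected:
                    raise ValueError(f"bad medium header {fields!r}, expected {expected!r}")
                continue
            cid, conc, unit, droppable = fields
            if cid in components:
                raise ValueError(f"duplicate medium component {cid!r}")
            components[cid] = MediumComponent(
                compound_id=cid,
                concentration=float(conc),
                unit=unit,
                droppable=droppable.lower() in ("true", "1", "yes"),
            )
        medium = Medium(name=name, components=components, liquid=False)
        return medium.to_liquid() if liquid else medium
    finally:
        if close:
            fh.close()
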