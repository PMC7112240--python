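"""Compound registry for holidic-diet screen analysis.

Every compound referenced by a medium or a reaction network resolves against a
:class:`CompoundRegistry`.  Roles mirror the ingredient classes of the
fly-exome-matched (FLYAA) holidic diet: the ten fly-essential and ten
fly-nonessential amino acids, seven B-vitamins, nucleic-acid/lipid precursors
(NALs), cholesterol, sucrose, trace metal ions, and buffer/gelling agents.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

#: Valid role classes, in the row order used by screen heatmaps.
ROLES = (
    "EAA_fly",
    "NEAA_fly",
    "vitamin",
    "NAL",
    "sterol",
    "sugar",
    "metal",
    "buffer",
    "other",
)


class UnknownCompoundError(KeyError):
    """A compound id does not resolve in the registry."""


@dataclass(frozen=True)
class Compound:
    """A chemically pure diet or network compound.

    Parameters
    ----------
    id:
        Unique identifier, e.g. ``"Ile"`` or ``"nicotinate"``.
    name:
        Display name.
    role:
        One of :data:`ROLES`.
    organic:
        Whether the compound is organic.  Metal ions are inorganic and can
        never be biosynthesized, only acquired.
    """

    id: str
    name: str
    role: str = "other"
    organic: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for compound {self.id!r}")
        if self.role == "metal" and self.organic:
            raise ValueError(f"metal ion {self.id!r} cannot be organic")


class CompoundRegistry:
    """Mapping of compound id -> :class:`Compound` with uniqueness enforced."""

    def __init__(self, compounds: Iterable[Compound] = ()) -> None:
        self._compounds: dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.id in self._compounds:
            raise ValueError(f"duplicate compound id {compound.id!r}")
        self._compounds[compound.id] = compound

    def __getitem__(self, cid: str) -> Compound:
        try:
            return self._compounds[cid]
        except KeyError:
            raise UnknownCompoundError(cid) from None

    def __contains__(self, cid: str) -> bool:
        return cid in self._compounds

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    def ids(self) -> set[str]:
        return set(self._compounds)

    def require(self, cids: Iterable[str], context: str = "input") -> None:
        """Raise :class:`UnknownCompoundError` naming the first unresolvable id."""
        for cid in cids:
            if cid not in self._compounds:
                raise UnknownCompoundError(f"unknown compound id {cid!r} in {context}")


def read_compound_registry(path: str | Path | io.TextIOBase) -> CompoundRegistry:
    """Read a TSV compound registry: ``compound_id name role organic``.

    Lines starting with ``#`` are comments; the header row is required.
    """
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "r", encoding="utf-8")
        close = True
    else:
        fh = path
    try:
        registry = CompoundRegistry()
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["compound_id", "name", "role", "organic"]
                if fields != expected:
                    raise ValueError(f"bad registry header {fields!r}, expected {expected!r}")
                continue
            cid, name, role, organic = fields
            registry.add(
                Compound(id=cid, name=name, role=role, organic=organic.lower() in ("true", "1", "yes"))
            )
        return registry
    finally:
        if close:
            fh.close()
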