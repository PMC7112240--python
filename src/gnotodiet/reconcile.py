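"""Joining genome predictions with in vivo phenotypes: the four situations.

For every nutrient that is essential to germ-free larvae, each bacterium's
record joins (i) the genome-predicted producibility verdict, (ii) whether the
bacterium grows on the dropout medium, and (iii) whether association with the
living bacterium rescues larval development.  Compensated auxotrophies fall
into four situations:

* **S1** — the bacterium synthesizes the missing nutrient and rescues;
* **S2** — it neither synthesizes nor rescues;
* **S3** — it cannot synthesize the nutrient de novo yet rescues, pointing to
  provision of an intermediate/derivative (e.g. nicotinate or pyridoxine
  intermediates) or a functional analogue (choline);
* **S4** — rescue of a mineral/metal deficiency (elements cannot be made;
  the bacterium concentrates contaminating traces);
* **EXC** — the bacterium synthesizes the nutrient and grows without it but
  does not rescue (e.g. pantothenate: enough for its own growth, none made
  available to the host).

Rescue is read from larval outcomes alone; the bacterial growth category
never gates the classification (a bacterium may be fed by the host itself,
as for Cys).  Situation *counting* is per nutrient over the union of
bacteria, which is the convention under which 19 compensations split
15 (S1) + 3 (S3) + 1 (S4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

SITUATIONS = ("S1", "S2", "S3", "S4", "EXC", "NA")


@dataclass(frozen=True)
class ReconciliationRecord:
    nutrient: str
    bacterium: str
    predicted: str  # producibility verdict: feasible | limited | impossible
    grows_without: str | None  # growth category or None when unmeasured
    rescues: bool
    requirement: str  # GF larval requirement: essential | limiting | dispensable
    is_metal: bool = False
    situation: str = "NA"


class IncompletePhenotypeError(ValueError):
    """A phenotype cell needed for classification is missing."""


def classify_situation(
    nutrient: str,
    predicted: str,
    rescues: bool | None,
    requirement: str,
    is_metal: bool = False,
) -> str:
    """Situation label for one (nutrient, bacterium) record.

    Only nutrients essential to germ-free larvae are classified (``NA``
    otherwise).  Metals take precedence over S3: rescued metal deficiencies
    are S4 regardless of the (necessarily ``impossible``) synthesis verdict.
    ``limited`` synthesis counts as "can synthesize".
    """
    if requirement != "essential":
        return "NA"
    if predicted is None or rescues is None:
        raise IncompletePhenotypeError(f"missing phenotype cell for nutrient {nutrient!r}")
    can_make = predicted in ("feasible", "limited")
    if is_metal and rescues:
        return "S4"
    if can_make and rescues:
        return "S1"
    if can_make and not rescues:
        return "EXC"
    if rescues:  # organic, cannot synthesize de novo, yet rescues
        return "S3"
    return "S2"


def classify_records(records: Iterable[ReconciliationRecord]) -> list[ReconciliationRecord]:
    out = []
    for r in records:
        situation = classify_situation(r.nutrient, r.predicted, r.rescues, r.requirement, r.is_metal)
        out.append(
            ReconciliationRecord(
                nutrient=r.nutrient, bacterium=r.bacterium, predicted=r.predicted,
                grows_without=r.grows_without, rescues=r.rescues, requirement=r.requirement,
                is_metal=r.is_metal, situation=situation,
            )
        )
    return out


def summarize_compensations(records: Sequence[ReconciliationRecord]) -> dict[str, int]:
    """Headline counts over the union of bacteria.

    For each GF-essential nutrient: it is *compensated* when at least one
    bacterium rescues.  A compensated nutrient is S1 when any rescuing
    bacterium can synthesize it (feasible or limited), S4 when it is a metal,
    else S3.  An uncompensated nutrient is EXC when some bacterium could
    synthesize it (the in vitro/in vivo exception), else S2.
    """
    essential = sorted({r.nutrient for r in records if r.requirement == "essential"})
    by_nutrient: dict[str, list[ReconciliationRecord]] = {}
    for r in records:
        if r.requirement == "essential":
            by_nutrient.setdefault(r.nutrient, []).append(r)
    bacteria = sorted({r.bacterium for r in records})
    per_bacterium = {
        b: sum(1 for r in records if r.bacterium == b and r.requirement == "essential" and r.rescues)
        for b in bacteria
    }
    counts = {s: 0 for s in ("S1", "S2", "S3", "S4", "EXC")}
    union_rescued = 0
    for nutrient in essential:
        recs = by_nutrient[nutrient]
        rescuers = [r for r in recs if r.rescues]
        if rescuers:
            union_rescued += 1
            if recs[0].is_metal:
                counts["S4"] += 1
            elif any(r.predicted in ("feasible", "limited") for r in rescuers):
                counts["S1"] += 1
            else:
                counts["S3"] += 1
        else:
            if any(r.predicted in ("feasible", "limited") for r in recs):
                counts["EXC"] += 1
            else:
                counts["S2"] += 1
    summary = {
        "essential": len(essential),
        "union_rescued": union_rescued,
        **{f"{b}_rescues": n for b, n in per_bacterium.items()},
        **{s.lower(): n for s, n in counts.items()},
    }
    return summary


def discrepancy_ledger(records: Sequence[ReconciliationRecord],
                       static_growth: Mapping[tuple[str, str], str] | None = None) -> pd.DataFrame:
    """Rows where genome prediction and observation disagree.

    Flags: predicted ``impossible`` yet the bacterium grows on the dropout;
    predicted ``feasible`` yet no growth; and, when static-regime calls are
    supplied, agitated/static contradictions (excess oxygenation artifacts).
    A free-text ``hypothesis`` slot is left for curation.
    """
    static_growth = static_growth or {}
    rows = []
    for r in records:
        if r.grows_without is None:
            continue
        static = static_growth.get((r.nutrient, r.bacterium))
        flags = []
        if static is not None and (static != "none") != (r.grows_without != "none"):
            flags.append("regime-dependent growth (agitated vs static)")
        if r.predicted == "impossible" and r.grows_without in ("growth", "reduced"):
            flags.append("grows without a nutrient it cannot synthesize")
        if r.predicted == "feasible" and r.grows_without == "none" and not flags:
            flags.append("predicted synthesis but no growth on dropout")
        if r.predicted == "limited" and r.grows_without == "none" and not flags:
            flags.append("limited-route synthesis insufficient under assay regime")
        for flag in flags:
            rows.append(
                {
                    "nutrient": r.nutrient, "organism": r.bacterium,
                    "predicted": r.predicted, "growth": r.grows_without,
                    "growth_static": static, "flag": flag, "hypothesis": "",
                }
            )
    return pd.DataFrame(
        rows, columns=["nutrient", "organism", "predicted", "growth", "growth_static", "flag", "hypothesis"]
    )


def situation_report(records: Sequence[ReconciliationRecord]) -> str:
    """Markdown report: per-bacterium situation table plus headline counts."""
    summary = summarize_compensations(records)
    lines = ["# Host-auxotrophy compensation summary", ""]
    lines.append(f"GF-essential nutrients: {summary['essential']}")
    for key, val in summary.items():
        if key.endswith("_rescues"):
            lines.append(f"- {key.removesuffix('_rescues')} rescues: {val}")
    lines.append(f"- rescued by at least one bacterium: {summary['union_rescued']}")
    lines.append("")
    lines.append("| situation | nutrients (union convention) |")
    lines.append("|---|---|")
    by_situation: dict[str, list[str]] = {}
    essential = sorted({r.nutrient for r in records if r.requirement == "essential"})
    for nutrient in essential:
        recs = [r for r in records if r.nutrient == nutrient and r.requirement == "essential"]
        rescuers = [r for r in recs if r.rescues]
        if rescuers:
            if recs[0].is_metal:
                s = "S4"
            elif any(r.predicted in ("feasible", "limited") for r in rescuers):
                s = "S1"
            else:
                s = "S3"
        else:
            s = "EXC" if any(r.predicted in ("feasible", "limited") for r in recs) else "S2"
        by_situation.setdefault(s, []).append(nutrient)
    for s in ("S1", "S2", "S3", "S4", "EXC"):
        lines.append(f"| {s} ({summary[s.lower()]}) | {', '.join(by_situation.get(s, []))} |")
    return "\n".join(lines)
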