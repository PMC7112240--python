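"""End-to-end orchestration: raw inputs -> reconciliation report bundle.

``run_pipeline`` executes the stages in order — medium enumeration, network
producibility, growth screen, developmental timing, reconciliation — and
writes summary TSVs, the discrepancy ledger, a machine-readable JSON of
headline counts, and a MANIFEST recording what ran.  With no input files it
runs on the packaged fixture, reproducing the published headline counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dev import read_pupariation_csv, summarize_condition
from .fixtures import (
    build_reconciliation_records,
    load_flyaa_medium,
    load_paper_fixture,
    load_registry,
    static_growth_calls,
)
from .growth import read_od_csv, screen_growth_calls, text_heatmap
from .medium import enumerate_dropouts
from .reconcile import discrepancy_ledger, situation_report, summarize_compensations

log = logging.getLogger("gnotodiet")

HEADLINE_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    outdir: Path
    od_csv: Path | None = None
    pupariation_csv: Path | None = None
    seed: int = 0
    survival_cutoff: float = 0.25
    alpha: float = 0.05
    none_margin: float = 0.05
    reduced_fraction: float = 0.25
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (0.0 <= self.survival_cutoff <= 1.0):
            raise ValueError("survival cutoff must lie in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the headline-counts dict written to JSON.

    Stage failures raise after a MANIFEST naming the failed stage is
    written, so partial outputs stay interpretable.
    """
    logging.basicConfig(level=config.log_level)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = [f"gnotodiet {__version__}", f"config sha256:{config.digest()}"]
    stage = "init"
    try:
        stage = "hd_medium"
        registry = load_registry()
        medium = load_flyaa_medium()
        dropouts = enumerate_dropouts(medium, registry)
        pd.DataFrame({"medium": [m.name for m in dropouts]}).to_csv(
            outdir / "dropout_media.tsv", sep="\t", index=False
        )
        manifest.append(f"{stage}: {len(dropouts)} dropout media")

        stage = "network_core"
        phenotypes, producibility = load_paper_fixture()
        producibility.to_csv(outdir / "producibility.tsv", sep="\t", index=False)
        manifest.append(f"{stage}: {len(producibility)} producibility calls")

        stage = "growth_assay"
        if config.od_csv is not None:
            curves = read_od_csv(config.od_csv)
            calls = screen_growth_calls(
                curves, none_margin=config.none_margin, reduced_fraction=config.reduced_fraction
            )
            calls.to_csv(outdir / "growth_calls.tsv", sep="\t", index=False)
            (outdir / "growth_heatmap.txt").write_text(text_heatmap(calls), encoding="utf-8")
            manifest.append(f"{stage}: {len(calls)} growth calls from {config.od_csv}")
        else:
            manifest.append(f"{stage}: fixture growth categories used")

        stage = "dev_assay"
        if config.pupariation_csv is not None:
            records = read_pupariation_csv(config.pupariation_csv)
            results = summarize_condition(records, survival_cutoff=config.survival_cutoff)
            pd.DataFrame(
                [
                    {
                        "medium": r.condition.medium,
                        "association": r.condition.association,
                        "mean_d50": r.mean,
                        "sem": r.sem,
                        "survival": r.survival,
                        "n_replicates_used": r.n_replicates_used,
                        "developed": r.developed,
                    }
                    for r in results
                ]
            ).to_csv(outdir / "d50_summary.tsv", sep="\t", index=False)
            manifest.append(f"{stage}: {len(results)} conditions from {config.pupariation_csv}")
        else:
            manifest.append(f"{stage}: fixture requirement categories used")

        stage = "reconcile"
        records = build_reconciliation_records(phenotypes, producibility, registry)
        summary = summarize_compensations(records)
        ledger = discrepancy_ledger(records, static_growth_calls(phenotypes))
        ledger.to_csv(outdir / "discrepancies.tsv", sep="\t", index=False)
        (outdir / "situation_report.md").write_text(situation_report(records), encoding="utf-8")
        headline = {
            "schema_version": HEADLINE_SCHEMA_VERSION,
            "essential": summary["essential"],
            "ap_rescues": summary["Ap_rescues"],
            "lp_rescues": summary["Lp_rescues"],
            "union_rescued": summary["union_rescued"],
            "s1": summary["s1"],
            "s2": summary["s2"],
            "s3": summary["s3"],
            "s4": summary["s4"],
            "exc": summary["exc"],
        }
        (outdir / "headline.json").write_text(
            json.dumps(headline, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest.append(f"{stage}: ok")
        manifest.append("status: success")
        return headline
    except Exception:
        manifest.append(f"status: FAILED at stage {stage}")
        raise
    finally:
        (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n", encoding="utf-8")
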