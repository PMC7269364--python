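"""End-to-end pipeline: simulate/load cards, QC, growth trends, energy
needs, protocol performance, and a single run report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from . import __version__
from .anthropometry import GrowthReference
from .energy import DEFAULT_PARAMS, EnergyNeedsModel, EnergyNeedsResults, EnergyParams
from .growth import GrowthTrendModel, GrowthTrendResults
from .io import read_patient_cards, write_patient_cards, write_result_table
from .protocol import PROTOCOLS, ProtocolSimulation, ProtocolSimulationResults
from .qc import QCResult, qc_cohort
from .synthetic import generate_cohort, preset_config
from .types import PatientCard, RunConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    attrition: pd.DataFrame
    qc: QCResult
    growth: Optional[GrowthTrendResults]
    energy: Optional[EnergyNeedsResults]
    protocol: Optional[ProtocolSimulationResults]
    provenance: dict
    skipped: Optional[str] = None  # explanation when downstream stages were skipped

    def summary(self) -> str:
        parts = ["Run report", "=" * 54, "Attrition:"]
        parts += [f"  {r.step:32s} {r['count']:8d}" for _, r in self.attrition.iterrows()]
        if self.skipped:
            parts.append(f"Downstream stages skipped: {self.skipped}")
        for res in (self.growth, self.energy, self.protocol):
            if res is not None:
                parts += ["", res.summary()]
        parts += ["", f"provenance: {json.dumps(self.provenance, sort_keys=True)}"]
        return "\n".join(parts)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(
    config: Optional[RunConfig] = None,
    cards: Optional[Sequence[PatientCard]] = None,
    cards_path=None,
    preset: Optional[str] = None,
    n_per_country: int = 400,
    reference: Optional[GrowthReference] = None,
    params: EnergyParams = DEFAULT_PARAMS,
    protocol_name: str = "proposed",
    outdir=None,
) -> RunReport:
    """Execute the full pipeline in fixed order and return a RunReport.

    Cards come from exactly one of ``cards``, ``cards_path`` or a
    generator ``preset`` (seeded from the run config). When ``outdir`` is
    given every stage's tables are written there as CSV; a rerun with the
    same config and seed reproduces every output.
    """
    config = config or RunConfig()
    config.validate()  # fail before any stage runs

    sources = sum(x is not None for x in (cards, cards_path, preset))
    if sources != 1:
        raise ValueError("provide exactly one of cards, cards_path or preset")

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_run_config

        write_run_config(config, out / "config.yaml")  # provenance snapshot

    try:
        if preset is not None:
            cards = generate_cohort(preset_config(preset, n_per_country=n_per_country, seed=config.rng_seed))
            if out is not None:
                write_patient_cards(cards, out / "cards.csv")
        elif cards_path is not None:
            cards = read_patient_cards(cards_path)
    except Exception as e:  # noqa: BLE001 - abort with the failing stage named
        raise StageError("input", e) from e

    try:
        qc = qc_cohort(cards, reference=reference, config=config)
        if out is not None:
            write_result_table(qc.attrition, out / "attrition.csv")
            write_result_table(qc.card_flags, out / "card_flags.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", e) from e

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.rng_seed,
        "muacdose_version": __version__,
        "n_cards_in": len(cards),
        "n_cards_analyzed": len(qc.analysis_cards),
    }

    if qc.observations.empty:
        why = "no analyzable observations after filtering"
        log.warning("%s; downstream stages skipped", why)
        return RunReport(qc.attrition, qc, None, None, None, provenance, skipped=why)

    try:
        growth = GrowthTrendModel(qc.observations, config).fit()
        if out is not None:
            write_result_table(growth.curves_frame(), out / "curves.csv")
            write_result_table(growth.trend.to_frame(), out / "trend.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("growth", e) from e

    try:
        energy = EnergyNeedsModel(qc.observations, params, config).fit()
        if out is not None:
            write_result_table(energy.band_table, out / "energy_bands.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("energy", e) from e

    try:
        protocol = ProtocolSimulation(qc.observations, PROTOCOLS[protocol_name], config, params).fit()
        if out is not None:
            write_result_table(protocol.performance.table, out / "performance.csv")
            write_result_table(protocol.energy_curves, out / "protocol_curves.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("protocol", e) from e

    report = RunReport(qc.attrition, qc, growth, energy, protocol, provenance)
    if out is not None:
        (out / "report.txt").write_text(report.summary() + "\n")
        (out / "provenance.json").write_text(json.dumps(provenance, sort_keys=True, indent=2) + "\n")
    return report
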