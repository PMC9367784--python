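"""Inventory assembly and reporting.

Builds the per-process emission inventory of a scenario, groups it by gas
and industry, compares scenarios, and writes CSV/JSON reports.

Computation is full precision in kg·a⁻¹; the reporting unit 10⁷ t·a⁻¹
(1 unit = 10¹⁰ kg) and the 2-decimal display rounding (half away from
zero) exist only in the report writer.

Two computation modes:

``replication``
    reproduces the published tables, including the as-printed process
    overrides a scenario carries and the per-head manure-application
    reading with its 273 N₂O potential.

``corrected``
    ignores overrides and applies the stated method uniformly
    (herd-scale N excretion, 265 N₂O potential).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import breeding, planting
from .config import ScenarioSpec

__all__ = [
    "KG_PER_REPORT_UNIT",
    "MODES",
    "PROCESS_INDUSTRY",
    "ProcessEmission",
    "InventoryReport",
    "ComparisonReport",
    "build_inventory",
    "gas_totals",
    "compare",
    "write_report",
    "read_report_json",
    "round_display",
]

#: kg·a⁻¹ per reporting unit (10⁷ t·a⁻¹).
KG_PER_REPORT_UNIT = 1e10

MODES = ("replication", "corrected")

GASES = ("CO2", "CH4", "N2O")

#: Which industry each process belongs to.  Straw burning is a planting-side
#: residue fate; the published industry percentages leave it outside both
#: industries, which is noted in the methods documentation.
PROCESS_INDUSTRY = {
    "corn_planting": "planting",
    "n_fertilizer": "planting",
    "manure_application": "planting",
    "feed_production": "planting",
    "straw_burning": "planting",
    "enteric_fermentation": "breeding",
    "manure_management": "breeding",
}


def round_display(value_kg: float, unit: float = KG_PER_REPORT_UNIT) -> float:
    """Display value in reporting units, 2 decimals, half away from zero."""
    q = Decimal(repr(value_kg / unit)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass(frozen=True)
class ProcessEmission:
    """One (process, gas) cell of the inventory, CO₂-eq kg·a⁻¹."""

    process: str
    gas: str
    industry: str
    co2eq: float
    overridden: bool = False


@dataclass
class InventoryReport:
    """Process × gas emission inventory of one scenario."""

    scenario_name: str
    model_kind: str
    mode: str
    entries: list[ProcessEmission] = field(default_factory=list)

    @property
    def total(self) -> float:
        return sum(e.co2eq for e in self.entries)

    def gas_totals(self) -> dict[str, float]:
        out = {g: 0.0 for g in GASES}
        for e in self.entries:
            out[e.gas] += e.co2eq
        return out

    def industry_totals(self) -> dict[str, float]:
        out = {"planting": 0.0, "breeding": 0.0}
        for e in self.entries:
            out[e.industry] += e.co2eq
        return out

    def process_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.entries:
            out[e.process] = out.get(e.process, 0.0) + e.co2eq
        return out

    def shares(self) -> dict[tuple[str, str], float]:
        t = self.total
        if t == 0:
            return {(e.process, e.gas): 0.0 for e in self.entries}
        return {(e.process, e.gas): e.co2eq / t for e in self.entries}

    def get(self, process: str, gas: str | None = None) -> float:
        """CO₂-eq of one process (optionally one gas of it); absent → 0."""
        return sum(
            e.co2eq
            for e in self.entries
            if e.process == process and (gas is None or e.gas == gas)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "industry": e.industry,
                "process": e.process,
                "gas": e.gas,
                "co2eq_kg_per_a": e.co2eq,
                "co2eq_1e7_t_per_a": round_display(e.co2eq),
                "share": e.co2eq / self.total if self.total else 0.0,
                "overridden": e.overridden,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario_name": self.scenario_name,
            "model_kind": self.model_kind,
            "mode": self.mode,
            "entries": [
                {
                    "process": e.process,
                    "gas": e.gas,
                    "industry": e.industry,
                    "co2eq_kg_per_a": e.co2eq,
                    "overridden": e.overridden,
                }
                for e in self.entries
            ],
            "total_kg_per_a": self.total,
            "gas_totals_kg_per_a": self.gas_totals(),
            "industry_totals_kg_per_a": self.industry_totals(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InventoryReport":
        return cls(
            scenario_name=data["scenario_name"],
            model_kind=data["model_kind"],
            mode=data["mode"],
            entries=[
                ProcessEmission(
                    process=e["process"],
                    gas=e["gas"],
                    industry=e["industry"],
                    co2eq=e["co2eq_kg_per_a"],
                    overridden=e["overridden"],
                )
                for e in data["entries"]
            ],
        )


def _entry(process: str, gas: str, co2eq: float, overridden: bool = False) -> ProcessEmission:
    return ProcessEmission(
        process=process,
        gas=gas,
        industry=PROCESS_INDUSTRY[process],
        co2eq=co2eq,
        overridden=overridden,
    )


def build_inventory(spec: ScenarioSpec, mode: str = "replication") -> InventoryReport:
    """Run every process applicable to the scenario's model kind.

    Ecological-cycle scenarios include feed production and no straw
    burning; conventional scenarios the reverse.  As-printed overrides
    are applied only in replication mode.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    herd, pl, man, fac, gwp = spec.herd, spec.planting, spec.manure, spec.factors, spec.gwp

    entries: list[ProcessEmission] = []

    def add(process: str, gas: str, value: float) -> None:
        if mode == "replication" and process in spec.overrides:
            entries.append(_entry(process, gas, spec.overrides[process], overridden=True))
        else:
            entries.append(_entry(process, gas, value))

    feed_demand = planting.annual_feed_demand(
        pl.feed_intake_per_head_day, herd.herd_size, herd.fattening_days
    )

    # corn planting: EC plants the silage the herd eats; non-EC plants the
    # full straw requirement behind the feed share
    if spec.model_kind == "EC":
        corn_mass = feed_demand
    else:
        balance = planting.straw_balance(
            feed_demand, pl.straw_feed_fraction, pl.straw_burn_fraction
        )
        corn_mass = balance.total_straw_normalized
    add("corn_planting", "CO2", planting.corn_planting_co2(corn_mass, fac.ef_farm_corn))

    n_input = planting.fertilizer_nitrogen_input(
        pl.planting_area,
        pl.fertilizer_application_rate,
        pl.n_fertilizer_share,
        pl.compound_fertilizer_share,
        pl.compound_n_content,
    )
    add(
        "n_fertilizer",
        "N2O",
        planting.soil_n2o(
            n_input,
            fac.ef_n_direct,
            fac.ef_n_vol_indirect,
            fac.f_gas_fert,
            fac.ef_n_leach_indirect,
            fac.f_leach_soil,
            gwp.gwp_n2o,
        ),
    )

    add("manure_application", "N2O", planting.manure_application_n2o(spec, mode))

    if spec.model_kind == "EC":
        add("feed_production", "CO2", planting.scenario_feed_production_co2(spec))
    else:
        burn = planting.scenario_straw_burning(spec)
        add("straw_burning", "CO2", burn.co2)
        add("straw_burning", "CH4", burn.ch4)
        add("straw_burning", "N2O", burn.n2o)

    add("enteric_fermentation", "CH4", breeding.enteric_ch4(herd.herd_size, herd.enteric_ef, gwp.gwp_ch4))

    vs = breeding.volatile_solids_annual(man.vs_rate, herd.live_weight)
    add(
        "manure_management",
        "CH4",
        breeding.manure_mgmt_ch4(herd.herd_size, vs, man.ms_fraction, man.mm_ch4_ef, gwp.gwp_ch4),
    )
    nex = breeding.n_excretion_annual(herd.n_excretion_rate, herd.live_weight)
    add(
        "manure_management",
        "N2O",
        breeding.manure_mgmt_n2o(herd.herd_size, nex, man, fac, gwp.gwp_n2o).total,
    )

    return InventoryReport(
        scenario_name=spec.name, model_kind=spec.model_kind, mode=mode, entries=entries
    )


def gas_totals(report: InventoryReport) -> pd.DataFrame:
    """Per-gas CO₂-eq totals with shares of the inventory total."""
    totals = report.gas_totals()
    grand = report.total
    return pd.DataFrame(
        [
            {
                "gas": g,
                "co2eq_kg_per_a": v,
                "co2eq_1e7_t_per_a": round_display(v),
                "share": v / grand if grand else 0.0,
            }
            for g, v in totals.items()
        ]
    )


@dataclass
class ComparisonReport:
    """Differences b − a between two same-mode inventories.

    Positive values are emission reductions achieved by scenario ``a``
    relative to ``b``; processes absent from one scenario count as zero
    there, so differences may be negative (a process only ``a`` has).
    """

    a_name: str
    b_name: str
    mode: str
    process_diffs: dict[tuple[str, str], float]
    gas_diffs: dict[str, float]
    total_diff: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "process": p,
                "gas": g,
                "diff_kg_per_a": v,
                "diff_1e7_t_per_a": round_display(v),
            }
            for (p, g), v in self.process_diffs.items()
        ]
        return pd.DataFrame(rows)


def compare(a: InventoryReport, b: InventoryReport) -> ComparisonReport:
    """Elementwise b − a; both reports must use the same mode."""
    if a.mode != b.mode:
        raise ValueError(
            f"cannot compare inventories of different modes ({a.mode} vs {b.mode})"
        )
    keys: list[tuple[str, str]] = []
    for rep in (a, b):
        for e in rep.entries:
            if (e.process, e.gas) not in keys:
                keys.append((e.process, e.gas))
    process_diffs = {k: b.get(*k) - a.get(*k) for k in keys}
    ga, gb = a.gas_totals(), b.gas_totals()
    gas_diffs = {g: gb[g] - ga[g] for g in GASES}
    return ComparisonReport(
        a_name=a.scenario_name,
        b_name=b.scenario_name,
        mode=a.mode,
        process_diffs=process_diffs,
        gas_diffs=gas_diffs,
        total_diff=b.total - a.total,
    )


def write_report(report: InventoryReport, path: str | Path, format: str = "csv") -> Path:
    """Write an inventory to ``path`` as RFC-4180 CSV or JSON.

    The CSV carries process rows, per-gas rows and a total row
    (``row_type`` column), each with full-precision kg·a⁻¹ and the
    2-decimal 10⁷ t·a⁻¹ display value.  JSON round-trips through
    :func:`read_report_json`.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2))
        return path
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")

    frame = report.to_frame()
    frame.insert(0, "row_type", "process")
    gas_frame = gas_totals(report)
    gas_rows = pd.DataFrame(
        {
            "row_type": "gas_total",
            "industry": "",
            "process": "",
            "gas": gas_frame["gas"],
            "co2eq_kg_per_a": gas_frame["co2eq_kg_per_a"],
            "co2eq_1e7_t_per_a": gas_frame["co2eq_1e7_t_per_a"],
            "share": gas_frame["share"],
            "overridden": False,
        }
    )
    total_row = pd.DataFrame(
        [
            {
                "row_type": "total",
                "industry": "",
                "process": "",
                "gas": "",
                "co2eq_kg_per_a": report.total,
                "co2eq_1e7_t_per_a": round_display(report.total),
                "share": 1.0 if report.total else 0.0,
                "overridden": False,
            }
        ]
    )
    out = pd.concat([frame, gas_rows, total_row], ignore_index=True)
    out.insert(0, "mode", report.mode)
    out.insert(0, "scenario", report.scenario_name)
    try:
        out.to_csv(path, index=False, lineterminator="\r\n")
    except OSError as exc:
        raise OSError(f"could not write report to {path}: {exc}") from exc
    return path


def read_report_json(path: str | Path) -> InventoryReport:
    """Read back a JSON report written by :func:`write_report`."""
    return InventoryReport.from_dict(json.loads(Path(path).read_text()))
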