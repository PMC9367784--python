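"""Scenario data model: herd, planting, manure management, emission factors.

A scenario bundles everything needed to compute the annual greenhouse-gas
inventory of a beef-cattle herd integrated with its feed-corn planting
system.  Two breeding models are distinguished:

``EC`` (ecological cycle)
    Whole-plant silage corn is grown and processed into feed on-farm, all
    manure is returned to the field, and no crop residue is burned.

``non-EC`` (conventional)
    Common corn grain is fed, only part of the manure re-enters the
    planting system, and most of the corn straw is disposed of by open
    burning.

All masses are carried internally in kg per year (kg·a⁻¹); conversion to
the reporting unit of 10⁷ t·a⁻¹ happens only when a report is written.
Emission factors default to the values of the published coefficient table
(IPCC 2019-refinement vintage plus regional literature values) and may be
overridden per scenario.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "HerdSpec",
    "PlantingSpec",
    "ManureSpec",
    "EmissionFactorSet",
    "GWPSet",
    "ScenarioSpec",
    "ScenarioFormatError",
    "load_scenario",
    "save_scenario",
    "paper_scenarios",
    "scenario_json_schema",
    "PROCESS_IDS",
]

#: Process identifiers a scenario may carry as-printed overrides for.
PROCESS_IDS = (
    "corn_planting",
    "n_fertilizer",
    "manure_application",
    "feed_production",
    "straw_burning",
    "enteric_fermentation",
    "manure_management",
)


class ScenarioFormatError(ValueError):
    """Raised when a scenario file cannot be parsed as hierarchical config."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class HerdSpec(_Model):
    """Herd description and animal-level defaults."""

    herd_size: float = Field(ge=0, description="head per year (head·a⁻¹)")
    live_weight: float = Field(
        gt=0, description="average live mass per head (kg)"
    )
    fattening_days: float = Field(
        ge=0, default=365.0, description="days per fattening cycle (d·a⁻¹)"
    )
    enteric_ef: float = Field(
        ge=0,
        description="enteric-fermentation CH₄ factor (kg CH₄·head⁻¹·a⁻¹)",
    )
    n_excretion_rate: float = Field(
        ge=0,
        description="N excretion rate (kg N·(1000 kg live mass)⁻¹·d⁻¹)",
    )
    manure_per_head_day: float = Field(
        ge=0, description="manure (dung + urine) mass per head (kg·d⁻¹)"
    )


class PlantingSpec(_Model):
    """Feed-corn planting system and straw-fate shares."""

    feed_intake_per_head_day: float = Field(
        ge=0, description="corn feed intake (kg·head⁻¹·d⁻¹)"
    )
    planting_area: float = Field(ge=0, description="planting area (hm²)")
    fertilizer_application_rate: float = Field(
        ge=0, description="total fertilizer applied (kg·hm⁻²·a⁻¹)"
    )
    n_fertilizer_share: float = Field(
        ge=0, le=1, description="share of fertilizer that is straight N"
    )
    compound_fertilizer_share: float = Field(
        ge=0, le=1, description="share of fertilizer that is compound"
    )
    compound_n_content: float = Field(
        ge=0, le=1, description="N mass fraction of compound fertilizer"
    )
    straw_feed_fraction: float = Field(
        ge=0, le=1, description="fraction of straw production used as feed"
    )
    straw_burn_fraction: float = Field(
        ge=0, le=1, description="fraction of straw production open-burned"
    )
    is_silage: bool = Field(
        description="True when the crop is whole-plant silage corn"
    )

    @model_validator(mode="after")
    def _fates_sum(self) -> "PlantingSpec":
        if self.straw_feed_fraction + self.straw_burn_fraction > 1 + 1e-9:
            raise ValueError(
                "straw_feed_fraction + straw_burn_fraction must not exceed 1"
            )
        return self


class ManureSpec(_Model):
    """Manure management and field-return parameters."""

    return_rate: float = Field(
        ge=0, le=1, description="fraction of manure entering the planting system"
    )
    vs_rate: float = Field(
        ge=0,
        description="volatile-solids excretion (kg VS·(1000 kg live mass)⁻¹·d⁻¹)",
    )
    ms_fraction: float = Field(
        ge=0, le=1, description="fraction of annual VS/N that is managed"
    )
    mm_ch4_ef: float = Field(
        ge=0, description="manure-management CH₄ factor (kg CH₄·kg VS⁻¹)"
    )
    mm_n2o_direct_ef: float = Field(
        ge=0, description="direct N₂O-N factor for managed manure (kg·kg N⁻¹)"
    )
    f_gas: float = Field(
        ge=0, le=1, description="volatilized fraction of managed manure N"
    )
    f_leach: float = Field(
        ge=0, le=1, description="leached fraction of managed manure N"
    )


class EmissionFactorSet(_Model):
    """Emission factors and loss fractions of the coefficient table.

    Defaults are the published values; every field can be overridden
    per scenario in the config file.
    """

    ef_farm_corn: float = Field(
        default=1.50, ge=0, description="corn-planting CO₂ (t CO₂·t corn⁻¹)"
    )
    ef_feed_corn: float = Field(
        default=0.0102, ge=0, description="silage feed processing CO₂ (t·t⁻¹)"
    )
    ef_n_direct: float = Field(
        default=0.0105, ge=0, description="direct soil N₂O-N (t·t N⁻¹)"
    )
    ef_n_vol_indirect: float = Field(
        default=0.01, ge=0, description="indirect N₂O-N from deposition (t·t N⁻¹)"
    )
    ef_n_leach_indirect: float = Field(
        default=0.0075, ge=0, description="indirect N₂O-N from leaching (t·t N⁻¹)"
    )
    f_gas_fert: float = Field(
        default=0.1, ge=0, le=1, description="volatilized fraction of fertilizer N"
    )
    f_gas_manure: float = Field(
        default=0.2, ge=0, le=1, description="volatilized fraction of applied manure N"
    )
    f_leach_soil: float = Field(
        default=0.25, ge=0, le=1, description="leached fraction of soil-applied N"
    )
    burn_combustion_factor: float = Field(
        default=0.1, ge=0, description="straw open-burning combustion factor (–)"
    )
    ef_burn_co2: float = Field(
        default=1.39, ge=0, description="burning CO₂ (kg·kg burned⁻¹)"
    )
    ef_burn_ch4: float = Field(
        default=2.19e-3, ge=0, description="burning CH₄ (kg·kg burned⁻¹)"
    )
    ef_burn_n2o: float = Field(
        default=7e-5, ge=0, description="burning N₂O (kg·kg burned⁻¹)"
    )
    ef_mm_idn_vol: float = Field(
        default=0.010,
        ge=0,
        description="indirect N₂O-N per kg volatilized manure-management N",
    )
    ef_mm_idn_leach: float = Field(
        default=0.011,
        ge=0,
        description="indirect N₂O-N per kg leached manure-management N",
    )


class GWPSet(_Model):
    """100-year global-warming potentials (CO₂-eq per unit gas mass)."""

    gwp_ch4: float = Field(default=28.0, gt=0)
    gwp_n2o: float = Field(default=265.0, gt=0)
    gwp_n2o_manure_application: float = Field(
        default=273.0,
        gt=0,
        description=(
            "N₂O GWP used only by the manure-application replication path; "
            "the published manure-application cells are reproducible only "
            "with this constant, not with the stated 265"
        ),
    )


class ScenarioSpec(_Model):
    """One breeding model: herd + planting + manure + factors + GWPs.

    ``overrides`` carries optional as-printed per-process CO₂-eq values
    (kg·a⁻¹) that replication mode reports verbatim where the published
    table is not derivable from its own inputs; corrected mode ignores
    them.
    """

    name: str
    model_kind: Literal["EC", "non-EC"]
    herd: HerdSpec
    planting: PlantingSpec
    manure: ManureSpec
    factors: EmissionFactorSet = Field(default_factory=EmissionFactorSet)
    gwp: GWPSet = Field(default_factory=GWPSet)
    overrides: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _structure(self) -> "ScenarioSpec":
        errors = []
        if self.model_kind == "EC":
            if self.planting.straw_burn_fraction != 0:
                errors.append("EC scenarios must have straw_burn_fraction = 0")
            if not self.planting.is_silage:
                errors.append(
                    "EC scenarios must grow silage corn (is_silage = True, "
                    "feed-production process present)"
                )
        else:
            if self.planting.straw_burn_fraction <= 0:
                errors.append("non-EC scenarios must have straw_burn_fraction > 0")
            if self.planting.is_silage:
                errors.append(
                    "non-EC scenarios must not have a feed-production process "
                    "(is_silage = False)"
                )
        for key, value in self.overrides.items():
            if key not in PROCESS_IDS:
                errors.append(f"unknown override process id {key!r}")
            elif value < 0:
                errors.append(f"override for {key!r} must be >= 0")
        if errors:
            raise ValueError("; ".join(errors))
        return self


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Load and validate a scenario from a YAML (or JSON) file.

    Omitted emission factors and GWPs are filled with the coefficient-table
    defaults.  Raises :class:`ScenarioFormatError` if the file does not
    parse as a mapping, and ``pydantic.ValidationError`` (listing every
    violation) if it parses but breaks an invariant.
    """
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ScenarioFormatError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ScenarioFormatError(
            f"{path}: top level must be a mapping, got {type(data).__name__}"
        )
    return ScenarioSpec.model_validate(data)


def save_scenario(spec: ScenarioSpec, path: str | Path) -> Path:
    """Write a scenario to YAML so that ``load_scenario`` round-trips it."""
    path = Path(path)
    path.write_text(yaml.safe_dump(spec.model_dump(), sort_keys=False))
    return path


def scenario_json_schema() -> dict:
    """Machine-readable (JSON-schema) description of the scenario format."""
    return ScenarioSpec.model_json_schema()


def _fixture_path(name: str):
    return resources.files("cattle_lca").joinpath("data", name)


def paper_scenarios() -> tuple[ScenarioSpec, ScenarioSpec]:
    """The two published scenarios (EC, non-EC), verbatim coefficient-table
    values for a 10⁷-head herd.

    Notes on two deliberate choices:

    * ``manure_per_head_day`` is 22.0 kg·d⁻¹ so that the annual per-head
      manure mass is the published 8030.00 kg; the coefficient table also
      prints a daily figure of 22.67 kg·d⁻¹ that is inconsistent with its
      own annual mass, and every downstream number uses the annual mass.
    * the EC scenario carries an as-printed override for the N-fertilizer
      process (2.1 × 10⁹ kg CO₂-eq·a⁻¹ = 0.21 × 10⁷ t·a⁻¹), because that
      published cell is not derivable from the coefficient table; see the
      methods note.
    """
    common_herd = dict(
        herd_size=1e7,
        live_weight=319.0,
        fattening_days=365.0,
        enteric_ef=65.0,
        n_excretion_rate=0.41,
        manure_per_head_day=22.0,
    )
    ec = ScenarioSpec(
        name="ec_paper",
        model_kind="EC",
        herd=HerdSpec(**common_herd),
        planting=PlantingSpec(
            feed_intake_per_head_day=20.0,
            planting_area=9.01e5,
            fertilizer_application_rate=679.33,
            n_fertilizer_share=0.3105,
            compound_fertilizer_share=0.5363,
            compound_n_content=0.2841,
            straw_feed_fraction=1.0,
            straw_burn_fraction=0.0,
            is_silage=True,
        ),
        manure=ManureSpec(
            return_rate=1.0,
            vs_rate=6.8,
            ms_fraction=0.28,
            mm_ch4_ef=1.05,
            mm_n2o_direct_ef=0.005,
            f_gas=0.30,
            f_leach=0.035,
        ),
        overrides={"n_fertilizer": 2.1e9},
    )
    nonec = ScenarioSpec(
        name="nonec_paper",
        model_kind="non-EC",
        herd=HerdSpec(**common_herd),
        planting=PlantingSpec(
            feed_intake_per_head_day=9.0,
            planting_area=70.66e5,
            fertilizer_application_rate=679.33,
            n_fertilizer_share=0.3105,
            compound_fertilizer_share=0.5363,
            compound_n_content=0.2841,
            straw_feed_fraction=0.0988,
            straw_burn_fraction=0.8575,
            is_silage=False,
        ),
        manure=ManureSpec(
            return_rate=0.45,
            vs_rate=10.8,
            ms_fraction=0.29,
            mm_ch4_ef=2.05,
            mm_n2o_direct_ef=0.01,
            f_gas=0.45,
            f_leach=0.02,
        ),
    )
    return ec, nonec
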