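"""Planting-industry emission processes.

Five processes belong to the planting side of the crop-livestock system:
corn-planting CO₂, N-fertilizer N₂O (direct + volatilization + leaching),
manure-application N₂O, silage feed-production CO₂ (ecological-cycle
scenarios only) and straw open-burning CO₂/CH₄/N₂O (conventional
scenarios only).

All functions take and return masses in kg·a⁻¹ and are linear
(degree-1 homogeneous) in their activity input.  The N₂O-N → N₂O mass
conversion is the exact stoichiometric ratio 44/28, never a rounded
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import EmissionFactorSet, GWPSet, ScenarioSpec

__all__ = [
    "DomainError",
    "ProcessNotApplicableError",
    "StrawBalance",
    "BurningEmissions",
    "annual_feed_demand",
    "straw_balance",
    "corn_planting_co2",
    "fertilizer_nitrogen_input",
    "soil_n2o",
    "manure_application_n2o",
    "feed_production_co2",
    "straw_burning_emissions",
    "scenario_feed_production_co2",
    "scenario_straw_burning",
    "N2O_N_TO_N2O",
]

#: Exact stoichiometric conversion of N₂O-N mass to N₂O mass.
N2O_N_TO_N2O = 44.0 / 28.0


class DomainError(ValueError):
    """An argument lies outside its physical domain (e.g. negative mass)."""


class ProcessNotApplicableError(RuntimeError):
    """A process was requested for a scenario kind that does not contain it."""


def _require_nonneg(**kwargs: float) -> None:
    bad = [f"{k}={v}" for k, v in kwargs.items() if v < 0]
    if bad:
        raise DomainError("negative input(s): " + ", ".join(bad))


@dataclass(frozen=True)
class StrawBalance:
    """Total straw implied by an annual feed demand and the straw-fate shares.

    The published mass balance admits two readings of "total straw", and
    both are needed to reproduce the published tables:

    ``total_straw_normalized``
        feed and burn shares rescaled to sum to one, i.e.
        ``feed_demand × (feed + burn) / feed`` — the printed total straw
        requirement (31.80 × 10¹⁰ kg for the conventional scenario);
        consumed by corn-planting CO₂.

    ``total_straw_feed_share``
        ``feed_demand / feed_fraction`` — the gross straw production of
        which the feed share is the herd's demand (33.25 × 10¹⁰ kg);
        consumed by straw burning, whose printed values require it.
    """

    annual_feed_demand: float
    total_straw_normalized: float
    total_straw_feed_share: float


@dataclass(frozen=True)
class BurningEmissions:
    """Per-gas CO₂-eq record for straw open burning (kg·a⁻¹)."""

    co2: float
    ch4: float
    n2o: float

    @property
    def total(self) -> float:
        return self.co2 + self.ch4 + self.n2o


def annual_feed_demand(
    intake_per_head_day: float, herd_size: float, days: float = 365.0
) -> float:
    """Annual herd feed demand, kg·a⁻¹ = intake × head × days."""
    _require_nonneg(
        intake_per_head_day=intake_per_head_day, herd_size=herd_size, days=days
    )
    return intake_per_head_day * herd_size * days


def straw_balance(
    feed_demand: float, feed_fraction: float, burn_fraction: float
) -> StrawBalance:
    """Scale an annual feed demand up to the total straw it implies."""
    _require_nonneg(feed_demand=feed_demand, burn_fraction=burn_fraction)
    if feed_fraction <= 0:
        raise DomainError(
            "straw feed fraction must be > 0 to infer total straw from feed "
            "demand; set straw_feed_fraction to the share of straw used as feed"
        )
    if feed_fraction + burn_fraction > 1 + 1e-9:
        raise DomainError("feed_fraction + burn_fraction must not exceed 1")
    return StrawBalance(
        annual_feed_demand=feed_demand,
        total_straw_normalized=feed_demand * (feed_fraction + burn_fraction) / feed_fraction,
        total_straw_feed_share=feed_demand / feed_fraction,
    )


def corn_planting_co2(corn_mass: float, ef_farm_corn: float) -> float:
    """CO₂ from growing the corn feed, kg·a⁻¹.

    ``corn_mass`` is the annual silage feed demand for ecological-cycle
    scenarios and the normalized total straw requirement for conventional
    ones.
    """
    _require_nonneg(corn_mass=corn_mass, ef_farm_corn=ef_farm_corn)
    return corn_mass * ef_farm_corn


def fertilizer_nitrogen_input(
    area: float,
    application_rate: float,
    n_fert_share: float,
    compound_share: float,
    compound_n_content: float,
) -> float:
    """Annual N applied as synthetic fertilizer, kg N·a⁻¹.

    area × rate × (straight-N share + compound share × compound N content).
    """
    _require_nonneg(
        area=area,
        application_rate=application_rate,
        n_fert_share=n_fert_share,
        compound_share=compound_share,
        compound_n_content=compound_n_content,
    )
    return area * application_rate * (n_fert_share + compound_share * compound_n_content)


def soil_n2o(
    n_input: float,
    ef_direct: float,
    ef_vol: float,
    f_gas: float,
    ef_leach: float,
    f_leach: float,
    gwp_n2o: float,
) -> float:
    """Soil N₂O (direct + both indirect pathways) as CO₂-eq kg·a⁻¹."""
    _require_nonneg(
        n_input=n_input,
        ef_direct=ef_direct,
        ef_vol=ef_vol,
        f_gas=f_gas,
        ef_leach=ef_leach,
        f_leach=f_leach,
        gwp_n2o=gwp_n2o,
    )
    return (
        n_input
        * (ef_direct + ef_vol * f_gas + ef_leach * f_leach)
        * N2O_N_TO_N2O
        * gwp_n2o
    )


def manure_application_n2o(spec: ScenarioSpec, mode: str) -> float:
    """N₂O from manure returned to the field, as CO₂-eq kg·a⁻¹.

    ``replication`` mode reproduces the published cells: the applied
    "nitrogen" is the per-head annual manure mass (22 kg·d⁻¹ × 365 d =
    8030 kg, not scaled by herd size and not an N mass) times the return
    rate, converted with the 273 N₂O potential.  This is dimensionally
    inconsistent but is the only reading that yields the printed 49.53 t
    (ecological cycle) and 22.29 t (conventional).

    ``corrected`` mode applies the stated method uniformly: herd N
    excretion × return rate × the same emission-factor composite, with
    the stated 265 potential.

    An empty herd produces no manure, so ``herd_size = 0`` yields 0 in
    both modes even though the replication basis is otherwise per-head.
    """
    if spec.herd.herd_size == 0:
        return 0.0
    composite = (
        spec.factors.ef_n_direct
        + spec.factors.ef_n_vol_indirect * spec.factors.f_gas_manure
        + spec.factors.ef_n_leach_indirect * spec.factors.f_leach_soil
    ) * N2O_N_TO_N2O
    if mode == "replication":
        tnm = (
            spec.herd.manure_per_head_day
            * spec.herd.fattening_days
            * spec.manure.return_rate
        )
        return tnm * composite * spec.gwp.gwp_n2o_manure_application
    if mode == "corrected":
        from .breeding import n_excretion_annual

        nex = n_excretion_annual(spec.herd.n_excretion_rate, spec.herd.live_weight)
        tnm = spec.herd.herd_size * nex * spec.manure.return_rate
        return tnm * composite * spec.gwp.gwp_n2o
    raise ValueError(f"unknown mode {mode!r}; expected 'replication' or 'corrected'")


def feed_production_co2(silage_mass: float, ef_feed_corn: float) -> float:
    """CO₂ from processing silage corn into feed, kg·a⁻¹."""
    _require_nonneg(silage_mass=silage_mass, ef_feed_corn=ef_feed_corn)
    return silage_mass * ef_feed_corn


def straw_burning_emissions(
    straw_mass: float,
    burn_fraction: float,
    combustion_factor: float,
    factors: EmissionFactorSet,
    gwp: GWPSet,
) -> BurningEmissions:
    """Open-burning CO₂/CH₄/N₂O as CO₂-eq kg·a⁻¹.

    ``straw_mass`` is the feed-share straw total (gross production); the
    burned mass is straw × burn fraction × combustion factor.
    """
    _require_nonneg(
        straw_mass=straw_mass,
        burn_fraction=burn_fraction,
        combustion_factor=combustion_factor,
    )
    burned = straw_mass * burn_fraction * combustion_factor
    return BurningEmissions(
        co2=burned * factors.ef_burn_co2,
        ch4=burned * factors.ef_burn_ch4 * gwp.gwp_ch4,
        n2o=burned * factors.ef_burn_n2o * gwp.gwp_n2o,
    )


def scenario_feed_production_co2(spec: ScenarioSpec) -> float:
    """Feed-production CO₂ for a scenario; ecological-cycle scenarios only."""
    if spec.model_kind != "EC":
        raise ProcessNotApplicableError(
            "feed production is only part of the ecological-cycle model"
        )
    silage = annual_feed_demand(
        spec.planting.feed_intake_per_head_day,
        spec.herd.herd_size,
        spec.herd.fattening_days,
    )
    return feed_production_co2(silage, spec.factors.ef_feed_corn)


def scenario_straw_burning(spec: ScenarioSpec) -> BurningEmissions:
    """Straw-burning record for a scenario; conventional scenarios only."""
    if spec.model_kind != "non-EC":
        raise ProcessNotApplicableError(
            "straw burning is only part of the non-ecological-cycle model"
        )
    demand = annual_feed_demand(
        spec.planting.feed_intake_per_head_day,
        spec.herd.herd_size,
        spec.herd.fattening_days,
    )
    balance = straw_balance(
        demand, spec.planting.straw_feed_fraction, spec.planting.straw_burn_fraction
    )
    return straw_burning_emissions(
        balance.total_straw_feed_share,
        spec.planting.straw_burn_fraction,
        spec.factors.burn_combustion_factor,
        spec.factors,
        spec.gwp,
    )
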