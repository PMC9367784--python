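"""Breeding-industry emission processes.

Enteric-fermentation CH₄ uses a single Tier-1 factor per head; manure
management emits CH₄ from volatile solids and N₂O (direct plus the
volatilization and leaching indirect pathways) from managed nitrogen.
Masses in kg·a⁻¹; every emission is linear in herd size.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import EmissionFactorSet, ManureSpec
from .planting import N2O_N_TO_N2O, _require_nonneg

__all__ = [
    "ManureN2OBreakdown",
    "enteric_ch4",
    "volatile_solids_annual",
    "manure_mgmt_ch4",
    "n_excretion_annual",
    "manure_mgmt_n2o",
]


@dataclass(frozen=True)
class ManureN2OBreakdown:
    """Manure-management N₂O split by pathway (CO₂-eq kg·a⁻¹)."""

    direct: float
    indirect_volatilization: float
    indirect_leaching: float

    @property
    def total(self) -> float:
        return self.direct + self.indirect_volatilization + self.indirect_leaching


def enteric_ch4(herd_size: float, enteric_ef: float, gwp_ch4: float) -> float:
    """Enteric-fermentation CH₄ as CO₂-eq kg·a⁻¹ (Tier-1 per-head factor)."""
    _require_nonneg(herd_size=herd_size, enteric_ef=enteric_ef, gwp_ch4=gwp_ch4)
    return herd_size * enteric_ef * gwp_ch4


def volatile_solids_annual(vs_rate: float, live_weight: float) -> float:
    """Annual volatile-solids excretion per head, kg·head⁻¹·a⁻¹.

    vs_rate is per 1000 kg live mass per day.
    """
    _require_nonneg(vs_rate=vs_rate, live_weight=live_weight)
    return vs_rate * live_weight / 1000.0 * 365.0


def manure_mgmt_ch4(
    herd_size: float,
    vs_annual: float,
    ms_fraction: float,
    mm_ch4_ef: float,
    gwp_ch4: float,
) -> float:
    """Manure-management CH₄ as CO₂-eq kg·a⁻¹."""
    _require_nonneg(
        herd_size=herd_size,
        vs_annual=vs_annual,
        ms_fraction=ms_fraction,
        mm_ch4_ef=mm_ch4_ef,
        gwp_ch4=gwp_ch4,
    )
    return herd_size * vs_annual * ms_fraction * mm_ch4_ef * gwp_ch4


def n_excretion_annual(n_rate: float, live_weight: float) -> float:
    """Annual N excretion per head, kg N·head⁻¹·a⁻¹."""
    _require_nonneg(n_rate=n_rate, live_weight=live_weight)
    return n_rate * live_weight / 1000.0 * 365.0


def manure_mgmt_n2o(
    herd_size: float,
    nex: float,
    manure: ManureSpec,
    factors: EmissionFactorSet,
    gwp_n2o: float,
) -> ManureN2OBreakdown:
    """Manure-management N₂O by pathway, CO₂-eq kg·a⁻¹.

    Managed N = herd × per-head annual excretion × managed fraction;
    the direct pathway applies the management-system factor, the two
    indirect pathways apply the deposition/leaching factors to the
    volatilized and leached shares of the same managed N.
    """
    _require_nonneg(herd_size=herd_size, nex=nex, gwp_n2o=gwp_n2o)
    managed_n = herd_size * nex * manure.ms_fraction
    k = N2O_N_TO_N2O * gwp_n2o
    return ManureN2OBreakdown(
        direct=managed_n * manure.mm_n2o_direct_ef * k,
        indirect_volatilization=managed_n * manure.f_gas * factors.ef_mm_idn_vol * k,
        indirect_leaching=managed_n * manure.f_leach * factors.ef_mm_idn_leach * k,
    )
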