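"""ATP balances, carbon/energy costs and pathway yields of flux components.

Every flux component is mass-balanced, so its net ATP production by the
metabolic reactions is exactly the flux it carries through the maintenance
hydrolysis reaction: the ATP "earned" or "spent" by a function is read off a
single matrix entry, and the components' entries sum to J_ATPM by
construction.  Costs are derived the same way: the carbon cost of a building
block is the substrate carbon drawn by its component per unit demand, and the
ATP cost is minus its maintenance flux per unit demand (negative cost = the
pathway is a net ATP producer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fdm_core import FluxDecomposition
from .model import MetabolicModel, ModelError

__all__ = [
    "EnergyBalance",
    "CostRecord",
    "YieldRecord",
    "component_atp_balance",
    "biosynthesis_costs",
    "pathway_only_costs",
    "energy_yield_per_carbon",
    "component_carbon_balance",
]

_BIOSYNTHETIC = {"building_block", "biosynthesis"}


@dataclass
class EnergyBalance:
    """Net ATP flux per function (positive = production into the pool)."""

    table: pd.DataFrame  # columns: atp_flux, category
    atpm_flux: float

    @property
    def total(self) -> float:
        return float(self.table["atp_flux"].sum())


@dataclass
class CostRecord:
    function_id: str
    carbon_cost: float  # substrate C atoms per molecule produced
    atp_cost: float  # mol ATP per mol produced; negative = net production
    demand_flux: float
    carbon_cost_per_gDW: float | None = None  # mmol C per gDW
    atp_cost_per_gDW: float | None = None


@dataclass
class YieldRecord:
    pathway: str
    atp_per_carbon: float
    substrate_id: str
    condition: str = ""


def component_atp_balance(
    decomp: FluxDecomposition,
    atpm_reaction: str,
) -> EnergyBalance:
    """Net ATP hydrolysis flux of each (coupled) component.

    The sign convention is production-positive: a component with positive flux
    through the maintenance reaction delivers ATP to the shared pool.
    """
    if atpm_reaction not in decomp.components.columns:
        raise ModelError(f"maintenance reaction {atpm_reaction!r} not in decomposition")
    flux = decomp.components[atpm_reaction]
    cats = pd.Series({f: decomp.categories.get(f, "") for f in decomp.function_ids})
    table = pd.DataFrame({"atp_flux": flux, "category": cats})
    return EnergyBalance(table=table, atpm_flux=float(decomp.flux_vector[atpm_reaction]))


def _demand_flux(decomp: FluxDecomposition, function_id: str) -> float | None:
    try:
        return decomp.demands.get(function_id).flux
    except KeyError:
        return None


def biosynthesis_costs(
    decomp: FluxDecomposition,
    substrate_id: str,
    carbon_atoms_per_substrate: int,
    atpm_reaction: str,
    mu: float | None = None,
    functions: list[str] | None = None,
) -> list[CostRecord]:
    """Carbon and ATP cost per molecule for each biosynthetic function.

    carbon cost = (component substrate uptake x C atoms) / J_gamma;
    ATP cost    = -(component maintenance flux) / J_gamma.
    With ``mu`` given, demand-weighted per-gDW variants (x J_gamma / mu) are
    also filled in.
    """
    import warnings

    if substrate_id not in decomp.components.columns:
        raise ModelError(f"substrate exchange {substrate_id!r} not in decomposition")
    chosen = functions or [
        f
        for f in decomp.function_ids
        if decomp.categories.get(f, "") in _BIOSYNTHETIC
    ]
    records = []
    for f in chosen:
        J = _demand_flux(decomp, f)
        if J is None or J <= 0:
            warnings.warn(f"function {f!r} has no positive demand flux; skipped", stacklevel=2)
            continue
        uptake = -float(decomp.components.loc[f, substrate_id])  # uptake is negative flux
        carbon = uptake * carbon_atoms_per_substrate / J
        atp = -float(decomp.components.loc[f, atpm_reaction]) / J
        records.append(
            CostRecord(
                function_id=f,
                carbon_cost=carbon,
                atp_cost=atp,
                demand_flux=J,
                carbon_cost_per_gDW=carbon * J / mu if mu else None,
                atp_cost_per_gDW=atp * J / mu if mu else None,
            )
        )
    return records


def pathway_only_costs(
    decomp: FluxDecomposition,
    model: MetabolicModel,
    central_reactions: set[str],
    atp_metabolite: str,
    atpm_reaction: str,
    substrate_id: str,
    carbon_atoms_per_substrate: int,
    functions: list[str] | None = None,
) -> list[CostRecord]:
    """ATP costs with the central carbon pathways' credit removed.

    The component is restricted to non-central reactions and its net ATP
    production recomputed from the stoichiometry of the ATP metabolite; the
    maintenance reaction itself is always excluded from the sum, so an empty
    central set reproduces the full-network cost.
    """
    rxn_ids = list(decomp.components.columns)
    S = model.stoichiometric_matrix()
    met_idx = model.metabolite_ids.index(atp_metabolite)
    atp_row = pd.Series(S[met_idx, :], index=model.reaction_ids).reindex(rxn_ids).fillna(0.0)
    excluded = set(central_reactions) | {atpm_reaction}
    keep = np.array([rid not in excluded for rid in rxn_ids])
    full = biosynthesis_costs(
        decomp, substrate_id, carbon_atoms_per_substrate, atpm_reaction, functions=functions
    )
    records = []
    for rec in full:
        comp = decomp.components.loc[rec.function_id].to_numpy()
        net_atp = float((comp * atp_row.to_numpy())[keep].sum())
        records.append(
            CostRecord(
                function_id=rec.function_id,
                carbon_cost=rec.carbon_cost,
                atp_cost=-net_atp / rec.demand_flux,
                demand_flux=rec.demand_flux,
            )
        )
    return records


def energy_yield_per_carbon(
    decomp: FluxDecomposition,
    substrate_id: str,
    carbon_atoms_per_substrate: int,
    atpm_reaction: str,
    modes: tuple[str, ...] = ("respiration", "fermentation"),
    condition: str = "",
) -> list[YieldRecord]:
    """ATP yield per substrate carbon atom for each energy mode.

    A mode with (numerically) zero substrate uptake has no defined yield and is
    omitted from the result.
    """
    records = []
    for mode in modes:
        if mode not in decomp.components.index:
            continue
        uptake = -float(decomp.components.loc[mode, substrate_id])
        atp = float(decomp.components.loc[mode, atpm_reaction])
        carbon_in = uptake * carbon_atoms_per_substrate
        if carbon_in <= 1e-12:
            continue
        records.append(
            YieldRecord(
                pathway=mode,
                atp_per_carbon=atp / carbon_in,
                substrate_id=substrate_id,
                condition=condition,
            )
        )
    return records


def component_carbon_balance(
    decomp: FluxDecomposition,
    model: MetabolicModel,
    function_id: str,
) -> float:
    """Net boundary carbon flow of one component (imbalance; ~0 when conserved).

    Internal reactions conserve carbon, so for a mass-balanced component the
    substrate carbon drawn through exchanges equals the carbon leaving through
    product sinks and CO2/byproduct excretion; the signed sum over boundary
    reactions is the imbalance.
    """
    met = {m.id: m for m in model.metabolites}
    comp = decomp.components.loc[function_id]
    total = 0.0
    for r in model.reactions:
        if not r.is_exchange:
            continue
        (mid, coeff), = r.stoichiometry.items()
        carbon = met[mid].element_counts.get("C", 0)
        # positive flux exports carbon, negative imports it
        total += float(comp.get(r.id, 0.0)) * (-coeff) * carbon
    return total
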