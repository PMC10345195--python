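"""Model and condition I/O, biomass splitting and demand-set assembly.

Genome-scale models are read and written through COBRApy (SBML Level 3 + FBC
via libsbml, and the BiGG JSON dialect) and converted to the package's own
lightweight containers.  The lumped biomass pseudo-reaction of a loaded model
is replaced by one irreversible sink per building block, so that each biomass
component enters the optimisation as an independent demand flux J_gamma =
c_gamma(mu) * mu -- the right-hand-side parameters of the flux decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import (
    BiomassComposition,
    Demand,
    DemandCategory,
    DemandSet,
    GrowthCondition,
    Limitation,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
)

__all__ = [
    "load_model",
    "write_model",
    "split_biomass",
    "ExcretionLaw",
    "build_demand_set",
    "apply_condition",
    "read_biomass_composition",
    "read_conditions",
    "demand_sink_id",
]

#: default ids used to recognise the growth-associated ATP hydrolysis block of
#: a lumped biomass reaction (BiGG naming).
ATP_HYDROLYSIS_METS = {
    "atp_c": -1.0,
    "h2o_c": -1.0,
    "adp_c": 1.0,
    "pi_c": 1.0,
    "h_c": 1.0,
}


def demand_sink_id(met_id: str) -> str:
    return f"DM_{met_id}"


# ---------------------------------------------------------------------------
# model formats (delegated to cobrapy)
# ---------------------------------------------------------------------------


def _from_cobra(cm) -> MetabolicModel:
    mets = []
    for m in cm.metabolites:
        elements = {el: int(n) for el, n in (m.elements or {}).items()}
        mets.append(
            Metabolite(
                id=m.id,
                name=m.name or "",
                compartment=m.compartment or "c",
                element_counts=elements,
                charge=int(m.charge) if m.charge is not None else 0,
            )
        )
    rxns = []
    for r in cm.reactions:
        if r.lower_bound is None or r.upper_bound is None:  # pragma: no cover
            raise ModelError(f"reaction {r.id!r} has missing bounds")
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gene_rule=r.gene_reaction_rule or "",
                subsystem=r.subsystem or "",
                name=r.name or "",
            )
        )
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=[g.id for g in cm.genes],
        id=cm.id or "model",
    )


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        formula = "".join(f"{el}{n}" for el, n in sorted(m.element_counts.items())) or None
        cm_met = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=formula, charge=m.charge
        )
        cmets[m.id] = cm_met
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, subsystem=r.subsystem)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoichiometry.items()})
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule
    return cm


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read an SBML (L3+FBC) or BiGG-JSON model into a :class:`MetabolicModel`."""
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    try:
        if fmt == "json":
            cm = cobra.io.load_json_model(str(path))
        elif fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelError(f"unknown model format {fmt!r}")
    except ModelError:
        raise
    except Exception as exc:  # parse errors from libsbml / json
        raise ModelError(f"failed to parse {path} as {fmt}: {exc}") from exc
    return _from_cobra(cm)


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    import cobra.io

    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    cm = _to_cobra(model)
    if fmt == "json":
        cobra.io.save_json_model(cm, str(path))
    elif fmt == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise ModelError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# biomass splitting
# ---------------------------------------------------------------------------


def find_biomass_reaction(model: MetabolicModel) -> str:
    candidates = [r.id for r in model.reactions if "biomass" in r.id.lower()]
    if len(candidates) != 1:
        raise ModelError(
            f"could not identify a unique biomass reaction (candidates: {candidates}); "
            "pass biomass_id explicitly"
        )
    return candidates[0]


def split_biomass(
    model: MetabolicModel,
    composition: BiomassComposition,
    mu: float,
    biomass_id: str | None = None,
    atp_hydrolysis: dict[str, float] | None = None,
) -> tuple[MetabolicModel, DemandSet]:
    """Replace the lumped biomass reaction by per-building-block demand sinks.

    Each building block gamma receives an irreversible sink with both bounds
    fixed to J_gamma = c_gamma(mu) * mu.  If the original biomass reaction
    contains a growth-associated ATP hydrolysis block, its stoichiometry is
    preserved as a maintenance demand of gam * mu through a dedicated
    hydrolysis reaction.
    """
    if mu < 0:
        raise ModelError("growth rate must be non-negative")
    model = model.copy()
    missing = [m for m in composition.metabolite_ids if m not in model.metabolite_ids]
    if missing:
        raise ModelError(f"composition metabolites absent from model: {missing}")

    gam = 0.0
    if biomass_id is None and any("biomass" in r.id.lower() for r in model.reactions):
        biomass_id = find_biomass_reaction(model)
    if biomass_id is not None and model.has_reaction(biomass_id):
        hydrolysis = atp_hydrolysis or ATP_HYDROLYSIS_METS
        biomass = model.remove_reaction(biomass_id)
        atp_key = next(iter(hydrolysis))
        if atp_key in biomass.stoichiometry and biomass.stoichiometry[atp_key] < 0:
            gam = -biomass.stoichiometry[atp_key]

    demands = []
    for met_id in composition.metabolite_ids:
        c = composition.coefficient(met_id, mu)
        flux = c * mu
        if flux < 0:
            raise ModelError(f"negative demand computed for {met_id!r}")
        sink = demand_sink_id(met_id)
        if not model.has_reaction(sink):
            model.add_reaction(
                Reaction(sink, {met_id: -1.0}, lower_bound=flux, upper_bound=flux)
            )
        else:
            model.set_bounds(sink, flux, flux)
        demands.append(Demand(met_id, flux, sink, DemandCategory.BUILDING_BLOCK))

    if gam > 0:
        hydrolysis = atp_hydrolysis or ATP_HYDROLYSIS_METS
        present = {m: c for m, c in hydrolysis.items() if m in model.metabolite_ids}
        gam_rxn = "GAM_hydrolysis"
        flux = gam * mu
        if not model.has_reaction(gam_rxn):
            model.add_reaction(Reaction(gam_rxn, present, lower_bound=flux, upper_bound=flux))
        else:
            model.set_bounds(gam_rxn, flux, flux)
        demands.append(Demand("GAM", flux, gam_rxn, DemandCategory.MAINTENANCE))

    return model, DemandSet(demands)


# ---------------------------------------------------------------------------
# demand-set assembly per condition
# ---------------------------------------------------------------------------


@dataclass
class ExcretionLaw:
    """Linear excretion flux law J(mu) = intercept + slope * mu, clipped at 0."""

    reaction_id: str
    intercept: float
    slope: float
    aerobic_only: bool = True

    def flux(self, mu: float) -> float:
        return max(0.0, self.intercept + self.slope * mu)


def build_demand_set(
    composition: BiomassComposition,
    condition: GrowthCondition,
    maintenance,
    excretion_laws: dict[str, ExcretionLaw] | None = None,
    sink_ids: dict[str, str] | None = None,
    atpm_reaction: str = "ATPM",
) -> DemandSet:
    """Building-block demands + maintenance ATP + condition-matched excretions.

    ``maintenance`` is anything with ``sigma0``/``sigma`` attributes (or a
    2-tuple): the maintenance flux is J_ATPM = sigma0 + sigma * mu.  Excretion
    laws apply according to the condition's aerobic flag (acetate aerobically,
    succinate anaerobically, in the canonical setup).
    """
    mu = condition.mu
    if isinstance(maintenance, tuple):
        sigma0, sigma = maintenance
    else:
        sigma0, sigma = maintenance.sigma0, maintenance.sigma
    j_atpm = sigma0 + sigma * mu
    if j_atpm < 0:
        raise ModelError(f"unphysical maintenance flux {j_atpm} at mu={mu}")

    demands = []
    for met_id in composition.metabolite_ids:
        flux = composition.coefficient(met_id, mu) * mu
        sink = (sink_ids or {}).get(met_id, demand_sink_id(met_id))
        demands.append(Demand(met_id, flux, sink, DemandCategory.BUILDING_BLOCK))
    demands.append(Demand("ATPM", j_atpm, atpm_reaction, DemandCategory.MAINTENANCE))
    for law in (excretion_laws or {}).values():
        if law.aerobic_only != condition.aerobic:
            continue
        demands.append(
            Demand(law.reaction_id, law.flux(mu), law.reaction_id, DemandCategory.EXCRETION)
        )
    return DemandSet(demands)


def apply_condition(
    model: MetabolicModel,
    condition: GrowthCondition,
    demands: DemandSet,
    oxygen_exchange: str = "EX_o2_e",
) -> MetabolicModel:
    """Fix demand bounds and gas constraints for one growth condition.

    Demand reactions get both bounds pinned to J_gamma; the oxygen exchange is
    closed when the condition is anaerobic; the substrate exchange is left free
    in the uptake direction so the parsimonious stage can minimise it.
    """
    model = model.copy()
    demands.validate_against(model)
    for d in demands:
        r = model.reaction(d.target_reaction)
        # an already-pinned sink is being re-parameterised; a genuine capacity
        # window that excludes the demand value is a modelling conflict
        if r.lower_bound != r.upper_bound and not (
            r.lower_bound - 1e-12 <= d.flux <= r.upper_bound + 1e-12
        ):
            raise ModelError(
                f"demand {d.function_id!r}: fixed flux {d.flux} outside original "
                f"bounds [{r.lower_bound}, {r.upper_bound}]"
            )
        model.set_bounds(d.target_reaction, d.flux, d.flux)
    if not condition.aerobic and model.has_reaction(oxygen_exchange):
        model.set_bounds(oxygen_exchange, 0.0, 0.0)
    sub = model.reaction(condition.substrate_id)
    sub.lower_bound = -float("inf")
    sub.upper_bound = min(sub.upper_bound, 0.0)
    return model


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------


def read_biomass_composition(path: str | Path, condition: str | None = None) -> BiomassComposition:
    """TSV with columns metabolite_id, mu, coefficient_mmol_per_gDW, condition."""
    df = pd.read_csv(path, sep="\t")
    required = {"metabolite_id", "mu", "coefficient_mmol_per_gDW"}
    if not required <= set(df.columns):
        raise ModelError(f"biomass composition table must have columns {sorted(required)}")
    if condition is not None and "condition" in df.columns:
        df = df[df["condition"] == condition]
    entries: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        entries.setdefault(row["metabolite_id"], []).append(
            (float(row["mu"]), float(row["coefficient_mmol_per_gDW"]))
        )
    return BiomassComposition(entries, condition=condition or "")


def read_conditions(path: str | Path) -> list[GrowthCondition]:
    """TSV with columns label, mu, substrate_exchange_id, uptake_mmol_gDW_h,
    acetate_mmol_gDW_h, limitation, aerobic."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        excretions = {}
        if "acetate_mmol_gDW_h" in df.columns and pd.notna(row.get("acetate_mmol_gDW_h")):
            excretions["EX_ac_e"] = float(row["acetate_mmol_gDW_h"])
        uptake = row.get("uptake_mmol_gDW_h")
        out.append(
            GrowthCondition(
                label=str(row["label"]),
                mu=float(row["mu"]),
                substrate_id=str(row["substrate_exchange_id"]),
                measured_uptake=float(uptake) if pd.notna(uptake) else None,
                measured_excretions=excretions,
                limitation=Limitation(str(row.get("limitation", "none"))),
                aerobic=bool(row.get("aerobic", True)),
            )
        )
    return out
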