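"""Deterministic toy networks and synthetic data series with known ground truth.

Every network is built so that the parsimonious optimum is unique and the
demand-flux response matrix has a closed form: apart from the parallel-paths
motif (where the L2 stage splits flux symmetrically), the active reactions at
the optimum form a square linear system, so the analytic response matrix is a
direct linear solve -- an oracle entirely independent of the LP/QP/finite
difference machinery it is used to check.

The six motifs exercise the situations that arise in genome-scale practice:

``linear_chain``     a single pathway (every response coefficient is 1);
``parallel_paths``   degeneracy broken by the L2 stage;
``branch``           a carbon-efficient vs a carbon-wasting route;
``overflow``         respiration vs fermentation with a fixed acetate
                     excretion, two NADH dehydrogenases of different
                     proton-pumping efficiency, and a biosynthetic demand
                     whose NADH by-product earns ATP credit;
``cofactor_mix``     an NADPH-balancing pathway whose sign-mismatched
                     components no pairwise coupling can remove;
``anaerobic_mix``    mixed-acid fermentation with a succinate excretion
                     constraint and ATP-consuming biosynthesis.

All generators are seed-free and bit-reproducible; the randomized synthetic
series take an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
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
    "Fixture",
    "TOY_KINDS",
    "make_toy_network",
    "write_fixture",
    "overflow_condition_factory",
    "synthetic_maintenance_conditions",
    "synthetic_allocation_series",
    "synthetic_efficiency_series",
    "synthetic_sector_series",
]

TOY_KINDS = (
    "linear_chain",
    "parallel_paths",
    "branch",
    "overflow",
    "cofactor_mix",
    "anaerobic_mix",
)


@dataclass
class Fixture:
    kind: str
    model: MetabolicModel
    demands: DemandSet
    substrate_id: str
    analytic_xi: pd.DataFrame  # function ids x reaction ids
    carbon_atoms: int  # per substrate molecule
    atpm_reaction: str | None = None
    atp_metabolite: str | None = None

    @property
    def analytic_components(self) -> pd.DataFrame:
        J = pd.Series({d.function_id: d.flux for d in self.demands})
        return self.analytic_xi.mul(J, axis=0)


def _analytic_xi_square(
    model: MetabolicModel,
    demands: DemandSet,
    inactive: set[str] = frozenset(),
) -> pd.DataFrame:
    """Closed-form response matrix when the active reactions form a square system.

    With the demand sinks and any LP-inactive reactions removed, the remaining
    stoichiometric sub-matrix must be square and invertible: the flux response
    to a unit demand is then the unique solution of S_free x = -S[:, sink].
    """
    rxn_ids = model.reaction_ids
    S = model.stoichiometric_matrix()
    targets = {d.target_reaction for d in demands}
    free_idx = [
        j for j, rid in enumerate(rxn_ids) if rid not in targets and rid not in inactive
    ]
    S_free = S[:, free_idx]
    touched = np.abs(S_free).sum(axis=1) > 0
    S_red = S_free[touched]
    if S_red.shape[0] != S_red.shape[1]:
        raise ModelError(
            f"active sub-network is not square ({S_red.shape}); "
            "no closed-form response for this fixture"
        )
    rows = {}
    for d in demands:
        col = S[:, rxn_ids.index(d.target_reaction)]
        x = np.linalg.solve(S_red, -col[touched])
        if np.abs(S_free @ x + col).max() > 1e-9:
            raise ModelError(
                f"closed-form response for {d.function_id!r} violates mass balance"
            )
        xi = np.zeros(len(rxn_ids))
        xi[free_idx] = x
        xi[rxn_ids.index(d.target_reaction)] = 1.0
        rows[d.function_id] = xi
    return pd.DataFrame.from_dict(rows, orient="index", columns=rxn_ids)


def _met(mid: str, carbons: int | None = None, compartment: str = "c") -> Metabolite:
    counts = {"C": carbons} if carbons is not None else {}
    return Metabolite(mid, name=mid, compartment=compartment, element_counts=counts)


def _exchange(mid: str, lb: float = -np.inf, ub: float = np.inf) -> Reaction:
    return Reaction(f"EX_{mid}", {mid: -1.0}, lower_bound=lb, upper_bound=ub)


def _sink(mid: str, flux: float) -> Reaction:
    return Reaction(f"DM_{mid}", {mid: -1.0}, lower_bound=flux, upper_bound=flux)


# ---------------------------------------------------------------------------
# the six motifs
# ---------------------------------------------------------------------------


def _linear_chain(n: int = 3, J: float = 1.0) -> Fixture:
    mets = [_met("s_e", 1, "e")] + [_met(f"m{i}", 1) for i in range(1, n + 1)]
    rxns = [_exchange("s_e", ub=0.0), Reaction("T", {"s_e": -1, "m1": 1})]
    for i in range(1, n):
        rxns.append(Reaction(f"R{i}", {f"m{i}": -1, f"m{i + 1}": 1}))
    rxns.append(_sink(f"m{n}", J))
    model = MetabolicModel(mets, rxns, id="linear_chain")
    demands = DemandSet([Demand("bb", J, f"DM_m{n}", DemandCategory.BUILDING_BLOCK)])
    xi = _analytic_xi_square(model, demands)
    return Fixture("linear_chain", model, demands, "EX_s_e", xi, carbon_atoms=1)


def _parallel_paths(J: float = 1.0) -> Fixture:
    mets = [_met("s_e", 1, "e"), _met("a", 1), _met("b", 1)]
    rxns = [
        _exchange("s_e", ub=0.0),
        Reaction("T", {"s_e": -1, "a": 1}),
        Reaction("P1", {"a": -1, "b": 1}),
        Reaction("P2", {"a": -1, "b": 1}),
        _sink("b", J),
    ]
    model = MetabolicModel(mets, rxns, id="parallel_paths")
    demands = DemandSet([Demand("bb", J, "DM_b", DemandCategory.BUILDING_BLOCK)])
    # the L2 stage splits the two identical routes evenly
    xi = pd.DataFrame(
        [[-1.0, 1.0, 0.5, 0.5, 1.0]],
        index=["bb"],
        columns=model.reaction_ids,
    )
    return Fixture("parallel_paths", model, demands, "EX_s_e", xi, carbon_atoms=1)


def _branch(J: float = 1.0) -> Fixture:
    mets = [_met("s_e", 1, "e"), _met("m", 1), _met("p", 1), _met("waste", 1)]
    rxns = [
        _exchange("s_e", ub=0.0),
        Reaction("T", {"s_e": -1, "m": 1}),
        Reaction("EFF", {"m": -1, "p": 1}),
        Reaction("WASTE", {"m": -2, "p": 1, "waste": 1}),
        _exchange("waste", lb=0.0),
        _sink("p", J),
    ]
    model = MetabolicModel(mets, rxns, id="branch")
    demands = DemandSet([Demand("bb", J, "DM_p", DemandCategory.BUILDING_BLOCK)])
    xi = _analytic_xi_square(model, demands, inactive={"WASTE", "EX_waste"})
    return Fixture("branch", model, demands, "EX_s_e", xi, carbon_atoms=1)


def _overflow(
    j_atp: float = 40.0,
    j_ac: float = 1.0,
    j_bm: float = 1.0,
    etc_mode: str | None = None,
) -> Fixture:
    """Aerobic respiration/fermentation motif with a fixed acetate excretion.

    Stoichiometry (lumped, currency metabolites carry no formula):
      GLYC    glc -> 2 pyr + 2 atp + 2 nadh
      TCA     pyr -> 3 co2 + 4 nadh + atp
      NADH16  nadh + 1/2 o2 -> 2 atp   (proton-pumping NDH-I, nuo genes)
      NADH5   nadh + 1/2 o2 -> 1 atp   (non-pumping NDH-II, ndh gene)
      ACK     pyr -> ac + co2 + nadh + atp
      PRECSYN pyr -> prec + nadh

    Full respiration of glucose yields 24 ATP; the acetate route yields
    6 ATP per acetate (2 substrate-level + 2 NADH respired at 2 ATP each).
    """
    mets = [
        _met("glc_e", 6, "e"),
        _met("glc_c", 6),
        _met("pyr", 3),
        _met("atp"),
        _met("nadh"),
        _met("ac", 2),
        _met("prec", 3),
        _met("o2", 0),
        _met("co2", 1),
    ]
    rxns = [
        _exchange("glc_e", ub=0.0),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, gene_rule="ptsG"),
        Reaction("GLYC", {"glc_c": -1, "pyr": 2, "atp": 2, "nadh": 2}, gene_rule="gapA"),
        Reaction("TCA", {"pyr": -1, "co2": 3, "nadh": 4, "atp": 1}, gene_rule="gltA"),
        Reaction(
            "NADH16", {"nadh": -1, "o2": -0.5, "atp": 2}, gene_rule="nuoA and nuoB"
        ),
        Reaction("NADH5", {"nadh": -1, "o2": -0.5, "atp": 1}, gene_rule="ndh"),
        Reaction("ACK", {"pyr": -1, "ac": 1, "co2": 1, "nadh": 1, "atp": 1}, gene_rule="ackA"),
        Reaction("PRECSYN", {"pyr": -1, "prec": 1, "nadh": 1}, gene_rule="precA"),
        _exchange("o2", ub=0.0),
        _exchange("co2", lb=0.0),
        Reaction("EX_ac", {"ac": -1.0}, lower_bound=j_ac, upper_bound=j_ac),
        Reaction("ATPM", {"atp": -1.0}, lower_bound=j_atp, upper_bound=j_atp),
        _sink("prec", j_bm),
    ]
    model = MetabolicModel(mets, rxns, id="overflow")
    if etc_mode is None:
        # both dehydrogenases open: carbon parsimony still forces NDH-II to 0
        inactive = {"NADH5"}
    elif etc_mode == "NDH_I":
        model.set_bounds("NADH5", 0.0, 0.0)
        inactive = {"NADH5"}
    elif etc_mode == "NDH_II":
        model.set_bounds("NADH16", 0.0, 0.0)
        inactive = {"NADH16"}
    else:
        raise ModelError(f"unknown etc_mode {etc_mode!r}")
    demands = DemandSet(
        [
            Demand("ATPM", j_atp, "ATPM", DemandCategory.MAINTENANCE),
            Demand("EX_ac", j_ac, "EX_ac", DemandCategory.EXCRETION),
            Demand("prec", j_bm, "DM_prec", DemandCategory.BUILDING_BLOCK),
        ]
    )
    xi = _analytic_xi_square(model, demands, inactive=inactive)
    return Fixture(
        "overflow",
        model,
        demands,
        "EX_glc_e",
        xi,
        carbon_atoms=6,
        atpm_reaction="ATPM",
        atp_metabolite="atp",
    )


def _cofactor_mix(j_atp: float = 45.0, j_p1: float = 1.0, j_p2: float = 1.0) -> Fixture:
    """NADPH-balancing motif: an oxidative pathway whose mixed components persist.

      ENERGY  g6p -> 6 co2 + 10 atp + 2 nadph   (respiration co-produces NADPH)
      PPP     g6p -> 6 co2 + 12 nadph           (dedicated NADPH supply)
      BIO1    g6p + 4 nadph + 2 atp -> prec1
      BIO2    g6p + 8 nadph + 1 atp -> prec2

    The PPP flux balances NADPH across functions, so its energy component is
    negative while both biosynthetic components are positive; with the chosen
    demands no pairwise merge of the three functions removes the mismatch.
    """
    mets = [
        _met("glc_e", 6, "e"),
        _met("g6p", 6),
        _met("atp"),
        _met("nadph"),
        _met("prec1", 6),
        _met("prec2", 6),
        _met("co2", 1),
    ]
    rxns = [
        _exchange("glc_e", ub=0.0),
        Reaction("UPT", {"glc_e": -1, "g6p": 1}),
        Reaction("ENERGY", {"g6p": -1, "co2": 6, "atp": 10, "nadph": 2}),
        Reaction("PPP", {"g6p": -1, "co2": 6, "nadph": 12}),
        Reaction("BIO1", {"g6p": -1, "nadph": -4, "atp": -2, "prec1": 1}),
        Reaction("BIO2", {"g6p": -1, "nadph": -8, "atp": -1, "prec2": 1}),
        _exchange("co2", lb=0.0),
        Reaction("ATPM", {"atp": -1.0}, lower_bound=j_atp, upper_bound=j_atp),
        _sink("prec1", j_p1),
        _sink("prec2", j_p2),
    ]
    model = MetabolicModel(mets, rxns, id="cofactor_mix")
    demands = DemandSet(
        [
            Demand("ATPM", j_atp, "ATPM", DemandCategory.MAINTENANCE),
            Demand("prec1", j_p1, "DM_prec1", DemandCategory.BUILDING_BLOCK),
            Demand("prec2", j_p2, "DM_prec2", DemandCategory.BUILDING_BLOCK),
        ]
    )
    xi = _analytic_xi_square(model, demands)
    return Fixture(
        "cofactor_mix",
        model,
        demands,
        "EX_glc_e",
        xi,
        carbon_atoms=6,
        atpm_reaction="ATPM",
        atp_metabolite="atp",
    )


def _anaerobic_mix(
    j_atp: float = 5.0,
    j_succ: float = 0.5,
    j_bm: float = 1.0,
    atp_per_prec: float = 4.0,
) -> Fixture:
    """Mixed-acid fermentation with a succinate excretion constraint.

      GLYC  glc -> 2 pyr + 2 atp + 2 nadh
      ACK   pyr -> ac + for + atp           (substrate-level ATP)
      ETOH  pyr + 2 nadh -> eth + for       (redox sink)
      FRD   pyr + co2 + 2 nadh -> succ      (reductive branch)
      PREC  pyr + k atp -> prec + co2 + nadh

    Without oxidative phosphorylation the biosynthetic demand is a net ATP
    consumer (k = 4 exceeds the substrate-level ATP earned en route), which is
    what the coupled decomposition must recover.
    """
    mets = [
        _met("glc_e", 6, "e"),
        _met("pyr", 3),
        _met("atp"),
        _met("nadh"),
        _met("ac", 2),
        _met("eth", 2),
        _met("fort", 1),
        _met("succ", 4),
        _met("prec", 2),
        _met("co2", 1),
    ]
    rxns = [
        _exchange("glc_e", ub=0.0),
        Reaction("GLYC", {"glc_e": -1, "pyr": 2, "atp": 2, "nadh": 2}, gene_rule="gapA"),
        Reaction("ACK", {"pyr": -1, "ac": 1, "fort": 1, "atp": 1}, gene_rule="ackA"),
        Reaction("ETOH", {"pyr": -1, "nadh": -2, "eth": 1, "fort": 1}, gene_rule="adhE"),
        Reaction("FRD", {"pyr": -1, "co2": -1, "nadh": -2, "succ": 1}, gene_rule="frdA"),
        Reaction(
            "PRECSYN",
            {"pyr": -1, "atp": -atp_per_prec, "prec": 1, "co2": 1, "nadh": 1},
            gene_rule="precA",
        ),
        _exchange("ac", lb=0.0),
        _exchange("eth", lb=0.0),
        _exchange("fort", lb=0.0),
        Reaction("EX_succ", {"succ": -1.0}, lower_bound=j_succ, upper_bound=j_succ),
        _exchange("co2", lb=0.0),
        Reaction("ATPM", {"atp": -1.0}, lower_bound=j_atp, upper_bound=j_atp),
        _sink("prec", j_bm),
    ]
    model = MetabolicModel(mets, rxns, id="anaerobic_mix")
    demands = DemandSet(
        [
            Demand("ATPM", j_atp, "ATPM", DemandCategory.MAINTENANCE),
            Demand("EX_succ", j_succ, "EX_succ", DemandCategory.EXCRETION),
            Demand("prec", j_bm, "DM_prec", DemandCategory.BUILDING_BLOCK),
        ]
    )
    xi = _analytic_xi_square(model, demands)
    return Fixture(
        "anaerobic_mix",
        model,
        demands,
        "EX_glc_e",
        xi,
        carbon_atoms=6,
        atpm_reaction="ATPM",
        atp_metabolite="atp",
    )


_BUILDERS = {
    "linear_chain": _linear_chain,
    "parallel_paths": _parallel_paths,
    "branch": _branch,
    "overflow": _overflow,
    "cofactor_mix": _cofactor_mix,
    "anaerobic_mix": _anaerobic_mix,
}


def make_toy_network(kind: str, **params) -> Fixture:
    """Build one of the packaged toy fixtures with its analytic response matrix."""
    try:
        builder = _BUILDERS[kind]
    except KeyError:
        raise ModelError(f"unknown fixture kind {kind!r}; choose from {TOY_KINDS}") from None
    return builder(**params)


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write a fixture as SBML + JSON model, demand table and analytic matrix."""
    from . import network_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out / f"{fixture.kind}.json",
        "sbml": out / f"{fixture.kind}.xml",
        "demands": out / f"{fixture.kind}_demands.tsv",
        "xi": out / f"{fixture.kind}_xi.tsv",
    }
    network_io.write_model(fixture.model, paths["json"], format="json")
    network_io.write_model(fixture.model, paths["sbml"], format="sbml")
    pd.DataFrame(
        [
            {
                "function_id": d.function_id,
                "flux_mmol_gDW_h": d.flux,
                "target_reaction": d.target_reaction,
                "category": d.category.value,
            }
            for d in fixture.demands
        ]
    ).to_csv(paths["demands"], sep="\t", index=False)
    fixture.analytic_xi.to_csv(paths["xi"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# synthetic condition / proteome series
# ---------------------------------------------------------------------------


def overflow_condition_factory(
    bb_coefficient: float = 1.0,
    acetate_intercept: float = -0.5,
    acetate_slope: float = 1.5,
):
    """Factory mapping (condition, J_ATPM) to a constrained overflow model.

    The building-block demand is c*mu and the acetate excretion follows the
    linear law max(0, intercept + slope*mu), mirroring how condition-specific
    demand sets are assembled for real models.
    """

    def factory(condition: GrowthCondition, j_atpm: float):
        mu = condition.mu
        j_ac = max(0.0, acetate_intercept + acetate_slope * mu)
        fx = _overflow(j_atp=max(j_atpm, 0.0), j_ac=j_ac, j_bm=bb_coefficient * mu)
        return fx.model, fx.demands, fx.substrate_id

    return factory


def synthetic_maintenance_conditions(
    sigma0: float,
    sigma: float,
    mu_grid,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    factory=None,
) -> list[GrowthCondition]:
    """Growth conditions whose measured uptakes come from a known maintenance law.

    The modeled uptake at J_ATPM = sigma0 + sigma*mu is computed with the
    stage-1 parsimonious objective and perturbed with multiplicative Gaussian
    noise of relative standard deviation ``noise_sd_frac``.
    """
    from .fba_engine import solve_min_uptake

    factory = factory or overflow_condition_factory()
    rng = np.random.default_rng(seed)
    conditions = []
    for i, mu in enumerate(mu_grid):
        cond = GrowthCondition(
            label=f"c{i}",
            mu=float(mu),
            substrate_id="EX_glc_e",
            limitation=Limitation.C,
            aerobic=True,
        )
        model, demands, sub = factory(cond, sigma0 + sigma * mu)
        uptake, _, _ = solve_min_uptake(model, demands, sub)
        noisy = uptake * (1.0 + noise_sd_frac * rng.standard_normal())
        conditions.append(
            GrowthCondition(
                label=cond.label,
                mu=cond.mu,
                substrate_id=sub,
                measured_uptake=float(noisy),
                limitation=Limitation.C,
                aerobic=True,
            )
        )
    return conditions


def synthetic_allocation_series(
    offset: float,
    slope: float,
    demand_fluxes,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Protein fraction vs demand flux observations from a known linear law."""
    rng = np.random.default_rng(seed)
    J = np.asarray(demand_fluxes, dtype=float)
    frac = offset + slope * J
    frac = frac * (1.0 + noise_sd_frac * rng.standard_normal(J.shape))
    return pd.DataFrame({"demand_flux": J, "protein_fraction": frac})


def synthetic_efficiency_series(
    epsilon: float,
    protein_fractions_pct,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """ATP flux vs proteome-percent observations with J = epsilon * phi."""
    rng = np.random.default_rng(seed)
    phi = np.asarray(protein_fractions_pct, dtype=float)
    J = epsilon * phi * (1.0 + noise_sd_frac * rng.standard_normal(phi.shape))
    return pd.DataFrame({"protein_pct": phi, "atp_flux": J})


def synthetic_sector_series(
    params,
    nu_C_grid,
    nu_R_grid,
    noise_phi: float = 0.0,
    noise_mu: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-sector proteome fractions across a C-limitation and an R-limitation
    series generated from a known allocation model.

    ``nu_C_grid`` scans carbon quality at the reference translational capacity
    (a carbon-limitation series, its last entry being the reference condition);
    ``nu_R_grid`` scans translational capacity at the reference carbon quality.
    """
    from .sector_model import predict_sectors

    rng = np.random.default_rng(seed)
    nu_C_grid = list(nu_C_grid)
    nu_R_grid = list(nu_R_grid)
    nu_C0, nu_R0 = nu_C_grid[-1], nu_R_grid[-1]
    rows = []
    for series, grid in (("C", nu_C_grid), ("R", nu_R_grid)):
        for i, nu in enumerate(grid):
            nu_C, nu_R = (nu, nu_R0) if series == "C" else (nu_C0, nu)
            is_ref = (series == "C" and nu == nu_C0) or (series == "R" and nu == nu_R0)
            if is_ref and series == "R":
                continue  # reference appears once, in the C series
            mu, fractions = predict_sectors(params, nu_C, nu_R)
            row = {
                "label": f"{series}{i}",
                "limitation": "none" if is_ref else series,
                "mu": mu + noise_mu * rng.standard_normal(),
                "nu_C_true": nu_C,
                "nu_R_true": nu_R,
            }
            for k, v in fractions.items():
                row[k] = v + noise_phi * rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)
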