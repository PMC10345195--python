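"""Demand-flux response analysis and functional decomposition of fluxes.

Given a unique parsimonious flux state v and the demand fluxes J_gamma that
parameterise it, the optimal fluxes are locally linear in the demands,

    v = sum_gamma xi^(gamma) J_gamma,

so each reaction flux splits into mass-balanced components v^(gamma) =
xi^(gamma) J_gamma, one per metabolic function (a biomass building block,
maintenance ATP, or a constrained excretion).  The response coefficients
xi^(gamma) are measured by finite differences: each demand is perturbed and
the full two-stage parsimonious problem re-solved, substrate minimisation
included, because the substrate uptake is a dependent variable of the demands.

Components of opposite sign on the same reaction signal metabolites (NADPH,
acetate, ...) whose balancing couples different functions.  The mixed fraction

    F_mix = (sum_gamma |v^(gamma)| - |v|) / sum_gamma |v^(gamma)|

quantifies that cancellation; linear recombination of components ("coupling")
removes removable mismatches and yields interpretable modes such as
respiration and fermentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .fba_engine import FluxState, InfeasibleError, solve_pfba
from .model import DemandSet, MetabolicModel, ModelError

__all__ = [
    "ResponseMatrix",
    "FluxDecomposition",
    "CouplingGroup",
    "CouplingSpec",
    "FunctionalShares",
    "ModuleTree",
    "DecompositionError",
    "compute_response_matrix",
    "decompose_fluxes",
    "couple_components",
    "energy_coupling_spec",
    "auto_coupling_search",
    "mixed_fraction",
    "mixed_fractions",
    "functional_shares",
    "cluster_functional_modules",
]

#: default relative demand perturbation and absolute floor (mmol/gDW/h)
DEFAULT_DELTA = 1e-6
DEMAND_FLOOR = 1e-6
#: default reporting/clustering activity threshold (mmol/gDW/h)
ACTIVITY_THRESHOLD = 1e-4
RECONSTRUCTION_RTOL = 1e-6


class DecompositionError(RuntimeError):
    pass


@dataclass
class ResponseMatrix:
    """xi[gamma, i]: flux response of reaction i per unit of demand gamma."""

    xi: pd.DataFrame  # index: function ids, columns: reaction ids
    demands: DemandSet
    delta: float

    @property
    def function_ids(self) -> list[str]:
        return list(self.xi.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.xi.columns)


@dataclass
class FluxDecomposition:
    v: FluxState
    components: pd.DataFrame  # index: function ids, columns: reaction ids
    demands: DemandSet
    reconstruction_residual: float
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def function_ids(self) -> list[str]:
        return list(self.components.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.components.columns)

    @property
    def flux_vector(self) -> pd.Series:
        return pd.Series(self.v.fluxes).reindex(self.components.columns)


@dataclass
class CouplingGroup:
    new_id: str
    weights: dict[str, float]  # member function id -> combination weight
    category: str | None = None


@dataclass
class CouplingSpec:
    groups: list[CouplingGroup]
    provenance: str = "user"

    @property
    def members(self) -> set[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= set(g.weights)
        return out


@dataclass
class FunctionalShares:
    """Per-reaction functional shares F^(gamma) plus the mixed fraction."""

    table: pd.DataFrame  # index: reaction ids; columns: function ids + "mixed"
    flux: pd.Series
    active: pd.Series
    threshold: float

    @property
    def function_ids(self) -> list[str]:
        return [c for c in self.table.columns if c != "mixed"]


# ---------------------------------------------------------------------------
# response matrix by finite differences
# ---------------------------------------------------------------------------


def compute_response_matrix(
    model: MetabolicModel,
    demands: DemandSet,
    substrate_id: str,
    delta: float = DEFAULT_DELTA,
    j_floor: float = DEMAND_FLOOR,
    base: FluxState | None = None,
) -> tuple[ResponseMatrix, FluxState]:
    """Estimate xi^(gamma) = dv/dJ_gamma by central finite differences.

    Central differences are used whenever the backward point keeps the demand
    non-negative; otherwise a forward difference.  If one side is infeasible,
    the other side is used alone; if both fail, the demand is reported.
    """
    if delta <= 0:
        raise ModelError("delta must be positive")
    if base is None:
        base = solve_pfba(model, demands, substrate_id)
    rxn_ids = base.reaction_ids
    rows = {}
    for d in demands:
        step = delta * max(d.flux, j_floor)

        def solve_at(j: float) -> np.ndarray | None:
            try:
                st = solve_pfba(model, demands.with_flux(d.function_id, j), substrate_id)
            except InfeasibleError:
                return None
            return st.vector

        hi = solve_at(d.flux + step)
        lo = solve_at(d.flux - step) if d.flux - step >= 0 else None
        if hi is not None and lo is not None:
            xi = (hi - lo) / (2 * step)
        elif hi is not None:
            xi = (hi - base.vector) / step
        elif lo is not None:
            xi = (base.vector - lo) / step
        else:
            raise DecompositionError(
                f"demand {d.function_id!r}: perturbed problem infeasible in both directions"
            )
        rows[d.function_id] = xi
    xi_df = pd.DataFrame.from_dict(rows, orient="index", columns=rxn_ids)
    xi_df = xi_df.reindex(demands.function_ids)
    return ResponseMatrix(xi=xi_df, demands=demands, delta=delta), base


def decompose_fluxes(
    xi: ResponseMatrix,
    demands: DemandSet,
    v: FluxState,
    rtol: float = RECONSTRUCTION_RTOL,
) -> FluxDecomposition:
    """Form components v^(gamma) = xi^(gamma) J_gamma and check reconstruction.

    The components must add back to the flux vector; a large residual signals
    an active-set change under perturbation (non-local linearity) and is
    raised rather than silently accepted.
    """
    if list(xi.xi.index) != demands.function_ids:
        raise ModelError("response matrix and demand set are not aligned")
    J = pd.Series({d.function_id: d.flux for d in demands})
    components = xi.xi.mul(J, axis=0)
    vvec = pd.Series(v.fluxes).reindex(components.columns)
    residual = float((components.sum(axis=0) - vvec).abs().max())
    scale = max(1.0, float(vvec.abs().max()))
    if residual > rtol * scale:
        raise DecompositionError(
            f"reconstruction residual {residual:.3e} exceeds {rtol:.1e}*{scale:.3g}; "
            "the optimum is changing active set under perturbation - try a smaller delta"
        )
    categories = {d.function_id: d.category.value for d in demands}
    return FluxDecomposition(
        v=v,
        components=components,
        demands=demands,
        reconstruction_residual=residual,
        categories=categories,
    )


# ---------------------------------------------------------------------------
# coupling
# ---------------------------------------------------------------------------


def couple_components(decomp: FluxDecomposition, spec: CouplingSpec) -> FluxDecomposition:
    """Re-express the decomposition through linear recombination of components.

    Every function mentioned in the spec must have its weights across groups
    sum to exactly 1, which makes the summed components an arithmetic identity
    before and after coupling.  Unmentioned functions pass through unchanged.
    """
    old = decomp.components
    mentioned = spec.members
    unknown = mentioned - set(old.index)
    if unknown:
        raise ModelError(f"coupling spec references unknown functions: {sorted(unknown)}")
    totals: dict[str, float] = {m: 0.0 for m in mentioned}
    for g in spec.groups:
        for m, w in g.weights.items():
            totals[m] += w
    bad = {m: t for m, t in totals.items() if abs(t - 1.0) > 1e-12}
    if bad:
        raise ModelError(
            f"coupling weights must sum to 1 per member function (violations: {bad}); "
            "such weights would break mass balance of the summed components"
        )
    new_rows = {}
    new_categories: dict[str, str] = {}
    for g in spec.groups:
        row = sum(w * old.loc[m] for m, w in g.weights.items())
        new_rows[g.new_id] = row
        if g.category is not None:
            new_categories[g.new_id] = g.category
        else:
            cats = {decomp.categories.get(m, "") for m in g.weights}
            new_categories[g.new_id] = cats.pop() if len(cats) == 1 else "coupled"
    for fid in old.index:
        if fid not in mentioned:
            new_rows[fid] = old.loc[fid]
            new_categories[fid] = decomp.categories.get(fid, "")
    components = pd.DataFrame(new_rows).T
    components = components.reindex(columns=old.columns)
    return FluxDecomposition(
        v=decomp.v,
        components=components,
        demands=decomp.demands,
        reconstruction_residual=float(
            (components.sum(axis=0) - decomp.flux_vector).abs().max()
        ),
        categories=new_categories,
    )


def _transfer_weight(
    partner: np.ndarray,
    energy: np.ndarray,
    exclude: np.ndarray | None = None,
    rtol: float = 1e-9,
) -> float:
    """Coupling weight of the energy component into a partner mode.

    The weight alpha makes the coupled mode m = v^(partner) + alpha v^(E)
    sign-consistent with the energy component over its support, binding at the
    reaction with the most negative ratio v^(partner)/v^(E):

        alpha = -min_r v_r^(partner) / v_r^(E).

    Aerobically this cancels the worst sign mismatch (alpha > 0: the partner
    earns ATP credit); anaerobically the ratios are all positive and the rule
    transfers the partner's ride on the energy route out of the mode
    (alpha < 0: the partner is a net ATP consumer).
    """
    support = np.abs(energy) > rtol * max(np.abs(energy).max(), 1e-300)
    if exclude is not None:
        support &= ~exclude  # demand sinks carry fixed fluxes, not pathway flux
    if not support.any():
        return 0.0
    ratios = partner[support] / energy[support]
    return float(-ratios.min())


def energy_coupling_spec(
    decomp: FluxDecomposition,
    energy_id: str,
    partners: dict[str, str],
    remainder_id: str = "respiration",
) -> CouplingSpec:
    """Canonical coupling of partner functions to the energy component.

    ``partners`` maps existing function ids to the mode names they become
    (e.g. ``{"EX_ac": "fermentation"}``); the energy remainder becomes
    ``remainder_id``.  Weights are derived from the components' stoichiometry
    (see :func:`_transfer_weight`), not fitted.
    """
    if energy_id not in decomp.components.index:
        raise ModelError(f"unknown energy function {energy_id!r}")
    energy = decomp.components.loc[energy_id].to_numpy()
    targets = {d.target_reaction for d in decomp.demands}
    exclude = np.array([rid in targets for rid in decomp.components.columns])
    groups = []
    total = 0.0
    for fid in sorted(partners):
        if fid not in decomp.components.index:
            raise ModelError(f"unknown partner function {fid!r}")
        alpha = _transfer_weight(decomp.components.loc[fid].to_numpy(), energy, exclude)
        cat = "fermentation" if decomp.categories.get(fid) == "excretion" else "biosynthesis"
        groups.append(CouplingGroup(partners[fid], {fid: 1.0, energy_id: alpha}, category=cat))
        total += alpha
    groups.append(CouplingGroup(remainder_id, {energy_id: 1.0 - total}, category="respiration"))
    return CouplingSpec(groups=groups, provenance="auto")


def _flux_weighted_mixed_total(components: pd.DataFrame, v: pd.Series, weighted: bool) -> float:
    fmix = _mixed_from_components(components.to_numpy(), v.to_numpy())
    if weighted:
        return float(np.abs(v.to_numpy()) @ fmix)
    return float(fmix.sum())


def auto_coupling_search(
    decomp: FluxDecomposition,
    candidate_functions: list[str] | None = None,
    flux_weighting: bool = True,
    tol: float = 1e-9,
) -> CouplingSpec:
    """Greedy pairwise merging of functions to reduce the mixed-flux burden.

    At each step the pair of candidates whose merge most reduces
    sum_i |v_i| F_i^mix is merged (ties broken lexicographically), but a merge
    is admissible only if the merged component is sign-consistent with the net
    flux on every reaction: two functions are declared coupled when combining
    them leaves no inconsistent flux direction.  Cofactor-balancing mismatches
    that no pairwise combination can remove are therefore left alone rather
    than blended away (merging always shrinks sum|v^(gamma)| by the triangle
    inequality, so without the admissibility condition the search would
    collapse every function into one).  The search stops when no admissible
    merge improves by more than ``tol``; an empty spec means nothing helps.
    """
    candidates = sorted(candidate_functions or decomp.function_ids)
    if len(candidates) < 2:
        raise ModelError("need at least two candidate functions")
    v = decomp.flux_vector
    vv = v.to_numpy()
    sign_tol = 1e-9 * max(1.0, float(np.abs(vv).max()))
    groups: dict[str, list[str]] = {c: [c] for c in candidates}
    comp = decomp.components.copy()
    score = _flux_weighted_mixed_total(comp, v, flux_weighting)
    while len(groups) > 1:
        best_pair, best_score = None, score - tol
        for a, b in itertools.combinations(sorted(groups), 2):
            merged = (comp.loc[a] + comp.loc[b]).to_numpy()
            if np.any(merged * np.sign(vv) < -sign_tol):
                continue  # merged component would oppose the net flux somewhere
            trial = comp.drop(index=[a, b])
            trial.loc[f"{a}+{b}"] = comp.loc[a] + comp.loc[b]
            s = _flux_weighted_mixed_total(trial, v, flux_weighting)
            if s < best_score - 1e-15:
                best_pair, best_score = (a, b), s
        if best_pair is None:
            break
        a, b = best_pair
        merged = f"{a}+{b}"
        groups[merged] = groups.pop(a) + groups.pop(b)
        comp.loc[merged] = comp.loc[a] + comp.loc[b]
        comp = comp.drop(index=[a, b])
        score = best_score
    out = [
        CouplingGroup(new_id, {m: 1.0 for m in members})
        for new_id, members in groups.items()
        if len(members) > 1
    ]
    return CouplingSpec(groups=out, provenance="auto")


# ---------------------------------------------------------------------------
# mixed fractions and functional shares
# ---------------------------------------------------------------------------


def mixed_fraction(components, v: float | None = None) -> float:
    """Mixed fraction of a single reaction from its flux components.

    ``v`` defaults to the component sum.  Zero when all components share one
    sign; approaches one for large cancelling components.
    """
    comps = np.asarray(components, dtype=float)
    if v is None:
        v = float(comps.sum())
    denom = np.abs(comps).sum()
    if denom == 0:
        return 0.0
    return float((denom - abs(v)) / denom)


def _mixed_from_components(comp: np.ndarray, v: np.ndarray) -> np.ndarray:
    denom = np.abs(comp).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fmix = (denom - np.abs(v)) / denom
    fmix = np.where(denom > 0, fmix, 0.0)
    return np.clip(fmix, 0.0, 1.0)


def mixed_fractions(decomp: FluxDecomposition) -> pd.Series:
    v = decomp.flux_vector
    fmix = _mixed_from_components(decomp.components.to_numpy(), v.to_numpy())
    return pd.Series(fmix, index=decomp.components.columns, name="mixed")


def functional_shares(
    decomp: FluxDecomposition,
    activity_threshold: float = ACTIVITY_THRESHOLD,
) -> FunctionalShares:
    """Split each reaction's flux into per-function shares plus F_mix.

    The remainder 1 - F_mix is distributed across the functions whose
    component sign matches the net flux, proportionally to the component
    magnitudes; opposite-signed components contribute only to the mixed
    fraction.  When no components cancel this reduces to F^(gamma) =
    v^(gamma)/v exactly.
    """
    comp = decomp.components.to_numpy()
    v = decomp.flux_vector.to_numpy()
    fmix = _mixed_from_components(comp, v)
    sign = np.sign(v)
    matched = np.where(comp * sign[None, :] > 0, np.abs(comp), 0.0)
    denom = matched.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = matched / denom[None, :] * (1.0 - fmix)[None, :]
    shares = np.where(denom > 0, shares, 0.0)
    table = pd.DataFrame(
        shares.T, index=decomp.components.columns, columns=decomp.components.index
    )
    table["mixed"] = fmix
    flux = decomp.flux_vector
    return FunctionalShares(
        table=table,
        flux=flux,
        active=flux.abs() >= activity_threshold,
        threshold=activity_threshold,
    )


# ---------------------------------------------------------------------------
# functional modules
# ---------------------------------------------------------------------------


@dataclass
class ModuleTree:
    linkage: np.ndarray
    labels: list[str]
    modules: dict[int, list[str]]
    threshold: float

    def to_newick(self) -> str:
        root = to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(root) + ";"


def cluster_functional_modules(
    shares: FunctionalShares,
    function_subset: list[str] | None = None,
    distance_threshold: float = 0.5,
    flux_filter: float = ACTIVITY_THRESHOLD,
) -> ModuleTree:
    """Agglomerative clustering of share profiles (cityblock, average linkage).

    Only reactions carrying at least ``flux_filter`` of flux are clustered;
    the profile is restricted to ``function_subset`` plus the mixed fraction.
    """
    subset = list(function_subset) if function_subset is not None else shares.function_ids
    if not subset:
        raise ModelError("function subset must be non-empty")
    unknown = set(subset) - set(shares.function_ids)
    if unknown:
        raise ModelError(f"unknown functions in subset: {sorted(unknown)}")
    mask = shares.flux.abs() >= flux_filter
    profiles = shares.table.loc[mask, subset + ["mixed"]]
    if len(profiles) < 2:
        raise ModelError("need at least two reactions above the flux filter")
    Z = linkage(pdist(profiles.to_numpy(), metric="cityblock"), method="average")
    flat = fcluster(Z, t=distance_threshold, criterion="distance")
    modules: dict[int, list[str]] = {}
    for rxn, m in zip(profiles.index, flat):
        modules.setdefault(int(m), []).append(rxn)
    return ModuleTree(
        linkage=Z,
        labels=list(profiles.index),
        modules={k: sorted(vs) for k, vs in sorted(modules.items())},
        threshold=distance_threshold,
    )
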