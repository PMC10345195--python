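"""Two-stage parsimonious FBA, maintenance-energy fitting, ETC variants.

The flux state is computed lexicographically: stage 1 minimises the substrate
uptake magnitude (an LP, solved with HiGHS through scipy), stage 2 pins the
uptake at its optimum and minimises the squared L2 norm of all fluxes (a
strictly convex QP solved by the exact active-set method in :mod:`fdm.qp`),
which makes the optimal flux vector unique.  Uniqueness is what licenses the
demand-flux response analysis downstream: derivatives of a non-unique optimum
are not well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, linprog

from .model import DemandSet, MetabolicModel, ModelError
from .qp import QPError, solve_box_qp

__all__ = [
    "FluxState",
    "MaintenanceFit",
    "InfeasibleError",
    "solve_min_uptake",
    "solve_pfba",
    "fit_maintenance",
    "set_etc_mode",
    "protein_synthesis_atp_demand",
]

#: stage-1 optimum is fixed to within this relative tolerance before stage 2
STAGE1_FIX_RTOL = 1e-9


class InfeasibleError(RuntimeError):
    pass


@dataclass
class FluxState:
    fluxes: dict[str, float]
    stage1_objective: float  # substrate uptake magnitude (mmol/gDW/h)
    stage2_objective: float  # sum of squared fluxes
    solver_status: str
    reaction_ids: list[str] = field(default_factory=list)
    vector: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def _pin_demands(model: MetabolicModel, demands: DemandSet | None) -> MetabolicModel:
    if demands is None:
        return model
    model = model.copy()
    demands.validate_against(model)
    for d in demands:
        model.set_bounds(d.target_reaction, d.flux, d.flux)
    return model


def solve_min_uptake(
    model: MetabolicModel,
    demands: DemandSet | None,
    substrate_id: str,
) -> tuple[float, np.ndarray, MetabolicModel]:
    """Stage 1: LP minimising the substrate uptake magnitude.

    Returns the uptake magnitude, the optimal vertex and the pinned model.
    """
    m = _pin_demands(model, demands)
    S = m.stoichiometric_matrix()
    lb, ub = m.bounds_arrays()
    j_sub = m.reaction_ids.index(substrate_id)
    c = np.zeros(len(m.reactions))
    c[j_sub] = -1.0  # uptake is negative flux; minimise its magnitude -v_sub
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        binding = [d.function_id for d in demands] if demands else []
        raise InfeasibleError(
            f"model infeasible under demand constraints {binding or '(none)'}"
        )
    if res.status == 3:
        raise InfeasibleError("substrate minimisation is unbounded")
    if res.status != 0:
        raise InfeasibleError(f"LP solver failure (status {res.status}: {res.message})")
    return float(-res.x[j_sub]), res.x, m


def solve_pfba(
    model: MetabolicModel,
    demands: DemandSet | None,
    substrate_id: str,
) -> FluxState:
    """Two-stage parsimonious FBA: min uptake, then min L2 norm of all fluxes."""
    uptake, x_lp, m = solve_min_uptake(model, demands, substrate_id)
    S = m.stoichiometric_matrix()
    lb, ub = m.bounds_arrays()
    j_sub = m.reaction_ids.index(substrate_id)
    # pin the uptake exactly at the stage-1 vertex value: the direct active-set
    # solver needs no relaxation band, and the LP vertex satisfies it exactly
    lb = lb.copy()
    ub = ub.copy()
    lb[j_sub] = ub[j_sub] = x_lp[j_sub]
    try:
        qp = solve_box_qp(S, np.zeros(S.shape[0]), lb, ub, x_lp)
    except QPError as exc:
        raise InfeasibleError(f"L2 stage did not converge: {exc}") from exc
    v = qp.x
    norm = max(1.0, np.abs(v).max())
    if np.abs(S @ v).max() > 1e-8 * norm:
        raise InfeasibleError("stage-2 solution violates mass balance")
    return FluxState(
        fluxes=dict(zip(m.reaction_ids, v.tolist())),
        stage1_objective=uptake,
        stage2_objective=float(v @ v),
        solver_status="optimal",
        reaction_ids=list(m.reaction_ids),
        vector=v,
    )


# ---------------------------------------------------------------------------
# ATP maintenance fit
# ---------------------------------------------------------------------------


@dataclass
class MaintenanceFit:
    """J_ATPM = sigma0 + sigma * mu fitted to measured substrate uptakes."""

    sigma0: float
    sigma: float
    sigma0_se: float
    sigma_se: float
    residuals: dict[str, float]

    def flux(self, mu: float) -> float:
        return self.sigma0 + self.sigma * mu


def fit_maintenance(
    model_factory,
    conditions,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 50.0), (0.0, 100.0)),
    grid_points: int = 9,
) -> MaintenanceFit:
    """Least-squares fit of (sigma0, sigma) against measured uptake fluxes.

    ``model_factory(condition, j_atpm)`` must return ``(model, demands,
    substrate_id)`` with the maintenance demand set to ``j_atpm``.  The modeled
    uptake is the stage-1 parsimonious optimum.  A deterministic coarse grid
    seeds a bounded Gauss-Newton refinement (the modeled uptake is piecewise
    linear in the parameters, so the residual surface is piecewise quadratic).
    """
    conds = [c for c in conditions if c.measured_uptake is not None]
    if len(conds) < 2:
        raise ModelError("need at least two conditions with measured uptake")

    def residuals(params: np.ndarray) -> np.ndarray:
        s0, s = params
        out = np.empty(len(conds))
        for i, c in enumerate(conds):
            j_atpm = s0 + s * c.mu
            if j_atpm < 0:
                out[i] = 1e3 * (1 + abs(j_atpm))
                continue
            m, d, sub = model_factory(c, j_atpm)
            try:
                uptake, _, _ = solve_min_uptake(m, d, sub)
            except InfeasibleError:
                out[i] = 1e3
                continue
            out[i] = uptake - abs(c.measured_uptake)
        return out

    (lo0, hi0), (lo1, hi1) = bounds
    scored = []
    for s0 in np.linspace(lo0, hi0, grid_points):
        for s in np.linspace(lo1, hi1, grid_points):
            r = residuals(np.array([s0, s]))
            scored.append((float(r @ r), float(s0), float(s)))
    scored.sort()
    if not scored or scored[0][0] >= 1e6:  # pragma: no cover
        raise InfeasibleError("model infeasible at all candidate maintenance parameters")

    # the squared-residual surface is piecewise quadratic but not convex (the
    # LP value function has kinks), so polish from several grid seeds
    res = None
    for _, s0, s in scored[:4]:
        cand = least_squares(
            residuals,
            np.array([s0, s]),
            bounds=([lo0, lo1], [hi0, hi1]),
            method="trf",
            diff_step=1e-6,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if res is None or cand.cost < res.cost - 1e-18:
            res = cand
    r = res.fun
    n, p = len(conds), 2
    ssr = float(r @ r)
    if n > p:
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * ssr / (n - p)
            ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # flat residual surface
            ses = np.full(2, np.nan)
    else:
        ses = np.full(2, np.nan)
    fit = MaintenanceFit(
        sigma0=float(res.x[0]),
        sigma=float(res.x[1]),
        sigma0_se=float(ses[0]),
        sigma_se=float(ses[1]),
        residuals={c.label: float(ri) for c, ri in zip(conds, r)},
    )
    if any(fit.flux(c.mu) < -1e-9 for c in conds):  # pragma: no cover
        raise ModelError("fitted maintenance flux negative over the data range")
    return fit


# ---------------------------------------------------------------------------
# electron-transport-chain variants
# ---------------------------------------------------------------------------

NDH1_GENE_PREFIX = "nuo"
NDH2_GENE_PREFIX = "ndh"


def _etc_reactions(model: MetabolicModel, prefix: str) -> list[str]:
    return [r.id for r in model.reactions if any(g.startswith(prefix) for g in r.genes)]


def set_etc_mode(
    model: MetabolicModel,
    mode: str,
    ndh1_reactions: list[str] | None = None,
    ndh2_reactions: list[str] | None = None,
) -> MetabolicModel:
    """Force the flux solution through one NADH dehydrogenase.

    ``NDH_I`` closes the NDH-II (non-proton-pumping) reactions; ``NDH_II``
    closes the proton-pumping NDH-I complex, emulating a nuo-deletion strain.
    Reaction sets default to gene-prefix lookup (nuo* / ndh*) and can be given
    explicitly.  Modes are exclusive and reversible: original bounds are
    remembered in the model annotations.
    """
    if mode not in ("NDH_I", "NDH_II"):
        raise ModelError(f"unknown ETC mode {mode!r}")
    model = model.copy()
    r1 = ndh1_reactions if ndh1_reactions is not None else _etc_reactions(model, NDH1_GENE_PREFIX)
    r2 = ndh2_reactions if ndh2_reactions is not None else _etc_reactions(model, NDH2_GENE_PREFIX)
    if not r1 and not r2:
        raise ModelError("model has no reactions mapped to either NADH dehydrogenase")
    saved = model.annotations.setdefault("etc_original_bounds", {})
    for rid in r1 + r2:
        if rid not in saved:
            r = model.reaction(rid)
            saved[rid] = (r.lower_bound, r.upper_bound)
    keep, close = (r1, r2) if mode == "NDH_I" else (r2, r1)
    for rid in keep:
        model.set_bounds(rid, *saved[rid])
    for rid in close:
        model.set_bounds(rid, 0.0, 0.0)
    model.annotations["etc_mode"] = mode
    return model


def protein_synthesis_atp_demand(
    protein_mass_fraction: float,
    mu: float,
    mean_aa_mass: float = 0.109,
) -> float:
    """ATP demand of tRNA charging plus polymerisation, 4 ATP per residue.

    ``protein_mass_fraction`` is g protein per gDW, ``mean_aa_mass`` the mean
    residue mass in g/mmol; the result is in mmol ATP/gDW/h.
    """
    if protein_mass_fraction <= 0 or mean_aa_mass <= 0 or mu < 0:
        raise ModelError("inputs must be positive (mu may be zero)")
    return 4.0 * protein_mass_fraction * mu / mean_aa_mass
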