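"""Coarse-grained five-sector model of proteome allocation and overflow.

The proteome is partitioned into energy, biomass, translation, foraging and
housekeeping sectors whose mass fractions respond to two condition parameters:
the carbon quality nu_C and the translational capacity nu_R (both with units
of growth rate).  The sector laws are

    phi_foraging    = phi_fo0 + mu / nu_C
    phi_translation = phi_tr0 + mu / nu_R
    phi_biomass     = phi_bm0 + b * mu
    phi_housekeeping= phi_hk                         (constant)
    phi_energy      = phi_E0 + kappa_C mu/nu_C + kappa_R mu/nu_R

and the growth rate follows from the proteome budget: the five sectors plus a
constant unmodelled remainder sum to one, which closes the model:

    mu = (1 - phi_rem - sum offsets) /
         ((1+kappa_C)/nu_C + (1+kappa_R)/nu_R + b).

Fitting minimises chi^2 = sum (delta phi)^2 + c * sum (delta mu)^2 with
c = 0.1 h^2 by default, jointly over the global parameters and the
per-condition limitation variable (nu_C along a carbon-limitation series at
fixed reference nu_R, and vice versa), using a deterministic multi-start
bounded least-squares.

The energy sector splits into respiration and fermentation so that their
protein-efficiency-weighted ATP supply meets the maintenance demand at
minimal protein: respiration (lower ATP flux per protein) is used up to
capacity, fermentation supplements beyond it, which reproduces acetate
overflow at fast growth and its disappearance under carbon limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import ModelError

__all__ = [
    "SectorParams",
    "SECTORS",
    "predict_sectors",
    "chi_squared",
    "fit_sector_model",
    "predict_overflow",
]

SECTORS = ("energy", "biomass", "translation", "foraging", "housekeeping")

DEFAULT_C = 0.1  # h^2, scale between fraction and growth-rate residuals


@dataclass
class SectorParams:
    phi_E0: float
    kappa_C: float
    kappa_R: float
    phi_fo0: float
    phi_tr0: float
    phi_bm0: float
    bm_slope: float  # biomass fraction per unit growth rate (h)
    phi_hk: float
    phi_rem: float  # constant unmodelled remainder of the proteome
    eps_res: float | None = None  # mmol ATP/gDW/h per % proteome
    eps_fer: float | None = None
    c: float = DEFAULT_C
    atp_per_byproduct: float | None = None  # mol ATP per mol excreted byproduct
    nu_table: pd.DataFrame | None = field(default=None, repr=False)
    chi2: float | None = None
    se: dict[str, float] = field(default_factory=dict, repr=False)


def predict_sectors(params: SectorParams, nu_C: float, nu_R: float) -> tuple[float, dict]:
    """Growth rate and sector fractions at given carbon/translation capacities."""
    if nu_C <= 0 or nu_R <= 0:
        raise ModelError("nu_C and nu_R must be positive")
    p = params
    offsets = p.phi_E0 + p.phi_fo0 + p.phi_tr0 + p.phi_bm0 + p.phi_hk
    denom = (1 + p.kappa_C) / nu_C + (1 + p.kappa_R) / nu_R + p.bm_slope
    mu = (1 - p.phi_rem - offsets) / denom
    if mu <= 0:
        raise ModelError(f"parameters give non-positive growth rate (mu={mu:.4g})")
    x, y = mu / nu_C, mu / nu_R
    fractions = {
        "energy": p.phi_E0 + p.kappa_C * x + p.kappa_R * y,
        "biomass": p.phi_bm0 + p.bm_slope * mu,
        "translation": p.phi_tr0 + y,
        "foraging": p.phi_fo0 + x,
        "housekeeping": p.phi_hk,
    }
    for name, v in fractions.items():
        if not 0 <= v <= 1:
            raise ModelError(f"predicted {name} fraction {v:.4g} outside [0, 1]")
    return mu, fractions


def chi_squared(params: SectorParams, data: pd.DataFrame, c: float | None = None) -> float:
    """Recompute chi^2 = sum (dphi)^2 + c sum (dmu)^2 from fitted nu values."""
    if params.nu_table is None:
        raise ModelError("params carry no per-condition nu table")
    c = params.c if c is None else c
    total = 0.0
    for _, row in data.iterrows():
        nus = params.nu_table.loc[row["label"]]
        mu, fr = predict_sectors(params, nus["nu_C"], nus["nu_R"])
        total += c * (row["mu"] - mu) ** 2
        total += sum((row[s] - fr[s]) ** 2 for s in SECTORS)
    return float(total)


def _unpack(z: np.ndarray, data: pd.DataFrame):
    p = SectorParams(
        phi_E0=z[0],
        kappa_C=z[1],
        kappa_R=z[2],
        phi_fo0=z[3],
        phi_tr0=z[4],
        phi_bm0=z[5],
        bm_slope=z[6],
        phi_hk=z[7],
        phi_rem=z[8],
    )
    nu_C0, nu_R0 = z[9], z[10]
    free = z[11:]
    nus = {}
    k = 0
    for _, row in data.iterrows():
        lim = row["limitation"]
        if lim == "C":
            nus[row["label"]] = (free[k], nu_R0)
            k += 1
        elif lim == "R":
            nus[row["label"]] = (nu_C0, free[k])
            k += 1
        else:
            nus[row["label"]] = (nu_C0, nu_R0)
    return p, nus


def fit_sector_model(
    data: pd.DataFrame,
    c: float = DEFAULT_C,
    n_starts: int = 16,
) -> SectorParams:
    """Fit the five-sector allocation model to per-condition fractions + mu.

    ``data`` needs columns label, limitation ("C", "R" or "none"), mu and one
    column per sector.  The reference (unlimited) condition uses the global
    (nu_C0, nu_R0); each C-limited condition gets its own nu_C at the reference
    nu_R, and symmetrically for R-limitation.  A deterministic list of
    ``n_starts`` start points seeds bounded least squares; the best chi^2 wins,
    ties by start index.
    """
    required = {"label", "limitation", "mu", *SECTORS}
    if not required <= set(data.columns):
        raise ModelError(f"sector table needs columns {sorted(required)}")
    if data["mu"].nunique() < 2:
        raise ModelError("all growth rates equal; model parameters not identifiable")
    n_free = int((data["limitation"] != "none").sum())

    def residuals(z: np.ndarray) -> np.ndarray:
        p, nus = _unpack(z, data)
        out = []
        for _, row in data.iterrows():
            nu_C, nu_R = nus[row["label"]]
            try:
                mu, fr = predict_sectors(p, nu_C, nu_R)
            except ModelError:
                out.extend([10.0] * (len(SECTORS) + 1))
                continue
            out.extend(row[s] - fr[s] for s in SECTORS)
            out.append(np.sqrt(c) * (row["mu"] - mu))
        return np.asarray(out)

    mu_max = float(data["mu"].max())
    mean_phi = {s: float(data[s].mean()) for s in SECTORS}
    n_par = 11 + n_free
    lo = np.concatenate([np.zeros(9), np.full(2 + n_free, 1e-3)])
    lo[1] = lo[2] = 0.0  # kappas
    lo[6] = 0.0  # biomass slope
    hi = np.concatenate(
        [np.array([1, 5, 5, 1, 1, 1, 10, 1, 1]), np.full(2 + n_free, 100.0)]
    )

    # deterministic multi-start lattice around data-driven magnitudes
    base = np.empty(n_par)
    base[0] = mean_phi["energy"] / 2
    base[1] = base[2] = 0.5
    base[3] = mean_phi["foraging"] / 2
    base[4] = mean_phi["translation"] / 2
    base[5] = mean_phi["biomass"] / 2
    base[6] = mean_phi["biomass"] / (2 * mu_max)
    base[7] = mean_phi["housekeeping"]
    base[8] = max(0.05, 1 - sum(mean_phi.values()))
    base[9:] = 2 * mu_max
    factors = [1.0, 0.5, 2.0, 0.25]
    starts = []
    for i in range(n_starts):
        f_nu = factors[i % 4]
        f_k = factors[(i // 4) % 4]
        s = base.copy()
        s[9:] *= f_nu
        s[1:3] *= f_k
        starts.append(np.clip(s, lo, hi))

    best = None
    for s in starts:
        try:
            res = least_squares(
                residuals, s, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-18:
            best = res
    if best is None:
        raise ModelError("sector-model fit failed from every start point")

    p, nus = _unpack(best.x, data)
    nu_table = pd.DataFrame.from_dict(nus, orient="index", columns=["nu_C", "nu_R"])
    nu_table.index.name = "label"
    # Gauss-Newton standard errors for the global parameters
    names = (
        "phi_E0 kappa_C kappa_R phi_fo0 phi_tr0 phi_bm0 bm_slope phi_hk phi_rem "
        "nu_C0 nu_R0"
    ).split()
    m, n_par = best.jac.shape
    se: dict[str, float] = {}
    if m > n_par:
        s2 = 2.0 * best.cost / (m - n_par)
        try:
            cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
            diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se = {name: float(diag[i]) for i, name in enumerate(names)}
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    p = replace(p, c=c, nu_table=nu_table, se=se)
    p = replace(p, chi2=chi_squared(p, data, c))
    return p


def predict_overflow(
    params: SectorParams,
    conditions,
    maintenance,
    atp_per_byproduct: float | None = None,
) -> pd.DataFrame:
    """Respiration/fermentation split of the energy sector and acetate flux.

    ``conditions`` is an iterable of (nu_C, nu_R); ``maintenance`` anything
    with sigma0/sigma attributes (or a 2-tuple) giving the ATP demand
    J_E = sigma0 + sigma*mu.  With the whole sector expressed (phi_r + phi_f =
    phi_E) and supply matching demand (eps_res phi_r + eps_fer phi_f = J_E),
    the split is unique:

        phi_f = max(0, (J_E - eps_res * phi_E) / (eps_fer - eps_res));

    phi_f = 0 when respiration alone covers the demand within phi_E (carbon
    limitation), and the condition is flagged infeasible when even pure
    fermentation falls short.

    The acetate flux converts the fermentation ATP flux through the ATP yield
    per excreted byproduct of the fermentation flux mode.
    """
    if params.eps_res is None or params.eps_fer is None:
        raise ModelError("params must carry eps_res and eps_fer")
    if params.eps_fer <= params.eps_res:
        raise ModelError("expected eps_fer > eps_res (fermentation leaner in protein)")
    y_atp = atp_per_byproduct or params.atp_per_byproduct
    if isinstance(maintenance, tuple):
        sigma0, sigma = maintenance
    else:
        sigma0, sigma = maintenance.sigma0, maintenance.sigma
    rows = []
    for nu_C, nu_R in conditions:
        mu, fr = predict_sectors(params, nu_C, nu_R)
        phi_E_pct = 100.0 * fr["energy"]
        j_demand = sigma0 + sigma * mu
        supply_res = params.eps_res * phi_E_pct
        supply_fer = params.eps_fer * phi_E_pct
        feasible = True
        if j_demand <= supply_res:
            phi_f = 0.0
        elif j_demand <= supply_fer:
            phi_f = (j_demand - supply_res) / (params.eps_fer - params.eps_res)
        else:
            phi_f = phi_E_pct
            feasible = False
        atp_fer = params.eps_fer * phi_f
        rows.append(
            {
                "nu_C": nu_C,
                "nu_R": nu_R,
                "mu": mu,
                "phi_E_pct": phi_E_pct,
                "phi_Ef_pct": phi_f,
                "phi_Er_pct": phi_E_pct - phi_f,
                "atp_demand": j_demand,
                "fermentation_atp": atp_fer,
                "acetate_flux": atp_fer / y_atp if y_atp else np.nan,
                "feasible": feasible,
            }
        )
    return pd.DataFrame(rows)
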