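"""Projection of reaction functional shares onto proteins and protein sectors.

Protein mass fractions (the direct output of label-free proteomics pipelines)
are combined with the reaction-level functional decomposition through the
gene-protein-reaction rules: a gene's share vector is the flux-weighted
average of the share vectors of its active reactions, so promiscuous enzymes
are attributed in proportion to how much flux each of their reactions
carries.  Genes outside the model, or whose reactions carry no flux, are
categorized by an iterative GO-term procedure and grouped into translation,
foraging and housekeeping sectors alongside the metabolic energy and biomass
sectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fba_engine import FluxState
from .fdm_core import FunctionalShares
from .model import MetabolicModel, ModelError

__all__ = [
    "ProteinAbundanceTable",
    "ProteinShares",
    "LinearFit",
    "EfficiencyFit",
    "map_protein_shares",
    "aggregate_sectors",
    "greedy_go_categorize",
    "fit_linear_allocation",
    "fit_pathway_efficiency",
    "read_annotations",
]

ENERGY_CATEGORIES = {"respiration", "fermentation", "maintenance", "excretion"}
BIOMASS_CATEGORIES = {"building_block", "biosynthesis"}


class ProteinAbundanceTable:
    """Gene -> mass fraction of total protein, per condition."""

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"gene_id", "condition", "mass_fraction"}
        if not required <= set(frame.columns):
            raise ModelError(f"abundance table needs columns {sorted(required)}")
        frac = frame["mass_fraction"]
        if ((frac < 0) | (frac > 1)).any():
            raise ModelError("protein mass fractions must lie in [0, 1]")
        sums = frame.groupby("condition")["mass_fraction"].sum()
        bad = sums[sums > 1 + 1e-6]
        if len(bad):
            raise ModelError(f"mass fractions exceed 1 in conditions {list(bad.index)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "ProteinAbundanceTable":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    def fractions(self, condition: str) -> pd.Series:
        sub = self.frame[self.frame["condition"] == condition]
        return sub.set_index("gene_id")["mass_fraction"]

    def mean_fractions(self, conditions: list[str] | None = None) -> pd.Series:
        sub = self.frame
        if conditions is not None:
            sub = sub[sub["condition"].isin(conditions)]
        return sub.groupby("gene_id")["mass_fraction"].mean()


@dataclass
class ProteinShares:
    """Per-gene functional shares plus assignment status."""

    shares: pd.DataFrame  # index gene_id; columns: functions + "mixed"
    status: pd.Series  # "assigned" | "zero_flux_metabolic" | "unassigned"
    condition: str = ""

    @property
    def function_ids(self) -> list[str]:
        return [c for c in self.shares.columns if c != "mixed"]


def map_protein_shares(
    shares: FunctionalShares,
    fluxes: FluxState,
    model: MetabolicModel,
    abundances: ProteinAbundanceTable,
    condition: str,
) -> ProteinShares:
    """Flux-weighted projection of reaction shares onto detected proteins.

    A gene catalysing several reactions receives the average of their share
    vectors weighted by |flux|; genes with no active reaction are flagged
    ``zero_flux_metabolic`` and genes absent from the model ``unassigned``.
    """
    gene_rxns: dict[str, list[str]] = {}
    for r in model.reactions:
        for g in r.genes:
            gene_rxns.setdefault(g, []).append(r.id)
    detected = abundances.fractions(condition).index
    cols = list(shares.table.columns)
    rows, status = {}, {}
    for gene in detected:
        if gene not in gene_rxns:
            rows[gene] = np.zeros(len(cols))
            status[gene] = "unassigned"
            continue
        active = [
            rid
            for rid in gene_rxns[gene]
            if rid in shares.table.index and abs(fluxes.fluxes.get(rid, 0.0)) >= shares.threshold
        ]
        if not active:
            rows[gene] = np.zeros(len(cols))
            status[gene] = "zero_flux_metabolic"
            continue
        w = np.array([abs(fluxes.fluxes[rid]) for rid in active])
        profile = shares.table.loc[active].to_numpy()
        rows[gene] = w @ profile / w.sum()
        status[gene] = "assigned"
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return ProteinShares(shares=frame, status=pd.Series(status), condition=condition)


def aggregate_sectors(
    pshares: ProteinShares,
    abundances: ProteinAbundanceTable,
    function_categories: dict[str, str],
    go_sectors: dict[str, str] | None = None,
) -> pd.Series:
    """Proteome mass fraction of each coarse-grained sector.

    Metabolic (assigned) genes contribute abundance x share to the energy and
    biomass sectors (respiration/fermentation sub-fractions are reported too);
    their mixed share is reported under ``mixed``.  Non-metabolic and zero-flux
    genes take the sector given by ``go_sectors`` (from the GO categorization),
    defaulting to ``unclassified``.
    """
    frac = abundances.fractions(pshares.condition)
    go_sectors = go_sectors or {}
    out = {
        "energy": 0.0,
        "respiration": 0.0,
        "fermentation": 0.0,
        "biomass": 0.0,
        "mixed": 0.0,
        "translation": 0.0,
        "foraging": 0.0,
        "housekeeping": 0.0,
        "zero_flux_metabolic": 0.0,
        "unclassified": 0.0,
    }
    for gene, a in frac.items():
        st = pshares.status.get(gene, "unassigned")
        if st == "assigned":
            row = pshares.shares.loc[gene]
            for f in pshares.function_ids:
                cat = function_categories.get(f, "")
                if cat in ENERGY_CATEGORIES:
                    out["energy"] += a * row[f]
                    if cat in ("respiration", "fermentation"):
                        out[cat] += a * row[f]
                elif cat in BIOMASS_CATEGORIES:
                    out["biomass"] += a * row[f]
                else:
                    out["mixed"] += a * row[f]
            out["mixed"] += a * row["mixed"]
        elif st == "zero_flux_metabolic":
            out[go_sectors.get(gene, "zero_flux_metabolic")] += a
        else:
            out[go_sectors.get(gene, "unclassified")] += a
    return pd.Series(out)


def greedy_go_categorize(
    mean_fractions: pd.Series,
    annotations: dict[str, list[str]],
    stop_threshold: float = 0.001,
) -> dict[str, str]:
    """Iterative exclusive assignment of genes to their heaviest GO term.

    At each step the GO term whose unassigned genes carry the largest summed
    protein mass is selected and those genes assigned to it exclusively; the
    iteration stops when the best remaining term falls below ``stop_threshold``
    (mass fraction).  Ties break lexicographically on the term id; genes left
    over are labelled ``unclassified``.
    """
    remaining = set(mean_fractions.index)
    result: dict[str, str] = {}
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    while remaining:
        best_term, best_mass = None, -1.0
        for term in sorted(term_genes):  # lexicographic tie-break via strict >
            mass = float(
                sum(mean_fractions.get(g, 0.0) for g in term_genes[term] & remaining)
            )
            if mass > best_mass + 1e-15:
                best_term, best_mass = term, mass
        if best_term is None or best_mass < stop_threshold:
            break
        for g in term_genes[best_term] & remaining:
            result[g] = best_term
        remaining -= term_genes[best_term]
    for g in remaining:
        result[g] = "unclassified"
    return result


@dataclass
class LinearFit:
    slope: float
    offset: float
    slope_se: float
    offset_se: float
    r_squared: float


def fit_linear_allocation(protein_fractions, demand_fluxes) -> LinearFit:
    """Ordinary least squares of protein fraction against demand flux."""
    phi = np.asarray(protein_fractions, dtype=float)
    J = np.asarray(demand_fluxes, dtype=float)
    if len(phi) < 3 or len(J) != len(phi):
        raise ModelError("need at least three matched conditions for a linear fit")
    if np.allclose(J, J[0]):
        raise ModelError("demand fluxes are constant; slope not identifiable")
    res = stats.linregress(J, phi)
    return LinearFit(
        slope=float(res.slope),
        offset=float(res.intercept),
        slope_se=float(res.stderr),
        offset_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class EfficiencyFit:
    """ATP flux per percent of proteome, from an origin-constrained fit."""

    pathway: str
    epsilon: float
    epsilon_se: float


def fit_pathway_efficiency(atp_fluxes, protein_fractions_pct, pathway: str = "") -> EfficiencyFit:
    """Origin-constrained least squares J_ATP = epsilon * phi (phi in % proteome)."""
    J = np.asarray(atp_fluxes, dtype=float)
    phi = np.asarray(protein_fractions_pct, dtype=float)
    if len(J) != len(phi) or len(J) == 0:
        raise ModelError("need matched, non-empty ATP flux and protein series")
    ss = float(phi @ phi)
    if ss <= 0:
        raise ModelError("all protein fractions are zero; efficiency undefined")
    eps = float(phi @ J) / ss
    resid = J - eps * phi
    n = len(J)
    se = float(np.sqrt((resid @ resid) / ((n - 1) * ss))) if n > 1 else float("nan")
    return EfficiencyFit(pathway=pathway, epsilon=eps, epsilon_se=se)


def read_annotations(path) -> dict[str, list[str]]:
    """Two-column TSV gene_id, go_id (one row per association)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "go_id"} <= set(df.columns):
        raise ModelError("annotation table needs columns gene_id, go_id")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["gene_id"]), []).append(str(row["go_id"]))
    return out
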