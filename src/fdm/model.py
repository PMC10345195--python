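"""Core in-memory containers for genome-scale metabolic models and demand sets.

The containers are deliberately lightweight: a model is a list of metabolites
and reactions plus an index, and the stoichiometric matrix is materialised on
demand. File-format concerns (SBML, BiGG JSON) live in :mod:`fdm.network_io`.

Sign conventions follow the BiGG dialect: an exchange reaction is written with
a single metabolite and coefficient -1, so negative flux means uptake and
positive flux means excretion.  Demand (sink) reactions used to drain biomass
building blocks or maintenance ATP are irreversible, with both bounds fixed to
the demand flux J_gamma >= 0.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BiomassComposition",
    "GrowthCondition",
    "Limitation",
    "DemandCategory",
    "Demand",
    "DemandSet",
    "ModelError",
]


class ModelError(ValueError):
    """Raised for structurally invalid models, reactions or demand sets."""


_GENE_TOKEN = re.compile(r"\b(?!and\b|or\b|AND\b|OR\b)[A-Za-z0-9_.\-]+\b")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    element_counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if n < 0:
                raise ModelError(f"negative {el} count in metabolite {self.id!r}")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = np.inf
    gene_rule: str = ""
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def genes(self) -> frozenset[str]:
        """Gene ids appearing in the gene-protein-reaction rule."""
        if not self.gene_rule.strip():
            return frozenset()
        tokens = _GENE_TOKEN.findall(self.gene_rule)
        return frozenset(t for t in tokens if t.lower() not in ("and", "or"))

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def reversed_copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            lower_bound=-self.upper_bound,
            upper_bound=-self.lower_bound,
            gene_rule=self.gene_rule,
            subsystem=self.subsystem,
            name=self.name,
        )


class MetabolicModel:
    """Stoichiometry, bounds and gene rules of a metabolic network."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        genes: Iterable[str] = (),
        annotations: Mapping[str, object] | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.annotations: dict[str, object] = dict(annotations or {})
        self._check_unique()
        explicit = set(genes)
        inferred = set().union(*(r.genes for r in self.reactions)) if self.reactions else set()
        self.genes: list[str] = sorted(explicit | inferred)
        self._validate_stoichiometry()

    # -- construction helpers -------------------------------------------------

    def _check_unique(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")

    def _validate_stoichiometry(self) -> None:
        known = {m.id for m in self.metabolites}
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[
                Metabolite(m.id, m.name, m.compartment, dict(m.element_counts), m.charge)
                for m in self.metabolites
            ],
            reactions=[
                Reaction(
                    r.id,
                    dict(r.stoichiometry),
                    r.lower_bound,
                    r.upper_bound,
                    r.gene_rule,
                    r.subsystem,
                    r.name,
                )
                for r in self.reactions
            ],
            genes=self.genes,
            annotations=dict(self.annotations),
            id=self.id,
        )

    # -- lookup ---------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- numerics -------------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense stoichiometric matrix S (metabolites x reactions)."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[met_index[met], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def add_reaction(self, reaction: Reaction) -> None:
        if self.has_reaction(reaction.id):
            raise ModelError(f"reaction {reaction.id!r} already present")
        missing = set(reaction.stoichiometry) - set(self.metabolite_ids)
        if missing:
            raise ModelError(
                f"reaction {reaction.id!r} references unknown metabolites {sorted(missing)}"
            )
        self.reactions.append(reaction)
        self.genes = sorted(set(self.genes) | reaction.genes)

    def remove_reaction(self, rxn_id: str) -> Reaction:
        r = self.reaction(rxn_id)
        self.reactions.remove(r)
        return r

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        if lower > upper:
            raise ModelError(f"reaction {rxn_id!r}: bounds {lower} > {upper}")
        r = self.reaction(rxn_id)
        r.lower_bound = lower
        r.upper_bound = upper

    # -- diagnostics ----------------------------------------------------------

    def element_imbalances(self, atol: float = 1e-9) -> dict[str, dict[str, float]]:
        """Per-reaction elemental imbalance of non-exchange reactions.

        Metabolites with no formula are tolerated with a warning and skipped.
        """
        out: dict[str, dict[str, float]] = {}
        met = {m.id: m for m in self.metabolites}
        for r in self.reactions:
            if r.is_exchange:
                continue
            if any(not met[mid].element_counts for mid in r.stoichiometry):
                missing = [mid for mid in r.stoichiometry if not met[mid].element_counts]
                warnings.warn(
                    f"reaction {r.id!r}: no formula for {missing}; balance check skipped",
                    stacklevel=2,
                )
                continue
            balance: dict[str, float] = {}
            for mid, coeff in r.stoichiometry.items():
                for el, n in met[mid].element_counts.items():
                    balance[el] = balance.get(el, 0.0) + coeff * n
            bad = {el: v for el, v in balance.items() if abs(v) > atol}
            if bad:
                out[r.id] = bad
        return out


@dataclass
class BiomassComposition:
    """Biomass building-block coefficients, optionally growth-rate dependent.

    ``entries`` maps a metabolite id to a list of ``(mu, coefficient)`` pairs
    (mmol per gDW).  A single pair means the coefficient is constant in mu;
    several pairs are interpolated piecewise-linearly over the tabulated range.
    """

    entries: dict[str, list[tuple[float, float]]]
    condition: str = ""

    def __post_init__(self) -> None:
        for met, pairs in self.entries.items():
            self.entries[met] = sorted(pairs)
            if any(c < 0 for _, c in pairs):
                raise ModelError(f"negative biomass coefficient for {met!r}")

    def coefficient(self, met_id: str, mu: float, extrapolate: bool = False) -> float:
        pairs = self.entries[met_id]
        if len(pairs) == 1:
            return pairs[0][1]
        mus = np.array([p[0] for p in pairs])
        cs = np.array([p[1] for p in pairs])
        if not extrapolate and not (mus.min() - 1e-12 <= mu <= mus.max() + 1e-12):
            raise ModelError(
                f"mu={mu} outside tabulated range [{mus.min()}, {mus.max()}] for "
                f"{met_id!r}; pass extrapolate=True to clamp"
            )
        return float(np.interp(mu, mus, cs))

    @property
    def metabolite_ids(self) -> list[str]:
        return sorted(self.entries)


class Limitation(str, Enum):
    C = "C"
    R = "R"
    NONE = "none"


@dataclass
class GrowthCondition:
    label: str
    mu: float
    substrate_id: str
    measured_uptake: float | None = None
    measured_excretions: dict[str, float] = field(default_factory=dict)
    limitation: Limitation = Limitation.NONE
    aerobic: bool = True

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ModelError(f"condition {self.label!r}: growth rate must be positive")
        vals = list(self.measured_excretions.values())
        if self.measured_uptake is not None:
            vals.append(self.measured_uptake)
        if not np.all(np.isfinite(vals)):
            raise ModelError(f"condition {self.label!r}: non-finite measured flux")


class DemandCategory(str, Enum):
    BUILDING_BLOCK = "building_block"
    MAINTENANCE = "maintenance"
    EXCRETION = "excretion"


@dataclass
class Demand:
    function_id: str
    flux: float
    target_reaction: str
    category: DemandCategory = DemandCategory.BUILDING_BLOCK

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ModelError(f"demand {self.function_id!r}: negative flux {self.flux}")


class DemandSet:
    """The set of demand fluxes J_gamma parameterising a flux state."""

    def __init__(self, demands: Iterable[Demand] = ()) -> None:
        self.demands: list[Demand] = list(demands)
        ids = [d.function_id for d in self.demands]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate demand function ids")

    def __iter__(self):
        return iter(self.demands)

    def __len__(self) -> int:
        return len(self.demands)

    @property
    def function_ids(self) -> list[str]:
        return [d.function_id for d in self.demands]

    def get(self, function_id: str) -> Demand:
        for d in self.demands:
            if d.function_id == function_id:
                return d
        raise KeyError(function_id)

    def add(self, demand: Demand) -> None:
        if demand.function_id in self.function_ids:
            raise ModelError(f"duplicate demand id {demand.function_id!r}")
        self.demands.append(demand)

    def with_flux(self, function_id: str, flux: float) -> "DemandSet":
        """A copy with one demand flux replaced (used for perturbations)."""
        out = []
        for d in self.demands:
            f = flux if d.function_id == function_id else d.flux
            out.append(Demand(d.function_id, f, d.target_reaction, d.category))
        return DemandSet(out)

    def scaled(self, factor: float) -> "DemandSet":
        return DemandSet(
            Demand(d.function_id, d.flux * factor, d.target_reaction, d.category)
            for d in self.demands
        )

    def validate_against(self, model: MetabolicModel) -> None:
        missing = [d.function_id for d in self.demands if not model.has_reaction(d.target_reaction)]
        if missing:
            raise ModelError(f"demand target reactions missing from model: {missing}")
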