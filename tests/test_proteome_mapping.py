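"""Gene-level shares, sector aggregation, GO categorization and allocation fits."""

import numpy as np
import pandas as pd
import pytest

from fdm.fba_engine import FluxState
from fdm.fdm_core import FunctionalShares
from fdm.fixtures import synthetic_allocation_series, synthetic_efficiency_series
from fdm.model import Metabolite, MetabolicModel, ModelError, Reaction
from fdm.proteome_mapping import (
    ProteinAbundanceTable,
    aggregate_sectors,
    fit_linear_allocation,
    fit_pathway_efficiency,
    greedy_go_categorize,
    map_protein_shares,
)


def _toy_projection(flux_r1=1.0, flux_r2=3.0, shares_r1=(1.0, 0.0), shares_r2=(0.0, 1.0)):
    mets = [Metabolite("a"), Metabolite("b"), Metabolite("c")]
    rxns = [
        Reaction("R1", {"a": -1, "b": 1}, gene_rule="gX"),
        Reaction("R2", {"b": -1, "c": 1}, gene_rule="gX and gY"),
    ]
    model = MetabolicModel(mets, rxns)
    table = pd.DataFrame(
        {
            "g1": [shares_r1[0], shares_r2[0]],
            "g2": [shares_r1[1], shares_r2[1]],
            "mixed": [0.0, 0.0],
        },
        index=["R1", "R2"],
    )
    flux = pd.Series({"R1": flux_r1, "R2": flux_r2})
    shares = FunctionalShares(
        table=table, flux=flux, active=flux.abs() >= 1e-4, threshold=1e-4
    )
    state = FluxState(
        fluxes=flux.to_dict(),
        stage1_objective=0.0,
        stage2_objective=0.0,
        solver_status="optimal",
        reaction_ids=list(flux.index),
        vector=flux.to_numpy(),
    )
    abundances = ProteinAbundanceTable(
        pd.DataFrame(
            {
                "gene_id": ["gX", "gY", "gZ"],
                "condition": ["ref"] * 3,
                "mass_fraction": [0.02, 0.01, 0.05],
            }
        )
    )
    return model, shares, state, abundances


class TestMapProteinShares:
    def test_single_reaction_gene_inherits_reaction_shares(self):
        model, shares, state, ab = _toy_projection()
        ps = map_protein_shares(shares, state, model, ab, "ref")
        assert ps.shares.loc["gY", "g2"] == pytest.approx(1.0)
        assert ps.shares.loc["gY", "g1"] == pytest.approx(0.0)

    def test_promiscuous_gene_is_flux_weighted(self):
        model, shares, state, ab = _toy_projection(flux_r1=1.0, flux_r2=3.0)
        ps = map_protein_shares(shares, state, model, ab, "ref")
        assert ps.shares.loc["gX", "g1"] == pytest.approx(0.25)
        assert ps.shares.loc["gX", "g2"] == pytest.approx(0.75)

    def test_identical_profiles_independent_of_weights(self):
        model, shares, state, ab = _toy_projection(
            flux_r1=1.0, flux_r2=7.0, shares_r1=(0.4, 0.6), shares_r2=(0.4, 0.6)
        )
        ps = map_protein_shares(shares, state, model, ab, "ref")
        assert ps.shares.loc["gX", "g1"] == pytest.approx(0.4)
        assert ps.shares.loc["gX", "g2"] == pytest.approx(0.6)

    def test_status_flags(self):
        model, shares, state, ab = _toy_projection(flux_r2=0.0)
        ps = map_protein_shares(shares, state, model, ab, "ref")
        assert ps.status["gZ"] == "unassigned"  # not in the model
        assert ps.status["gY"] == "zero_flux_metabolic"  # only reaction inactive
        assert ps.status["gX"] == "assigned"

    def test_assigned_gene_shares_sum_to_one(self):
        model, shares, state, ab = _toy_projection()
        ps = map_protein_shares(shares, state, model, ab, "ref")
        assigned = ps.status[ps.status == "assigned"].index
        assert np.allclose(ps.shares.loc[assigned].sum(axis=1), 1.0, atol=1e-9)


class TestAggregateSectors:
    def test_split_gene_contributes_to_both_sectors(self):
        model, shares, state, ab = _toy_projection(
            flux_r1=1.0, flux_r2=1.0, shares_r1=(0.5, 0.5), shares_r2=(0.5, 0.5)
        )
        ps = map_protein_shares(shares, state, model, ab, "ref")
        cats = {"g1": "respiration", "g2": "building_block"}
        sectors = aggregate_sectors(ps, ab, cats, {"gZ": "translation"})
        # gX (0.02) and gY (0.01) each split half energy / half biomass
        assert sectors["energy"] == pytest.approx(0.015)
        assert sectors["biomass"] == pytest.approx(0.015)
        assert sectors["translation"] == pytest.approx(0.05)

    def test_mass_conservation(self):
        model, shares, state, ab = _toy_projection()
        ps = map_protein_shares(shares, state, model, ab, "ref")
        cats = {"g1": "respiration", "g2": "building_block"}
        sectors = aggregate_sectors(ps, ab, cats)
        primary = sectors.drop(["respiration", "fermentation"])  # sub-fractions of energy
        assert primary.sum() == pytest.approx(ab.fractions("ref").sum())


class TestGreedyGo:
    fractions = pd.Series({"a": 0.2, "b": 0.1, "c": 0.15, "d": 0.05})

    def test_single_covering_term(self):
        cats = greedy_go_categorize(
            self.fractions, {g: ["GO:all"] for g in self.fractions.index}
        )
        assert set(cats.values()) == {"GO:all"}

    def test_selection_order_and_exclusivity(self):
        annotations = {"a": ["GO:1"], "b": ["GO:1"], "c": ["GO:2"], "d": ["GO:2", "GO:1"]}
        cats = greedy_go_categorize(self.fractions, annotations)
        # GO:1 carries 0.35 (a,b,d) > GO:2 0.20, and claims d exclusively
        assert cats["a"] == cats["b"] == cats["d"] == "GO:1"
        assert cats["c"] == "GO:2"

    def test_stop_threshold_leaves_light_terms_unclassified(self):
        fr = pd.Series({"x": 0.3, "y": 0.0005})
        cats = greedy_go_categorize(fr, {"x": ["GO:big"], "y": ["GO:tiny"]}, 0.001)
        assert cats["x"] == "GO:big"
        assert cats["y"] == "unclassified"

    def test_determinism(self):
        annotations = {"a": ["GO:1"], "b": ["GO:2"], "c": ["GO:3"], "d": ["GO:4"]}
        runs = [greedy_go_categorize(self.fractions, annotations) for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]


class TestLinearAllocationFit:
    def test_exact_recovery(self):
        series = synthetic_allocation_series(0.002, 0.01, np.linspace(0.1, 2.0, 6))
        fit = fit_linear_allocation(series["protein_fraction"], series["demand_flux"])
        assert fit.offset == pytest.approx(0.002, abs=1e-12)
        assert fit.slope == pytest.approx(0.01, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_series(self):
        fit = fit_linear_allocation([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.offset == pytest.approx(0.5)

    def test_noisy_recovery_within_three_se(self):
        series = synthetic_allocation_series(
            0.002, 0.01, np.linspace(0.1, 2.0, 8), noise_sd_frac=0.05, seed=11
        )
        fit = fit_linear_allocation(series["protein_fraction"], series["demand_flux"])
        assert abs(fit.slope - 0.01) <= 3 * fit.slope_se
        assert abs(fit.offset - 0.002) <= 3 * fit.offset_se

    def test_too_few_points(self):
        with pytest.raises(ModelError, match="three"):
            fit_linear_allocation([0.1, 0.2], [1.0, 2.0])


class TestPathwayEfficiencyFit:
    def test_exact_proportionality(self):
        series = synthetic_efficiency_series(5.0, np.linspace(0.5, 4.0, 6))
        fit = fit_pathway_efficiency(series["atp_flux"], series["protein_pct"], "respiration")
        assert fit.epsilon == pytest.approx(5.0, abs=1e-12)

    def test_single_point(self):
        fit = fit_pathway_efficiency([8.0], [2.0])
        assert fit.epsilon == pytest.approx(4.0)
        assert np.isnan(fit.epsilon_se)

    def test_noisy_recovery_within_three_se(self):
        series = synthetic_efficiency_series(
            9.62, np.linspace(0.5, 4.0, 8), noise_sd_frac=0.04, seed=7
        )
        fit = fit_pathway_efficiency(series["atp_flux"], series["protein_pct"])
        assert abs(fit.epsilon - 9.62) <= 3 * fit.epsilon_se

    def test_all_zero_fractions_rejected(self):
        with pytest.raises(ModelError, match="zero"):
            fit_pathway_efficiency([1.0, 2.0], [0.0, 0.0])


def test_abundance_table_validation():
    with pytest.raises(ModelError, match="\\[0, 1\\]"):
        ProteinAbundanceTable(
            pd.DataFrame({"gene_id": ["a"], "condition": ["c"], "mass_fraction": [1.5]})
        )
    with pytest.raises(ModelError, match="exceed 1"):
        ProteinAbundanceTable(
            pd.DataFrame(
                {
                    "gene_id": ["a", "b"],
                    "condition": ["c", "c"],
                    "mass_fraction": [0.7, 0.7],
                }
            )
        )
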