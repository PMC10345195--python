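"""Response matrices, flux components, coupling, shares and modules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdm.fba_engine import solve_pfba
from fdm.fdm_core import (
    CouplingGroup,
    CouplingSpec,
    auto_coupling_search,
    cluster_functional_modules,
    compute_response_matrix,
    couple_components,
    decompose_fluxes,
    energy_coupling_spec,
    functional_shares,
    mixed_fraction,
    mixed_fractions,
)
from fdm.fixtures import TOY_KINDS, make_toy_network
from fdm.model import ModelError


# ---------------------------------------------------------------------------
# response matrix and reconstruction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kind", TOY_KINDS)
def test_finite_differences_match_analytic_oracle(decompositions, kind):
    fx, xi, _ = decompositions[kind]
    err = (xi.xi - fx.analytic_xi.reindex_like(xi.xi)).abs().to_numpy().max()
    assert err < 1e-6


@pytest.mark.parametrize("kind", TOY_KINDS)
def test_reconstruction_identity(decompositions, kind):
    _, _, decomp = decompositions[kind]
    v = decomp.flux_vector
    resid = (decomp.components.sum(axis=0) - v).abs().max()
    assert resid <= 1e-6 * max(1.0, v.abs().max())


@pytest.mark.parametrize("kind", TOY_KINDS)
def test_response_columns_are_unit_sinks(decompositions, kind):
    """Each xi^(gamma) is mass-balanced with a unit flux at its own sink only."""
    fx, xi, _ = decompositions[kind]
    S = fx.model.stoichiometric_matrix()
    for d in fx.demands:
        row = xi.xi.loc[d.function_id].reindex(fx.model.reaction_ids).to_numpy()
        assert np.abs(S @ row).max() < 1e-6
        assert xi.xi.loc[d.function_id, d.target_reaction] == pytest.approx(1.0, abs=1e-6)
        for other in fx.demands:
            if other.function_id != d.function_id:
                assert abs(xi.xi.loc[d.function_id, other.target_reaction]) < 1e-6


def test_scaling_demands_scales_fluxes_not_responses():
    fx = make_toy_network("overflow")
    xi1, base1 = compute_response_matrix(fx.model, fx.demands, fx.substrate_id)
    doubled = fx.demands.scaled(2.0)
    xi2, base2 = compute_response_matrix(fx.model, doubled, fx.substrate_id)
    assert np.allclose(base2.vector, 2 * base1.vector, atol=1e-8)
    assert np.allclose(xi2.xi.to_numpy(), xi1.xi.to_numpy(), atol=1e-6)


def test_delta_robustness(overflow_decomp):
    fx, xi, _ = overflow_decomp
    xi_small, _ = compute_response_matrix(
        fx.model, fx.demands, fx.substrate_id, delta=1e-7
    )
    scale = np.abs(xi.xi.to_numpy()).max()
    assert np.abs(xi.xi.to_numpy() - xi_small.xi.to_numpy()).max() < 1e-4 * scale


def test_cofactor_balancing_signs(decompositions):
    """The NADPH-supplying pathway responds negatively to the energy demand and
    positively to the biosynthetic demands (the Fig.-1d-style motif)."""
    fx, xi, _ = decompositions["cofactor_mix"]
    assert xi.xi.loc["ATPM", "PPP"] < -1e-6
    assert xi.xi.loc["prec1", "PPP"] > 1e-6
    assert xi.xi.loc["prec2", "PPP"] > 1e-6
    assert fx.analytic_xi.loc["ATPM", "PPP"] < 0  # independent closed form agrees


def test_overflow_acetate_component_reverses_tca(decompositions):
    fx, xi, decomp = decompositions["overflow"]
    assert decomp.components.loc["EX_ac", "TCA"] < 0
    assert decomp.components.loc["ATPM", "TCA"] > 0


# ---------------------------------------------------------------------------
# mixed fractions and shares
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "components,expected",
    [
        ([2.0, -1.0], 2.0 / 3.0),
        ([1.0, -1.0, 2.0], 0.5),
        ([1.0, 2.0], 0.0),
        ([-1.0, -2.0], 0.0),
        ([0.0, 0.0], 0.0),
    ],
)
def test_mixed_fraction_worked_values(components, expected):
    assert mixed_fraction(components) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=1, max_size=6
    )
)
def test_mixed_fraction_bounds(components):
    f = mixed_fraction(components)
    assert 0.0 <= f <= 1.0
    if all(c >= 0 for c in components) or all(c <= 0 for c in components):
        assert f == pytest.approx(0.0, abs=1e-12)


def _manual_decomp(matrix: dict[str, list[float]], rxns: list[str]):
    """A FluxDecomposition built directly from a component matrix (v = column sums)."""
    from fdm.fba_engine import FluxState
    from fdm.fdm_core import FluxDecomposition
    from fdm.model import Demand, DemandSet

    comp = pd.DataFrame(matrix, index=rxns).T
    v = comp.sum(axis=0)
    state = FluxState(
        fluxes=v.to_dict(),
        stage1_objective=0.0,
        stage2_objective=float((v**2).sum()),
        solver_status="optimal",
        reaction_ids=rxns,
        vector=v.to_numpy(),
    )
    demands = DemandSet([Demand(f, 1.0, rxns[0]) for f in comp.index])
    return FluxDecomposition(
        v=state, components=comp, demands=demands, reconstruction_residual=0.0,
        categories={f: "building_block" for f in comp.index},
    )


def test_share_remainder_rule_worked_values():
    d = _manual_decomp({"a": [2.0], "b": [-1.0]}, ["R"])
    sh = functional_shares(d, activity_threshold=1e-9)
    assert sh.table.loc["R", "mixed"] == pytest.approx(2 / 3)
    assert sh.table.loc["R", "a"] == pytest.approx(1 / 3)
    assert sh.table.loc["R", "b"] == 0.0

    d2 = _manual_decomp({"a": [1.0], "b": [3.0]}, ["R"])
    sh2 = functional_shares(d2, activity_threshold=1e-9)
    assert sh2.table.loc["R", "a"] == pytest.approx(0.25)
    assert sh2.table.loc["R", "b"] == pytest.approx(0.75)
    assert sh2.table.loc["R", "mixed"] == 0.0


def test_shares_sum_to_one_on_fixture(overflow_decomp):
    _, _, decomp = overflow_decomp
    sh = functional_shares(decomp)
    sums = sh.table[sh.active].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_share_normalization_random_components(seed):
    rng = np.random.default_rng(seed)
    comp = {f"f{k}": rng.normal(size=4).tolist() for k in range(3)}
    d = _manual_decomp(comp, ["R1", "R2", "R3", "R4"])
    sh = functional_shares(d, activity_threshold=1e-9)
    sums = sh.table[sh.active].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# coupling
# ---------------------------------------------------------------------------


def test_identity_coupling_leaves_decomposition_unchanged(overflow_decomp):
    _, _, decomp = overflow_decomp
    spec = CouplingSpec([CouplingGroup(f, {f: 1.0}) for f in decomp.function_ids])
    out = couple_components(decomp, spec)
    assert np.allclose(
        out.components.loc[decomp.function_ids].to_numpy(),
        decomp.components.to_numpy(),
    )


def test_coupling_conserves_component_sum(overflow_decomp):
    _, _, decomp = overflow_decomp
    spec = energy_coupling_spec(
        decomp, "ATPM", {"EX_ac": "fermentation", "prec": "prec"}
    )
    out = couple_components(decomp, spec)
    before = decomp.components.sum(axis=0).to_numpy()
    after = out.components.sum(axis=0).to_numpy()
    assert np.allclose(before, after, rtol=0, atol=1e-12 * max(1, np.abs(before).max()))


def test_invalid_weights_rejected(overflow_decomp):
    _, _, decomp = overflow_decomp
    spec = CouplingSpec([CouplingGroup("x", {"ATPM": 0.6})])  # 0.4 of ATPM vanishes
    with pytest.raises(ModelError, match="sum to 1"):
        couple_components(decomp, spec)


def test_canonical_modes_structure(overflow_decomp):
    """Respiration carries no acetate; fermentation carries all of it and its
    stoichiometric ATP; the energy/acetate sign mismatch on TCA disappears."""
    fx, _, decomp = overflow_decomp
    spec = energy_coupling_spec(decomp, "ATPM", {"EX_ac": "fermentation"})
    out = couple_components(decomp, spec)
    j_ac = fx.demands.get("EX_ac").flux
    assert out.components.loc["respiration", "EX_ac"] == pytest.approx(0.0, abs=1e-9)
    assert out.components.loc["fermentation", "EX_ac"] == pytest.approx(j_ac)
    # the acetate route of this network yields 6 ATP per acetate
    assert out.components.loc["fermentation", "ATPM"] == pytest.approx(6 * j_ac, rel=1e-6)
    assert out.components.loc["fermentation", "TCA"] == pytest.approx(0.0, abs=1e-6)
    # both modes are individually mass-balanced over the internal metabolites
    S = fx.model.stoichiometric_matrix()
    targets = {d.target_reaction for d in fx.demands}
    internal_rows = [
        i
        for i, met in enumerate(fx.model.metabolites)
        if all(  # metabolites not drained by any demand sink
            met.id not in fx.model.reaction(t).stoichiometry for t in targets
        )
    ]
    for mode in ("respiration", "fermentation"):
        vec = out.components.loc[mode].reindex(fx.model.reaction_ids).to_numpy()
        assert np.abs((S @ vec)[internal_rows]).max() < 1e-6


def test_auto_coupling_on_overflow(overflow_decomp):
    from fdm.fdm_core import _flux_weighted_mixed_total

    _, _, decomp = overflow_decomp
    spec = auto_coupling_search(decomp, ["ATPM", "EX_ac"])
    assert len(spec.groups) == 1
    assert set(spec.groups[0].weights) == {"ATPM", "EX_ac"}
    out = couple_components(decomp, spec)
    before = _flux_weighted_mixed_total(decomp.components, decomp.flux_vector, True)
    after = _flux_weighted_mixed_total(out.components, out.flux_vector, True)
    assert after < before


def test_auto_coupling_all_positive_components_returns_empty():
    d = _manual_decomp({"a": [1.0, 2.0], "b": [3.0, 0.5]}, ["R1", "R2"])
    assert auto_coupling_search(d, ["a", "b"]).groups == []


def test_cofactor_mismatch_survives_every_pairwise_merge(decompositions):
    """No pairwise combination removes the NADPH-balancing sign mismatch, and
    the greedy search therefore leaves the functions unmerged."""
    _, _, decomp = decompositions["cofactor_mix"]
    base_mix = mixed_fractions(decomp)["PPP"]
    assert base_mix > 0.1
    for a, b in itertools.combinations(decomp.function_ids, 2):
        merged = decomp.components.loc[a] + decomp.components.loc[b]
        others = [f for f in decomp.function_ids if f not in (a, b)]
        comps = [merged["PPP"]] + [decomp.components.loc[f, "PPP"] for f in others]
        assert mixed_fraction(comps, decomp.flux_vector["PPP"]) > 0.0
    assert auto_coupling_search(decomp).groups == []


def test_anaerobic_coupling_makes_biosynthesis_a_net_consumer(decompositions):
    fx, _, decomp = decompositions["anaerobic_mix"]
    spec = energy_coupling_spec(
        decomp, "ATPM", {"EX_succ": "fermentation_succ", "prec": "prec"},
        remainder_id="fermentation_ac",
    )
    out = couple_components(decomp, spec)
    assert out.components.loc["prec", "ATPM"] < 0
    assert out.components.loc["fermentation_succ", "ATPM"] > 0
    assert out.components.loc["fermentation_ac", "ATPM"] > 0


# ---------------------------------------------------------------------------
# functional modules
# ---------------------------------------------------------------------------


def test_identical_profiles_cluster_together():
    d = _manual_decomp(
        {"a": [1.0, 1.0, 0.0], "b": [0.0, 0.0, 2.0]}, ["R1", "R2", "R3"]
    )
    sh = functional_shares(d, activity_threshold=1e-9)
    tree = cluster_functional_modules(sh, distance_threshold=0.1, flux_filter=1e-9)
    by_module = {frozenset(v) for v in tree.modules.values()}
    assert frozenset({"R1", "R2"}) in by_module
    assert frozenset({"R3"}) in by_module


def test_cityblock_distance_of_orthogonal_profiles():
    from scipy.spatial.distance import pdist

    assert pdist(np.array([[1.0, 0.0], [0.0, 1.0]]), "cityblock")[0] == pytest.approx(2.0)
    d = _manual_decomp({"a": [1.0, 0.0], "b": [0.0, 1.0]}, ["R1", "R2"])
    sh = functional_shares(d, activity_threshold=1e-9)
    tree = cluster_functional_modules(sh, distance_threshold=1.0, flux_filter=1e-9)
    assert tree.linkage[0, 2] == pytest.approx(2.0)


def test_modules_on_overflow_fixture(overflow_decomp):
    """Disjoint biosynthetic and fermentation branches form separate modules;
    the shared respiration backbone joins them only at larger thresholds."""
    _, _, decomp = overflow_decomp
    sh = functional_shares(decomp)
    tree = cluster_functional_modules(sh, distance_threshold=0.5)
    module_of = {r: m for m, rxns in tree.modules.items() for r in rxns}
    assert module_of["PRECSYN"] == module_of["DM_prec"]
    assert module_of["ACK"] == module_of["EX_ac"]
    assert module_of["PRECSYN"] != module_of["ACK"]
    assert module_of["GLYC"] == module_of["ATPM"]
    newick = tree.to_newick()
    assert newick.endswith(";") and newick.count("(") == newick.count(")")
    coarse = cluster_functional_modules(sh, distance_threshold=2.1)
    assert len(coarse.modules) == 1


def test_empty_function_subset_rejected(overflow_decomp):
    _, _, decomp = overflow_decomp
    sh = functional_shares(decomp)
    with pytest.raises(ModelError, match="non-empty"):
        cluster_functional_modules(sh, function_subset=[])
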