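"""Network/region data model: readers, region helpers, LP feasibility."""

import math

import numpy as np
import pytest

from fluxcut import (
    CutSet,
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    fig2_bundle,
    load_network,
    load_regions,
    make_cofeeding_target_pair,
    make_yield_region,
    read_cutsets_tsv,
    region_feasible,
    save_regions,
    target_contains_zero,
    write_cutsets_tsv,
    write_network_tabular,
)
from fluxcut.core_model import ValidationError, parse_linear_row


def test_tabular_load_small_network(tmp_path):
    path = tmp_path / "model.tsv"
    path.write_text(
        "reaction_id\tequation\tlb\tub\tgpr\tcost\tstatus\n"
        "r_up\t -> A\t0\t10\t\t\tnon_targetable\n"
        "r1\tA + 2 B <-> C\t-5\t5\tg1 and g2\t2\tdeletable\n"
        "r_ex\tC ->\t0\tinf\t\t\t\n"
    )
    net = load_network(path)
    assert net.n_reactions == 3
    assert net.n_metabolites == 3  # A, B, C
    j = net.index("r1")
    assert net.stoich[net.metabolite_ids.index("B"), j] == -2
    assert net.lb[j] == -5 and bool(net.reversible[j])
    assert math.isinf(net.ub[net.index("r_ex")])
    assert net.annotations["gpr"] == {"r1": "g1 and g2"}
    assert net.annotations["status"]["r_up"] == "non_targetable"


def test_tabular_rejects_duplicates_and_bad_equations(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "reaction_id\tequation\tlb\tub\n"
        "r1\tA -> B\t0\t1\n"
        "r1\tB -> C\t0\t1\n"
    )
    with pytest.raises(ValidationError, match="duplicate"):
        load_network(path)
    path.write_text("reaction_id\tequation\tlb\tub\nr1\tA + B\t0\t1\n")
    with pytest.raises(ValidationError, match="arrow"):
        load_network(path)


def test_sbml_roundtrip_bounds(tmp_path):
    cobra = pytest.importorskip("cobra")
    model = cobra.Model("toy")
    met_a, met_b = cobra.Metabolite("A", compartment="c"), cobra.Metabolite("B", compartment="c")
    rxn = cobra.Reaction("R1", lower_bound=-1000, upper_bound=1000)
    rxn.add_metabolites({met_a: -1, met_b: 1})
    rxn.gene_reaction_rule = "gX or gY"
    model.add_reactions([rxn])
    path = str(tmp_path / "toy.xml")
    cobra.io.write_sbml_model(model, path)
    net = load_network(path)
    j = net.index("R1")
    assert net.lb[j] == -1000 and net.ub[j] == 1000
    assert bool(net.reversible[j])
    assert "gX" in net.annotations["gpr"]["R1"]


def test_fig2_tabular_roundtrip(tmp_path):
    bundle = fig2_bundle()
    path = tmp_path / "fig2.tsv"
    write_network_tabular(bundle.network, path)
    loaded = load_network(path)
    assert loaded.reaction_ids == bundle.network.reaction_ids
    # metabolite order may differ; compare stoichiometry by name
    for rid in bundle.network.reaction_ids:
        for met in bundle.network.metabolite_ids:
            orig = bundle.network.stoich[
                bundle.network.metabolite_ids.index(met), bundle.network.index(rid)]
            if met in loaded.metabolite_ids:
                new = loaded.stoich[loaded.metabolite_ids.index(met), loaded.index(rid)]
            else:
                new = 0.0
            assert orig == new
    np.testing.assert_array_equal(loaded.lb, bundle.network.lb)
    np.testing.assert_array_equal(loaded.ub, bundle.network.ub)


def test_network_validation_errors():
    with pytest.raises(ValidationError, match="lb > ub"):
        MetabolicNetwork(np.zeros((1, 1)), [1.0], [0.0], ["r"], ["m"])
    with pytest.raises(ValidationError, match="duplicate metabolite"):
        MetabolicNetwork(np.zeros((2, 1)), [0.0], [1.0], ["r"], ["m", "m"])


def test_yield_region_single_substrate(fig2):
    net = fig2.network
    reg = make_yield_region(net, "r_p_ex", "r_s_up", 0.4, "<=",
                            extra_rows=[({"r_s_up": -1.0}, -0.1)])
    row = reg.V[0]
    expected = np.zeros(net.n_reactions)
    expected[net.index("r_p_ex")] = 1.0
    expected[net.index("r_s_up")] = -0.4
    np.testing.assert_allclose(row, expected)
    assert reg.v[0] == 0.0


def test_yield_region_zero_threshold_and_multisubstrate(fig2):
    net = fig2.network
    reg = make_yield_region(net, "r_p_ex", "r_s_up", 0.0, "<=",
                            extra_rows=[({"r_s_up": -1.0}, -0.1)])
    assert reg.V[0, net.index("r_s_up")] == 0.0  # reduces to r_P <= 0
    assert reg.V[0, net.index("r_p_ex")] == 1.0
    # carbon-weighted two-substrate yield: r_P - Y (6 r_s + 2 r_u) <= 0
    reg2 = make_yield_region(
        net, "r_p_ex", [("r_s_up", 6.0), ("r_u_up", 2.0)], 0.3, "<=",
        extra_rows=[({"r_s_up": -1.0}, -0.1)])
    assert reg2.V[0, net.index("r_s_up")] == pytest.approx(-1.8)
    assert reg2.V[0, net.index("r_u_up")] == pytest.approx(-0.6)


def test_target_zero_vector_rejected():
    net = MetabolicNetwork(np.zeros((1, 2)), [0.0, 0.0], [10.0, 10.0],
                           ["r_p", "r_s"], ["m"])
    with pytest.raises(ValidationError, match="zero flux vector"):
        make_yield_region(net, "r_p", "r_s", 0.4, "<=")
    reg = make_yield_region(net, "r_p", "r_s", 0.4, "<=",
                            extra_rows=[({"r_s": -1.0}, -0.1)])
    assert not target_contains_zero(net, reg)


def test_cofeeding_pair_rows(fig2):
    net = fig2.network
    t1, t2 = make_cofeeding_target_pair(
        net, "r_p_ex", "r_s_up", "r_u_up", "r_u_ex", 0.4, 0.1)
    # region 1: yield on S only, min uptake, U uptake pinned to zero
    assert t1.V.shape[0] == 3
    assert t1.V[0, net.index("r_p_ex")] == 1.0
    assert t1.V[0, net.index("r_s_up")] == pytest.approx(-0.4)
    assert t1.V[0, net.index("r_u_up")] == 0.0
    assert t1.V[1, net.index("r_s_up")] == -1.0 and t1.v[1] == pytest.approx(-0.1)
    assert t1.V[2, net.index("r_u_up")] == 1.0 and t1.v[2] == 0.0
    # region 2: combined yield, U export pinned to zero
    assert t2.V[0, net.index("r_u_up")] == pytest.approx(-0.4)
    assert t2.V[2, net.index("r_u_ex")] == 1.0 and t2.v[2] == 0.0
    # both nonempty on the wild type
    for reg in (t1, t2):
        feasible, witness = region_feasible(net, reg, None, fig2.spec)
        assert feasible and witness is not None


def test_cofeeding_degenerate_uptake_warns(fig2):
    net = fig2.network.copy()
    net.ub[net.index("r_u_up")] = 0.0
    with pytest.warns(UserWarning, match="degenerate"):
        make_cofeeding_target_pair(net, "r_p_ex", "r_s_up", "r_u_up", "r_u_ex",
                                   0.4, 0.1)


def test_region_feasible_with_cuts(chain3):
    net, spec, target = chain3
    feasible, witness = region_feasible(net, target, None, spec)
    assert feasible and witness[net.index("out")] >= 1.0 - 1e-9
    # the middle reaction is the only route: deleting it empties the region
    cut = CutSet(frozenset({"mid"}))
    feasible, _ = region_feasible(net, target, cut, spec)
    assert not feasible


def test_region_feasible_orange_mcs(fig2):
    orange = fig2.expected["orange_mcs"]
    infeasible_targets = [
        not region_feasible(fig2.network, t, orange, fig2.spec)[0]
        for t in fig2.targets
    ]
    assert all(infeasible_targets)
    assert region_feasible(fig2.network, fig2.desireds[0], orange, fig2.spec)[0]


def test_region_row_reproduces_inequality(fig2):
    """V,v applied to a witness reproduces the scalar yield inequality."""
    net = fig2.network
    reg = fig2.targets[0]
    feasible, r = region_feasible(net, reg, None, fig2.spec)
    assert feasible
    yield_row = (r[net.index("r_p_ex")] - 0.4 * r[net.index("r_s_up")])
    assert reg.V[0] @ r == pytest.approx(yield_row)
    assert np.all(reg.V @ r <= reg.v + 1e-6)


def test_region_yaml_roundtrip(tmp_path, fig2):
    path = tmp_path / "regions.yaml"
    save_regions(fig2.targets + fig2.desireds, fig2.network, path)
    regions = load_regions(path, fig2.network)
    assert len(regions) == 3
    for orig, back in zip(fig2.targets + fig2.desireds, regions):
        assert back.role == orig.role
        np.testing.assert_allclose(back.V, orig.V, atol=1e-12)
        np.testing.assert_allclose(back.v, orig.v, atol=1e-12)


def test_parse_linear_row(fig2):
    row, rhs = parse_linear_row("1.0 r_p_ex - 0.4 r_s_up <= 0", fig2.network)
    assert row[fig2.network.index("r_p_ex")] == 1.0
    assert row[fig2.network.index("r_s_up")] == pytest.approx(-0.4)
    assert rhs == 0.0
    row, rhs = parse_linear_row("r_bm_ex >= 0.1", fig2.network)
    assert row[fig2.network.index("r_bm_ex")] == -1.0 and rhs == pytest.approx(-0.1)
    with pytest.raises(ValidationError):
        parse_linear_row("r_bm_ex < 0.1", fig2.network)


def test_cutset_tsv_roundtrip(tmp_path):
    sets = [
        CutSet(frozenset({"r1", "r2"}), cost=2.0),
        CutSet(frozenset({"r6"}), frozenset({"u"}), 1.0, level="reaction"),
    ]
    path = tmp_path / "mcs.tsv"
    write_cutsets_tsv(sets, path)
    back = read_cutsets_tsv(path)
    assert {(c.deletions, c.additions, c.cost) for c in back} == \
        {(c.deletions, c.additions, c.cost) for c in sets}


def test_intervention_spec_validation():
    with pytest.raises(ValidationError):
        InterventionSpec({"r": "bogus"})
    with pytest.raises(ValidationError):
        InterventionSpec({}, {"r": -1.0})
    with pytest.raises(ValidationError):
        CutSet(frozenset({"a"}), frozenset({"a"}))
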