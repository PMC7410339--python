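"""FVA, blocked/essential detection and lossless network compression."""

from fractions import Fraction

import numpy as np
import pytest

from fluxcut import (
    CutSet,
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    compress_network,
    find_blocked,
    find_essential,
    fva,
    random_bundle,
    region_feasible,
)
from fluxcut._lp import SolverError


def _net(rows, lb, ub, rids, mids):
    return MetabolicNetwork(np.array(rows, float), np.array(lb, float),
                            np.array(ub, float), rids, mids)


def test_fva_chain_ranges():
    # up: -> A, mid: A -> B, out: B ->   with uptake capped at 10
    net = _net([[1, -1, 0], [0, 1, -1]], [0, 0, 0], [10, np.inf, np.inf],
               ["up", "mid", "out"], ["A", "B"])
    res = fva(net)
    for rid in net.reaction_ids:
        assert res[rid] == pytest.approx((0.0, 10.0), abs=1e-9)


def test_fva_dead_end_blocked():
    # A can leave through "alt"; "dead" feeds the dead-end metabolite X
    net = _net([[1, -1, -1], [0, 1, 0]], [0, 0, 0], [10, np.inf, np.inf],
               ["up", "dead", "alt"], ["A", "X"])
    assert find_blocked(net) == {"dead"}


def test_fva_infeasible_region_raises():
    net = _net([[1, -1]], [0, 0], [10, 10], ["up", "out"], ["A"])
    bad = FluxRegion("desired", np.array([[-1.0, 0.0]]), np.array([-20.0]), "too_much")
    with pytest.raises(SolverError, match="too_much"):
        fva(net, bad)


def test_fig4_desired_fva_minima(fig4):
    res = fva(fig4.network, fig4.desireds[0])
    assert res["r1"][0] > 1e-6
    assert res["r2"][0] > 1e-6
    assert res["r3"][0] == pytest.approx(0.0, abs=1e-9)


def test_find_essential_simple_cases():
    net = _net([[1, -1, -1]], [0, 0, 0], [10, np.inf, np.inf],
               ["up", "to_bm", "waste"], ["A"])
    growth = FluxRegion("desired", np.array([[0.0, -1.0, 0.0]]), np.array([-0.1]))
    assert find_essential(net, [growth]) == {"up", "to_bm"}
    # a fully reversible bypass pair: neither route is essential
    net2 = _net([[1, -1, -1, 0], [0, 1, 1, -1]], [0, -10, -10, 0],
                [10, 10, 10, 10], ["up", "path1", "path2", "ex"], ["A", "B"])
    sink = FluxRegion("desired", np.array([[0.0, 0.0, 0.0, -1.0]]), np.array([-0.1]))
    ess = find_essential(net2, [sink])
    assert "path1" not in ess and "path2" not in ess
    assert {"up", "ex"} <= ess


@pytest.mark.parametrize("seed", [2, 7, 13, 23])
def test_essential_matches_deletion_probe(seed):
    """FVA essentiality equals the single-deletion infeasibility probe."""
    bundle = random_bundle(seed, with_gpr=False)
    essential = find_essential(bundle.network, bundle.desireds)
    for rid in bundle.network.reaction_ids:
        cut = CutSet(frozenset({rid}))
        kills = any(
            not region_feasible(bundle.network, reg, cut, None)[0]
            for reg in bundle.desireds
        )
        assert (rid in essential) == kills, rid


def test_compress_linear_chain():
    net = _net([[1, -1, 0], [0, 1, -1]], [0, 0, 0], [10, 8, np.inf],
               ["up", "mid", "out"], ["A", "B"])
    spec = InterventionSpec({r: "deletable" for r in net.reaction_ids})
    comp, record = compress_network(net, spec)
    assert comp.n_reactions == net.n_reactions - 2
    (cid, members), = record.lumps().items()
    assert {m for m, _ in members} == {"up", "mid", "out"}
    # tightest implied interval
    assert comp.lb[0] == 0.0 and comp.ub[0] == 8.0
    assert record.cost_map[cid] == 1.0
    assert record.targetability_map[cid] == "deletable"


def test_compress_removes_conservation_relation():
    # duplicate metabolite row: one is a conservation relation
    net = _net([[1, -1], [1, -1]], [0, 0], [10, 10], ["a", "b"], ["M1", "M2"])
    spec = InterventionSpec()
    comp, record = compress_network(net, spec)
    assert "M2" in record.removed_metabolites or "M1" in record.removed_metabolites
    # after dropping the duplicate row, M-coupling lumps the pair
    assert comp.n_reactions == 1


def test_compress_scaling_correctness():
    # up: -> 2 A;  use: A -> B;  out: B ->   (scaling 2 between up and use)
    net = _net([[2, -1, 0], [0, 1, -1]], [0, 0, 0], [3, 10, np.inf],
               ["up", "use", "out"], ["A", "B"])
    spec = InterventionSpec({r: "deletable" for r in net.reaction_ids},
                            {"up": 5.0, "use": 2.0, "out": 7.0})
    comp, record = compress_network(net, spec)
    assert comp.n_reactions == 1
    (cid, members), = record.lumps().items()
    coeffs = dict(members)
    # exact rational identity: scaled member columns cancel A and B
    assert coeffs["use"] == 2 * coeffs["up"]
    assert coeffs["out"] == coeffs["use"]
    assert all(isinstance(c, Fraction) for c in coeffs.values())
    # bounds mapped through the scaling: up <= 3 binds (use/2 <= 5, out free)
    assert comp.ub[0] == pytest.approx(3.0)
    # lump cost: cheapest deletable member
    assert record.cost_map[cid] == 2.0


def test_compress_nothing_to_do():
    # branching point: no metabolite has a unique producer/consumer pair
    net = _net([[1, -1, -1]], [0, 0, 0], [10, 10, 10], ["up", "o1", "o2"], ["A"])
    spec = InterventionSpec()
    comp, record = compress_network(net, spec)
    assert comp.n_reactions == 3
    assert not record.lumps()


def test_compress_region_remap_preserves_feasibility():
    bundle = random_bundle(31, with_gpr=False)
    spec = bundle.spec
    comp, record = compress_network(bundle.network, spec)
    for reg in bundle.targets + bundle.desireds:
        orig, _ = region_feasible(bundle.network, reg, None, spec)
        mapped, _ = region_feasible(comp, record.map_region(reg), None,
                                    record.map_spec(spec))
        assert orig == mapped


def test_record_json_roundtrip():
    import json

    net = _net([[1, -1, 0], [0, 1, -1]], [0, 0, 0], [10, 8, np.inf],
               ["up", "mid", "out"], ["A", "B"])
    comp, record = compress_network(net, InterventionSpec())
    data = json.loads(record.to_json())
    assert set(data["mapping"]) == set(comp.reaction_ids)
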