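"""The duality MILP: construction, optimality, enumeration, minimization."""

import numpy as np
import pytest

from fluxcut import (
    CutSet,
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    build_milp,
    enumerate_mcs,
    minimize_within_support,
    oracle_enumerate,
    random_bundle,
    solve_smallest,
    verify_cutset,
)
from fluxcut.core_model import ValidationError
from fluxcut.fixtures import integrated_problem


def _sols(cutsets):
    return {(cs.deletions, cs.additions) for cs in cutsets}


def test_chain_optimum_is_single_deletion(chain3):
    net, spec, target = chain3
    milp = build_milp(net, [target], [], spec)
    best = solve_smallest(milp)
    assert best is not None and best.cost == 1.0
    assert verify_cutset(net, [target], [], spec, best)
    # brute-force deletion probe: every single reaction blocks the chain
    assert _sols(enumerate_mcs(milp, max_cost=3)) == {
        (frozenset({r}), frozenset()) for r in net.reaction_ids
    }


def test_block_structure_variable_count(fig2):
    milp = build_milp(fig2.network, fig2.targets, fig2.desireds, fig2.spec)
    n_t = len(milp.targetable)
    m = fig2.network.n_metabolites
    n = fig2.network.n_reactions
    expected = n_t  # shared indicators
    for blk in milp.dual_blocks:
        expected += m + blk.T.shape[0] + n_t
    expected += len(milp.primal_blocks) * n
    assert milp.n_vars == expected
    assert len(milp.dual_blocks) == 2 and len(milp.primal_blocks) == 1


def test_all_non_targetable_rejected(chain3):
    net, _, target = chain3
    with pytest.raises(ValidationError, match="targetable"):
        build_milp(net, [target], [], InterventionSpec())


def test_unbounded_addable_rejected(chain3):
    net, spec, target = chain3
    spec2 = spec.replace(status={**spec.status, "mid": "addable"})
    net = net.copy()
    net.ub[net.index("mid")] = np.inf
    with pytest.raises(ValidationError, match="finite activation"):
        build_milp(net, [target], [], spec2)


def test_zero_containing_target_rejected(chain3):
    net, spec, _ = chain3
    lazy = FluxRegion("target", np.array([[0.0, 0.0, 1.0]]), np.array([5.0]))
    with pytest.raises(ValidationError, match="zero flux vector"):
        build_milp(net, [lazy], [], spec)


def test_fig2_optimum_cost_one(fig2):
    milp = build_milp(fig2.network, fig2.targets, fig2.desireds, fig2.spec)
    best = solve_smallest(milp)
    assert best is not None
    assert best.cost == pytest.approx(1.0)
    assert best.deletions == frozenset({"r6"}) and best.additions == frozenset({"r_u_up"})


def test_already_blocked_target_gives_empty_cutset():
    # the export is capped at zero: the target is infeasible in the wild type
    net = MetabolicNetwork(np.array([[1.0, -1.0]]),
                           [0.0, 0.0], [10.0, 0.0], ["up", "out"], ["A"])
    spec = InterventionSpec({"up": "deletable"}, {"up": 1.0})
    target = FluxRegion("target", np.array([[0.0, -1.0]]), np.array([-1.0]))
    milp = build_milp(net, [target], [], spec)
    sols = enumerate_mcs(milp, max_cost=2)
    assert len(sols) == 1 and not sols[0].members and sols[0].cost == 0.0


@pytest.mark.parametrize("seed", [1, 4, 8, 15, 16, 23, 42])
def test_enumeration_matches_oracle(seed):
    bundle = random_bundle(seed, with_gpr=False)
    net, targets, desireds, spec = integrated_problem(bundle)
    milp = build_milp(net, targets, desireds, spec)
    sols = enumerate_mcs(milp, max_cost=3)
    assert _sols(sols) == _sols(oracle_enumerate(bundle, max_cost=3))


@pytest.mark.parametrize("seed", [6, 19])
def test_optimal_order_costs_non_decreasing(seed):
    bundle = random_bundle(seed, with_gpr=False)
    net, targets, desireds, spec = integrated_problem(bundle)
    sols = enumerate_mcs(build_milp(net, targets, desireds, spec), max_cost=3)
    costs = [cs.cost for cs in sols]
    assert costs == sorted(costs)


def test_any_feasible_mode_sound_and_minimal():
    bundle = random_bundle(12, with_gpr=False)
    net, targets, desireds, spec = integrated_problem(bundle)
    milp = build_milp(net, targets, desireds, spec)
    sols = enumerate_mcs(milp, max_cost=3, mode="any_feasible")
    reference = _sols(enumerate_mcs(build_milp(net, targets, desireds, spec),
                                    max_cost=10))
    for cs in sols:
        assert verify_cutset(net, targets, desireds, spec, cs)
        # support-minimality: dropping any paid member breaks soundness
        for uid in cs.members:
            if spec.cost_of(uid) <= 0:
                continue
            smaller = CutSet(cs.deletions - {uid}, cs.additions - {uid})
            assert not verify_cutset(net, targets, desireds, spec, smaller)
    # solutions within the cost budget agree with the optimal-order pool
    assert _sols(sols) <= reference


def test_minimize_within_support_drops_redundant(fig2):
    milp = build_milp(fig2.network, fig2.targets, fig2.desireds, fig2.spec)
    blue = fig2.expected["blue_mcs"]
    # already minimal: unchanged
    same = minimize_within_support(milp, blue)
    assert same.deletions == blue.deletions and same.additions == blue.additions
    # padded with a redundant deletion: the pad is removed
    padded = CutSet(blue.deletions | {"r11"}, blue.additions, blue.cost + 1)
    reduced = minimize_within_support(milp, padded)
    assert reduced.deletions == blue.deletions
    assert reduced.additions == blue.additions


def test_minimize_within_support_drops_zero_cost_redundancy(fig2):
    spec = fig2.spec.replace(cost={**fig2.spec.cost, "r11": 0.0})
    milp = build_milp(fig2.network, fig2.targets, fig2.desireds, spec)
    blue = fig2.expected["blue_mcs"]
    padded = CutSet(blue.deletions | {"r11"}, blue.additions, blue.cost)
    reduced = minimize_within_support(milp, padded)
    assert "r11" not in reduced.deletions


def test_multi_desired_regions_all_kept():
    bundle = random_bundle(27, n_desireds=2, with_gpr=False)
    net, targets, desireds, spec = integrated_problem(bundle)
    assert len(desireds) == 2
    milp = build_milp(net, targets, desireds, spec)
    for cs in enumerate_mcs(milp, max_cost=3):
        for reg in desireds:  # a witness must exist in each region separately
            assert verify_cutset(net, targets, [reg], spec, cs)
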