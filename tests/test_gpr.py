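"""GPR parsing, enzyme-pool integration and the seven compression rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcut import (
    FluxRegion,
    GeneCatalog,
    InterventionSpec,
    MetabolicNetwork,
    compress_gpr,
    evaluate_dnf,
    fva,
    integrate_gpr,
    minimal_falsifying_sets,
    parse_gpr,
    region_feasible,
    random_bundle,
)
from fluxcut.core_model import CutSet, ValidationError
from fluxcut.gpr import lump_cost
from fluxcut.netcompress import fva_combined


# ---------------------------------------------------------------------------
# parsing


@pytest.mark.parametrize(
    "text,expected",
    [
        ("(g1 and g2) or g3", {frozenset({"g1", "g2"}), frozenset({"g3"})}),
        ("g1 and (g2 or g3)", {frozenset({"g1", "g2"}), frozenset({"g1", "g3"})}),
        ("g1 & g2 | g3", {frozenset({"g1", "g2"}), frozenset({"g3"})}),
        ("g1 or (g1 and g2)", {frozenset({"g1"})}),  # absorption
        ("g1", {frozenset({"g1"})}),
    ],
)
def test_parse_gpr_dnf(text, expected):
    assert set(parse_gpr(text).dnf) == expected


def test_parse_gpr_empty_is_true():
    rule = parse_gpr("")
    assert rule.is_true
    assert rule.evaluate([])


def test_parse_gpr_errors():
    with pytest.raises(ValidationError):
        parse_gpr("(g1 and g2")
    with pytest.raises(ValidationError):
        parse_gpr("g1 and and g2")


_GENES = ["a", "b", "c", "d", "e", "f"]


def _expr(draw_depth=0):
    leaf = st.sampled_from(_GENES).map(lambda g: ("var", g))
    return st.recursive(
        leaf,
        lambda children: st.tuples(st.sampled_from(["and", "or"]), children, children),
        max_leaves=8,
    )


def _to_text(node):
    if node[0] == "var":
        return node[1]
    op, lhs, rhs = node
    return f"({_to_text(lhs)} {op} {_to_text(rhs)})"


def _eval(node, present):
    if node[0] == "var":
        return node[1] in present
    op, lhs, rhs = node
    if op == "and":
        return _eval(lhs, present) and _eval(rhs, present)
    return _eval(lhs, present) or _eval(rhs, present)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_expr())
def test_parse_gpr_truth_table_equivalent(tree):
    """Distribution to DNF preserves the Boolean function exhaustively."""
    rule = parse_gpr(_to_text(tree))
    for bits in itertools.product([False, True], repeat=len(_GENES)):
        present = {g for g, keep in zip(_GENES, bits) if keep}
        assert rule.evaluate(present) == _eval(tree, present)


# ---------------------------------------------------------------------------
# integration


def _toy_net(reversible=False):
    # rxn: -> A (the GPR-bearing reaction), ex: A ->
    stoich = np.array([[1.0, -1.0]])
    lb = np.array([-5.0 if reversible else 0.0, 0.0])
    return MetabolicNetwork(stoich, lb, np.array([10.0, 10.0]), ["rxn", "ex"], ["A"])


def test_integrate_single_gene_counts_and_knockout():
    net = _toy_net()
    rules = [parse_gpr("g1", "rxn")]
    ext_net, ext = integrate_gpr(net, rules)
    added = set(ext_net.reaction_ids) - set(net.reaction_ids)
    assert added == {"g1", "p__rxn__0"}
    assert set(ext_net.metabolite_ids) - set(net.metabolite_ids) == {"E__g1", "Q__rxn"}
    spec = InterventionSpec({"g1": "deletable"}, {"g1": 1.0})
    region = FluxRegion("desired", -np.eye(net.n_reactions)[net.index("ex")][None, :],
                        np.array([-1.0]))
    mapped = ext.map_region(region)
    assert region_feasible(ext_net, mapped, None, spec)[0]
    assert not region_feasible(ext_net, mapped, CutSet(frozenset({"g1"})), spec)[0]


def test_integrate_isoenzymes_no_flux_inflation():
    net = _toy_net()
    ext_net, _ = integrate_gpr(net, [parse_gpr("g1 or g2", "rxn")])
    hi = fva(ext_net, reactions=["rxn"])["rxn"][1]
    assert hi == pytest.approx(10.0, abs=1e-6)


def test_integrate_splits_reversible_and_preserves_bounds():
    net = _toy_net(reversible=True)
    ext_net, ext = integrate_gpr(net, [parse_gpr("g1", "rxn")])
    fwd, bwd = ext.split_map["rxn"]
    assert ext_net.ub[ext_net.index(fwd)] == 10.0
    assert ext_net.ub[ext_net.index(bwd)] == 5.0
    assert np.all(ext_net.lb >= 0)


@pytest.mark.parametrize("seed", [3, 11, 17])
def test_integration_preserves_fva_ranges(seed):
    """Original reactions keep their flux variability after integration."""
    bundle = random_bundle(seed)
    if not bundle.rules:
        pytest.skip("draw produced no rules")
    before = fva(bundle.network)
    ext_net, ext = integrate_gpr(bundle.network, bundle.rules)
    P = ext.projection()
    after = fva_combined(ext_net, {
        rid: P[i] for i, rid in enumerate(bundle.network.reaction_ids)})
    for rid in bundle.network.reaction_ids:
        lo, hi = before[rid]
        lo2, hi2 = after[rid]
        assert lo2 == pytest.approx(lo, abs=1e-6)
        assert hi2 == pytest.approx(hi, abs=1e-6)


# ---------------------------------------------------------------------------
# compression


def test_compress_gpr_fig4_ruleset(fig4):
    rules2, catalog2 = compress_gpr(fig4.rules, fig4.gene_catalog,
                                    blocked_rxns={"r6"}, essential_rxns={"r1", "r2"})
    genes = {g for r in rules2 for g in r.genes}
    assert len(genes) == 4
    lump = next(g for g in genes if catalog2.is_lump(g))
    assert catalog2.cost[lump] == 2.0
    assert {"g4", "g6", "g8"} < genes
    # protected genes never appear in compressed output
    assert not any(catalog2.status_of(g) == "protected" for g in genes)


def test_compress_gpr_fixed_point_on_flat_rules():
    rules = [parse_gpr("g1", "r1"), parse_gpr("g2", "r2")]
    catalog = GeneCatalog()
    rules2, _ = compress_gpr(rules, catalog)
    assert {r.reaction_id: r.dnf for r in rules2} == {r.reaction_id: r.dnf for r in rules}


def test_compress_gpr_idempotent(fig4):
    rules1, cat1 = compress_gpr(fig4.rules, fig4.gene_catalog, {"r6"}, {"r1", "r2"})
    rules2, cat2 = compress_gpr(rules1, cat1)
    assert {r.reaction_id: r.dnf for r in rules1} == {r.reaction_id: r.dnf for r in rules2}


def _lump_aware_eval(rule, catalog, deleted):
    """Evaluate a compressed rule: lumps true iff their expression survives."""
    present = set()
    for g in rule.genes:
        expr = catalog.lump_map.get(g, frozenset({frozenset({g})}))
        if evaluate_dnf(expr, set_all_genes(expr) - deleted):
            present.add(g)
    return rule.evaluate(present)


def set_all_genes(expr):
    return {g for c in expr for g in c}


@pytest.mark.parametrize("seed", [0, 5, 9, 21])
def test_compression_preserves_gene_deletion_semantics(seed):
    """Deletion sets up to size 3 disable the same reactions before/after."""
    bundle = random_bundle(seed)
    if not bundle.rules:
        pytest.skip("draw produced no rules")
    blocked = set()
    essential = set()
    rules2, cat2 = compress_gpr(bundle.rules, bundle.gene_catalog, blocked, essential)
    compressed = {r.reaction_id: r for r in rules2}
    genes = sorted({g for r in bundle.rules for g in r.genes})
    protected = {g for g in cat2.status if cat2.status[g] == "protected"}
    for size in range(0, 4):
        for deleted in itertools.combinations(genes, size):
            deleted = set(deleted)
            if deleted & protected:
                continue  # protected genes are no longer deletion candidates
            for rule in bundle.rules:
                original = rule.evaluate(set(genes) - deleted)
                if rule.reaction_id not in compressed:
                    # dropped rules are never disabled by allowed deletions
                    assert original, (rule, deleted)
                    continue
                assert _lump_aware_eval(compressed[rule.reaction_id], cat2, deleted) \
                    == original


def test_lump_cost_law():
    expr = frozenset({frozenset({"g5", "g9"}), frozenset({"g7"})})
    catalog = GeneCatalog(cost={"g5": 1.0, "g7": 1.0, "g9": 1.0})
    assert lump_cost(expr, catalog) == 2.0
    # brute force over all subsets
    genes = ["g5", "g7", "g9"]
    best = min(
        (sum(1.0 for g in s) for size in range(1, 4)
         for s in itertools.combinations(genes, size)
         if not evaluate_dnf(expr, set(genes) - set(s))),
    )
    assert best == 2.0
    assert {frozenset(s) for s in minimal_falsifying_sets(expr)} == {
        frozenset({"g5", "g7"}), frozenset({"g9", "g7"})}
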