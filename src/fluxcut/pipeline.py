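"""The full cut-set computation pipeline.

Steps, in order (each optional stage can be switched off losslessly):

0. problem definition (network, target/desired regions, interventions);
1. FVA of the full model (blocked reactions) and of every desired region
   (essential reactions);
2. GPR rule compression using the FVA results;
3. integration of the (compressed) rules into the network;
4. network compression (blocked removal, conservation relations, lumping);
5. MILP enumeration on the compressed network;
6. decompression of lumped reactions;
7. decompression of lumped genes.

Skipping steps 1-3 and 7 (no GPR rules) computes classical reaction-level
cut sets with the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core_model import (
    CutSet,
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    SolverError,
)
from .expand import expand_gene_lumps, expand_reaction_lumps, filter_redundant
from .gpr import GeneCatalog, GPRRule, compress_gpr, integrate_gpr
from .mcs_milp import build_milp, enumerate_mcs, verify_cutset
from .netcompress import compress_network, find_blocked, find_essential

__all__ = ["McsResult", "compute_mcs"]


@dataclass
class McsResult:
    """Outcome of a pipeline run: final cut sets plus per-step bookkeeping."""

    cutsets: list
    compressed_cutsets: list = field(default_factory=list)
    record: object = None
    stats: dict = field(default_factory=dict)
    discarded_over_budget: int = 0


def compute_mcs(
    network: MetabolicNetwork,
    targets: Sequence[FluxRegion],
    desireds: Sequence[FluxRegion],
    spec: InterventionSpec,
    rules: Sequence[GPRRule] = (),
    gene_catalog: GeneCatalog | None = None,
    gpr_compression: bool = True,
    network_compression: bool = True,
    max_cost: float | None = None,
    max_solutions: float | None = None,
    mode: str = "optimal_order",
    filter_supersets: bool = True,
    M: float = 1000.0,
    verify: bool = True,
    log=None,
) -> McsResult:
    """Run the pipeline end to end and return expanded, verified cut sets.

    With ``rules`` the result is at gene level (gene ids plus any directly
    targetable process reactions); otherwise at reaction level.  ``verify``
    re-checks every final cut set against the LP oracle on the
    uncompressed problem -- provably redundant when the compression
    invariants hold, but cheap at desk scale.
    """
    def say(msg):
        if log is not None:
            log(msg)

    stats: dict = {}
    budget = spec.max_cost if max_cost is None else float(max_cost)
    rules = [r for r in rules if not r.is_true]
    catalog = gene_catalog if gene_catalog is not None else GeneCatalog()

    # step 1: FVA
    blocked = find_blocked(network)
    essential = find_essential(network, desireds)
    stats["blocked_reactions"] = sorted(blocked)
    stats["essential_reactions"] = sorted(essential)
    say(f"step 1: {len(blocked)} blocked, {len(essential)} essential reactions")

    # step 2: GPR compression
    stats["n_genes_before"] = len({g for r in rules for g in r.genes})
    stats["n_rules_before"] = len(rules)
    if rules and gpr_compression:
        rules_used, catalog_used = compress_gpr(rules, catalog, blocked, essential)
    else:
        rules_used, catalog_used = list(rules), catalog.copy()
    live_genes = {g for r in rules_used for g in r.genes}
    stats["n_genes_after"] = len(live_genes)
    stats["n_rules_after"] = len(rules_used)
    if rules:
        say(f"step 2: {stats['n_genes_before']} -> {stats['n_genes_after']} genes, "
            f"{stats['n_rules_before']} -> {stats['n_rules_after']} rules")

    # step 3: integration
    if rules:
        ruled = {r.reaction_id for r in rules}
        integrated, ext = integrate_gpr(network, rules_used)
        status, cost = {}, {}
        for rid in network.reaction_ids:
            if rid in ruled:
                continue  # knockable only through its genes
            st = spec.status_of(rid)
            if st != "non_targetable":
                status[rid] = st
                cost[rid] = spec.cost_of(rid)
        for g in sorted(live_genes):
            st = catalog_used.status_of(g)
            if st in ("deletable", "addable"):
                status[g] = st
                cost[g] = catalog_used.cost_of(g)
        int_spec = InterventionSpec(status, cost, spec.max_cost, spec.max_solutions)
        int_targets = [ext.map_region(t) for t in targets]
        int_desireds = [ext.map_region(d) for d in desireds]
    else:
        integrated, ext = network, None
        int_spec, int_targets, int_desireds = spec, list(targets), list(desireds)
    stats["n_species_integrated"] = integrated.n_metabolites
    stats["n_reactions_integrated"] = integrated.n_reactions

    # step 4: network compression
    if network_compression:
        comp, record = compress_network(integrated, int_spec, protected=essential)
        comp_spec = record.map_spec(int_spec)
        comp_spec = comp_spec.replace(max_cost=spec.max_cost, max_solutions=spec.max_solutions)
        comp_targets = [record.map_region(t) for t in int_targets]
        comp_desireds = [record.map_region(d) for d in int_desireds]
    else:
        comp, record = integrated, None
        comp_spec, comp_targets, comp_desireds = int_spec, int_targets, int_desireds
    stats["n_species_compressed"] = comp.n_metabolites
    stats["n_reactions_compressed"] = comp.n_reactions
    stats["n_targetable"] = len(comp_spec.targetable(comp.reaction_ids))
    say(f"step 4: {comp.n_metabolites} species, {comp.n_reactions} reactions, "
        f"{stats['n_targetable']} targetable")

    # step 5: MILP enumeration
    level = "compressed_reaction" if network_compression else "reaction"
    if not comp_spec.targetable(comp.reaction_ids):
        # nothing can be intervened: solvable only if the targets are
        # already infeasible in the wild type
        empty = CutSet(frozenset(), frozenset(), 0.0, level)
        solutions = [empty] if verify_cutset(comp, comp_targets, comp_desireds,
                                             comp_spec, empty) else []
    else:
        milp = build_milp(comp, comp_targets, comp_desireds, comp_spec, M=M)
        solutions = enumerate_mcs(milp, max_cost=budget,
                                  max_solutions=max_solutions, mode=mode)
    compressed_sols = [
        CutSet(cs.deletions, cs.additions, cs.cost, level=level) for cs in solutions
    ]
    stats["n_mcs_compressed"] = len(compressed_sols)
    say(f"step 5: {len(compressed_sols)} compressed solutions")

    # step 6: reaction-level decompression
    discarded = 0
    reaction_sols: list[CutSet] = []
    if record is not None:
        for cs in compressed_sols:
            reaction_sols.extend(expand_reaction_lumps(cs, record, int_spec))
    else:
        reaction_sols = [CutSet(cs.deletions, cs.additions, cs.cost, "reaction")
                         for cs in compressed_sols]
    reaction_sols = filter_redundant(reaction_sols)
    stats["n_mcs_reaction"] = len(reaction_sols)

    # step 7: gene-level decompression
    if rules:
        def gene_cost(u: str) -> float:
            if u in catalog_used.cost:
                return float(catalog_used.cost[u])
            return int_spec.cost_of(u)

        final: list[CutSet] = []
        for cs in reaction_sols:
            res = expand_gene_lumps(cs, catalog_used, budget, cost_of=gene_cost)
            final.extend(res.expansions)
            discarded += res.discarded_over_budget
    else:
        final = reaction_sols
    if filter_supersets:
        final = filter_redundant(final)
    stats["n_mcs_final"] = len(final)
    say(f"steps 6-7: {len(final)} expanded solutions ({discarded} over budget)")

    if verify:
        vnet, vtargets, vdesireds, vspec = _verification_problem(
            network, targets, desireds, spec, rules, catalog)
        for cs in final:
            if not verify_cutset(vnet, vtargets, vdesireds, vspec, cs):
                raise SolverError(f"expanded cut set {cs!r} failed LP verification")

    return McsResult(final, compressed_sols, record, stats, discarded)


def _verification_problem(network, targets, desireds, spec, rules, catalog):
    """The finest-level uncompressed problem, for re-verifying expansions.

    Gene-level cut sets name *original* genes, so verification integrates
    the original (uncompressed) ruleset.
    """
    if not rules:
        return network, list(targets), list(desireds), spec
    net, ext = integrate_gpr(network, rules)
    ruled = {r.reaction_id for r in rules}
    status, cost = {}, {}
    for rid in network.reaction_ids:
        if rid in ruled:
            continue
        st = spec.status_of(rid)
        if st != "non_targetable":
            status[rid] = st
            cost[rid] = spec.cost_of(rid)
    for g in ext.gene_reactions:
        st = catalog.status_of(g)
        if st in ("deletable", "addable"):
            status[g] = st
            cost[g] = catalog.cost_of(g)
    vspec = InterventionSpec(status, cost, spec.max_cost, spec.max_solutions)
    return net, [ext.map_region(t) for t in targets], [ext.map_region(d) for d in desireds], vspec
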