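"""Flux variability analysis and lossless network compression.

FVA solves, per reaction, a flux minimization and maximization over the
steady-state polyhedron (optionally intersected with a region).  It yields
*blocked* reactions (attainable range {0}) and, evaluated on each desired
region, *essential* reactions: if a reaction's range excludes zero with both
endpoints of one sign for some desired region, no intervention set may
disable it.

Compression removes blocked reactions, drops linearly dependent
stoichiometry rows (conservation relations) and iteratively lumps reaction
pairs coupled through a metabolite with exactly one producer and one
consumer, cancelling the metabolite with an exact rational scaling.  The
:class:`CompressionRecord` keeps the invertible mapping, re-attributed
minimum costs and targetability so that cut sets found on the compressed
network expand losslessly to the original one.  All lumping arithmetic is
exact (fractions); floating inputs are rationalized first.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from ._lp import solve_lp
from .core_model import (
    UNBOUNDED,
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    SolverError,
    ValidationError,
    assemble_region_lp,
)

__all__ = [
    "FvaResult",
    "CompressionRecord",
    "fva",
    "find_blocked",
    "find_essential",
    "compress_network",
]

BLOCKED_TOL = 1e-6
RATIONALIZE_TOL = 1e-9


@dataclass
class FvaResult:
    """Attainable flux ranges per reaction; ``math.inf`` marks unboundedness."""

    ranges: dict  # reaction id -> (min, max)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def blocked(self, tol: float = BLOCKED_TOL) -> set:
        return {
            r for r, (lo, hi) in self.ranges.items()
            if abs(lo) <= tol and abs(hi) <= tol
        }

    def essential(self, tol: float = BLOCKED_TOL) -> set:
        return {
            r for r, (lo, hi) in self.ranges.items()
            if (lo > tol and hi > tol) or (lo < -tol and hi < -tol)
        }


def fva(
    network: MetabolicNetwork,
    region: FluxRegion | None = None,
    reactions: Sequence[str] | None = None,
) -> FvaResult:
    """Per-reaction min/max flux over the (region-constrained) flux space."""
    lp = assemble_region_lp(network, region)
    status, _ = solve_lp(lp)
    if status == "infeasible":
        label = getattr(region, "label", None) or "the plain network"
        raise SolverError(f"FVA: system is infeasible for {label}")
    todo = reactions if reactions is not None else network.reaction_ids
    n = network.n_reactions
    ranges = {}
    for rid in todo:
        j = network.index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        lo = _directed_opt(lp, c)          # min r_j
        hi = -_directed_opt(lp, -c)        # max r_j
        ranges[rid] = (lo, hi)
    return FvaResult(ranges)


def _directed_opt(lp, c) -> float:
    """Minimize c.x over the assembled polyhedron; -inf when unbounded."""
    lp.c = c
    status, x = solve_lp(lp)
    if status == "unbounded":
        return -UNBOUNDED
    if status != "optimal":
        raise SolverError(f"FVA subproblem status {status!r}")
    return float(c @ x)


def fva_combined(
    network: MetabolicNetwork,
    combinations: dict,
    region: FluxRegion | None = None,
) -> FvaResult:
    """Min/max of linear flux combinations (label -> coefficient vector).

    Used e.g. to range the *net* flux ``r_fwd - r_bwd`` of a split
    reversible reaction, where per-direction FVA intervals cannot simply be
    subtracted (both directions may cycle through an unbounded enzyme pool).
    """
    lp = assemble_region_lp(network, region)
    ranges = {}
    for key, c in combinations.items():
        c = np.asarray(c, dtype=float)
        ranges[key] = (_directed_opt(lp, c), -_directed_opt(lp, -c))
    return FvaResult(ranges)


def find_blocked(network: MetabolicNetwork, tol: float = BLOCKED_TOL) -> set:
    """Reactions that can carry no flux at steady state under the bounds."""
    return fva(network).blocked(tol)


def find_essential(
    network: MetabolicNetwork,
    desired_regions: Sequence[FluxRegion],
    tol: float = BLOCKED_TOL,
) -> set:
    """Union over desired regions of reactions whose FVA range excludes zero."""
    essential: set = set()
    for region in desired_regions:
        essential |= fva(network, region).essential(tol)
    return essential


# ---------------------------------------------------------------------------
# compression


@dataclass
class CompressionRecord:
    """Invertible map between original and compressed reactions.

    ``mapping[comp_id]`` lists ``(original_id, coefficient)`` pairs such
    that each member's original flux equals ``coefficient *`` the compressed
    reaction's flux; singleton reactions map with coefficient 1.  Removed
    (blocked) reactions carry zero flux in every steady state and simply
    vanish.  ``cost_map``/``targetability_map`` re-attribute intervention
    costs: a deletable lump costs the minimum over its deletable members.
    """

    original_reaction_ids: list
    mapping: dict = field(default_factory=dict)
    removed_blocked: list = field(default_factory=list)
    removed_metabolites: list = field(default_factory=list)
    cost_map: dict = field(default_factory=dict)
    targetability_map: dict = field(default_factory=dict)

    @property
    def compressed_ids(self) -> list:
        return list(self.mapping)

    def lumps(self) -> dict:
        return {cid: mem for cid, mem in self.mapping.items() if len(mem) > 1}

    def map_region(self, region: FluxRegion) -> FluxRegion:
        """Re-express a region over original reactions on compressed columns."""
        orig_index = {r: i for i, r in enumerate(self.original_reaction_ids)}
        V = np.zeros((region.V.shape[0], len(self.mapping)))
        for j, (cid, members) in enumerate(self.mapping.items()):
            for orig, coef in members:
                V[:, j] += float(coef) * region.V[:, orig_index[orig]]
        return FluxRegion(region.role, V, region.v.copy(), region.label)

    def map_spec(self, spec: InterventionSpec) -> InterventionSpec:
        status, cost = {}, {}
        for cid in self.mapping:
            st = self.targetability_map[cid]
            if st != "non_targetable":
                status[cid] = st
                cost[cid] = self.cost_map[cid]
        return InterventionSpec(status, cost, spec.max_cost, spec.max_solutions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mapping": {
                    cid: [[orig, float(c)] for orig, c in mem]
                    for cid, mem in self.mapping.items()
                },
                "removed_blocked": self.removed_blocked,
                "removed_metabolites": self.removed_metabolites,
                "cost_map": self.cost_map,
                "targetability_map": self.targetability_map,
            },
            indent=1,
            sort_keys=True,
        )


def _rationalize(x: float) -> Fraction:
    if x == int(x):
        return Fraction(int(x))
    return Fraction(x).limit_denominator(10**9)


def compress_network(
    network: MetabolicNetwork,
    intervention_spec: InterventionSpec,
    protected: Iterable[str] = (),
    blocked: Iterable[str] | None = None,
    fva_tighten: bool = False,
) -> tuple[MetabolicNetwork, CompressionRecord]:
    """Losslessly compress a network for cut-set computation.

    Removes blocked reactions (computed by FVA unless supplied), removes
    conservation relations, then iterates one-producer/one-consumer lumping
    to a fixed point.  Addable reactions are never lumped so their
    activation gating stays unambiguous.  ``protected`` reactions (e.g.
    essential ones) may participate in lumps; the lump's targetability is
    decided purely by whether any member is targetable.
    """
    if blocked is None:
        blocked = find_blocked(network)
    blocked = set(blocked)
    record = CompressionRecord(original_reaction_ids=list(network.reaction_ids))
    record.removed_blocked = sorted(blocked)

    keep = [j for j, r in enumerate(network.reaction_ids) if r not in blocked]
    rxn_ids = [network.reaction_ids[j] for j in keep]
    cols = [
        {i: _rationalize(network.stoich[i, j]) for i in range(network.n_metabolites)
         if network.stoich[i, j] != 0}
        for j in keep
    ]
    lbs = [float(network.lb[j]) for j in keep]
    ubs = [float(network.ub[j]) for j in keep]
    members: list[list[tuple[str, Fraction]]] = [[(r, Fraction(1))] for r in rxn_ids]
    addable = {r for r in rxn_ids if intervention_spec.status_of(r) == "addable"}

    # conservation relations: keep a maximal independent row set (exact rref)
    live_mets = sorted({i for col in cols for i in col})
    removed_mets = [network.metabolite_ids[i]
                    for i in range(network.n_metabolites) if i not in live_mets]
    indep = _independent_rows(cols, live_mets)
    dropped = [i for i in live_mets if i not in indep]
    removed_mets += [network.metabolite_ids[i] for i in dropped]
    for col in cols:
        for i in dropped:
            col.pop(i, None)

    # iterated lumping of uniquely coupled pairs
    while True:
        pair = _find_lump_pair(cols, rxn_ids, addable)
        if pair is None:
            break
        met, j1, j2 = pair
        a, b = cols[j1][met], cols[j2][met]
        s = -a / b  # r_{j2} = s * r_{j1}, s > 0 by the opposite-sign criterion
        merged = dict(cols[j1])
        for i, c in cols[j2].items():
            merged[i] = merged.get(i, Fraction(0)) + s * c
            if merged[i] == 0:
                del merged[i]
        sf = float(s)
        lb2, ub2 = lbs[j2] / sf, ubs[j2] / sf
        lbs[j1] = max(lbs[j1], lb2)
        ubs[j1] = min(ubs[j1], ub2)
        if lbs[j1] > ubs[j1] + 1e-12:
            raise ValidationError(
                f"lumping {rxn_ids[j1]!r} with {rxn_ids[j2]!r} yields an empty "
                "flux interval; the network is bound-infeasible"
            )
        cols[j1] = merged
        members[j1] = members[j1] + [(orig, s * c) for orig, c in members[j2]]
        removed_mets.append(network.metabolite_ids[met])
        for seq in (cols, rxn_ids, lbs, ubs, members):
            del seq[j2]

    # final naming: multi-member columns become rc1, rc2, ... in column order
    existing = set(network.reaction_ids)
    comp_ids: list[str] = []
    k = 0
    for j, mem in enumerate(members):
        if len(mem) == 1:
            comp_ids.append(mem[0][0])
        else:
            k += 1
            cid = f"rc{k}"
            while cid in existing:
                cid = "_" + cid
            comp_ids.append(cid)

    met_keep = sorted({i for col in cols for i in col})
    met_ids = [network.metabolite_ids[i] for i in met_keep]
    met_pos = {i: p for p, i in enumerate(met_keep)}
    stoich = np.zeros((len(met_keep), len(cols)))
    for j, col in enumerate(cols):
        for i, c in col.items():
            stoich[met_pos[i], j] = float(c)

    extra_A = extra_b = None
    if network.extra_A is not None:
        orig_index = {r: i for i, r in enumerate(network.reaction_ids)}
        extra_A = np.zeros((network.extra_A.shape[0], len(cols)))
        for j, mem in enumerate(members):
            for orig, c in mem:
                extra_A[:, j] += float(c) * network.extra_A[:, orig_index[orig]]
        extra_b = network.extra_b.copy()

    compressed = MetabolicNetwork(stoich, np.asarray(lbs), np.asarray(ubs),
                                  comp_ids, met_ids, extra_A, extra_b)
    if fva_tighten:
        ranges = fva(compressed)
        for j, rid in enumerate(comp_ids):
            lo, hi = ranges[rid]
            compressed.lb[j] = max(compressed.lb[j], lo)
            compressed.ub[j] = min(compressed.ub[j], hi)

    protected = set(protected)
    for cid, mem in zip(comp_ids, members):
        record.mapping[cid] = [(orig, c) for orig, c in mem]
        deletable = [orig for orig, _ in mem
                     if intervention_spec.status_of(orig) == "deletable"]
        if len(mem) == 1:
            orig = mem[0][0]
            record.targetability_map[cid] = intervention_spec.status_of(orig)
            record.cost_map[cid] = intervention_spec.cost_of(orig)
        elif deletable:
            record.targetability_map[cid] = "deletable"
            record.cost_map[cid] = min(intervention_spec.cost_of(o) for o in deletable)
        else:
            record.targetability_map[cid] = "non_targetable"
            record.cost_map[cid] = math.inf
    record.removed_metabolites = removed_mets
    return compressed, record


def _find_lump_pair(cols, rxn_ids, addable):
    """First metabolite with exactly one producer and one consumer."""
    census: dict[int, list[int]] = {}
    for j, col in enumerate(cols):
        for i in col:
            census.setdefault(i, []).append(j)
    for i in sorted(census):
        touching = census[i]
        if len(touching) != 2:
            continue
        j1, j2 = touching
        if rxn_ids[j1] in addable or rxn_ids[j2] in addable:
            continue
        if cols[j1][i] * cols[j2][i] < 0:  # one producer, one consumer
            return i, j1, j2
    return None


def _independent_rows(cols, live_rows):
    """Maximal independent subset of stoichiometry rows, by exact elimination.

    Each metabolite row is a rational vector over reactions; rows reduced to
    zero against the running echelon basis are conservation relations.
    """
    pivots: dict[int, dict[int, Fraction]] = {}  # lead reaction index -> row
    keep: list[int] = []
    for i in live_rows:
        vec = {j: col[i] for j, col in enumerate(cols) if i in col}
        while vec:
            lead = min(vec)
            if lead not in pivots:
                pivots[lead] = vec
                keep.append(i)
                break
            b = pivots[lead]
            factor = vec[lead] / b[lead]
            for j, c in b.items():
                vec[j] = vec.get(j, Fraction(0)) - factor * c
                if vec[j] == 0:
                    del vec[j]
    return set(keep)
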