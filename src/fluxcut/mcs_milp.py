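"""Duality-based MILP for constrained minimal cut sets.

For every *target* region the MILP carries a dual (Farkas) block: the
steady-state system ``{N r = 0, T r <= t, r_i >= 0 (i in Irrev)}`` -- with
finite flux bounds and extra constraints folded into ``(T, t)`` -- is
infeasible iff there exist multipliers ``u`` (free, one per metabolite),
``w >= 0`` (one per target row) and per-reaction duals ``v`` with

    N' u + T' w + v  = 0   (reversible columns)
    N' u + T' w + v >= 0   (irreversible columns)
    t' w <= -c,  c = 1.

A nonzero ``v_i`` stands for the knockout constraint ``r_i = 0`` entering
the primal system; it is therefore gated by the binary intervention marker
``z_i`` (for irreversible reactions only positive ``v_i`` counts, so only
that side is gated).  Addable reactions are gated inversely: their ``v_i``
may be nonzero only while the reaction is *not* added (``z_i = 0``).
Non-targetable reactions get no ``v`` at all.  Every *desired* region joins
in its primal form: one flux vector per region satisfying the network
constraints and ``D r <= d``, with deletions forcing ``r_i = 0`` at
``z_i = 1`` and additions releasing ``lb_i z_i <= r_i <= ub_i z_i``.

The objective minimizes the weighted intervention cost ``sum p_i z_i``;
enumeration adds integer cuts excluding found supports.  Because the
``v``/``z`` linking uses big-M boxes, every incumbent is re-verified with
the plain LP oracle before it is reported; a verification failure aborts
with advice to raise ``M`` rather than returning an artifact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from ._lp import SolverError, solve_milp
from .core_model import (
    CutSet,
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    ValidationError,
    cutset_cost,
    region_feasible,
    target_contains_zero,
)

__all__ = [
    "MilpProblem",
    "build_milp",
    "solve_smallest",
    "enumerate_mcs",
    "minimize_within_support",
    "verify_cutset",
]

DEFAULT_M = 1000.0
DEFAULT_FLUX_M = 1000.0


# ---------------------------------------------------------------------------
# block descriptions (index bookkeeping)


@dataclass
class DualBlock:
    """One Farkas block per target region: slices of u, w, v variables."""

    region: FluxRegion
    T: np.ndarray
    t: np.ndarray
    u_slice: slice = field(default_factory=lambda: slice(0, 0))
    w_slice: slice = field(default_factory=lambda: slice(0, 0))
    v_slice: slice = field(default_factory=lambda: slice(0, 0))  # one v per targetable unit


@dataclass
class PrimalBlock:
    """One primal block per desired region: slice of its flux variables."""

    region: FluxRegion
    r_slice: slice = field(default_factory=lambda: slice(0, 0))


@dataclass
class IndicatorSet:
    """Shared binary intervention markers z over the targetable units."""

    unit_ids: list
    z_slice: slice = field(default_factory=lambda: slice(0, 0))


@dataclass
class MilpProblem:
    """Assembled MILP with lazily appendable integer-cut rows."""

    network: MetabolicNetwork
    targets: list
    desireds: list
    spec: InterventionSpec
    indicator: IndicatorSet
    dual_blocks: list
    primal_blocks: list
    M: float
    flux_M: float
    n_vars: int = 0
    integer_cuts: list = field(default_factory=list)  # list of member-id frozensets
    time_limit: float | None = None

    @property
    def targetable(self) -> list:
        return self.indicator.unit_ids

    def z_index(self, uid: str) -> int:
        return self.indicator.z_slice.start + self.targetable.index(uid)


# ---------------------------------------------------------------------------
# construction


def _fold_target_system(
    network: MetabolicNetwork, region: FluxRegion, spec: InterventionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Target inequalities with bounds and extra constraints absorbed.

    Pure irreversibility constraints (``lb = 0``) stay out -- they enter as
    sign conditions on the dual columns.  Bound rows of targetable units
    that would be violated at zero flux (``lb > 0`` or ``ub < 0``) are not
    folded: a knockout voids the bound together with the reaction, and
    folding them would let the dual "block" the target by deleting a
    flux-forced reaction.  Dropping them is sound (it enlarges the system
    the certificate must refute).
    """
    rows = [region.V]
    rhs = [region.v]
    if network.extra_A is not None:
        rows.append(network.extra_A)
        rhs.append(network.extra_b)
    n = network.n_reactions
    for i, rid in enumerate(network.reaction_ids):
        targetable = spec.status_of(rid) != "non_targetable"
        ub, lb = network.ub[i], network.lb[i]
        if math.isfinite(ub) and (ub >= 0 or not targetable):
            e = np.zeros(n)
            e[i] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([ub]))
        if math.isfinite(lb) and lb != 0 and (lb < 0 or not targetable):
            e = np.zeros(n)
            e[i] = -1.0
            rows.append(e[None, :])
            rhs.append(np.array([-lb]))
    return np.vstack(rows), np.concatenate(rhs)


def build_milp(
    network: MetabolicNetwork,
    targets: Sequence[FluxRegion],
    desireds: Sequence[FluxRegion],
    spec: InterventionSpec,
    M: float = DEFAULT_M,
    flux_M: float = DEFAULT_FLUX_M,
    max_cuts: float | None = None,
    time_limit: float | None = None,
) -> MilpProblem:
    """Assemble the multi-region intervention MILP.

    One dual block per target region, one primal block per desired region,
    one shared indicator set.  ``M`` boxes the dual multipliers; ``flux_M``
    substitutes for unbounded flux limits in knockout gating rows of the
    primal blocks.  ``max_cuts`` optionally bounds the *number* of
    interventions; the cost budget comes from ``spec.max_cost``.
    """
    if not targets:
        raise ValidationError("at least one target region is required")
    for reg in targets:
        reg.check_dimension(network)
        if reg.role != "target":
            raise ValidationError(f"region {reg.label!r} is not a target region")
        if target_contains_zero(network, reg):
            raise ValidationError(
                f"target region {reg.label!r} contains the zero flux vector"
            )
    for reg in desireds:
        reg.check_dimension(network)
        if reg.role != "desired":
            raise ValidationError(f"region {reg.label!r} is not a desired region")

    targetable = spec.targetable(network.reaction_ids)
    if not targetable:
        raise ValidationError("no targetable unit: nothing can block the target region")
    for rid in spec.addable(network.reaction_ids):
        i = network.index(rid)
        if not (math.isfinite(network.lb[i]) and math.isfinite(network.ub[i])):
            raise ValidationError(
                f"addable reaction {rid!r} needs finite activation bounds"
            )
        if network.lb[i] > 0:
            raise ValidationError(
                f"addable reaction {rid!r} has a strictly positive lower bound; "
                "forced-activation addables are not supported"
            )

    indicator = IndicatorSet(unit_ids=list(targetable))
    dual_blocks = [DualBlock(reg, *_fold_target_system(network, reg, spec)) for reg in targets]
    primal_blocks = [PrimalBlock(reg) for reg in desireds]

    pos = 0
    indicator.z_slice = slice(pos, pos + len(targetable))
    pos += len(targetable)
    m = network.n_metabolites
    for blk in dual_blocks:
        blk.u_slice = slice(pos, pos + m)
        pos += m
        blk.w_slice = slice(pos, pos + blk.T.shape[0])
        pos += blk.T.shape[0]
        blk.v_slice = slice(pos, pos + len(targetable))
        pos += len(targetable)
    n = network.n_reactions
    for blk in primal_blocks:
        blk.r_slice = slice(pos, pos + n)
        pos += n

    problem = MilpProblem(
        network=network,
        targets=list(targets),
        desireds=list(desireds),
        spec=spec,
        indicator=indicator,
        dual_blocks=dual_blocks,
        primal_blocks=primal_blocks,
        M=M,
        flux_M=flux_M,
        n_vars=pos,
        time_limit=time_limit,
    )
    problem.max_cuts = max_cuts  # type: ignore[attr-defined]
    return problem


# ---------------------------------------------------------------------------
# materialization


def _materialize(problem: MilpProblem, fixed_zero: set | None = None,
                 feasibility_only: bool = False):
    """Build the sparse row system, bounds, objective and integrality."""
    net = problem.network
    spec = problem.spec
    n = net.n_reactions
    m = net.n_metabolites
    targetable = problem.targetable
    t_index = {u: k for k, u in enumerate(targetable)}
    M, flux_M = problem.M, problem.flux_M

    lb = np.full(problem.n_vars, -np.inf)
    ub = np.full(problem.n_vars, np.inf)
    integrality = np.zeros(problem.n_vars)
    zs = problem.indicator.z_slice
    lb[zs], ub[zs] = 0.0, 1.0
    integrality[zs.start:zs.stop] = 1
    if fixed_zero:
        for uid in fixed_zero:
            ub[problem.z_index(uid)] = 0.0

    rows, cols, vals = [], [], []
    row_lb, row_ub = [], []
    r_no = 0

    def add_row(entries, lo, hi):
        nonlocal r_no
        for j, c in entries:
            rows.append(r_no)
            cols.append(j)
            vals.append(c)
        row_lb.append(lo)
        row_ub.append(hi)
        r_no += 1

    # dual blocks
    for blk in problem.dual_blocks:
        u0, w0, v0 = blk.u_slice.start, blk.w_slice.start, blk.v_slice.start
        lb[blk.u_slice], ub[blk.u_slice] = -M, M
        lb[blk.w_slice], ub[blk.w_slice] = 0.0, M
        lb[blk.v_slice], ub[blk.v_slice] = -M, M
        n_trows = blk.T.shape[0]
        for i, rid in enumerate(net.reaction_ids):
            entries = [(u0 + r, net.stoich[r, i]) for r in range(m) if net.stoich[r, i] != 0]
            entries += [(w0 + r, blk.T[r, i]) for r in range(n_trows) if blk.T[r, i] != 0]
            if rid in t_index:
                entries.append((v0 + t_index[rid], 1.0))
            if net.lb[i] < 0:  # reversible column: equality
                add_row(entries, 0.0, 0.0)
            else:  # irreversible: >= 0
                add_row(entries, 0.0, np.inf)
        # infeasibility certificate t'w <= -1
        add_row([(w0 + r, blk.t[r]) for r in range(n_trows) if blk.t[r] != 0],
                -np.inf, -1.0)
        # v/z linking (big-M); addable units are gated by (1 - z)
        for uid in targetable:
            i = net.index(uid)
            vz = v0 + t_index[uid]
            zj = zs.start + t_index[uid]
            sign = -1.0 if spec.status_of(uid) == "addable" else 1.0
            off = M if sign < 0 else 0.0  # v <= M z  or  v <= M (1 - z)
            add_row([(vz, 1.0), (zj, -sign * M)], -np.inf, off)
            if net.lb[i] < 0:  # negative side only counts for reversible columns
                add_row([(vz, -1.0), (zj, -sign * M)], -np.inf, off)
            else:
                pass  # negative v is harmless slack on a >=0 column

    # primal (desired) blocks
    for blk in problem.primal_blocks:
        r0 = blk.r_slice.start
        for r in range(m):
            entries = [(r0 + i, net.stoich[r, i]) for i in range(n) if net.stoich[r, i] != 0]
            if entries:
                add_row(entries, 0.0, 0.0)
        V, v = blk.region.V, blk.region.v
        for r in range(V.shape[0]):
            add_row([(r0 + i, V[r, i]) for i in range(n) if V[r, i] != 0], -np.inf, v[r])
        if net.extra_A is not None:
            for r in range(net.extra_A.shape[0]):
                add_row([(r0 + i, net.extra_A[r, i]) for i in range(n)
                         if net.extra_A[r, i] != 0], -np.inf, net.extra_b[r])
        for i, rid in enumerate(net.reaction_ids):
            st = spec.status_of(rid)
            blo = net.lb[i] if math.isfinite(net.lb[i]) else -flux_M
            bhi = net.ub[i] if math.isfinite(net.ub[i]) else flux_M
            if st == "non_targetable":
                lb[r0 + i], ub[r0 + i] = blo, bhi
            else:
                zj = zs.start + t_index[rid]
                lb[r0 + i], ub[r0 + i] = min(blo, 0.0), max(bhi, 0.0)
                if st == "deletable":  # r <= ub (1-z), r >= lb (1-z)
                    add_row([(r0 + i, 1.0), (zj, bhi)], -np.inf, bhi)
                    add_row([(r0 + i, -1.0), (zj, -blo)], -np.inf, -blo)
                else:  # addable: r <= ub z, r >= lb z
                    add_row([(r0 + i, 1.0), (zj, -bhi)], -np.inf, 0.0)
                    add_row([(r0 + i, -1.0), (zj, blo)], -np.inf, 0.0)

    # budget rows
    costs = np.array([spec.cost_of(u) for u in targetable])
    if math.isfinite(spec.max_cost):
        add_row([(zs.start + k, costs[k]) for k in range(len(targetable))],
                -np.inf, spec.max_cost)
    max_cuts = getattr(problem, "max_cuts", None)
    if max_cuts is not None and math.isfinite(max_cuts):
        add_row([(zs.start + k, 1.0) for k in range(len(targetable))],
                -np.inf, float(max_cuts))

    # integer cuts: sum_{j in C} z_j <= |C| - 1
    for members in problem.integer_cuts:
        add_row([(problem.z_index(u), 1.0) for u in members],
                -np.inf, len(members) - 1.0)

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(r_no, problem.n_vars)
    )
    c = np.zeros(problem.n_vars)
    if not feasibility_only:
        c[zs.start:zs.stop] = costs
    return c, A, np.asarray(row_lb), np.asarray(row_ub), lb, ub, integrality


def _extract_support(problem: MilpProblem, x: np.ndarray) -> tuple[set, set]:
    zs = problem.indicator.z_slice
    z = x[zs.start:zs.stop]
    deletions, additions = set(), set()
    for k, uid in enumerate(problem.targetable):
        if z[k] > 0.5:
            if problem.spec.status_of(uid) == "addable":
                additions.add(uid)
            else:
                deletions.add(uid)
    return deletions, additions


# ---------------------------------------------------------------------------
# verification oracle


def verify_cutset(
    network: MetabolicNetwork,
    targets: Sequence[FluxRegion],
    desireds: Sequence[FluxRegion],
    spec: InterventionSpec,
    cutset: CutSet,
) -> bool:
    """All targets LP-infeasible and all desired regions LP-feasible."""
    for reg in targets:
        feas, _ = region_feasible(network, reg, cutset, spec)
        if feas:
            return False
    for reg in desireds:
        feas, _ = region_feasible(network, reg, cutset, spec)
        if not feas:
            return False
    return True


def _verify_or_raise(problem: MilpProblem, cutset: CutSet) -> None:
    if not verify_cutset(problem.network, problem.targets, problem.desireds,
                         problem.spec, cutset):
        raise SolverError(
            f"incumbent {cutset!r} failed LP verification; the dual big-M "
            f"(M={problem.M}) is likely too small -- rebuild with a larger M"
        )


# ---------------------------------------------------------------------------
# solving


def _solve_once(problem: MilpProblem, fixed_zero: set | None = None,
                feasibility_only: bool = False):
    c, A, rlo, rhi, lb, ub, integ = _materialize(problem, fixed_zero, feasibility_only)
    status, x, fun = solve_milp(c, A, rlo, rhi, lb, ub, integ,
                                time_limit=problem.time_limit)
    if status == "timeout":
        if x is None:
            raise SolverError("MILP time limit reached with no incumbent")
        warnings.warn("MILP time limit reached; using the incumbent solution "
                      "(enumeration may be incomplete)", stacklevel=3)
        status = "optimal"
    return status, x, fun


def solve_smallest(problem: MilpProblem) -> CutSet | None:
    """Minimum-cost intervention set, or None if none exists within budget.

    The incumbent is LP-verified and support-minimized (cost first, then a
    greedy pass dropping redundant zero-cost members).
    """
    status, x, _ = _solve_once(problem)
    if status in ("infeasible", "unbounded"):
        return None
    deletions, additions = _extract_support(problem, x)
    candidate = CutSet(frozenset(deletions), frozenset(additions),
                       cutset_cost(deletions | additions, problem.spec))
    _verify_or_raise(problem, candidate)
    return minimize_within_support(problem, candidate)


def minimize_within_support(problem: MilpProblem, candidate: CutSet) -> CutSet:
    """Reduce a verified cut set to a support-minimal one inside its support.

    First re-minimizes cost over the confined MILP where only the found
    interventions are allowed, then greedily removes members (zero-cost ones
    first) whose removal keeps every target blocked and every desired region
    feasible.
    """
    members = set(candidate.members)
    if members:
        fixed_zero = {u for u in problem.targetable if u not in members}
        status, x, _ = _solve_once(problem, fixed_zero=fixed_zero)
        if status == "optimal":
            deletions, additions = _extract_support(problem, x)
            confined = CutSet(frozenset(deletions), frozenset(additions),
                              cutset_cost(deletions | additions, problem.spec))
            if verify_cutset(problem.network, problem.targets, problem.desireds,
                             problem.spec, confined):
                members = set(confined.members)

    order = sorted(members, key=lambda u: (problem.spec.cost_of(u), u), reverse=False)
    # try dropping cheap members first so free riders go before paid cuts
    changed = True
    while changed:
        changed = False
        for uid in list(order):
            if uid not in members:
                continue
            trial = members - {uid}
            cs = _as_cutset(problem.spec, trial)
            if verify_cutset(problem.network, problem.targets, problem.desireds,
                             problem.spec, cs):
                members = trial
                changed = True
    result = _as_cutset(problem.spec, members)
    _verify_or_raise(problem, result)
    return result


def _as_cutset(spec: InterventionSpec, members: set) -> CutSet:
    additions = frozenset(u for u in members if spec.status_of(u) == "addable")
    deletions = frozenset(members) - additions
    return CutSet(deletions, additions, cutset_cost(members, spec))


def enumerate_mcs(
    problem: MilpProblem,
    max_cost: float | None = None,
    max_solutions: float | None = None,
    mode: str = "optimal_order",
) -> list[CutSet]:
    """Enumerate minimal cut sets via integer cuts.

    ``optimal_order`` repeats the cost-minimizing solve, so reported costs
    are non-decreasing; ``any_feasible`` accepts arbitrary incumbents and
    support-minimizes them before recording -- a faster way to sample
    solutions without cost ordering.  Integer cuts are posted against the
    minimized supports, so supersets of found solutions never reappear.
    """
    if mode not in ("optimal_order", "any_feasible"):
        raise ValidationError(f"unknown enumeration mode {mode!r}")
    budget = problem.spec.max_cost if max_cost is None else float(max_cost)
    limit = problem.spec.max_solutions if max_solutions is None else float(max_solutions)
    if not math.isfinite(budget) and not math.isfinite(limit):
        warnings.warn("enumerating with neither a cost budget nor a solution "
                      "limit may not terminate", stacklevel=2)
    found: list[CutSet] = []
    saved_cuts = list(problem.integer_cuts)
    try:
        while len(found) < limit:
            if mode == "optimal_order":
                cs = solve_smallest(problem)
            else:
                status, x, _ = _solve_once(problem, feasibility_only=True)
                if status in ("infeasible", "unbounded"):
                    cs = None
                else:
                    deletions, additions = _extract_support(problem, x)
                    raw = _as_cutset(problem.spec, deletions | additions)
                    _verify_or_raise(problem, raw)
                    cs = minimize_within_support(problem, raw)
            if cs is None or cs.cost > budget + 1e-9:
                break
            found.append(cs)
            if not cs.members:  # empty cut set: the target is already blocked
                break
            problem.integer_cuts.append(frozenset(cs.members))
    finally:
        problem.integer_cuts = saved_cuts
    return found
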