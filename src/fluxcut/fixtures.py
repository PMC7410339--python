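"""Reference networks, random instances and the brute-force oracle.

Two small strain-design problems exercise every feature end to end:

* :func:`fig2_bundle` -- a co-feeding network: substrate S feeds an
  ATP/Z-coupled product branch (P), a costly biomass-precursor branch
  (B -> U -> biomass) and several overflow escapes.  A classical
  four-knockout design couples growth to P on S alone; alternatively one
  deletion plus the *addition* of an uptake reaction for U splits
  metabolism into S -> energy+product and U -> biomass.  Because U is both
  a potential product and a potential substrate, the low-yield target set
  is described by two target regions (single-substrate and co-feeding
  cases), each excluding the uptake/export cycle of U.

* :func:`fig4_bundle` -- a nine-gene network for gene-level designs: block
  production of the by-product D while keeping growth.  The GPR ruleset
  compresses to four (partially lumped) genes, the compressed MILP returns
  two solutions, and decompression yields four gene cut sets.

The networks are transcriptions of the published example diagrams; where a
coefficient is not pinned down by the accompanying description, the variant
reproducing the documented solution sets verbatim (including minimality)
was chosen and frozen here.

:func:`random_bundle` generates seeded mass-balanced instances with a
guaranteed substrate->biomass path, and :func:`oracle_enumerate` is the
independent correctness standard: exhaustive LP probing of every
intervention subset, with no MILP involved.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    UNBOUNDED,
    CutSet,
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    ValidationError,
    make_cofeeding_target_pair,
    region_feasible,
)
from .gpr import GeneCatalog, GPRRule, integrate_gpr, parse_gpr

__all__ = ["FixtureBundle", "fig2_bundle", "fig4_bundle", "random_bundle", "oracle_enumerate"]

ORACLE_SUBSET_CAP = 200_000


@dataclass
class FixtureBundle:
    """A complete strain-design problem instance with documented answers."""

    network: MetabolicNetwork
    targets: list
    desireds: list
    spec: InterventionSpec
    rules: list = field(default_factory=list)        # GPRRule, possibly empty
    gene_catalog: GeneCatalog = field(default_factory=GeneCatalog)
    expected: dict = field(default_factory=dict)
    label: str = ""

    @property
    def has_gpr(self) -> bool:
        return bool(self.rules)


def _network_from_table(rows, lb, ub):
    """rows: list of (rid, {met: coef}); bounds by reaction id."""
    met_order: list[str] = []
    for _rid, coeffs in rows:
        for met in coeffs:
            if met not in met_order:
                met_order.append(met)
    stoich = np.zeros((len(met_order), len(rows)))
    met_index = {mid: i for i, mid in enumerate(met_order)}
    for j, (_rid, coeffs) in enumerate(rows):
        for met, c in coeffs.items():
            stoich[met_index[met], j] = c
    rids = [rid for rid, _ in rows]
    return MetabolicNetwork(
        stoich,
        np.array([lb[r] for r in rids], float),
        np.array([ub[r] for r in rids], float),
        rids,
        met_order,
    )


# ---------------------------------------------------------------------------
# co-feeding example


def fig2_bundle() -> FixtureBundle:
    """Co-feeding network: orange 4-knockout vs blue 1-deletion+1-addition.

    Mechanism: r2 couples ATP formation to the by-metabolite Z, which only
    product synthesis r4 can drain once the alternative Z sinks (r7, r9)
    are cut; ATP-recovering overflow escapes (r3, r12) and the ATP price of
    biomass precursor synthesis (r6, r8) bound how much substrate can avoid
    the product branch.  With the orange knockouts, S as sole substrate
    yields at least 3/7 > 0.4 product per substrate in every steady state
    that consumes substrate.  Deleting r6 instead severs the precursor
    supply entirely -- growth then requires the *added* uptake of U, and S
    can only flow through the product-coupled branch (blue design).
    """
    inf = UNBOUNDED
    rows = [
        ("r_s_up", {"S": 1}),                       # substrate uptake (medium)
        ("r1", {"S": -1, "A": 1}),
        ("r2", {"A": -1, "ATP": 1, "Z": 1}),        # energy, coupled to Z
        ("r3", {"B": -1, "Q": 1, "ATP": 2}),        # overflow to Q, ATP gain
        ("r4", {"A": -1, "Z": -1, "P": 1}),         # product synthesis drains Z
        ("r5", {"B": -1, "U": 1}),
        ("r6", {"A": -1, "ATP": -3, "B": 1}),       # biomass precursor branch
        ("r7", {"B": -1, "Z": -1, "Q": 1}),         # alternative Z sink
        ("r8", {"U": -1, "ATP": -3, "BM": 1}),      # biomass synthesis
        ("r9", {"B": -1, "Z": -1, "R": 1}),         # alternative Z sink
        ("r10", {"ATP": -1}),                       # ATP maintenance (spontaneous)
        ("r11", {"Q": -1, "R": 1}),
        ("r12", {"B": -1, "R": 1, "ATP": 2}),       # overflow to R, ATP gain
        ("r_p_ex", {"P": -1}),
        ("r_q_ex", {"Q": -1}),
        ("r_r_ex", {"R": -1}),
        ("r_u_ex", {"U": -1}),
        ("r_bm_ex", {"BM": -1}),
        ("r_u_up", {"U": 1}),                       # addable co-substrate uptake
    ]
    lb = {rid: 0.0 for rid, _ in rows}
    ub = {rid: inf for rid, _ in rows}
    ub["r_s_up"] = 10.0
    ub["r_u_up"] = 10.0
    network = _network_from_table(rows, lb, ub)

    internal = [f"r{i}" for i in range(1, 13) if i != 10]
    status = {rid: "deletable" for rid in internal}
    status["r_u_up"] = "addable"
    cost = {rid: 1.0 for rid in internal}
    cost["r_u_up"] = 0.0
    spec = InterventionSpec(status, cost)

    target1, target2 = make_cofeeding_target_pair(
        network, "r_p_ex", "r_s_up", "r_u_up", "r_u_ex",
        threshold=0.4, min_primary_uptake=0.1,
    )
    desired = FluxRegion(
        "desired",
        -np.eye(network.n_reactions)[network.index("r_bm_ex")][None, :],
        np.array([-0.1]),
        label="growth",
    )
    expected = {
        "orange_mcs": CutSet(frozenset({"r3", "r7", "r9", "r12"}), cost=4.0),
        "blue_mcs": CutSet(frozenset({"r6"}), frozenset({"r_u_up"}), cost=1.0),
    }
    return FixtureBundle(network, [target1, target2], [desired], spec,
                         expected=expected, label="cofeeding")


# ---------------------------------------------------------------------------
# gene-MCS pipeline example


def fig4_bundle() -> FixtureBundle:
    """Nine-gene network: suppress by-product D while preserving growth.

    Substrate S feeds growth (r2) and a branch (r3) toward the by-product D
    (r4) and the product P (r5); r6 leads to a dead end and is blocked.
    Reactions r1 and r2 are essential under the growth requirement, which
    protects genes g1, g2, g3 during GPR compression; g5/g9 co-occur and
    lump, then the rule-local disjunction with g7 lumps again, leaving four
    (partially lumped) genes.  The documented solutions: knock out g8, or
    g4, or {g5, g7}, or {g7, g9}.
    """
    inf = UNBOUNDED
    rows = [
        ("r1", {"S": 1}),                 # substrate uptake (transporter gene g1)
        ("r2", {"S": -1, "BM": 1}),       # growth
        ("r3", {"S": -1, "C": 1}),
        ("r4", {"C": -1, "D": 1}),        # by-product D (the targeted route)
        ("r5", {"C": -1, "P": 1}),
        ("r6", {"C": -1, "X": 1}),        # dead end: blocked
        ("ex_bm", {"BM": -1}),
        ("ex_d", {"D": -1}),
        ("ex_p", {"P": -1}),
    ]
    lb = {rid: 0.0 for rid, _ in rows}
    ub = {rid: inf for rid, _ in rows}
    ub["r1"] = 10.0
    network = _network_from_table(rows, lb, ub)

    rule_text = {
        "r1": "g1",
        "r2": "g2 and g3",
        "r3": "(g4 and g5 and g9) or (g4 and g7 and g2)",
        "r4": "g8",
        "r5": "g6",
        "r6": "g9",
    }
    rules = [parse_gpr(text, rid) for rid, text in rule_text.items()]
    catalog = GeneCatalog(
        cost={f"g{i}": 1.0 for i in range(1, 10)},
        status={f"g{i}": "deletable" for i in range(1, 10)},
    )
    # all reactions carry rules or are spontaneous exchanges: nothing is
    # targetable at the reaction level
    spec = InterventionSpec()

    n = network.n_reactions
    target = FluxRegion("target", -np.eye(n)[network.index("ex_d")][None, :],
                        np.array([-1.0]), label="d_production")
    desired = FluxRegion("desired", -np.eye(n)[network.index("ex_bm")][None, :],
                         np.array([-0.1]), label="growth")
    expected = {
        "essential_gpr_reactions": {"r1", "r2"},
        "blocked_reactions": {"r6"},
        "genes_after_compression": 4,
        "n_compressed_solutions": 2,
        "gene_mcs": [
            CutSet(frozenset({"g8"}), cost=1.0, level="gene"),
            CutSet(frozenset({"g4"}), cost=1.0, level="gene"),
            CutSet(frozenset({"g5", "g7"}), cost=2.0, level="gene"),
            CutSet(frozenset({"g7", "g9"}), cost=2.0, level="gene"),
        ],
    }
    return FixtureBundle(network, [target], [desired], spec, rules, catalog,
                         expected, label="gene_pipeline")


# ---------------------------------------------------------------------------
# random instances


def random_bundle(
    seed: int,
    n_mets: int = 6,
    n_rxns: int = 9,
    n_genes: int = 6,
    n_targets: int = 1,
    n_desireds: int = 1,
    with_gpr: bool = True,
    max_resample: int = 50,
) -> FixtureBundle:
    """Seeded random instance with a guaranteed substrate->biomass path.

    The backbone uptake -> M1 -> ... -> biomass keeps the desired region
    feasible by construction; sparse unit-coefficient side reactions, an
    occasional addable uptake and small random GPR rules provide the
    variability.  Degenerate draws (infeasible target/desired) are
    resampled up to ``max_resample`` times, then rejected.
    """
    rng = np.random.default_rng(seed)
    for trial in range(max_resample):
        bundle = _draw_bundle(rng, n_mets, n_rxns, n_genes, n_targets,
                              n_desireds, with_gpr)
        if bundle is not None:
            bundle.label = f"random_{seed}"
            return bundle
    raise ValidationError(f"no feasible random instance after {max_resample} draws (seed {seed})")


def _draw_bundle(rng, n_mets, n_rxns, n_genes, n_targets, n_desireds, with_gpr):
    n_mets = max(4, n_mets)
    mets = [f"M{i}" for i in range(n_mets - 1)] + ["BM"]
    backbone_len = int(rng.integers(2, 4))
    chain = ["M0"] + [f"M{i}" for i in rng.choice(range(1, n_mets - 1),
                                                  size=backbone_len - 1, replace=False)]
    rows = [("up_s", {"M0": 1})]
    for k in range(len(chain) - 1):
        rows.append((f"b{k}", {chain[k]: -1, chain[k + 1]: 1}))
    rows.append(("b_bm", {chain[-1]: -1, "BM": 1}))
    rows.append(("ex_bm", {"BM": -1}))

    # product: exported from a random metabolite
    prod_src = mets[int(rng.integers(0, n_mets - 1))]
    rows.append(("mk_p", {prod_src: -1, "P": 1}))
    rows.append(("ex_p", {"P": -1}))

    n_extra = max(0, n_rxns - len(rows))
    for k in range(n_extra):
        a, b = (str(x) for x in rng.choice(mets[:-1], size=2, replace=False))
        coeffs = {a: -1.0, b: 1.0}
        if rng.random() < 0.3:
            c = str(rng.choice(mets[:-1]))
            if c not in coeffs:
                coeffs[c] = float(rng.choice([-1.0, 1.0]))
        rows.append((f"x{k}", coeffs))

    rids = [r for r, _ in rows]
    lb = {rid: 0.0 for rid in rids}
    ub = {rid: 10.0 for rid in rids}
    ub["up_s"] = 10.0
    for rid in rids:
        if rid.startswith("x") and rng.random() < 0.3:
            lb[rid] = -10.0

    addable_id = None
    if rng.random() < 0.3:
        addable_id = "up_alt"
        tgt = str(rng.choice(mets[:-1]))
        rows.append((addable_id, {tgt: 1.0}))
        rids.append(addable_id)
        lb[addable_id], ub[addable_id] = 0.0, 5.0

    network = _network_from_table(rows, lb, ub)

    internal = [r for r in rids if r not in ("up_s", "ex_bm", "ex_p", addable_id)]
    status = {rid: "deletable" for rid in internal}
    cost = {rid: 1.0 for rid in internal}
    if addable_id:
        status[addable_id] = "addable"
        cost[addable_id] = float(rng.choice([0.0, 1.0]))
    spec = InterventionSpec(status, cost)

    n = network.n_reactions
    targets = []
    for _ in range(n_targets):
        row = -np.eye(n)[network.index("ex_p")][None, :]
        targets.append(FluxRegion("target", row, np.array([-0.5]), label="p_flux"))
    desireds = []
    for k in range(n_desireds):
        thr = 0.1 * (k + 1)
        row = -np.eye(n)[network.index("ex_bm")][None, :]
        desireds.append(FluxRegion("desired", row, np.array([-thr]), label=f"growth_{k}"))

    # reject degenerate draws: every region must be feasible in the wild type
    try:
        for reg in targets + desireds:
            feasible, _ = region_feasible(network, reg, None, spec)
            if not feasible:
                return None
    except Exception:
        return None

    rules: list[GPRRule] = []
    catalog = GeneCatalog()
    if with_gpr and n_genes > 0:
        genes = [f"g{i}" for i in range(1, n_genes + 1)]
        catalog = GeneCatalog(cost={g: 1.0 for g in genes},
                              status={g: "deletable" for g in genes})
        for rid in internal:
            if rng.random() < 0.6:
                n_conj = int(rng.integers(1, 3))
                dnf = frozenset(
                    frozenset(str(g) for g in rng.choice(
                        genes, size=int(rng.integers(1, 3)), replace=False))
                    for _ in range(n_conj)
                )
                rules.append(GPRRule(rid, dnf))
                status.pop(rid, None)  # GPR-bearing reactions lose targetability
        spec = InterventionSpec(status, cost)
        if not rules:
            rules = []
    return FixtureBundle(network, targets, desireds, spec, rules, catalog)


# ---------------------------------------------------------------------------
# brute-force oracle


def integrated_problem(bundle: FixtureBundle):
    """The bundle's problem at its finest level, without any compression.

    With GPR rules, integrates them (uncompressed) and moves targetability
    to the gene synthesis pseudo-reactions; without rules it is the plain
    reaction-level problem.  Returns (network, targets, desireds, spec).
    """
    if not bundle.has_gpr:
        return bundle.network, list(bundle.targets), list(bundle.desireds), bundle.spec
    net, ext = integrate_gpr(bundle.network, bundle.rules)
    ruled = {r.reaction_id for r in bundle.rules if not r.is_true}
    status, cost = {}, {}
    for rid in bundle.network.reaction_ids:
        if rid in ruled:
            continue  # gene level: GPR-bearing reactions are not directly cuttable
        st = bundle.spec.status_of(rid)
        if st != "non_targetable":
            status[rid] = st
            cost[rid] = bundle.spec.cost_of(rid)
    for g in ext.gene_reactions:
        st = bundle.gene_catalog.status_of(g)
        if st in ("deletable", "addable"):
            status[g] = st
            cost[g] = bundle.gene_catalog.cost_of(g)
    spec = InterventionSpec(status, cost, bundle.spec.max_cost, bundle.spec.max_solutions)
    targets = [ext.map_region(t) for t in bundle.targets]
    desireds = [ext.map_region(d) for d in bundle.desireds]
    return net, targets, desireds, spec


def oracle_enumerate(bundle: FixtureBundle, max_cost: float) -> list[CutSet]:
    """Exhaustive LP-probe enumeration of minimal cut sets (no MILP).

    Tests every subset of targetable units with total cost within budget:
    a subset is *sound* when every target region becomes LP-infeasible and
    every desired region stays LP-feasible; the support-minimal sound sets
    are returned.  Refuses instances whose subset count exceeds the cap.
    """
    network, targets, desireds, spec = integrated_problem(bundle)
    units = sorted(spec.targetable(network.reaction_ids))
    if 2 ** len(units) > ORACLE_SUBSET_CAP:
        raise ValidationError(
            f"{len(units)} targetable units exceed the oracle's exhaustive cap"
        )
    level = "gene" if bundle.has_gpr else "reaction"
    sound: list[CutSet] = []
    for size in range(0, len(units) + 1):
        for combo in itertools.combinations(units, size):
            members = set(combo)
            cost = sum(spec.cost_of(u) for u in members)
            if cost > max_cost + 1e-9:
                continue
            if any(set(s.members) <= members for s in sound):
                continue  # superset of a sound set can never be minimal
            cs = CutSet(
                frozenset(u for u in members if spec.status_of(u) != "addable"),
                frozenset(u for u in members if spec.status_of(u) == "addable"),
                cost,
                level=level,
            )
            ok = all(not region_feasible(network, t, cs, spec)[0] for t in targets) and \
                all(region_feasible(network, d, cs, spec)[0] for d in desireds)
            if ok:
                sound.append(cs)
    # subset-minimality (soundness is not monotone, so re-filter)
    minimal = [
        cs for cs in sound
        if not any(o.members < cs.members for o in sound)
    ]
    return sorted(minimal, key=CutSet.sort_key)
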