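"""Core data model: metabolic networks, flux regions, interventions, cut sets.

A metabolic network is the usual constraint-based object: a stoichiometric
matrix ``N`` (metabolites x reactions), flux bounds ``lb <= r <= ub`` (in
mmol/gDW/h by convention) and, optionally, additional linear constraints
``A r <= b`` (e.g. enzyme-allocation style constraints).  Steady-state flux
vectors satisfy ``N r = 0`` together with these bounds.

Flux *regions* are polyhedra over the flux space, written ``V r <= v``:

* a **target** region collects undesired flux states (for instance all
  states with a product yield below a threshold) that an intervention set
  must render infeasible; it must not contain the zero flux vector, since
  no set of deletions can ever remove ``r = 0``;
* a **desired** region collects wanted states (e.g. growth above a minimum)
  of which at least one must remain feasible after the interventions.

Interventions are reaction (or, downstream, gene) deletions and additions
with nonnegative costs; a :class:`CutSet` is one such intervention set.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._lp import LPProblem, SolverError, solve_lp

__all__ = [
    "UNBOUNDED",
    "MetabolicNetwork",
    "FluxRegion",
    "InterventionSpec",
    "CutSet",
    "SolverError",
    "load_network",
    "write_network_tabular",
    "load_regions",
    "save_regions",
    "write_cutsets_tsv",
    "read_cutsets_tsv",
    "make_yield_region",
    "make_cofeeding_target_pair",
    "region_feasible",
    "apply_cutset",
    "target_contains_zero",
]

#: Sentinel for an unbounded flux bound.  It is never multiplied by a binary
#: variable; MILP construction demands finite activation bounds instead.
UNBOUNDED = math.inf

DEFAULT_COST = 1.0
STATUSES = ("deletable", "addable", "non_targetable")


class ValidationError(ValueError):
    """A model, region or intervention specification is inconsistent."""


# ---------------------------------------------------------------------------
# network


@dataclass
class MetabolicNetwork:
    """Stoichiometric network with flux bounds and optional extra constraints.

    Parameters
    ----------
    stoich
        Dense ``m x n`` stoichiometric matrix (metabolites x reactions).
    lb, ub
        Per-reaction flux bounds; ``math.inf`` marks an unbounded direction.
    reaction_ids, metabolite_ids
        Unique identifier strings, order matching the matrix.
    extra_A, extra_b
        Optional global linear constraints ``extra_A @ r <= extra_b``.
    annotations
        Free-form side information (e.g. raw GPR text per reaction read from
        a model file); never interpreted by the numerics.
    """

    stoich: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    extra_A: np.ndarray | None = None
    extra_b: np.ndarray | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stoich = np.asarray(self.stoich, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.reaction_ids = list(self.reaction_ids)
        self.metabolite_ids = list(self.metabolite_ids)
        m, n = self.stoich.shape
        if not (len(self.lb) == len(self.ub) == len(self.reaction_ids) == n):
            raise ValidationError(
                f"inconsistent reaction dimension: stoich has {n} columns, "
                f"lb/ub/ids have {len(self.lb)}/{len(self.ub)}/{len(self.reaction_ids)}"
            )
        if len(self.metabolite_ids) != m:
            raise ValidationError(
                f"{len(self.metabolite_ids)} metabolite ids for {m} stoich rows"
            )
        for name, ids in (("reaction", self.reaction_ids), ("metabolite", self.metabolite_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValidationError(f"duplicate {name} id: {dup!r}")
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ValidationError(f"lb > ub for reaction {bad!r}")
        if self.extra_A is not None:
            self.extra_A = np.atleast_2d(np.asarray(self.extra_A, dtype=float))
            self.extra_b = np.atleast_1d(np.asarray(self.extra_b, dtype=float))
            if self.extra_A.shape != (len(self.extra_b), n):
                raise ValidationError("extra constraint dimensions do not match network")
        self._index = {rid: i for i, rid in enumerate(self.reaction_ids)}

    # -- basic queries ----------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.stoich.shape[0]

    def index(self, reaction_id: str) -> int:
        try:
            return self._index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    @property
    def irreversible(self) -> np.ndarray:
        """Boolean mask of reactions with ``lb >= 0`` (the set Irrev)."""
        return self.lb >= 0

    @property
    def reversible(self) -> np.ndarray:
        return self.lb < 0

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.stoich.copy(),
            self.lb.copy(),
            self.ub.copy(),
            list(self.reaction_ids),
            list(self.metabolite_ids),
            None if self.extra_A is None else self.extra_A.copy(),
            None if self.extra_b is None else self.extra_b.copy(),
            dict(self.annotations),
        )


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# regions


@dataclass
class FluxRegion:
    """One target or desired polyhedron ``V r <= v`` over reaction rates."""

    role: str  # "target" | "desired"
    V: np.ndarray
    v: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("target", "desired"):
            raise ValidationError(f"region role must be target/desired, got {self.role!r}")
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if self.V.shape[0] != len(self.v):
            raise ValidationError("region matrix/vector row mismatch")

    @property
    def n_rows(self) -> int:
        return self.V.shape[0]

    def check_dimension(self, network: MetabolicNetwork) -> None:
        if self.V.shape[1] != network.n_reactions:
            raise ValidationError(
                f"region {self.label!r} has {self.V.shape[1]} columns for a "
                f"network with {network.n_reactions} reactions"
            )


def target_contains_zero(network: MetabolicNetwork, region: FluxRegion) -> bool:
    """Whether ``r = 0`` lies inside the region *including* network constraints.

    The zero vector always satisfies ``N r = 0``; it is excluded exactly when
    some bound, extra constraint or region row has a strictly negative
    right-hand side at ``r = 0``.
    """
    if np.any(network.lb > 0) or np.any(network.ub < 0):
        return False
    if network.extra_b is not None and np.any(network.extra_b < 0):
        return False
    return not np.any(region.v < 0)


def _reject_zero_containing_target(network: MetabolicNetwork, region: FluxRegion) -> None:
    if region.role == "target" and target_contains_zero(network, region):
        raise ValidationError(
            f"target region {region.label!r} contains the zero flux vector; "
            "no intervention set can block it.  Add a zero-excluding row "
            "(e.g. a minimum substrate uptake rate)."
        )


def make_yield_region(
    network: MetabolicNetwork,
    product_rxn: str,
    substrate_rxns: Sequence[tuple[str, float]] | str,
    threshold: float,
    sense: str = "<=",
    extra_rows: Sequence[tuple[Mapping[str, float], float]] | None = None,
    role: str = "target",
    label: str = "",
) -> FluxRegion:
    """Linearized yield constraint ``r_P / sum_s w_s r_s  (<=|>=)  Y``.

    ``sense='<='`` produces the single row ``r_P - Y * sum w_s r_s <= 0``
    (all flux states at or below the yield threshold -- the usual *target*
    for growth-coupled designs); ``sense='>='`` the negated row.  Substrate
    weights are e.g. carbon numbers for carbon-based multi-substrate yields.
    ``extra_rows`` are additional ``(coefficient-dict, rhs)`` inequalities,
    typically a minimum-uptake row that excludes the zero flux vector.
    """
    if isinstance(substrate_rxns, str):
        substrate_rxns = [(substrate_rxns, 1.0)]
    if not math.isfinite(threshold):
        raise ValidationError("yield threshold must be finite")
    n = network.n_reactions
    row = np.zeros(n)
    row[network.index(product_rxn)] += 1.0
    for rid, w in substrate_rxns:
        if w <= 0:
            raise ValidationError(f"substrate weight for {rid!r} must be > 0")
        row[network.index(rid)] -= threshold * w
    if sense == ">=":
        row = -row
    elif sense != "<=":
        raise ValidationError(f"sense must be '<=' or '>=', got {sense!r}")
    rows = [row]
    rhs = [0.0]
    for coeffs, b in extra_rows or ():
        extra = np.zeros(n)
        for rid, c in coeffs.items():
            extra[network.index(rid)] = c
        rows.append(extra)
        rhs.append(float(b))
    region = FluxRegion(role, np.vstack(rows), np.asarray(rhs), label or f"yield_{sense}_{threshold}")
    _reject_zero_containing_target(network, region)
    return region


def make_cofeeding_target_pair(
    network: MetabolicNetwork,
    product_rxn: str,
    primary_substrate: str,
    co_substrate_uptake: str,
    co_substrate_export: str,
    threshold: float,
    min_primary_uptake: float,
) -> tuple[FluxRegion, FluxRegion]:
    """Two target regions for a co-substrate that is also a potential product.

    Region 1 covers the single-substrate case: low yield on the primary
    substrate with the co-substrate uptake pinned to zero.  Region 2 covers
    the co-feeding case: low *combined* yield with the co-substrate export
    pinned to zero (so the irrelevant uptake/export cycle never enters the
    target set).  Both carry a minimum primary-uptake row excluding ``r=0``.
    """
    n = network.n_reactions
    i_up = network.index(co_substrate_uptake)
    i_ex = network.index(co_substrate_export)

    def pin_rows(idx: int) -> list[tuple[dict[str, float], float]]:
        rid = network.reaction_ids[idx]
        rows = [({rid: 1.0}, 0.0)]
        if network.lb[idx] < 0:  # also forbid negative flux
            rows.append(({rid: -1.0}, 0.0))
        return rows

    min_up_row = ({primary_substrate: -1.0}, -float(min_primary_uptake))
    region1 = make_yield_region(
        network,
        product_rxn,
        [(primary_substrate, 1.0)],
        threshold,
        "<=",
        extra_rows=[min_up_row, *pin_rows(i_up)],
        role="target",
        label="target_single_substrate",
    )
    region2 = make_yield_region(
        network,
        product_rxn,
        [(primary_substrate, 1.0), (co_substrate_uptake, 1.0)],
        threshold,
        "<=",
        extra_rows=[min_up_row, *pin_rows(i_ex)],
        role="target",
        label="target_cofeeding",
    )
    if network.ub[i_up] <= 0 and network.lb[i_up] >= 0:
        warnings.warn(
            f"co-substrate uptake {co_substrate_uptake!r} is pinned to zero by its "
            "bounds; the co-feeding target region is degenerate",
            stacklevel=2,
        )
    return region1, region2


# ---------------------------------------------------------------------------
# interventions


@dataclass
class InterventionSpec:
    """Targetability and costs of the intervenable units (reactions/genes).

    Units absent from ``status`` are non-targetable.  Costs default to 1.
    ``max_cost`` bounds the summed cost of a cut set (the maxCuts budget in
    the unit-cost case); ``max_solutions`` caps enumeration length.
    """

    status: dict[str, str] = field(default_factory=dict)
    cost: dict[str, float] = field(default_factory=dict)
    max_cost: float = math.inf
    max_solutions: float = math.inf

    def __post_init__(self) -> None:
        for uid, st in self.status.items():
            if st not in STATUSES:
                raise ValidationError(f"unknown status {st!r} for unit {uid!r}")
        for uid, c in self.cost.items():
            if c < 0:
                raise ValidationError(f"negative cost for unit {uid!r}")
        if self.max_cost < 0 or self.max_solutions < 1:
            raise ValidationError("max_cost must be >= 0 and max_solutions >= 1")

    def status_of(self, uid: str) -> str:
        return self.status.get(uid, "non_targetable")

    def cost_of(self, uid: str) -> float:
        return float(self.cost.get(uid, DEFAULT_COST))

    def deletable(self, ids: Iterable[str]) -> list[str]:
        return [u for u in ids if self.status_of(u) == "deletable"]

    def addable(self, ids: Iterable[str]) -> list[str]:
        return [u for u in ids if self.status_of(u) == "addable"]

    def targetable(self, ids: Iterable[str]) -> list[str]:
        return [u for u in ids if self.status_of(u) != "non_targetable"]

    def replace(self, **kw) -> "InterventionSpec":
        data = dict(
            status=dict(self.status),
            cost=dict(self.cost),
            max_cost=self.max_cost,
            max_solutions=self.max_solutions,
        )
        data.update(kw)
        return InterventionSpec(**data)


@dataclass(frozen=True)
class CutSet:
    """One intervention set: deletions plus additions, with its total cost.

    ``level`` records the resolution: ``compressed_reaction`` (on a
    compressed network), ``reaction`` or ``gene``.
    """

    deletions: frozenset[str]
    additions: frozenset[str] = frozenset()
    cost: float = 0.0
    level: str = "reaction"

    def __post_init__(self) -> None:
        object.__setattr__(self, "deletions", frozenset(self.deletions))
        object.__setattr__(self, "additions", frozenset(self.additions))
        if self.deletions & self.additions:
            raise ValidationError("a unit cannot be both deleted and added")

    @property
    def members(self) -> frozenset[str]:
        return self.deletions | self.additions

    def sort_key(self) -> tuple:
        return (round(self.cost, 9), len(self.members), tuple(sorted(self.deletions)), tuple(sorted(self.additions)))

    def __repr__(self) -> str:  # compact, deterministic
        d = ",".join(sorted(self.deletions)) or "-"
        a = ",".join(sorted(self.additions)) or "-"
        return f"CutSet(del=[{d}] add=[{a}] cost={self.cost:g} level={self.level})"


def cutset_cost(cutset_members: Iterable[str], spec: InterventionSpec) -> float:
    return float(sum(spec.cost_of(u) for u in cutset_members))


def apply_cutset(
    network: MetabolicNetwork,
    spec: InterventionSpec | None = None,
    applied: CutSet | None = None,
) -> MetabolicNetwork:
    """Mutant network: deleted and non-added addable reactions pinned to zero."""
    net = network.copy()
    deletions = applied.deletions if applied is not None else frozenset()
    additions = applied.additions if applied is not None else frozenset()
    for i, rid in enumerate(net.reaction_ids):
        absent = rid in deletions
        if spec is not None and spec.status_of(rid) == "addable" and rid not in additions:
            absent = True
        if absent:
            net.lb[i] = 0.0
            net.ub[i] = 0.0
    return net


# ---------------------------------------------------------------------------
# LP feasibility oracle


def assemble_region_lp(network: MetabolicNetwork, region: FluxRegion | None) -> LPProblem:
    """Assemble ``{N r = 0, bounds, extra, V r <= v}`` as an LP problem."""
    rows_ub: list[np.ndarray] = []
    rhs_ub: list[float] = []
    if network.extra_A is not None:
        rows_ub.append(network.extra_A)
        rhs_ub.extend(network.extra_b)
    if region is not None:
        region.check_dimension(network)
        rows_ub.append(region.V)
        rhs_ub.extend(region.v)
    A_ub = np.vstack(rows_ub) if rows_ub else None
    b_ub = np.asarray(rhs_ub) if rhs_ub else None
    return LPProblem(
        A_eq=network.stoich,
        b_eq=np.zeros(network.n_metabolites),
        A_ub=A_ub,
        b_ub=b_ub,
        lb=network.lb,
        ub=network.ub,
    )


def region_feasible(
    network: MetabolicNetwork,
    region: FluxRegion | None,
    applied: CutSet | None = None,
    spec: InterventionSpec | None = None,
) -> tuple[bool, np.ndarray | None]:
    """LP feasibility of a region under an intervention set.

    Deleted reactions -- and addable reactions not contained in
    ``applied.additions`` -- are pinned to zero flux.  Returns the verdict
    and, if feasible, one witness flux vector.
    """
    net = apply_cutset(network, spec, applied)
    lp = assemble_region_lp(net, region)
    status, x = solve_lp(lp)
    if status == "infeasible":
        return False, None
    if status != "optimal":
        raise SolverError(f"LP solver returned status {status!r} for region "
                          f"{getattr(region, 'label', None)!r}")
    return True, x


# ---------------------------------------------------------------------------
# tabular model dialect

_ARROWS = ("<->", "<=>", "->", "=>")


def _parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A + 2 B -> C"``; returns (metabolite coefficients, reversible)."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ValidationError(f"equation {text!r} has no reaction arrow")
    reversible = arrow in ("<->", "<=>")
    left, right = text.split(arrow, 1)
    coeffs: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError:
                    raise ValidationError(f"bad stoichiometric coefficient in {term!r}")
                met = parts[1]
            else:
                raise ValidationError(f"cannot parse equation term {term!r}")
            coeffs[met] = coeffs.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {m: c for m, c in coeffs.items() if c != 0.0}, reversible


def _format_equation(coeffs: Mapping[str, float], reversible: bool) -> str:
    def side(items):
        out = []
        for met, c in items:
            out.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(out)

    left = side((m, -c) for m, c in coeffs.items() if c < 0)
    right = side((m, c) for m, c in coeffs.items() if c > 0)
    return f"{left} {'<->' if reversible else '->'} {right}".strip()


TABULAR_COLUMNS = ["reaction_id", "equation", "lb", "ub", "gpr", "cost", "status"]


def _network_from_tabular_rows(rows: list[dict[str, str]], source: str) -> MetabolicNetwork:
    reaction_ids, lbs, ubs = [], [], []
    gpr: dict[str, str] = {}
    cost: dict[str, float] = {}
    status: dict[str, str] = {}
    met_order: list[str] = []
    coeff_rows: list[dict[str, float]] = []
    for k, row in enumerate(rows):
        rid = row["reaction_id"].strip()
        if not rid:
            raise ValidationError(f"{source}: empty reaction_id in data row {k + 1}")
        try:
            coeffs, _rev = _parse_equation(row["equation"])
        except ValidationError as exc:
            raise ValidationError(f"{source}: reaction {rid!r}: {exc}") from None
        lb = float(row["lb"]) if row["lb"].strip() not in ("", "-inf") else -UNBOUNDED
        ub = float(row["ub"]) if row["ub"].strip() not in ("", "inf") else UNBOUNDED
        reaction_ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        coeff_rows.append(coeffs)
        for met in coeffs:
            if met not in met_order:
                met_order.append(met)
        if row.get("gpr", "").strip():
            gpr[rid] = row["gpr"].strip()
        if row.get("cost", "").strip():
            cost[rid] = float(row["cost"])
        if row.get("status", "").strip():
            status[rid] = row["status"].strip()
    stoich = np.zeros((len(met_order), len(reaction_ids)))
    met_index = {m: i for i, m in enumerate(met_order)}
    for j, coeffs in enumerate(coeff_rows):
        for met, c in coeffs.items():
            stoich[met_index[met], j] = c
    return MetabolicNetwork(
        stoich, np.asarray(lbs), np.asarray(ubs), reaction_ids, met_order,
        annotations={"gpr": gpr, "cost": cost, "status": status},
    )


def _load_tabular(path: str) -> MetabolicNetwork:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: empty model file")
    header = lines[0].split("\t")
    if header[:2] != ["reaction_id", "equation"]:
        raise ValidationError(f"{path}: first columns must be reaction_id, equation")
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        cells += [""] * (len(header) - len(cells))
        rows.append(dict(zip(header, cells)))
    return _network_from_tabular_rows(rows, path)


def _load_sbml(path: str) -> MetabolicNetwork:
    """Read an SBML L3/fbc model through cobra; keep raw GPR strings."""
    from cobra.io import read_sbml_model

    model = read_sbml_model(path)
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    met_index = {m: i for i, m in enumerate(mets)}
    stoich = np.zeros((len(mets), len(rxns)))
    lbs, ubs = [], []
    gpr: dict[str, str] = {}
    for j, r in enumerate(model.reactions):
        for met, coef in r.metabolites.items():
            stoich[met_index[met.id], j] = coef
        lbs.append(-UNBOUNDED if r.lower_bound <= -1e30 else r.lower_bound)
        ubs.append(UNBOUNDED if r.upper_bound >= 1e30 else r.upper_bound)
        text = r.gene_reaction_rule
        if text:
            gpr[r.id] = text
    return MetabolicNetwork(
        stoich, np.asarray(lbs), np.asarray(ubs), rxns, mets,
        annotations={"gpr": gpr, "cost": {}, "status": {}},
    )


def load_network(path: str, format: str | None = None) -> MetabolicNetwork:
    """Read a model from the tabular TSV dialect or SBML L3+fbc.

    The format is inferred from the extension (``.xml``/``.sbml`` -> SBML)
    unless given.  GPR rule text, per-reaction costs and targetability are
    returned in ``network.annotations['gpr'|'cost'|'status']``.
    """
    if format is None:
        format = "sbml" if str(path).lower().endswith((".xml", ".sbml")) else "tabular"
    if format == "sbml":
        return _load_sbml(path)
    if format == "tabular":
        return _load_tabular(path)
    raise ValidationError(f"unknown model format {format!r}")


def write_network_tabular(network: MetabolicNetwork, path: str) -> None:
    gpr = network.annotations.get("gpr", {})
    cost = network.annotations.get("cost", {})
    status = network.annotations.get("status", {})
    with open(path, "w") as fh:
        fh.write("\t".join(TABULAR_COLUMNS) + "\n")
        for j, rid in enumerate(network.reaction_ids):
            coeffs = {
                network.metabolite_ids[i]: network.stoich[i, j]
                for i in range(network.n_metabolites)
                if network.stoich[i, j] != 0
            }
            eq = _format_equation(coeffs, reversible=network.lb[j] < 0)
            lb = "-inf" if network.lb[j] == -UNBOUNDED else f"{network.lb[j]:g}"
            ub = "inf" if network.ub[j] == UNBOUNDED else f"{network.ub[j]:g}"
            c = f"{cost[rid]:g}" if rid in cost else ""
            fh.write("\t".join([rid, eq, lb, ub, gpr.get(rid, ""), c, status.get(rid, "")]) + "\n")


# ---------------------------------------------------------------------------
# region config files

_TERM_RE = re.compile(r"([+-]?)\s*(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)?\s*\*?\s*([A-Za-z_][\w.\-]*)")


def parse_linear_row(text: str, network: MetabolicNetwork) -> tuple[np.ndarray, float]:
    """Parse e.g. ``"1.0 R_EX_p - 0.4 R_EX_s <= 0"`` into a ``<=`` row."""
    m = re.split(r"(<=|>=)", text)
    if len(m) != 3:
        raise ValidationError(f"region row {text!r} needs exactly one <= or >=")
    lhs, op, rhs = m[0], m[1], m[2]
    row = np.zeros(network.n_reactions)
    pos = 0
    for match in _TERM_RE.finditer(lhs):
        if match.group(0).strip() == "":
            continue
        sign = -1.0 if match.group(1) == "-" else 1.0
        coef = float(match.group(2)) if match.group(2) else 1.0
        row[network.index(match.group(3))] += sign * coef
        pos = match.end()
    if lhs[pos:].strip():
        raise ValidationError(f"could not parse region row tail {lhs[pos:]!r}")
    const = float(rhs)
    if op == ">=":
        row, const = -row, -const
    return row, const


def load_regions(path: str, network: MetabolicNetwork) -> list[FluxRegion]:
    """Read target/desired regions from a YAML file.

    Layout: a list of mappings with keys ``role`` (target|desired),
    ``label`` and ``rows`` (list of linear inequality strings over
    reaction ids, e.g. ``"1.0 R_EX_p - 0.4 R_EX_s <= 0"``).
    """
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    regions = []
    for entry in spec:
        rows, rhs = [], []
        for text in entry["rows"]:
            row, const = parse_linear_row(str(text), network)
            rows.append(row)
            rhs.append(const)
        region = FluxRegion(entry["role"], np.vstack(rows), np.asarray(rhs),
                            entry.get("label", ""))
        _reject_zero_containing_target(network, region)
        regions.append(region)
    return regions


def save_regions(regions: Sequence[FluxRegion], network: MetabolicNetwork, path: str) -> None:
    import yaml

    out = []
    for reg in regions:
        rows = []
        for k in range(reg.n_rows):
            terms = []
            for j in np.flatnonzero(reg.V[k]):
                c = reg.V[k, j]
                rid = network.reaction_ids[j]
                terms.append(f"{'- ' if c < 0 else '+ ' if terms else ''}{abs(c):g} {rid}")
            rows.append(f"{' '.join(terms)} <= {reg.v[k]:g}")
        out.append({"role": reg.role, "label": reg.label, "rows": rows})
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# cut-set TSV

CUTSET_COLUMNS = ["rank", "cost", "deletions", "additions", "level"]


def write_cutsets_tsv(cutsets: Sequence[CutSet], path: str) -> None:
    ordered = sorted(cutsets, key=CutSet.sort_key)
    with open(path, "w") as fh:
        fh.write("\t".join(CUTSET_COLUMNS) + "\n")
        for k, cs in enumerate(ordered, 1):
            fh.write("\t".join([
                str(k),
                f"{cs.cost:g}",
                ",".join(sorted(cs.deletions)),
                ",".join(sorted(cs.additions)),
                cs.level,
            ]) + "\n")


def read_cutsets_tsv(path: str) -> list[CutSet]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for ln in fh:
            if not ln.strip():
                continue
            row = dict(zip(header, ln.rstrip("\n").split("\t")))
            out.append(CutSet(
                deletions=frozenset(x for x in row["deletions"].split(",") if x),
                additions=frozenset(x for x in row["additions"].split(",") if x),
                cost=float(row["cost"]),
                level=row["level"],
            ))
    return out
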