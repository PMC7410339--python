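"""Gene-protein-reaction (GPR) rules: parsing, network integration, compression.

A GPR rule is a Boolean function over genes in disjunctive normal form
(DNF): OR of conjunctions, isoenzymes contributing alternative conjunctions
and enzyme subunits conjoined within one.  The rule decides whether the
reaction can carry flux given a set of present genes.

Integration translates rules into network structure so that the purely
reaction-based cut-set machinery can act on genes: every gene becomes an
unbounded irreversible *synthesis* pseudo-reaction producing its
enzyme/subunit pseudo-metabolite; every conjunction becomes a *pool-filling*
pseudo-reaction consuming one unit of each member subunit and producing the
reaction-specific enzyme-pool metabolite Q; the metabolic reaction consumes
one unit of its own Q per unit flux.  Because the pool reactions are
unbounded, the feasible flux ranges of the original reactions are exactly
preserved (no isoenzyme flux inflation); reversible reactions are split into
two irreversible directions with mapped bounds, both directions drawing on
the same enzyme species.

Compression applies seven reduction rules (drop rules of blocked reactions,
protect genes that only serve essential reactions or are essential for one,
discard untargetable rules, strip protected genes, minimize the DNF, lump
equivalent genes) so that far fewer binary knockout candidates reach the
MILP; lumped pseudo-genes carry the minimum cost over the gene-deletion
sets that falsify their recorded Boolean expression and are expanded back
after solving.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_model import UNBOUNDED, FluxRegion, MetabolicNetwork, ValidationError

__all__ = [
    "GPRRule",
    "GeneCatalog",
    "GprExtension",
    "parse_gpr",
    "integrate_gpr",
    "compress_gpr",
    "evaluate_dnf",
    "minimal_falsifying_sets",
    "dnf_to_text",
]

DNF = frozenset  # of frozensets of gene ids
TRUE_DNF: frozenset = frozenset({frozenset()})

MAX_DNF_CONJUNCTIONS = 10_000
MAX_LUMP_GENES = 20


@dataclass(frozen=True)
class GPRRule:
    """Boolean gene association of one reaction, held in minimized DNF."""

    reaction_id: str
    dnf: frozenset  # frozenset of frozensets of gene ids

    def __post_init__(self) -> None:
        object.__setattr__(self, "dnf", _absorb(frozenset(frozenset(c) for c in self.dnf)))

    @property
    def is_true(self) -> bool:
        return frozenset() in self.dnf

    @property
    def genes(self) -> frozenset:
        return frozenset(g for c in self.dnf for g in c)

    def evaluate(self, present_genes: Iterable[str]) -> bool:
        return evaluate_dnf(self.dnf, present_genes)


def _absorb(dnf: frozenset) -> frozenset:
    """Remove conjunctions that are supersets of another (absorption law)."""
    conjs = sorted(dnf, key=len)
    kept: list[frozenset] = []
    for c in conjs:
        if not any(k <= c for k in kept):
            kept.append(c)
    return frozenset(kept)


def evaluate_dnf(dnf: frozenset, present_genes: Iterable[str]) -> bool:
    present = set(present_genes)
    return any(c <= present for c in dnf)


def dnf_to_text(dnf: frozenset) -> str:
    if frozenset() in dnf:
        return ""
    parts = []
    for c in sorted(dnf, key=lambda c: sorted(c)):
        inner = " and ".join(sorted(c))
        parts.append(f"({inner})" if len(c) > 1 and len(dnf) > 1 else inner)
    return " or ".join(parts)


# ---------------------------------------------------------------------------
# parsing


def parse_gpr(rule_text: str, reaction_id: str = "", max_conjunctions: int = MAX_DNF_CONJUNCTIONS) -> GPRRule:
    """Parse AND/OR rule text (``&``, ``|``, ``and``, ``or``, parentheses) to DNF.

    An empty rule is the constant-true rule (the reaction needs no enzyme).
    Distribution can blow up exponentially; past ``max_conjunctions`` the
    parse aborts with an explicit error rather than degrading silently.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        return GPRRule(reaction_id, TRUE_DNF)
    dnf, pos = _parse_or(tokens, 0, max_conjunctions)
    if pos != len(tokens):
        raise ValidationError(f"trailing tokens in GPR rule {rule_text!r}")
    return GPRRule(reaction_id, dnf)


def _tokenize(text: str) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()&|":
            out.append(ch)
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()&|":
                j += 1
            word = text[i:j]
            low = word.lower()
            out.append("&" if low == "and" else "|" if low == "or" else word)
            i = j
    return out


def _parse_or(tokens, pos, cap):
    dnf, pos = _parse_and(tokens, pos, cap)
    terms = set(dnf)
    while pos < len(tokens) and tokens[pos] == "|":
        rhs, pos = _parse_and(tokens, pos + 1, cap)
        terms |= rhs
        _check_cap(terms, cap)
    return _absorb(frozenset(terms)), pos


def _parse_and(tokens, pos, cap):
    dnf, pos = _parse_atom(tokens, pos, cap)
    while pos < len(tokens) and tokens[pos] == "&":
        rhs, pos = _parse_atom(tokens, pos + 1, cap)
        dnf = frozenset(a | b for a in dnf for b in rhs)
        _check_cap(dnf, cap)
        dnf = _absorb(dnf)
    return dnf, pos


def _parse_atom(tokens, pos, cap):
    if pos >= len(tokens):
        raise ValidationError("unexpected end of GPR rule")
    tok = tokens[pos]
    if tok == "(":
        dnf, pos = _parse_or(tokens, pos + 1, cap)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValidationError("unbalanced parentheses in GPR rule")
        return dnf, pos + 1
    if tok in ")&|":
        raise ValidationError(f"unexpected token {tok!r} in GPR rule")
    return frozenset({frozenset({tok})}), pos + 1


def _check_cap(dnf, cap):
    if len(dnf) > cap:
        raise ValidationError(
            f"DNF conversion exceeded {cap} conjunctions; the rule is too "
            "entangled for direct distribution"
        )


# ---------------------------------------------------------------------------
# gene catalog


@dataclass
class GeneCatalog:
    """Per-gene cost and targetability, plus lumped pseudo-gene bookkeeping.

    ``lump_map`` maps a lumped pseudo-gene id to its Boolean expression
    (a DNF over *original* gene ids); deleting the pseudo-gene means
    falsifying that expression.  Its cost equals the minimum total deletion
    cost over the expression's minimal falsifying sets.
    """

    cost: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)  # deletable | addable | protected
    lump_map: dict = field(default_factory=dict)

    def cost_of(self, gene: str) -> float:
        return float(self.cost.get(gene, 1.0))

    def status_of(self, gene: str) -> str:
        return self.status.get(gene, "deletable")

    def is_lump(self, gene: str) -> bool:
        return gene in self.lump_map

    def copy(self) -> "GeneCatalog":
        return GeneCatalog(dict(self.cost), dict(self.status), dict(self.lump_map))


def minimal_falsifying_sets(dnf: frozenset, max_size: int | None = None) -> list[frozenset]:
    """All minimal gene-deletion sets that make a DNF expression false.

    A deletion set falsifies the expression iff it hits every conjunction
    (removes at least one gene from each); the result is the family of
    minimal hitting sets, found by exhaustive search over the expression's
    genes (lump expressions are small by construction; a hard cap guards
    against misuse).
    """
    if frozenset() in dnf:
        return []  # constant true can never be falsified
    universe = sorted({g for c in dnf for g in c})
    if len(universe) > MAX_LUMP_GENES:
        raise ValidationError(
            f"expression over {len(universe)} genes exceeds the exhaustive "
            f"hitting-set cap of {MAX_LUMP_GENES}"
        )
    limit = max_size if max_size is not None else len(universe)
    found: list[frozenset] = []
    for size in range(1, limit + 1):
        for combo in itertools.combinations(universe, size):
            s = frozenset(combo)
            if any(f <= s for f in found):
                continue
            if all(c & s for c in dnf):
                found.append(s)
    return found


def lump_cost(expression: frozenset, catalog: GeneCatalog) -> float:
    sets = minimal_falsifying_sets(expression)
    if not sets:
        return math.inf
    return min(sum(catalog.cost_of(g) for g in s) for s in sets)


# ---------------------------------------------------------------------------
# integration into the network (enzyme-pool encoding)


@dataclass
class GprExtension:
    """Bookkeeping of the pseudo-species/reactions added by integration.

    ``split_map`` maps an originally reversible GPR-bearing reaction to its
    forward/backward columns; ``gene_reactions`` maps gene id to its
    synthesis pseudo-reaction id (identical string -- genes and their
    synthesis reactions are in 1:1 correspondence).
    """

    split_map: dict = field(default_factory=dict)
    gene_reactions: dict = field(default_factory=dict)
    pool_species: dict = field(default_factory=dict)     # reaction(dir) id -> Q id
    enzyme_species: dict = field(default_factory=dict)   # gene id -> E id
    pool_reactions: list = field(default_factory=list)   # p reaction ids
    original_reaction_ids: list = field(default_factory=list)
    integrated_reaction_ids: list = field(default_factory=list)

    def projection(self) -> np.ndarray:
        """Matrix P with r_original = P @ r_integrated (original rows)."""
        n_old = len(self.original_reaction_ids)
        n_new = len(self.integrated_reaction_ids)
        idx = {r: j for j, r in enumerate(self.integrated_reaction_ids)}
        P = np.zeros((n_old, n_new))
        for i, rid in enumerate(self.original_reaction_ids):
            if rid in self.split_map:
                fwd, bwd = self.split_map[rid]
                P[i, idx[fwd]] = 1.0
                P[i, idx[bwd]] = -1.0
            else:
                P[i, idx[rid]] = 1.0
        return P

    def map_region(self, region: FluxRegion) -> FluxRegion:
        """Re-express a region given over original reactions on the extension."""
        P = self.projection()
        return FluxRegion(region.role, region.V @ P, region.v.copy(), region.label)

    def is_pseudo(self, rid: str) -> bool:
        return rid in self.gene_reactions or rid in set(self.pool_reactions)


def integrate_gpr(
    network: MetabolicNetwork,
    rules: Sequence[GPRRule],
) -> tuple[MetabolicNetwork, GprExtension]:
    """Wire GPR rules into the stoichiometry via enzyme pools.

    Returns the extended network and the :class:`GprExtension` needed to map
    regions onto it and to translate solutions back.  Constant-true rules
    are skipped (no enzyme requirement).  Flux projections of the original
    reactions are preserved exactly.
    """
    by_rxn: dict[str, GPRRule] = {}
    for rule in rules:
        if rule.reaction_id in by_rxn:
            raise ValidationError(f"duplicate GPR rule for reaction {rule.reaction_id!r}")
        network.index(rule.reaction_id)  # existence check
        if not rule.is_true:
            by_rxn[rule.reaction_id] = rule

    ext = GprExtension(original_reaction_ids=list(network.reaction_ids))
    met_ids = list(network.metabolite_ids)
    met_index = {m: i for i, m in enumerate(met_ids)}
    columns: list[dict[int, float]] = []
    rxn_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add_met(mid: str) -> int:
        if mid in met_index:
            raise ValidationError(f"pseudo-metabolite id collision: {mid!r}")
        met_index[mid] = len(met_ids)
        met_ids.append(mid)
        return met_index[mid]

    def add_rxn(rid: str, col: dict[int, float], lb: float, ub: float) -> None:
        if rid in set(rxn_ids):
            raise ValidationError(f"pseudo-reaction id collision: {rid!r}")
        rxn_ids.append(rid)
        columns.append(col)
        lbs.append(lb)
        ubs.append(ub)

    # original (possibly split) metabolic columns
    directions: dict[str, list[tuple[str, float]]] = {}  # rxn -> [(column id, sign)]
    for j, rid in enumerate(network.reaction_ids):
        base = {i: network.stoich[i, j] for i in range(network.n_metabolites)
                if network.stoich[i, j] != 0}
        if rid in by_rxn and network.lb[j] < 0:
            fwd, bwd = f"{rid}__fwd", f"{rid}__bwd"
            add_rxn(fwd, dict(base), max(0.0, network.lb[j]), max(0.0, network.ub[j]))
            add_rxn(bwd, {i: -c for i, c in base.items()},
                    max(0.0, -network.ub[j]), -network.lb[j])
            ext.split_map[rid] = (fwd, bwd)
            directions[rid] = [(fwd, 1.0), (bwd, -1.0)]
        else:
            add_rxn(rid, dict(base), network.lb[j], network.ub[j])
            directions[rid] = [(rid, 1.0)]

    col_index = {r: j for j, r in enumerate(rxn_ids)}

    # enzyme species, one per gene; synthesis reactions named after the gene
    genes = sorted({g for rule in by_rxn.values() for g in rule.genes})
    for g in genes:
        if g in col_index or g in met_index:
            raise ValidationError(f"gene id {g!r} collides with a network id")
        e_mid = f"E__{g}"
        e_row = add_met(e_mid)
        ext.enzyme_species[g] = e_mid
        add_rxn(g, {e_row: 1.0}, 0.0, UNBOUNDED)
        ext.gene_reactions[g] = g

    # per reaction direction: pool species Q plus one pool-filling p per conjunction
    for rid, rule in sorted(by_rxn.items()):
        for dir_id, _sign in directions[rid]:
            q_row = add_met(f"Q__{dir_id}")
            ext.pool_species[dir_id] = f"Q__{dir_id}"
            columns[col_index[dir_id]][q_row] = columns[col_index[dir_id]].get(q_row, 0.0) - 1.0
            for k, conj in enumerate(sorted(rule.dnf, key=lambda c: sorted(c))):
                p_id = f"p__{dir_id}__{k}"
                col = {q_row: 1.0}
                for g in conj:
                    e_row = met_index[ext.enzyme_species[g]]
                    col[e_row] = col.get(e_row, 0.0) - 1.0
                add_rxn(p_id, col, 0.0, UNBOUNDED)
                ext.pool_reactions.append(p_id)

    stoich = np.zeros((len(met_ids), len(rxn_ids)))
    for j, col in enumerate(columns):
        for i, c in col.items():
            stoich[i, j] = c
    extended = MetabolicNetwork(
        stoich, np.asarray(lbs), np.asarray(ubs), rxn_ids, met_ids,
        extra_A=None if network.extra_A is None else _remap_extra(network, rxn_ids, directions),
        extra_b=None if network.extra_b is None else network.extra_b.copy(),
    )
    ext.integrated_reaction_ids = list(rxn_ids)
    return extended, ext


def _remap_extra(network, rxn_ids, directions):
    idx = {r: j for j, r in enumerate(rxn_ids)}
    A = np.zeros((network.extra_A.shape[0], len(rxn_ids)))
    for i_old, rid in enumerate(network.reaction_ids):
        for cid, sign in directions[rid]:
            A[:, idx[cid]] += sign * network.extra_A[:, i_old]
    return A


# ---------------------------------------------------------------------------
# the seven compression rules


def compress_gpr(
    rules: Sequence[GPRRule],
    gene_catalog: GeneCatalog,
    blocked_rxns: Iterable[str] = (),
    essential_rxns: Iterable[str] = (),
) -> tuple[list[GPRRule], GeneCatalog]:
    """Compress a GPR ruleset given blocked and essential reactions.

    In order: (1) drop rules of blocked reactions; (2) protect genes
    occurring only in rules of essential reactions; (3) protect genes
    essential for at least one essential reaction (present in every
    conjunction of its rule); (4) discard rules holding a conjunction made
    solely of protected genes (the reaction cannot be knocked out);
    (5) strip protected genes from the remaining conjunctions; (6) minimize
    the DNF by absorption; (7) lump equivalent deletion candidates --
    genes always co-occurring in conjunctions, then rule-local disjunctions
    over genes that appear nowhere else -- recording lump expressions and
    re-attributed minimum costs in the returned catalog.

    Idempotent: compressing an already-compressed ruleset is a no-op.
    """
    blocked = set(blocked_rxns)
    essential = set(essential_rxns)
    catalog = gene_catalog.copy()

    # (1)
    live = [r for r in rules if r.reaction_id not in blocked and not r.is_true]

    # (2) occurrence census on surviving rules
    occurs: dict[str, set[str]] = {}
    for rule in live:
        for g in rule.genes:
            occurs.setdefault(g, set()).add(rule.reaction_id)
    protected = {g for g, rxns in occurs.items() if rxns <= essential}

    # (3) essential for an essential reaction: in every conjunction of its rule
    for rule in live:
        if rule.reaction_id in essential:
            protected |= frozenset.intersection(*rule.dnf) if rule.dnf else frozenset()

    for g in protected:
        catalog.status[g] = "protected"

    # (4) + (5) + (6)
    reduced: list[GPRRule] = []
    for rule in live:
        if any(c <= protected for c in rule.dnf):
            continue
        stripped = frozenset(frozenset(c - protected) for c in rule.dnf)
        reduced.append(GPRRule(rule.reaction_id, stripped))  # absorption in ctor

    # (7a) lump genes that always co-occur in conjunctions (plain genes only;
    # pseudo-genes from earlier lumping keep their identity, which also makes
    # the whole procedure idempotent)
    signature: dict[str, list] = {}
    status_of: dict[str, str] = {}
    for ri, rule in enumerate(reduced):
        for ci, conj in enumerate(sorted(rule.dnf, key=lambda c: sorted(c))):
            for g in conj:
                signature.setdefault(g, []).append((ri, ci))
    classes: dict[tuple, list[str]] = {}
    for g, sig in signature.items():
        if catalog.is_lump(g):
            continue
        key = (tuple(sorted(sig)), catalog.status_of(g))
        classes.setdefault(key, []).append(g)
    rename: dict[str, str] = {}
    for (_sig, status), members in sorted(classes.items()):
        if len(members) < 2:
            continue
        members = sorted(members)
        lump_id = "g_(" + "&".join(members) + ")"
        expression = _substituted_expression(frozenset({frozenset(members)}), catalog)
        catalog.lump_map[lump_id] = expression
        catalog.cost[lump_id] = lump_cost(expression, gene_catalog)
        catalog.status[lump_id] = status
        for g in members:
            rename[g] = lump_id
    if rename:
        reduced = [
            GPRRule(r.reaction_id,
                    frozenset(frozenset(rename.get(g, g) for g in c) for c in r.dnf))
            for r in reduced
        ]

    # (7b) rule-local disjunction lumping over genes exclusive to one rule
    occurs2: dict[str, set[str]] = {}
    for rule in reduced:
        for g in rule.genes:
            occurs2.setdefault(g, set()).add(rule.reaction_id)
    final_rules: list[GPRRule] = []
    for rule in reduced:
        if len(rule.dnf) < 2:
            final_rules.append(rule)
            continue
        common = frozenset.intersection(*rule.dnf)
        residuals = [c - common for c in rule.dnf]
        res_genes = {g for c in residuals for g in c}
        exclusive = all(occurs2[g] == {rule.reaction_id} for g in res_genes)
        statuses = {catalog.status_of(g) for g in res_genes}
        if not (exclusive and res_genes and all(c for c in residuals) and len(statuses) == 1):
            final_rules.append(rule)
            continue
        expression = _substituted_expression(frozenset(residuals), catalog)
        lump_id = "g_(" + "|".join(
            "&".join(sorted(c)) for c in sorted(residuals, key=lambda c: sorted(c))
        ) + ")"
        catalog.lump_map[lump_id] = expression
        catalog.cost[lump_id] = lump_cost(expression, gene_catalog)
        catalog.status[lump_id] = statuses.pop()
        final_rules.append(GPRRule(rule.reaction_id, frozenset({common | {lump_id}})))

    return final_rules, catalog


def _substituted_expression(dnf: frozenset, catalog: GeneCatalog) -> frozenset:
    """Expand nested lump members so the expression is over original genes."""
    out: set[frozenset] = set()
    for conj in dnf:
        partial = [frozenset()]
        for g in conj:
            sub = catalog.lump_map.get(g, frozenset({frozenset({g})}))
            partial = [p | c for p in partial for c in sub]
        out.update(partial)
    return _absorb(frozenset(out))
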