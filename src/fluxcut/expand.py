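"""Decompression of cut sets: lumped reactions, lumped genes, redundancy.

A cut set found on a compressed network is a representative of an
equivalence class: each lumped member stands for any one of the original
reactions whose deletion disables the whole lump, and each lumped
pseudo-gene stands for any minimal gene-deletion set falsifying its Boolean
expression.  Expansion enumerates all combinations, recomputes costs from
the original members, discards combinations exceeding the cost budget and
finally removes sets that are strict supersets of other solutions.
Every cut set found in a compressed network expands to at least one cut set
of identical cost in the original network; other expansions may be larger
or more expensive yet remain distinct minimal solutions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core_model import CutSet, InterventionSpec, ValidationError
from .gpr import GeneCatalog, minimal_falsifying_sets
from .netcompress import CompressionRecord

__all__ = [
    "ExpansionResult",
    "expand_reaction_lumps",
    "expand_gene_lumps",
    "filter_redundant",
]


@dataclass
class ExpansionResult:
    """Expansions of one compressed cut set, with over-budget bookkeeping."""

    source: CutSet
    expansions: list = field(default_factory=list)
    discarded_over_budget: int = 0


def expand_reaction_lumps(
    mcs: CutSet,
    record: CompressionRecord,
    spec: InterventionSpec,
) -> list[CutSet]:
    """Replace every lumped deletion by each targetable member reaction.

    Deleting any single member zeroes the whole lump (member fluxes are
    proportional), so each deletable member is an alternative; costs are
    re-attributed from the original members.  Additions pass through
    unchanged -- addable reactions are never lumped.
    """
    lumps = record.lumps()
    alternatives: list[list[tuple[str, float]]] = []
    for rid in sorted(mcs.deletions):
        if rid in lumps:
            options = [
                (orig, spec.cost_of(orig))
                for orig, _coef in lumps[rid]
                if spec.status_of(orig) == "deletable"
            ]
            if not options:
                raise ValidationError(
                    f"lump {rid!r} was deleted but has no deletable member"
                )
            alternatives.append(sorted(options))
        else:
            alternatives.append([(rid, spec.cost_of(rid))])
    out: dict[frozenset, CutSet] = {}
    add_cost = sum(spec.cost_of(a) for a in mcs.additions)
    for combo in itertools.product(*alternatives) if alternatives else [()]:
        deletions = frozenset(rid for rid, _c in combo)
        members = deletions | mcs.additions
        if members not in out:
            out[members] = CutSet(
                deletions, mcs.additions,
                sum(c for _r, c in combo) + add_cost,
                level="reaction",
            )
    return sorted(out.values(), key=CutSet.sort_key)


def expand_gene_lumps(
    mcs: CutSet,
    catalog: GeneCatalog,
    max_cost: float = math.inf,
    cost_of: Callable[[str], float] | None = None,
) -> ExpansionResult:
    """Expand lumped pseudo-genes into original gene interventions.

    A deleted pseudo-gene is replaced by every minimal falsifying set of
    its recorded expression (every disjunct must lose a gene); an added
    pseudo-gene by every minimal satisfying set (one complete disjunct).
    Combinations are taken across lumps, costed on original members, pruned
    at ``max_cost`` (counting discards) and superset-filtered.
    """
    if cost_of is None:
        cost_of = catalog.cost_of

    def options_for(uid: str, role: str) -> list[frozenset]:
        if not catalog.is_lump(uid):
            return [frozenset({uid})]
        expr = catalog.lump_map[uid]
        if role == "deletion":
            sets = minimal_falsifying_sets(expr)
        else:  # addition: enable one full conjunction
            sets = sorted({frozenset(c) for c in expr}, key=sorted)
            sets = [s for s in sets if not any(o < s for o in sets)]
        if not sets:
            raise ValidationError(f"lump {uid!r} has no valid expansion as a {role}")
        return sets

    del_options = [options_for(u, "deletion") for u in sorted(mcs.deletions)]
    add_options = [options_for(u, "addition") for u in sorted(mcs.additions)]
    result = ExpansionResult(source=mcs)
    seen: set[tuple[frozenset, frozenset]] = set()
    for dels in itertools.product(*del_options) if del_options else [()]:
        deletions = frozenset().union(*dels) if dels else frozenset()
        for adds in itertools.product(*add_options) if add_options else [()]:
            additions = frozenset().union(*adds) if adds else frozenset()
            if deletions & additions:
                continue
            key = (deletions, additions)
            if key in seen:
                continue
            seen.add(key)
            cost = sum(cost_of(g) for g in deletions | additions)
            if cost > max_cost + 1e-9:
                result.discarded_over_budget += 1
                continue
            result.expansions.append(CutSet(deletions, additions, cost, level="gene"))
    result.expansions = filter_redundant(result.expansions)
    return result


def filter_redundant(mcs_list: Sequence[CutSet]) -> list[CutSet]:
    """Drop duplicates and strict supersets; stable (cost, members) order."""
    ordered = sorted(mcs_list, key=CutSet.sort_key)
    kept: list[CutSet] = []
    seen: set[tuple[frozenset, frozenset]] = set()
    by_size = sorted(ordered, key=lambda cs: len(cs.members))
    minimal: list[CutSet] = []
    for cs in by_size:
        if any(k.deletions <= cs.deletions and k.additions <= cs.additions
               and k.members != cs.members for k in minimal):
            continue
        minimal.append(cs)
    minimal_keys = {(cs.deletions, cs.additions) for cs in minimal}
    for cs in ordered:
        key = (cs.deletions, cs.additions)
        if key in minimal_keys and key not in seen:
            seen.add(key)
            kept.append(cs)
    return kept
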