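# fluxcut

Minimal cut sets (MCS) for constraint-based metabolic network design.

`fluxcut` computes minimal sets of interventions — reaction or gene
**deletions** and reaction **additions**, each with a user-defined cost —
that reshape the steady-state flux space of a metabolic network: every flux
vector in one or more **target** (undesired) regions becomes infeasible,
while every **desired** region keeps at least one feasible flux vector.
The classic application is growth-coupled production strain design: block
all low-yield flux states while preserving the ability to grow.  Because
arbitrarily many target and desired regions are supported, non-convex
specifications such as substrate co-feeding (where a metabolite may act as
substrate *or* by-product) or multi-condition robustness are expressible
directly.

It is written for systems/metabolic engineers working with
constraint-based models (SBML L3+fbc or a plain TSV dialect) at desk scale,
and as a transparent, fully verified reference implementation of the
algorithm class: every reported solution is re-checked against a plain LP
oracle.

## The model

A network with stoichiometric matrix `N`, flux bounds `lb ≤ r ≤ ub` and
optional extra constraints `A r ≤ b` has the steady-state polyhedron
`{r : N r = 0, lb ≤ r ≤ ub, A r ≤ b}`.  Regions are linear systems over
fluxes:

* target regions `T r ≤ t` (e.g. product yield `r_P − Y·r_S ≤ 0` plus a
  minimum uptake row that excludes `r = 0`, which no knockout can remove);
* desired regions `D r ≤ d` (e.g. growth `r_BM ≥ 0.1`).

Blocking a target region is certified by Farkas duality: the target system
is infeasible iff multipliers `u` (free), `w ≥ 0`, `v` exist with
`Nᵀu + Tᵀw + v = 0` (`≥ 0` on irreversible columns) and `tᵀw ≤ −1`.  Each
`v_i` may be nonzero only if the binary intervention marker `z_i` is set
(inverted for addable reactions), desired regions enter in their primal
form with `z`-gated flux bounds, and the MILP minimizes `Σ p_i z_i`.
Enumeration proceeds by integer cuts `Σ_{j∈C} z_j ≤ |C|−1`.

Two lossless compressions shrink the MILP: seven GPR-rule reduction steps
(drop rules of blocked reactions, protect genes of essential reactions,
strip protected genes, minimize the DNF, lump equivalent genes with
re-attributed minimum costs) and structural network compression (blocked
reactions, conservation relations, one-producer/one-consumer lumping in
exact rational arithmetic).  Solutions found on the compressed network are
expanded back to reaction and gene level afterwards.

## Worked example

The built-in nine-gene example network turns a substrate S into biomass
and two products; the goal is to abolish synthesis of the by-product D by
gene knockouts while keeping growth possible:

```
$ fluxcut fixtures --out-dir fx
$ fluxcut compute fx/gene_pipeline_model.tsv \
      --regions fx/gene_pipeline_regions.yaml --max-cost 3 --out-dir out
step 1: 1 blocked, 3 essential reactions
step 2: 9 -> 4 genes, 6 -> 3 rules
step 4: 2 species, 5 reactions, 3 targetable
step 5: 2 compressed solutions
steps 6-7: 4 expanded solutions (0 over budget)
wrote 4 cut sets to out/mcs.tsv

$ cat out/mcs.tsv
rank    cost    deletions       additions       level
1       1       g4                      gene
2       1       g8                      gene
3       2       g5,g7                   gene
4       2       g7,g9                   gene
```

Reading: FVA finds one blocked reaction (dropped with its rule) and the
growth-essential reactions, whose genes are protected; GPR compression
shrinks nine genes to four (two of them lumped, e.g. the pseudo-gene for
`(g5 ∧ g9) ∨ g7`, which costs 2 because both disjuncts must be falsified).
The MILP on the compressed network returns two representative solutions,
which decompress into the four gene cut sets listed: deleting `g8` (the
gene of the D-forming reaction) or `g4`, `{g5,g7}` or `{g7,g9}` (the
minimal gene sets disabling the upstream route).  `fluxcut verify` replays
the LP checks on any cut-set file; the co-feeding example
(`fx/cofeeding_*`) likewise yields a four-knockout single-substrate design
and a one-deletion-plus-one-addition co-feeding design.

The same machinery is available as a library:

```python
from fluxcut import fig4_bundle, compute_mcs
b = fig4_bundle()
res = compute_mcs(b.network, b.targets, b.desireds, b.spec,
                  b.rules, b.gene_catalog, max_cost=3)
print([sorted(cs.deletions) for cs in res.cutsets])
# [['g4'], ['g8'], ['g5', 'g7'], ['g7', 'g9']]
```

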