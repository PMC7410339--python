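# Methods

## Problem statement

Given a stoichiometric network (`N`, bounds `lb ≤ r ≤ ub`, optional global
linear constraints `A r ≤ b`), a set of *target* regions `T_k r ≤ t_k`
(undesired flux states) and *desired* regions `D_l r ≤ d_l` (states that
must survive), and an intervention specification (per reaction/gene:
deletable, addable or non-targetable, with a nonnegative cost), `fluxcut`
enumerates cost-minimal intervention sets that empty every target region
while keeping every desired region nonempty.  A deletion pins a reaction's
flux to zero in every region; an addable reaction is absent (zero flux) by
default and activates its stated bounds when added.  With gene rules, the
intervenable units are genes acting on reactions through their
gene-protein-reaction (GPR) association.

Target regions must exclude the zero flux vector (`r = 0` survives any
deletion set); region constructors check this at build time and refuse
otherwise, since the MILP would just be silently infeasible.  Following
the region semantics used throughout, finite flux bounds and the global
constraints are folded into each target system, while desired regions keep
the bounds separate (their primal blocks carry them directly).

## MILP construction

Per target region one Farkas block certifies infeasibility of
`{N r = 0, T r ≤ t, r_i ≥ 0 (i ∈ Irrev)}`: variables `u` (free, per
metabolite), `w ≥ 0` (per target row), `v` (per *targetable* reaction)
with `Nᵀu + Tᵀw + v = 0` on reversible columns, `≥ 0` on irreversible
ones, and the normalization `tᵀw ≤ −1` (any positive constant is
equivalent by scaling; 1 is used).  A nonzero `v_i` corresponds to the
knockout equality `r_i = 0` entering the target system, so `v_i` is gated
by the shared binary `z_i`; for irreversible columns only the positive
side of `v_i` needs gating (negative values are slack on a `≥ 0` row).
For addable reactions the gate is inverted (`v_i` free only while
`z_i = 0`).  Non-targetable reactions carry no `v` at all.  The gating is
projected onto two box rows per unit and region
(`−M z ≤ v ≤ M z`, resp. with `1 − z`), which is the linear projection of
the sign-split indicator pair sometimes written with separate positive and
negative markers; the variable count per dual block is therefore
`m + |target rows| + |targetable|`.

Desired regions enter as primal blocks: one flux vector per region with
`N r = 0`, `D r ≤ d`, bounds, and gating rows
`lb(1−z) ≤ r ≤ ub(1−z)` (deletable) or `lb·z ≤ r ≤ ub·z` (addable).
The objective is `Σ p_i z_i`; an optional budget row bounds total cost,
and enumeration adds integer cuts over the support of each found solution.

Bound rows of targetable units that are violated at zero flux (`lb > 0` or
`ub < 0`) are *not* folded into target systems: a knockout would void the
bound together with the reaction, and folding would let the dual "block" a
target merely by deleting a flux-forced reaction.  Dropping the row only
enlarges the system a certificate must refute, so it is sound.  Addable
reactions must have finite activation bounds with `lb ≤ 0`; forced-
activation addables are rejected.

### Big-M and verification

HiGHS (via scipy) has no indicator constraints, so the `v`/`z` linking
uses big-M boxes with `M = 1000` by default on all dual variables, and a
flux surrogate `flux_M = 1000` replaces unbounded limits in primal gating
rows only.  Too small an `M` can only produce *spurious* incumbents, never
hide true ones on these box-bounded duals, and every incumbent is
re-verified by plain LPs (all targets infeasible, all desireds feasible)
before being reported; a verification failure raises with the advice to
increase `M` instead of silently returning an artifact.  Solutions are
additionally support-minimized: a confined MILP (only found interventions
allowed) re-minimizes cost, then a greedy pass drops members — cheapest
first, so zero-cost free riders go before paid cuts — whose removal keeps
the verdict.  In `any_feasible` mode the first incumbent of a pure
feasibility solve is minimized the same way, and integer cuts are posted
against the minimized support so supersets never reappear.

## GPR handling

Rules are parsed from `and`/`or` text into DNF with absorption; the
distribution cap (10,000 conjunctions) aborts pathological rules
explicitly.  Integration follows the enzyme-pool encoding: per gene one
unbounded irreversible synthesis pseudo-reaction (named after the gene;
the two are in 1:1 correspondence) producing a subunit species `E_g`; per
reaction direction a pool species `Q` consumed 1:1 by the reaction; per
conjunction a pool-filling reaction consuming one unit of each member
subunit and producing `Q`.  Subunit species are kept per *gene* rather
than per conjunction: a per-conjunction complex produced independently by
each member gene would structurally break AND semantics, while combining
subunits in the pool reaction realizes it exactly.  Isoenzymes feed the
same pool, so finite flux bounds are never multiplied — the feasible
projection onto original fluxes is preserved exactly (tested via FVA of
the projected net fluxes; per-direction FVA intervals of a split
reversible reaction cannot simply be subtracted because both directions
may idle through the unbounded pool).  Reversible GPR reactions are split
into two irreversible directions with mapped bounds; both directions draw
on the same enzyme species.

### The seven compression steps

Given blocked reactions (FVA on the full network) and essential reactions
(per desired region, FVA interval excluding zero with one sign):
(1) drop rules of blocked reactions; (2) protect genes occurring only in
rules of essential reactions; (3) protect genes present in every
conjunction of an essential reaction's rule; (4) discard rules containing
an all-protected conjunction (the reaction is untargetable through genes);
(5) strip protected genes from remaining conjunctions; (6) minimize by
absorption; (7) lump.  Step 7 runs co-occurrence lumping (genes appearing
in exactly the same conjunctions, same status, original genes only) to a
fixed point first, then rule-local disjunction lumping: if, after
factoring out the genes common to all conjunctions, every residual gene is
exclusive to that rule, the residual disjunction becomes one pseudo-gene.
Co-occurrence lumping is deliberately *not* re-applied afterwards — doing
so would merge the factored common genes with the disjunction lump,
collapsing structure the expansion step is meant to report separately —
and this ordering also makes the whole procedure idempotent.  Occurrence
counts in step 2 ignore rules already dropped in step 1.  A lumped
pseudo-gene records its Boolean expression over original genes; its cost
is the minimum summed cost over the expression's minimal falsifying sets
(minimal hitting sets of the DNF disjuncts, found exhaustively — lump
expressions are rule-local and small; a 20-gene cap guards misuse).

## Network compression

On the integrated network (pseudo- and real reactions alike): blocked
columns are removed; linearly dependent stoichiometry rows (conservation
relations) are dropped by exact rational elimination; then any metabolite
with exactly one producer and one consumer merges its two reactions with
the exact cancelling ratio, iterated to a fixed point.  All arithmetic is
on `fractions.Fraction` (floats rationalized at 1e-9) because row
reduction and scaling are brittle in floating point.  Lump bounds are the
intersection of member intervals mapped through the scalings; bounds are
not FVA-tightened by default (a flag exists) so compression stays purely
structural and invertible.  Addable reactions never join lumps, keeping
activation gating unambiguous.  A lump is deletable iff any member is
(deleting any one member zeroes the proportional ensemble) and carries the
minimum member cost; region matrices and the extra-constraint block are
remapped exactly through the member/coefficient record.  The
`CompressionRecord` is serializable to JSON for audit.

## Expansion

Compressed solutions expand in two stages: each lumped reaction member is
replaced by every deletable member (with its own cost), then each lumped
pseudo-gene by every minimal falsifying set of its expression (for an
*added* pseudo-gene: every minimal satisfying disjunct).  Combinations
exceeding the cost budget are discarded and counted; remaining sets are
deduplicated and superset-filtered (filtering is on by default with a
flag, since equal-cost supersets can arise from zero-cost members).  At
least one expansion always attains the compressed cost, so enumerating at
the compressed level with a budget misses nothing.  Expansions are
provably sound when the compression invariants hold; the pipeline still
re-verifies every final cut set by LP at desk scale (`verify=False`
disables this for larger runs, `--paranoid` controls it on the CLI).

## Fixtures and the oracle

The two reference problems are transcriptions of published example
diagrams whose figures name the species, reactions, targetability and the
resulting intervention sets but not every coefficient; the frozen
stoichiometries were chosen so that the documented solution sets are
reproduced verbatim *and* minimal, and the brute-force oracle confirms on
the co-feeding network that they are the only minimal designs within the
stated budget.  Mechanistically, the co-feeding network couples ATP
formation to a by-metabolite Z drained only by product synthesis, prices
the biomass-precursor branch in ATP, and routes all overflow escapes
through that branch — which is what makes the single deletion r6 plus the
added uptake of U a valid design, and the four escape knockouts the
classical alternative.

Random instances draw a guaranteed substrate→biomass backbone, sparse
unit-coefficient side reactions (occasionally reversible), an optional
addable uptake and small random GPR rules; degenerate draws are resampled.
They emulate desk-scale toy networks, not genome-scale models: unit
coefficients, shallow rules, few compartments, no thermodynamics — so
passing tests demonstrate algorithmic correctness (agreement with
exhaustive LP probing, losslessness of both compressions), not biological
realism or genome-scale performance.  The oracle enumerates every subset
of targetable units within budget by LP feasibility alone, sharing no code
with the MILP path, and refuses instances beyond a subset cap.

## Numerical choices and problem sizes

LP/MILP: HiGHS through scipy; LP feasibility tolerance is the solver
default, blocked/essential calls use an absolute 1e-6 on FVA endpoints;
stoichiometric validation uses exact rationals when inputs are rational,
else 1e-9.  Costs compare with a 1e-9 slack.  Equal-cost tie-breaking
among optima is solver-dependent; all tests compare solution *sets*.
Output ordering is (cost, cardinality, lexicographic members), making runs
byte-reproducible.  The test suite and the acceptance script run the
pipeline on the two reference problems and on ~100 seeded random instances
(≤ ~10 reactions, ≤ 6 genes, budget 3), sizes chosen so the exhaustive
oracle stays exact and the whole suite completes in minutes on one CPU.

## Known limitations

* Big-M linking instead of indicator constraints; pathological scaling
  would surface as verification errors, not wrong answers.
* Desired-region witnesses of unbounded reactions are capped at `flux_M`
  in gating rows; designs needing larger witness fluxes would be missed
  (not an issue at the bound magnitudes used here).
* Genome-scale enumeration is out of the tested envelope: the machinery is
  size-agnostic but the always-on verification and the exhaustive lump
  expansion are tuned for desk scale.
* No thermodynamic/kinetic constraints, no FBA-optimality-biased designs,
  no ranking of solutions by practical criteria.
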