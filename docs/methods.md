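# Methods

## Model

The package operates on the support structure of elementary flux modes
(EMs). A binary mode matrix **B** has one row per mode and one 0/1 entry
per reaction; the binarization of a flux-valued mode e is b_i = 1 iff
|e_i| exceeds a zero tolerance (default 1e-9 — EM files written by
floating-point enumerators carry round-off, so an exact-zero test would
misclassify tiny residuals; a row with no entry above tolerance is an
error, because EMs are non-trivial by definition).

An intervention problem I(T, D, n) consists of a target matrix T, a
desired matrix D over the same ordered reaction namespace, and the
survival threshold n. A cut set I ⊆ reactions is a solution iff

* every target row shares a reaction with I and no proper subset of I
  does (minimal hitting set over the hypergraph of target supports), and
* at least n desired rows (weighted by multiplicity, see below) are
  disjoint from I.

Survival is anti-monotone under inclusion: any subset of a
survival-satisfying cut also satisfies survival. Two consequences are
used throughout: (i) the minimal hitting sets among survival-satisfying
sets are exactly the cMCSs, and (ii) a candidate that violates survival
can be discarded permanently, since all its supersets violate it too.

## Adapted Berge algorithm (`cmcs.berge`)

Target supports are processed as hyperedges in ascending support size
(stable by input index — small edges prune earliest; the result is
provably independent of the order, and a test permutes edges to confirm).
Candidates hitting the new edge are kept; each non-hitting candidate
spawns one extension per edge element. Every extension is tested
**first** against the survival constraint, **then** against minimality
(superset-of-existing-candidate filtering, smaller candidates first).
Candidates become solutions only at termination; there is no streaming
output, mirrored in the API (the full list is returned at once).

Implementation notes: candidates are fixed-width bit masks; each
candidate carries a bit mask of the desired rows it leaves alive, updated
incrementally on extension, so the survival test is an AND plus a
weighted popcount. Superset filtering compares bit masks sorted by
cardinality, so equal-size duplicates deduplicate and a proper superset
is always tested after its subsets are in place.

## Binary integer program (`cmcs.bip`)

Variables: x^i ∈ {0,1} per reaction (1 = kept) and y^d ∈ {0,1} per
desired row (1 = survives). The model maximizes Σ_i x^i subject to

* linkage, per desired row d (one two-sided row):
  ||b_d|| y_d ≤ b_d^T x ≤ ||b_d|| y_d + ||b_d|| − 1.
  With y_d = 1 the lower bound forces every reaction of d kept; with
  y_d = 0 the upper bound becomes a kill constraint on d.
* kill, per target row t: b_t^T x ≤ ||b_t|| − 1 (at least one deletion
  inside t's support).
* survivor count: Σ_d w_d y_d + a ≥ n, where w_d are desired-row
  multiplicities and a the always-surviving pool (below).
* norm bound: Σ_i x^i ≤ previous optimum. Logically redundant but
  carried between iterations to tighten the relaxation.
* exclusion, per previously found cut k: Σ_{i ∈ k} x^i ≥ 1. This forbids
  re-finding k and every deletion-superset of k in one row.

Iterating solve → record cut {i : x^i = 0} → append exclusion enumerates
all cMCSs in non-increasing kept-count (non-decreasing deletion-count)
order. Minimality is implied: if a found cut C had a feasible proper
subset C′, then C′ has a strictly larger objective and cannot itself be
excluded (an excluded C′ would force C to be excluded too), so the solver
would have returned C′ instead.

The MILP backend is an injected callable; the default is
`scipy.optimize.milp` (HiGHS). Solver tie-breaking among equal-norm
optima may vary; the final *set* of solutions cannot, and canonical
ordering (ascending cardinality, then lexicographic by sorted reaction
names) fixes the output order. Per-reaction objective weights are exposed
on the BIP route (they reorder enumeration to prefer experimentally easy
deletions) but default to all ones and carry no test weight; with
non-uniform weights the minimality argument above no longer follows from
the objective alone, so weights are a post-hoc ranking aid, not a
different solution set.

## Compression (`cmcs.preprocess`)

Step 1 — drop every reaction that is zero in all target rows: deleting it
hits nothing, so it appears in no minimal cut. Desired rows emptied by
column removal join the *always-surviving* pool `a` (no remaining
deletion can touch them); the pool enters every survivor count.

Step 2 — a reaction i is essential iff |D| − s^i < n, with s^i the
multiplicity-weighted count of desired rows using i and |D| the weighted
row total plus the always-surviving pool. Essential columns leave the
search space. A target row supported only by essential reactions renders
the problem infeasible (hitting it would violate survival) — reported as
a flag, never an exception.

Step 3 — duplicate target rows collapse; target rows whose support
properly contains another remaining row's support are removed (hitting
the subset hits them for free). The result is an antichain. The scan
buckets rows by cardinality, so only strictly smaller rows are tested as
subsets and the outcome is order-independent.

Step 4 — columns identical across the vertical concatenation of D and T
merge into one representative column (first member in column order).
Identity within T alone is not enough: deleting one member must be
indistinguishable from deleting any other in both matrices.

Steps 1–3 feed each other (essential-column removal creates new
duplicate/superset rows; row removal frees new columns), so they iterate
to a fixpoint. Step 4 runs once at the end: merging identical columns
maps supports bijectively, so it cannot create new Step 1–3
opportunities. Desired rows are also deduplicated into multiplicities
w_d up front — bookkeeping only; survival counting still respects how
many original modes each residual row represents.

Expansion replaces each representative in a compressed cut set by every
member of its group (Cartesian product across groups), deduplicates and
canonically orders. The expanded count is Σ over compressed cuts of the
product of referenced group sizes. A solution-preservation suite checks
`expand(solve(preprocess(P))) == solve(P)` on seeded random problems.

## Classification (`cmcs.classification`)

For growth-coupled production designs, each mode's product and biomass
fluxes are normalized by its total substrate influx; efficiency is their
product. p* is the normalized product secretion of the
maximum-efficiency mode; ties for maximal efficiency resolve p* to the
smallest product secretion among the tied modes, so all of them remain
desirable. Desired = secretion ≥ p*; neutral = product uptake (negative
secretion, typically repressed in the production medium and not worth
targeting); target = the rest, including zero-secretion modes.
Normalization sums raw fluxes over the named substrate reactions without
carbon-atom weighting — identical for single-substrate designs, a
documented caveat for mixed substrates with different carbon counts.

## Synthetic test bed and its limits

`generate_problem` draws uniform-density Bernoulli support matrices
(zero rows repaired by one random activation), seeded explicitly. Default
batch conditions used by the acceptance checks: 200 instances with 4–12
reactions, 1–20 target rows, 0–10 desired rows, density 0.2–0.6 and n
uniform in 0..|D| — small enough that the exponential brute-force oracle
(hard ceiling: 20 reactions) verifies every instance, large enough to
exercise all preprocessing paths, and within a few seconds of run time.
Random supports do not reproduce the correlation structure of genuine
EMs (no stoichiometry, no reversibility splitting, no nested pathway
structure), so passing tests demonstrate the combinatorial correctness
of the solvers on arbitrary binary matrices — not performance or
biological plausibility on real networks. Genome-scale claims (hundreds
of millions of modes) require externally enumerated EM matrices and are
out of scope here, as is EM enumeration itself, SBML parsing, and
runtime benchmarking.

## Numerical and design choices

* Binarization tolerance 1e-9 (absolute), user-overridable.
* Reaction identity is by name at all public interfaces; column
  positions are internal.
* Reversible reactions: a reaction and its split reverse twin are
  distinct columns only if the input presents them so; the tool never
  splits or merges directions.
* The BIP kill constraint is implemented with the ≤ direction
  (b_t^T x ≤ ||b_t|| − 1); the opposite direction would fail to remove
  the target mode.
* MILP solutions are rounded to {0,1} before interpretation; HiGHS
  returns vertex-integral solutions for pure binary programs, so the
  rounding only strips floating-point fuzz.
* Infeasibility (n larger than the protectable desired weight, or a
  target mode hittable only through essential reactions) is a reported
  state carried on the problem/record/report, never an exception.
* Empty target set ⇒ the unique solution is the empty cut set.
* Mode indices in partition files are 0-based.

## Known limitations

* The Berge route's superset filtering is quadratic per edge in the
  candidate count (mitigated by cardinality bucketing); very large
  unconstrained dualizations are better served by specialized
  transversal solvers.
* One MILP solve per enumerated solution plus one final infeasibility
  proof makes the BIP route slower than Berge for bulk enumeration; its
  advantage is early exit (`solution_limit`) with the fewest-deletion
  solutions first.
* The classifier assumes substrate uptake fluxes are recorded positive
  in the mode matrix.
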