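# cmcs — constrained minimal cut sets from elementary flux modes

`cmcs` enumerates **constrained minimal cut sets (cMCSs)**: minimal sets of
reaction knockouts that disable every unwanted flux route through a
metabolic network while protecting a required amount of wanted
functionality. It is aimed at metabolic engineers doing elementary-mode
based strain design — the elementary modes (EMs) themselves are assumed to
be already enumerated by an external tool; this package takes the mode
matrix from there.

## The problem

An elementary mode is a minimal steady-state pathway; for knockout design
only its *support* (the set of active reactions) matters. Given

* a set **T** of *target* modes to eliminate,
* a set **D** of *desired* modes to protect, and
* a survival threshold *n*,

an intervention *I* (a set of deleted reactions) solves the intervention
problem *I(T, D, n)* when

1. *hitting*: every target mode shares at least one reaction with *I*
   (t ∩ I ≠ ∅ for all t ∈ T), and no proper subset of *I* does the same
   (minimality), and
2. *survival*: at least *n* desired modes are untouched by *I*
   (|D_I| ≥ n).

Condition 1 alone is the classical minimal-hitting-set / hypergraph
dualization problem; condition 2 is what makes the cut sets *constrained*.

## What the package provides

* **Adapted Berge algorithm** (`cmcs.berge`) — incremental transversal
  enumeration over target supports, with the survival constraint checked
  *before* the minimality check so infeasible candidates are discarded
  permanently.
* **Iterative binary integer program** (`cmcs.bip`) — maximize the number
  of kept reactions subject to kill, survival-linkage, survivor-count,
  norm-bound and solution-exclusion constraints; re-solving after each
  optimum enumerates all cMCSs sorted by increasing deletions. Backend:
  scipy's HiGHS MILP interface (injectable).
* **Problem compression** (`cmcs.preprocess`) — four reduction steps
  (drop target-unused reactions; remove essential reactions; de-duplicate
  and de-superset target rows; merge duplicate columns) with a complete
  `CompressionRecord`, plus `expand_solutions` to reconstruct the full
  solution set exactly.
* **Mode classification** (`cmcs.classification`) — the efficiency-based
  desired/target/neutral split for growth-coupled production designs.
* **Oracle & synthesis** (`cmcs.oracle_synth`) — a brute-force reference
  solver and a seeded random problem generator; both solver routes are
  continuously tested against the oracle.
* **CLI** — `cmcs classify | preprocess | solve | expand | synth`.

Both routes return identical solution sets; the recommended pipeline
(`cmcs solve`, default) is compression followed by the Berge algorithm.

## Worked example

Take eleven binary modes over eight reactions (`em.tsv`, header + 0/1
rows): five desired modes and six target modes, with at least *n* = 3
desired modes required to survive:

```sh
cmcs solve --em em.tsv --partition partition.json --n 3 \
     --method berge --out cutsets.tsv --report report.json
```

prints

```
1 constrained minimal cut sets -> cutsets.tsv
```

and `cutsets.tsv` contains the single solution

```
R2,R4,R8
```

Deleting R2, R4 and R8 hits all six target modes and leaves exactly three
desired modes operational. The run report shows what compression did
first: 2 reactions (R1, R7) were *essential* — deleting either one alone
would already drop desired survivors below 3, so they leave the search
space — and 3 of the 6 target rows were removed as duplicates/supersets,
leaving a 3-row residual problem:

```json
{
 "targets_before": 6,  "targets_after": 3,
 "desired_before": 5,  "desired_after": 4,
 "essential": 2,
 "compressed_solutions": 1,  "expanded_solutions": 1
}
```

Running the same command with `--method bip` produces a byte-identical
`cutsets.tsv`.

## Scope

EM enumeration, SBML parsing and stoichiometric analysis are out of
scope: inputs are plain-text mode matrices (see `docs/methods.md` for
formats, model details and limitations).
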