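"""Iterative binary integer program for constrained minimal cut sets.

Variables: one binary x^i per reaction (1 = kept, 0 = deleted) and one
binary y^d per desired mode (1 = survives).  The model maximizes the
number of kept reactions subject to

* linkage, per desired row d:   ||b_d|| y_d  <=  b_d^T x  <=  ||b_d|| y_d + ||b_d|| - 1
  (y_d = 1 forces every reaction of d to be kept; y_d = 0 relaxes the
  lower bound and the upper bound becomes a kill constraint on d);
* kill, per target row t:       b_t^T x  <=  ||b_t|| - 1;
* survivor count:               sum_d w_d y_d + always_surviving  >=  n
  (w_d are desired-row multiplicities);
* optional norm bound:          sum_i x^i  <=  previous optimum
  (redundant, but tightens the relaxation between iterations);
* exclusion, per found cut k:   sum_{i deleted in k} x^i  >=  1,
  which simultaneously forbids repeating k and any deletion-superset.

Re-solving after appending each solution's exclusion row enumerates all
cMCSs in non-increasing order of kept reactions, i.e. sorted by
increasing number of deletions.  The MILP backend is an injected
callable; the default uses scipy's HiGHS interface.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .core_types import (
    CutSet,
    InterventionProblem,
    SolveReport,
    canonical_order,
)

__all__ = ["BipModelSpec", "build_bip", "bip_solve_all", "solve_with_scipy"]


@dataclass
class BipModelSpec:
    """One BIP instance: maximize ``objective . v`` over binary v.

    The variable vector v stacks the m kept-reaction indicators x first,
    then the |D| survivor indicators y.  Constraint rows are stored as a
    dense matrix with elementwise lower/upper bounds, with a parallel
    list of human-readable labels.
    """

    reaction_names: tuple[str, ...]
    n_desired: int
    objective: np.ndarray
    constraints: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_names)

    @property
    def n_variables(self) -> int:
        return self.n_reactions + self.n_desired

    def __post_init__(self) -> None:
        n = self.n_variables
        if self.objective.shape != (n,):
            raise ValueError("objective length must match variable count")
        if self.constraints.shape[1:] != (n,):
            raise ValueError("constraint rows must match variable count")
        if len(self.labels) != self.constraints.shape[0]:
            raise ValueError("one label per constraint row required")


def build_bip(
    problem: InterventionProblem,
    previous_solutions: Sequence[CutSet] = (),
    previous_norm: int | None = None,
    weights: Sequence[float] | None = None,
) -> BipModelSpec:
    """Assemble the BIP for one enumeration step.

    ``weights`` optionally scores kept reactions in the objective
    (default all ones); the constraint system is unaffected, so weights
    reorder the enumeration within feasibility, nothing more.
    """
    m = problem.n_reactions
    n_d = problem.desired.n_modes
    n_vars = m + n_d
    names = problem.reaction_names
    name_to_col = {r: i for i, r in enumerate(names)}

    objective = np.zeros(n_vars)
    if weights is None:
        objective[:m] = 1.0
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,):
            raise ValueError("weights must have one entry per reaction")
        objective[:m] = w

    rows: list[np.ndarray] = []
    lower: list[float] = []
    upper: list[float] = []
    labels: list[str] = []

    # linkage pair per desired row: 0 <= b_d.x - ||b_d|| y_d <= ||b_d|| - 1
    for d in range(n_d):
        b_d = problem.desired.entries[d].astype(float)
        norm = float(b_d.sum())
        row = np.zeros(n_vars)
        row[:m] = b_d
        row[m + d] = -norm
        rows.append(row)
        lower.append(0.0)
        upper.append(norm - 1.0)
        labels.append(f"linkage[d{d}]")

    # kill constraint per target row: b_t.x <= ||b_t|| - 1
    for t in range(problem.targets.n_modes):
        b_t = problem.targets.entries[t].astype(float)
        row = np.zeros(n_vars)
        row[:m] = b_t
        rows.append(row)
        lower.append(-np.inf)
        upper.append(float(b_t.sum()) - 1.0)
        labels.append(f"kill[t{t}]")

    # survivor count: sum w_d y_d >= n - always_surviving
    row = np.zeros(n_vars)
    row[m:] = problem.desired.row_multiplicity.astype(float)
    rows.append(row)
    lower.append(float(problem.n - problem.always_surviving))
    upper.append(np.inf)
    labels.append("survivors>=n")

    # redundant norm bound carried between iterations
    if previous_norm is not None:
        row = np.zeros(n_vars)
        row[:m] = 1.0
        rows.append(row)
        lower.append(-np.inf)
        upper.append(float(previous_norm))
        labels.append("norm-bound")

    # exclusion per previous solution: at least one of its deleted
    # reactions must now be kept
    for k, cut in enumerate(previous_solutions):
        row = np.zeros(n_vars)
        for r in cut:
            row[name_to_col[r]] = 1.0
        rows.append(row)
        lower.append(1.0)
        upper.append(np.inf)
        labels.append(f"exclude[{k}]")

    constraints = (
        np.vstack(rows) if rows else np.zeros((0, n_vars))
    )
    return BipModelSpec(
        reaction_names=names,
        n_desired=n_d,
        objective=objective,
        constraints=constraints,
        lower=np.asarray(lower),
        upper=np.asarray(upper),
        labels=labels,
    )


def solve_with_scipy(spec: BipModelSpec) -> np.ndarray | None:
    """Default MILP backend: scipy.optimize.milp (HiGHS).

    Returns the optimal variable assignment rounded to {0,1}, or None
    when the model is infeasible.  Raises ``RuntimeError`` on any other
    solver outcome.
    """
    n = spec.n_variables
    res = milp(
        c=-spec.objective,  # milp minimizes; the model maximizes
        constraints=LinearConstraint(spec.constraints, spec.lower, spec.upper),
        integrality=np.ones(n),
        bounds=Bounds(np.zeros(n), np.ones(n)),
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise RuntimeError(f"MILP backend failed: {res.message}")
    return np.round(res.x).astype(int)


def bip_solve_all(
    problem: InterventionProblem,
    solution_limit: int | None = None,
    use_norm_bound: bool = True,
    weights: Sequence[float] | None = None,
    backend: Callable[[BipModelSpec], np.ndarray | None] = solve_with_scipy,
) -> tuple[list[CutSet], SolveReport]:
    """Enumerate all cMCSs by iterated BIP solves.

    Each optimum's deleted-reaction set becomes a cut set and an
    exclusion constraint; the iteration stops at infeasibility (complete
    enumeration) or after ``solution_limit`` solutions.  Deletion counts
    are non-decreasing along the sequence.
    """
    t0 = time.perf_counter()
    report = SolveReport(method="bip", iterations=0)
    if problem.infeasible:
        report.feasible = False
        report.infeasible_reason = problem.infeasible_reason
        return [], report

    m = problem.n_reactions
    names = problem.reaction_names

    if problem.targets.n_modes == 0:
        # nothing to hit; the empty cut is the unique minimal solution
        cutsets = [CutSet()]
        report.solutions_found = 1
        report.histogram = {0: 1}
        report.timings["solve"] = time.perf_counter() - t0
        return cutsets, report

    solutions: list[CutSet] = []
    norm_bound: int | None = m if use_norm_bound else None
    while solution_limit is None or len(solutions) < solution_limit:
        spec = build_bip(
            problem,
            previous_solutions=solutions,
            previous_norm=norm_bound,
            weights=weights,
        )
        report.iterations += 1
        try:
            assignment = backend(spec)
        except Exception as exc:
            raise RuntimeError(
                f"MILP backend failed at iteration {report.iterations}: {exc}"
            ) from exc
        if assignment is None:
            break
        x = assignment[:m]
        cut = CutSet.of(names[i] for i in np.flatnonzero(x == 0))
        solutions.append(cut)
        if use_norm_bound:
            norm_bound = int(x.sum())

    if not solutions:
        report.feasible = False
        report.infeasible_reason = (
            "no reaction set can hit every target while satisfying the "
            "survival constraint"
        )
    cutsets = canonical_order(solutions)
    report.solutions_found = len(cutsets)
    for cs in cutsets:
        report.histogram[len(cs)] = report.histogram.get(len(cs), 0) + 1
    report.timings["solve"] = time.perf_counter() - t0
    return cutsets, report
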