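"""Brute-force reference solver and synthetic problem generator.

The oracle enumerates reaction subsets in ascending cardinality and
keeps those that hit every target support, leave at least n weighted
desired survivors, and contain no already-kept set.  Because survival is
anti-monotone under set inclusion (a subset of a survival-satisfying cut
also satisfies survival), superset skipping is exact: the kept sets are
precisely the constrained minimal cut sets.  Exponential in the reaction
count, hence guarded to small instances — it is the ground truth the
Berge and BIP routes are tested against, never a production path.

The generator draws uniform-density random binary matrices.  No attempt
is made to mimic the support structure of genuine elementary modes
(steady-state stoichiometry is out of scope); the solvers operate on
arbitrary binary matrices, so uniform fixtures exercise them fully.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_types import (
    BinaryModeMatrix,
    CutSet,
    InterventionProblem,
)

__all__ = ["SynthSpec", "brute_force_cmcs", "generate_problem"]

#: Hard ceiling on reactions for the exponential oracle.
ORACLE_MAX_REACTIONS = 20


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic intervention problem."""

    reactions: int
    n_targets: int
    n_desired: int
    density: float = 0.4
    n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reactions < 1:
            raise ValueError("at least one reaction is required")
        if self.n_targets < 0 or self.n_desired < 0:
            raise ValueError("mode counts must be non-negative")
        if self.n_targets == 0 and self.n_desired == 0:
            raise ValueError("a problem needs at least one mode")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie strictly between 0 and 1")
        if self.n < 0:
            raise ValueError("survival threshold must be non-negative")


def brute_force_cmcs(problem: InterventionProblem) -> list[CutSet]:
    """Enumerate all cMCSs by exhaustive ascending-cardinality search."""
    m = problem.n_reactions
    if m > ORACLE_MAX_REACTIONS:
        raise ValueError(
            f"oracle refuses {m} reactions (> {ORACLE_MAX_REACTIONS}); "
            "exponential enumeration"
        )
    if problem.infeasible:
        return []

    names = problem.reaction_names
    target_rows = problem.targets.entries.astype(bool)
    desired_rows = problem.desired.entries.astype(bool)
    weights = problem.desired.row_multiplicity

    if target_rows.shape[0] and not target_rows.any(axis=1).all():
        return []  # an empty-support target mode can never be hit

    kept: list[frozenset[int]] = []
    results: list[CutSet] = []
    for size in range(m + 1):
        for combo in itertools.combinations(range(m), size):
            cand = frozenset(combo)
            if any(k <= cand for k in kept):
                continue
            cols = list(combo)
            if target_rows.shape[0]:
                if not target_rows[:, cols].any(axis=1).all():
                    continue
            if desired_rows.shape[0] and cols:
                dead = desired_rows[:, cols].any(axis=1)
                alive = int(weights[~dead].sum())
            else:
                alive = int(weights.sum())
            if alive + problem.always_surviving < problem.n:
                continue
            kept.append(cand)
            results.append(CutSet.of(names[i] for i in combo))
    return sorted(results)


def generate_problem(spec: SynthSpec) -> InterventionProblem:
    """Draw a reproducible random intervention problem.

    Rows are Bernoulli(density) with at least one active reaction each
    (a zero row is repaired by activating one uniformly chosen column).
    Desired and target rows are drawn independently.
    """
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"R{i + 1}" for i in range(spec.reactions))

    def draw(n_rows: int) -> np.ndarray:
        block = (rng.random((n_rows, spec.reactions)) < spec.density).astype(
            np.uint8
        )
        for j in np.flatnonzero(~block.any(axis=1)):
            block[j, rng.integers(spec.reactions)] = 1
        return block

    desired = BinaryModeMatrix(draw(spec.n_desired), names)
    targets = BinaryModeMatrix(draw(spec.n_targets), names)
    return InterventionProblem(targets=targets, desired=desired, n=spec.n)
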