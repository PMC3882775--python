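"""Adapted Berge algorithm for constrained minimal cut sets.

Target-mode supports are the hyperedges of a hypergraph; minimal cut
sets are its minimal transversals.  Berge's scheme processes edges
incrementally: candidates hitting the new edge are kept, every other
candidate spawns one extension per edge element, and extensions that are
supersets of surviving candidates are discarded.

The adaptation for intervention problems checks the survival constraint
*before* the (much more expensive) minimality check: an extension that
already kills too many desired modes is discarded permanently, which is
sound because supersets kill weakly more desired modes.  Candidates only
become cut sets at termination — there is no streaming output.
"""

from __future__ import annotations

import time

import numpy as np

from .core_types import (
    BinaryModeMatrix,
    CutSet,
    InterventionProblem,
    SolveReport,
    canonical_order,
)

__all__ = ["berge_cmcs", "count_survivors"]


def count_survivors(
    cut: CutSet, desired: BinaryModeMatrix, always_surviving: int = 0
) -> int:
    """Weighted count of desired modes untouched by ``cut``.

    A mode survives iff its support is disjoint from the cut; modes in
    the always-surviving pool (emptied by preprocessing) survive any cut.
    """
    if desired.n_modes == 0:
        return always_surviving
    cols = [desired.column_index(r) for r in cut if r in desired.reaction_names]
    if not cols:
        return always_surviving + desired.total_weight
    hit = desired.entries[:, cols].any(axis=1)
    return always_surviving + int(desired.row_multiplicity[~hit].sum())


def berge_cmcs(
    problem: InterventionProblem,
) -> tuple[list[CutSet], SolveReport]:
    """Enumerate all cMCSs of ``problem`` by the adapted Berge algorithm.

    Edges are processed in ascending support size (stable by input
    index); the output set is independent of that order.  An infeasible
    problem yields an empty list and a report, never an exception.
    """
    t0 = time.perf_counter()
    report = SolveReport(method="berge")
    if problem.infeasible:
        report.feasible = False
        report.infeasible_reason = problem.infeasible_reason
        return [], report

    names = problem.reaction_names
    targets = problem.targets
    desired = problem.desired

    # edge masks over reaction bits, sorted by ascending support size
    edge_rows = sorted(
        range(targets.n_modes), key=lambda j: int(targets.entries[j].sum())
    )
    edges = []
    for j in edge_rows:
        mask = 0
        for i in np.flatnonzero(targets.entries[j]):
            mask |= 1 << int(i)
        edges.append(mask)

    if any(mask == 0 for mask in edges):
        report.feasible = False
        report.infeasible_reason = (
            "a target mode has empty support and can never be hit"
        )
        return [], report

    # per reaction: bitmask (over desired rows) of modes NOT using it;
    # a candidate's surviving desired rows are the AND over its reactions
    n_d = desired.n_modes
    all_desired = (1 << n_d) - 1
    not_using = []
    for i in range(problem.n_reactions):
        mask = all_desired
        for j in np.flatnonzero(desired.entries[:, i]):
            mask &= ~(1 << int(j))
        not_using.append(mask)
    weights = desired.row_multiplicity

    def survivors(alive_mask: int) -> int:
        total = problem.always_surviving
        mask = alive_mask
        while mask:
            j = (mask & -mask).bit_length() - 1
            total += int(weights[j])
            mask &= mask - 1
        return total

    # candidates as (reaction mask, surviving desired-row mask)
    candidates: list[tuple[int, int]] = [(0, all_desired)]
    for edge in edges:
        keep = [(c, alive) for c, alive in candidates if c & edge]
        extensions: list[tuple[int, int]] = []
        for c, alive in candidates:
            if c & edge:
                continue
            e = edge
            while e:
                bit = e & -e
                e &= e - 1
                cand = c | bit
                new_alive = alive & not_using[bit.bit_length() - 1]
                # constraint first: survival check before minimality
                if survivors(new_alive) < problem.n:
                    continue
                extensions.append((cand, new_alive))
        # minimality second: superset filtering, smaller candidates first
        extensions.sort(key=lambda item: item[0].bit_count())
        kept_masks = [c for c, _ in keep]
        accepted: list[tuple[int, int]] = []
        for cand, alive in extensions:
            if any(k & cand == k for k in kept_masks):
                continue
            if any(a & cand == a for a, _ in accepted):
                continue
            accepted.append((cand, alive))
        candidates = keep + accepted

    cutsets = canonical_order(
        CutSet.of(names[i] for i in _bits(c)) for c, _ in candidates
    )
    report.solutions_found = len(cutsets)
    for cs in cutsets:
        report.histogram[len(cs)] = report.histogram.get(len(cs), 0) + 1
    report.timings["solve"] = time.perf_counter() - t0
    return cutsets, report


def _bits(mask: int):
    while mask:
        yield (mask & -mask).bit_length() - 1
        mask &= mask - 1
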