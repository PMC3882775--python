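"""Problem compression for cMCS enumeration, with exact expansion.

Four reduction steps shrink an intervention problem I(T, D, n) without
changing its solution set:

1. drop reactions inactive in every target mode (deleting them hits
   nothing, so they can never appear in a minimal cut);
2. remove *essential* reactions — those whose single deletion already
   leaves fewer than n surviving desired modes — from the search space;
3. collapse duplicate target rows and discard target rows whose support
   is a proper superset of another's (hitting the subset hits them too);
4. merge reaction columns that are identical across the concatenation of
   D and T; deleting any member of such a group is interchangeable, so
   the compressed problem carries one representative column and the
   solutions are re-expanded by Cartesian product afterwards.

Steps 1-3 feed each other (removing essential columns creates new
duplicate/superset rows, removing rows frees new columns), so they are
iterated to a fixpoint before the final column merge.  Every edit is
logged in a :class:`CompressionRecord` so :func:`expand_solutions` can
reconstruct the complete cut-set list of the original problem.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_types import BinaryModeMatrix, CutSet, InterventionProblem, canonical_order

__all__ = [
    "CompressionRecord",
    "drop_unused_reactions",
    "find_essential_reactions",
    "remove_essential",
    "dedup_and_desupset_targets",
    "merge_duplicate_columns",
    "preprocess",
    "expand_solutions",
]

RECORD_VERSION = 1


@dataclass
class CompressionRecord:
    """Ordered log of every preprocessing transformation.

    ``merged_columns`` maps each representative name to the ordered list
    of member names it stands for (the representative is the first
    member).  ``removed_target_rows`` keeps (original row index, reason)
    pairs with reason ``duplicate`` or ``superset``.
    """

    dropped_unused: list[str] = field(default_factory=list)
    essential: list[str] = field(default_factory=list)
    removed_target_rows: list[tuple[int, str]] = field(default_factory=list)
    merged_columns: list[dict] = field(default_factory=list)
    always_surviving: int = 0
    infeasible: bool = False
    infeasible_reason: str | None = None
    version: int = RECORD_VERSION

    def __post_init__(self) -> None:
        for group in self.merged_columns:
            if len(group["members"]) < 2:
                raise ValueError("merged column groups must have >= 2 members")
        overlap = (
            set(self.dropped_unused)
            & set(self.essential)
            | set(self.dropped_unused) & self._merged_members()
            | set(self.essential) & self._merged_members()
        )
        if overlap:
            raise ValueError(
                f"reactions logged in more than one disposition: {sorted(overlap)}"
            )

    def _merged_members(self) -> set[str]:
        return {m for g in self.merged_columns for m in g["members"]}

    def group_for(self, representative: str) -> list[str] | None:
        for group in self.merged_columns:
            if group["representative"] == representative:
                return list(group["members"])
        return None

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "dropped_unused": list(self.dropped_unused),
            "essential": list(self.essential),
            "removed_target_rows": [
                {"row": r, "reason": why} for r, why in self.removed_target_rows
            ],
            "merged_columns": [
                {
                    "representative": g["representative"],
                    "members": list(g["members"]),
                }
                for g in self.merged_columns
            ],
            "always_surviving": self.always_surviving,
            "infeasible": self.infeasible,
            "infeasible_reason": self.infeasible_reason,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CompressionRecord":
        version = data.get("version", RECORD_VERSION)
        if version != RECORD_VERSION:
            raise ValueError(f"unsupported compression record version {version}")
        return cls(
            dropped_unused=list(data.get("dropped_unused", [])),
            essential=list(data.get("essential", [])),
            removed_target_rows=[
                (int(item["row"]), str(item["reason"]))
                for item in data.get("removed_target_rows", [])
            ],
            merged_columns=[
                {
                    "representative": g["representative"],
                    "members": list(g["members"]),
                }
                for g in data.get("merged_columns", [])
            ],
            always_surviving=int(data.get("always_surviving", 0)),
            infeasible=bool(data.get("infeasible", False)),
            infeasible_reason=data.get("infeasible_reason"),
        )


def _drop_columns(
    problem: InterventionProblem, drop: Sequence[int]
) -> tuple[InterventionProblem, int]:
    """Remove columns from T and D; desired rows emptied thereby become
    always-surviving.  Returns the new problem and the count of target
    rows emptied (a nonzero count means infeasibility for essential
    removals)."""
    keep = [i for i in range(problem.n_reactions) if i not in set(drop)]
    targets = problem.targets.select_columns(keep)
    desired = problem.desired.select_columns(keep)

    newly_safe = 0
    if desired.n_modes:
        alive = desired.entries.any(axis=1)
        newly_safe = int(desired.row_multiplicity[~alive].sum())
        desired = desired.select_rows(np.flatnonzero(alive))

    emptied_targets = 0
    if targets.n_modes:
        emptied_targets = int((~targets.entries.any(axis=1)).sum())

    new_problem = InterventionProblem(
        targets=targets,
        desired=desired,
        n=problem.n,
        always_surviving=problem.always_surviving + newly_safe,
        infeasible=problem.infeasible,
        infeasible_reason=problem.infeasible_reason,
    )
    return new_problem, emptied_targets


def drop_unused_reactions(
    problem: InterventionProblem,
) -> tuple[InterventionProblem, list[str]]:
    """Step 1: drop reactions that are zero in every target mode.

    With an empty target set every column is unused and the problem is
    trivially solved by the empty cut.
    """
    if problem.targets.n_modes == 0:
        unused = list(range(problem.n_reactions))
    else:
        unused = np.flatnonzero(~problem.targets.entries.any(axis=0)).tolist()
    names = [problem.reaction_names[i] for i in unused]
    if not unused:
        return problem, []
    new_problem, _ = _drop_columns(problem, unused)
    return new_problem, names


def find_essential_reactions(problem: InterventionProblem) -> list[str]:
    """Step 2 test: reaction i is essential iff |D| - s^i < n.

    s^i is the multiplicity-weighted count of desired modes using i; |D|
    counts weighted desired rows plus the always-surviving pool.
    """
    s = problem.desired.column_sums()
    total = problem.max_survivors
    essential = np.flatnonzero(total - s < problem.n)
    return [problem.reaction_names[i] for i in essential]


def remove_essential(
    problem: InterventionProblem, essentials: Sequence[str]
) -> tuple[InterventionProblem, list[str]]:
    """Step 2: remove essential columns from the search space.

    A target mode supported only on essential reactions can never be hit
    without violating the survival constraint; the problem is then
    flagged infeasible (a reported state, not an exception).
    """
    if not essentials:
        return problem, []
    cols = [problem.targets.column_index(name) for name in essentials]
    new_problem, emptied_targets = _drop_columns(problem, cols)
    if emptied_targets:
        new_problem.infeasible = True
        new_problem.infeasible_reason = (
            f"{emptied_targets} target mode(s) are supported only by "
            "essential reactions; hitting them would violate the survival "
            "constraint"
        )
    return new_problem, list(essentials)


def dedup_and_desupset_targets(
    targets: BinaryModeMatrix,
    row_ids: Sequence[int] | None = None,
) -> tuple[BinaryModeMatrix, list[tuple[int, str]], list[int]]:
    """Step 3: collapse duplicate target rows, discard superset rows.

    Returns the reduced matrix (an antichain of supports), the removal
    log as (row id, reason) pairs, and the ids of surviving rows.
    ``row_ids`` labels rows in the log (defaults to positional indices).
    """
    ids = list(row_ids) if row_ids is not None else list(range(targets.n_modes))
    if len(ids) != targets.n_modes:
        raise ValueError("row_ids must label every target row")

    masks = [_row_mask(row) for row in targets.entries]
    removed: list[tuple[int, str]] = []

    seen: dict[int, int] = {}
    survivors: list[int] = []
    for j, mask in enumerate(masks):
        if mask in seen:
            removed.append((ids[j], "duplicate"))
        else:
            seen[mask] = j
            survivors.append(j)

    # cardinality bucketing: only strictly smaller supports can be proper subsets
    order = sorted(survivors, key=lambda j: int(targets.entries[j].sum()))
    kept: list[int] = []
    for j in order:
        mask = masks[j]
        if any(masks[k] & mask == masks[k] for k in kept):
            removed.append((ids[j], "superset"))
        else:
            kept.append(j)

    kept_in_input_order = [j for j in survivors if j in set(kept)]
    reduced = targets.select_rows(kept_in_input_order)
    removed.sort(key=lambda item: ids.index(item[0]))
    return reduced, removed, [ids[j] for j in kept_in_input_order]


def merge_duplicate_columns(
    problem: InterventionProblem,
) -> tuple[InterventionProblem, list[dict]]:
    """Step 4: merge columns identical across the stack of D over T.

    Columns identical within T but differing within D are left apart —
    deleting one member must be indistinguishable from deleting any
    other in *both* sets for the merge to preserve solutions.
    """
    stacked = np.vstack([problem.desired.entries, problem.targets.entries])
    m = problem.n_reactions
    groups: dict[bytes, list[int]] = {}
    for i in range(m):
        groups.setdefault(stacked[:, i].tobytes(), []).append(i)

    merged: list[dict] = []
    drop: set[int] = set()
    for cols in groups.values():
        if len(cols) >= 2:
            members = [problem.reaction_names[i] for i in cols]
            merged.append({"representative": members[0], "members": members})
            drop.update(cols[1:])
    if not merged:
        return problem, []

    keep = [i for i in range(m) if i not in drop]
    new_problem = InterventionProblem(
        targets=problem.targets.select_columns(keep),
        desired=problem.desired.select_columns(keep),
        n=problem.n,
        always_surviving=problem.always_surviving,
        infeasible=problem.infeasible,
        infeasible_reason=problem.infeasible_reason,
    )
    return new_problem, merged


def _dedup_desired_rows(problem: InterventionProblem) -> InterventionProblem:
    """Fold identical desired rows into multiplicities (counts preserved)."""
    desired = problem.desired
    if desired.n_modes <= 1:
        return problem
    groups: dict[bytes, list[int]] = {}
    for j in range(desired.n_modes):
        groups.setdefault(desired.entries[j].tobytes(), []).append(j)
    if all(len(rows) == 1 for rows in groups.values()):
        return problem
    first_rows = sorted(rows[0] for rows in groups.values())
    weights = {
        rows[0]: int(desired.row_multiplicity[rows].sum())
        for rows in groups.values()
    }
    folded = BinaryModeMatrix(
        desired.entries[first_rows],
        desired.reaction_names,
        np.array([weights[j] for j in first_rows], dtype=np.int64),
    )
    return InterventionProblem(
        targets=problem.targets,
        desired=folded,
        n=problem.n,
        always_surviving=problem.always_surviving,
        infeasible=problem.infeasible,
        infeasible_reason=problem.infeasible_reason,
    )


def preprocess(
    problem: InterventionProblem,
) -> tuple[InterventionProblem, CompressionRecord]:
    """Run Steps 1-4 (1-3 to fixpoint) and return the compressed problem.

    The returned :class:`CompressionRecord` holds everything
    :func:`expand_solutions` needs to reconstruct the full solution set;
    infeasibility discovered along the way is propagated as a flag.
    """
    record = CompressionRecord()
    current = _dedup_desired_rows(problem)
    target_ids = list(range(current.targets.n_modes))

    if current.infeasible:
        record.infeasible = True
        record.infeasible_reason = current.infeasible_reason
        record.always_surviving = current.always_surviving
        return current, record

    while True:
        changed = False

        current, dropped = drop_unused_reactions(current)
        if dropped:
            record.dropped_unused.extend(dropped)
            changed = True

        essentials = find_essential_reactions(current)
        if essentials:
            current, removed = remove_essential(current, essentials)
            record.essential.extend(removed)
            changed = True
            if current.infeasible:
                break

        reduced, removed_rows, target_ids_new = dedup_and_desupset_targets(
            current.targets, target_ids
        )
        if removed_rows:
            record.removed_target_rows.extend(removed_rows)
            target_ids = target_ids_new
            current = InterventionProblem(
                targets=reduced,
                desired=current.desired,
                n=current.n,
                always_surviving=current.always_surviving,
                infeasible=current.infeasible,
                infeasible_reason=current.infeasible_reason,
            )
            changed = True

        if not changed:
            break

    if not current.infeasible:
        current, merged = merge_duplicate_columns(current)
        record.merged_columns.extend(merged)

    record.always_surviving = current.always_surviving
    record.infeasible = current.infeasible
    record.infeasible_reason = current.infeasible_reason
    return current, record


def expand_solutions(
    compressed_cutsets: Iterable[CutSet], record: CompressionRecord
) -> list[CutSet]:
    """Reconstruct the full cut-set list from compressed solutions.

    Each representative reaction in a cut set expands to the Cartesian
    product over its merged group's members; all other reactions pass
    through.  Output is deduplicated and canonically ordered.  A cut set
    naming a merged member that is not its group's representative raises
    ``KeyError`` (such a column no longer exists in the compressed
    namespace).
    """
    group_of = {g["representative"]: list(g["members"]) for g in record.merged_columns}
    hidden_members = {
        m for g in record.merged_columns for m in g["members"][1:]
    }
    expanded: list[CutSet] = []
    for cs in compressed_cutsets:
        choices = []
        for name in cs.sorted_names:
            if name in group_of:
                choices.append(group_of[name])
            elif name in hidden_members:
                raise KeyError(
                    f"cut set references {name!r}, a merged column member; "
                    "only group representatives exist in the compressed problem"
                )
            else:
                choices.append([name])
        for combo in itertools.product(*choices):
            expanded.append(CutSet.of(combo))
    return canonical_order(expanded)


def _row_mask(row: np.ndarray) -> int:
    mask = 0
    for i in np.flatnonzero(row):
        mask |= 1 << int(i)
    return mask
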