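"""Shared data model for constrained minimal cut set (cMCS) problems.

An elementary flux mode (EM) is a minimal steady-state pathway through a
metabolic network.  For cut-set purposes only the *support* of a mode
matters: the set of reactions carrying nonzero flux.  A mode is "hit" by an
intervention (a set of reaction deletions) if at least one of its support
reactions is deleted.  The intervention problem I(T, D, n) asks for all
inclusion-minimal reaction sets that hit every target mode in T while
leaving at least n desired modes of D untouched.

This module holds the containers shared by every solver and preprocessing
step: binary mode matrices, flux-valued mode matrices, intervention
problems and cut sets, plus the binarization that maps flux vectors to
supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BinaryModeMatrix",
    "FluxModeMatrix",
    "InterventionProblem",
    "CutSet",
    "SolveReport",
    "binarize",
    "support_size",
]

#: Default magnitude below which a flux value counts as zero when
#: binarizing.  EM enumerators work in floating point, so exact zeros
#: cannot be relied upon.
DEFAULT_ZERO_TOLERANCE = 1e-9


def _check_names(reaction_names: Sequence[str], n_cols: int) -> tuple[str, ...]:
    names = tuple(str(n) for n in reaction_names)
    if len(names) != n_cols:
        raise ValueError(
            f"got {len(names)} reaction names for {n_cols} matrix columns"
        )
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate reaction names: {dupes}")
    return names


@dataclass
class BinaryModeMatrix:
    """Modes-by-reactions 0/1 matrix with named columns.

    Rows are mode supports; ``row_multiplicity`` counts how many original
    modes each row represents (identical desired modes are merged during
    preprocessing, and survival counting must still weight them).
    """

    entries: np.ndarray
    reaction_names: tuple[str, ...]
    row_multiplicity: np.ndarray | None = None

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        if entries.size and not np.isin(entries, (0, 1)).all():
            raise ValueError("entries must contain only 0 and 1")
        self.entries = entries.astype(np.uint8, copy=False)
        self.reaction_names = _check_names(self.reaction_names, entries.shape[1])
        if self.row_multiplicity is None:
            mult = np.ones(entries.shape[0], dtype=np.int64)
        else:
            mult = np.asarray(self.row_multiplicity, dtype=np.int64)
            if mult.shape != (entries.shape[0],):
                raise ValueError("row_multiplicity must have one entry per row")
            if entries.size or mult.size:
                if (mult < 1).any():
                    raise ValueError("row multiplicities must be >= 1")
        self.row_multiplicity = mult

    # -- basic geometry -------------------------------------------------
    @property
    def n_modes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.entries.shape[1]

    @property
    def total_weight(self) -> int:
        """Number of original modes represented (multiplicity sum)."""
        return int(self.row_multiplicity.sum())

    def column_index(self, name: str) -> int:
        try:
            return self.reaction_names.index(name)
        except ValueError:
            raise KeyError(f"unknown reaction {name!r}") from None

    def supports(self) -> list[frozenset[str]]:
        """Row supports as sets of reaction names."""
        names = np.asarray(self.reaction_names, dtype=object)
        return [frozenset(names[row.astype(bool)]) for row in self.entries]

    def column_sums(self) -> np.ndarray:
        """Multiplicity-weighted column sums (the s vector of Step 2)."""
        if self.n_modes == 0:
            return np.zeros(self.n_reactions, dtype=np.int64)
        return self.row_multiplicity @ self.entries

    # -- structural edits (return new matrices) -------------------------
    def select_columns(self, keep: Sequence[int]) -> "BinaryModeMatrix":
        keep = list(keep)
        return BinaryModeMatrix(
            self.entries[:, keep],
            tuple(self.reaction_names[i] for i in keep),
            self.row_multiplicity.copy(),
        )

    def select_rows(self, keep: Sequence[int]) -> "BinaryModeMatrix":
        keep = list(keep)
        return BinaryModeMatrix(
            self.entries[keep, :],
            self.reaction_names,
            self.row_multiplicity[keep],
        )

    @classmethod
    def from_supports(
        cls,
        supports: Iterable[Iterable[str]],
        reaction_names: Sequence[str],
    ) -> "BinaryModeMatrix":
        """Build a matrix from named row supports over a fixed namespace."""
        names = tuple(reaction_names)
        index = {n: i for i, n in enumerate(names)}
        rows = []
        for sup in supports:
            row = np.zeros(len(names), dtype=np.uint8)
            for r in sup:
                row[index[r]] = 1
            rows.append(row)
        entries = (
            np.vstack(rows) if rows else np.zeros((0, len(names)), dtype=np.uint8)
        )
        return cls(entries, names)


@dataclass
class FluxModeMatrix:
    """Modes-by-reactions matrix of signed real flux values."""

    entries: np.ndarray
    reaction_names: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        self.entries = entries
        self.reaction_names = _check_names(self.reaction_names, entries.shape[1])
        zero_rows = np.flatnonzero(~(entries != 0).any(axis=1))
        if zero_rows.size:
            raise ValueError(
                f"mode row(s) {zero_rows.tolist()} are entirely zero; "
                "elementary modes are non-trivial flux distributions"
            )

    @property
    def n_modes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.entries.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.reaction_names.index(name)
        except ValueError:
            raise KeyError(f"unknown reaction {name!r}") from None


@dataclass(frozen=True, order=True)
class CutSet:
    """A set of reactions deleted by an intervention.

    Sorting/equality go through the canonical (cardinality, sorted names)
    key so lists of cut sets order deterministically.
    """

    sort_index: tuple[int, tuple[str, ...]] = field(init=False, repr=False)
    deleted_reactions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "deleted_reactions", frozenset(self.deleted_reactions)
        )
        object.__setattr__(
            self,
            "sort_index",
            (len(self.deleted_reactions), tuple(sorted(self.deleted_reactions))),
        )

    @classmethod
    def of(cls, reactions: Iterable[str]) -> "CutSet":
        return cls(frozenset(reactions))

    def __len__(self) -> int:
        return len(self.deleted_reactions)

    def __contains__(self, reaction: str) -> bool:
        return reaction in self.deleted_reactions

    def __iter__(self) -> Iterator[str]:
        return iter(self.sorted_names)

    @property
    def sorted_names(self) -> tuple[str, ...]:
        return self.sort_index[1]

    def issubset(self, other: "CutSet") -> bool:
        return self.deleted_reactions <= other.deleted_reactions

    def issuperset(self, other: "CutSet") -> bool:
        return self.deleted_reactions >= other.deleted_reactions


def canonical_order(cutsets: Iterable[CutSet]) -> list[CutSet]:
    """Ascending cardinality, then lexicographic by sorted reaction names."""
    return sorted(set(cutsets))


@dataclass
class InterventionProblem:
    """The triple (T, D, n) plus preprocessing bookkeeping.

    ``always_surviving`` counts desired modes whose entire support was
    removed by preprocessing; no remaining deletion can touch them, so
    they survive any cut and are added to every survivor count.
    """

    targets: BinaryModeMatrix
    desired: BinaryModeMatrix
    n: int = 0
    always_surviving: int = 0
    infeasible: bool = False
    infeasible_reason: str | None = None

    def __post_init__(self) -> None:
        if self.targets.reaction_names != self.desired.reaction_names:
            raise ValueError(
                "targets and desired must share identical reaction names "
                "in identical order"
            )
        if self.n < 0:
            raise ValueError("survival threshold n must be non-negative")
        if self.always_surviving < 0:
            raise ValueError("always_surviving must be non-negative")
        if not self.infeasible and self.n > self.max_survivors:
            self.infeasible = True
            self.infeasible_reason = (
                f"n={self.n} exceeds the {self.max_survivors} desired modes "
                "available to survive"
            )

    @property
    def reaction_names(self) -> tuple[str, ...]:
        return self.targets.reaction_names

    @property
    def n_reactions(self) -> int:
        return self.targets.n_reactions

    @property
    def max_survivors(self) -> int:
        """|D| in survival arithmetic: weighted rows plus always-surviving."""
        return self.desired.total_weight + self.always_surviving


@dataclass
class SolveReport:
    """Outcome summary of a solver run."""

    method: str
    feasible: bool = True
    solutions_found: int = 0
    histogram: dict[int, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    iterations: int | None = None
    infeasible_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "feasible": self.feasible,
            "solutions_found": self.solutions_found,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "timings": self.timings,
            "iterations": self.iterations,
            "infeasible_reason": self.infeasible_reason,
        }


def binarize(
    flux_modes: FluxModeMatrix,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
) -> BinaryModeMatrix:
    """Map flux vectors to their binary supports.

    Entry (j, i) becomes 1 exactly when ``|flux(j, i)| > zero_tolerance``.
    A row with no entry above tolerance violates the non-triviality of
    elementary modes and raises ``ValueError`` naming the row.
    """
    if zero_tolerance < 0:
        raise ValueError("zero_tolerance must be non-negative")
    binary = (np.abs(flux_modes.entries) > zero_tolerance).astype(np.uint8)
    empty = np.flatnonzero(~binary.any(axis=1))
    if empty.size:
        raise ValueError(
            f"mode row(s) {empty.tolist()} have no flux above tolerance "
            f"{zero_tolerance}; elementary modes are non-trivial"
        )
    return BinaryModeMatrix(binary, flux_modes.reaction_names)


def support_size(mode_row: np.ndarray) -> int:
    """Number of active reactions in a binary mode row (the norm ||b||)."""
    row = np.asarray(mode_row)
    if row.size and not np.isin(row, (0, 1)).all():
        raise ValueError("mode row must be binary")
    return int(row.sum())
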