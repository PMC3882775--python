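"""Readers and writers for EM matrices, mode partitions, and cut-set results.

Formats are deliberately plain text:

* EM matrix — first line a header of reaction names, then one
  whitespace/tab-delimited numeric row per mode (``tsv_flux`` for signed
  fluxes, ``tsv_binary`` for 0/1 supports).
* Partition — JSON or YAML mapping ``desired`` / ``target`` / ``neutral``
  to 0-based row-index lists.
* Cut sets — TSV (one comma-separated cut set per line, ``#`` metadata
  comments) or JSON (metadata header plus list of lists).

Cut-set files are always written in canonical order: ascending
cardinality, then lexicographic by sorted reaction names, so the Berge
and BIP routes produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .core_types import (
    BinaryModeMatrix,
    CutSet,
    FluxModeMatrix,
    canonical_order,
)

__all__ = [
    "ProblemConfig",
    "read_em_matrix",
    "write_em_matrix",
    "read_partition",
    "write_partition",
    "read_cutsets",
    "write_cutsets",
]

EM_FORMATS = ("tsv_binary", "tsv_flux")


@dataclass
class ProblemConfig:
    """Declarative description of one solve, mirrored by the CLI flags."""

    em_file: str
    format: str = "tsv_binary"
    partition_file: str | None = None
    desired: list[int] = field(default_factory=list)
    target: list[int] | str = "complement"
    n: int = 0
    method: str = "berge"
    preprocessing: bool = True
    output: str | None = None
    report: str | None = None

    def __post_init__(self) -> None:
        if self.format not in EM_FORMATS:
            raise ValueError(f"format must be one of {EM_FORMATS}")
        if self.method not in ("berge", "bip"):
            raise ValueError("method must be 'berge' or 'bip'")
        if isinstance(self.target, str) and self.target != "complement":
            raise ValueError("target must be an index list or 'complement'")
        if not isinstance(self.target, str):
            overlap = set(self.desired) & set(self.target)
            if overlap:
                raise ValueError(
                    f"desired and target index lists overlap: {sorted(overlap)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProblemConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def read_em_matrix(
    path: str | Path, format: str = "tsv_binary"
) -> BinaryModeMatrix | FluxModeMatrix:
    """Read an EM matrix from a header + delimited-rows text file.

    Returns a :class:`BinaryModeMatrix` for ``tsv_binary`` (values
    validated to be 0/1) or a :class:`FluxModeMatrix` for ``tsv_flux``.
    """
    if format not in EM_FORMATS:
        raise ValueError(f"format must be one of {EM_FORMATS}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()]
    # drop trailing blank lines; internal blanks are errors caught below
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ValueError(f"{path}: empty EM matrix file")
    names = lines[0].split()
    if not names:
        raise ValueError(f"{path}: header line holds no reaction names")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate reaction names {dupes}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        if len(tokens) != len(names):
            raise ValueError(
                f"{path}: line {lineno} has {len(tokens)} values, "
                f"expected {len(names)}"
            )
        try:
            rows.append([float(t) for t in tokens])
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno} holds a non-numeric value"
            ) from None
    entries = np.asarray(rows, dtype=float).reshape(len(rows), len(names))
    if format == "tsv_binary":
        if entries.size and not np.isin(entries, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(entries, (0.0, 1.0)))[0]
            raise ValueError(
                f"{path}: line {bad[0] + 2} column {names[bad[1]]} holds "
                f"{entries[tuple(bad)]}, not a 0/1 value"
            )
        return BinaryModeMatrix(entries.astype(np.uint8), tuple(names))
    return FluxModeMatrix(entries, tuple(names))


def write_em_matrix(
    matrix: BinaryModeMatrix | FluxModeMatrix, path: str | Path
) -> None:
    """Write a mode matrix in the header + rows text format."""
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.reaction_names) + "\n")
        is_binary = isinstance(matrix, BinaryModeMatrix)
        for row in matrix.entries:
            if is_binary:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write("\t".join(format(v, "g") for v in row) + "\n")


def read_partition(path: str | Path) -> dict[str, list[int]]:
    """Read a desired/target/neutral partition file (JSON or YAML)."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: partition file must hold a mapping")
    out: dict[str, list[int]] = {}
    for key in ("desired", "target", "neutral"):
        values = data.get(key, [])
        out[key] = [int(v) for v in values]
    seen: dict[int, str] = {}
    for key in ("desired", "target", "neutral"):
        for idx in out[key]:
            if idx in seen and seen[idx] != key:
                raise ValueError(
                    f"{path}: mode index {idx} appears in both "
                    f"{seen[idx]} and {key}"
                )
            seen[idx] = key
    return out


def write_partition(
    partition: Mapping[str, Sequence[int]], path: str | Path
) -> None:
    path = Path(path)
    data = {
        key: [int(v) for v in partition.get(key, [])]
        for key in ("desired", "target", "neutral")
    }
    with open(path, "w") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=True)
        else:
            json.dump(data, fh, indent=2)
            fh.write("\n")


def write_cutsets(
    cutsets: Iterable[CutSet],
    path: str | Path,
    format: str = "tsv",
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write cut sets in canonical order as TSV or JSON.

    An empty solution list produces an empty body whose metadata records
    zero solutions.
    """
    ordered = canonical_order(cutsets)
    meta = dict(metadata or {})
    meta["count"] = len(ordered)
    if format == "tsv":
        with open(path, "w") as fh:
            for key in sorted(meta):
                fh.write(f"# {key}: {meta[key]}\n")
            for cs in ordered:
                fh.write(",".join(cs.sorted_names) + "\n")
    elif format == "json":
        payload = {
            "metadata": meta,
            "cutsets": [list(cs.sorted_names) for cs in ordered],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError("format must be 'tsv' or 'json'")


def read_cutsets(path: str | Path, format: str = "tsv") -> list[CutSet]:
    """Read a cut-set file written by :func:`write_cutsets`."""
    if format == "tsv":
        cutsets = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line.startswith("#"):
                continue
            # a bare empty line is the empty cut set (trivially solved problem)
            cutsets.append(CutSet.of(line.split(",")) if line else CutSet())
        return cutsets
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return [CutSet.of(names) for names in payload["cutsets"]]
    raise ValueError("format must be 'tsv' or 'json'")
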