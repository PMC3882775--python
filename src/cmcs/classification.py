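"""Efficiency-based partition of elementary modes into desired/target/neutral.

The design objective is growth-coupled product formation.  Each mode's
product and biomass fluxes are normalized by its total substrate influx,
and efficiency is defined as the product of normalized growth and
normalized product secretion.  Modes secreting at least as much product
(per substrate) as the most efficient mode are desirable; modes that
consume the product are neutral (their operation is typically repressed
in the production medium and need not be targeted); everything else is a
target for elimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import FluxModeMatrix

__all__ = ["DesignCriterion", "ModePartition", "classify_modes"]


@dataclass(frozen=True)
class DesignCriterion:
    """Names the reactions that define the strain-design objective."""

    product_reaction: str
    biomass_reaction: str
    substrate_reactions: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "substrate_reactions", tuple(self.substrate_reactions)
        )
        if not self.substrate_reactions:
            raise ValueError("at least one substrate reaction is required")


@dataclass(frozen=True)
class ModePartition:
    """Disjoint, exhaustive split of mode row indices."""

    desired: tuple[int, ...]
    target: tuple[int, ...]
    neutral: tuple[int, ...]

    def to_dict(self) -> dict[str, list[int]]:
        return {
            "desired": list(self.desired),
            "target": list(self.target),
            "neutral": list(self.neutral),
        }


def classify_modes(
    flux_modes: FluxModeMatrix, criterion: DesignCriterion
) -> ModePartition:
    """Partition modes by the normalized-efficiency rule.

    Per mode, product and biomass fluxes are divided by the summed
    substrate influx; efficiency is their product.  With p* the
    normalized product secretion of the maximum-efficiency mode (ties
    resolved to the smallest such secretion, keeping every maximally
    efficient mode desirable):

    * desired — normalized product secretion >= p*;
    * neutral — product flux < 0 (product uptake);
    * target — everything else (secretion in [0, p*)).

    Raises ``ValueError`` naming the first mode with non-positive
    substrate influx, and ``KeyError`` for unknown reaction names.
    """
    prod_col = flux_modes.column_index(criterion.product_reaction)
    bio_col = flux_modes.column_index(criterion.biomass_reaction)
    sub_cols = [
        flux_modes.column_index(name) for name in criterion.substrate_reactions
    ]

    influx = flux_modes.entries[:, sub_cols].sum(axis=1)
    bad = np.flatnonzero(influx <= 0)
    if bad.size:
        raise ValueError(
            f"mode {bad[0]} has non-positive total substrate influx "
            f"({influx[bad[0]]:g}); cannot normalize"
        )

    product = flux_modes.entries[:, prod_col] / influx
    biomass = flux_modes.entries[:, bio_col] / influx
    efficiency = biomass * product

    neutral_mask = flux_modes.entries[:, prod_col] < 0
    eligible = np.flatnonzero(~neutral_mask)
    if eligible.size == 0:
        return ModePartition(
            desired=(),
            target=(),
            neutral=tuple(range(flux_modes.n_modes)),
        )

    best = efficiency[eligible].max()
    # ties for maximal efficiency: p* is the smallest product secretion
    # among the tied modes, so all of them stay desirable
    tied = eligible[efficiency[eligible] == best]
    p_star = product[tied].min()

    desired, target, neutral = [], [], []
    for j in range(flux_modes.n_modes):
        if neutral_mask[j]:
            neutral.append(j)
        elif product[j] >= p_star:
            desired.append(j)
        else:
            target.append(j)
    return ModePartition(tuple(desired), tuple(target), tuple(neutral))
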