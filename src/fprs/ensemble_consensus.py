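"""Cell-wise median consensus over a GCM x predictor-set ensemble.

Prediction uncertainty is addressed by running one species distribution
model per (general circulation model, predictor set) combination — a full
Cartesian design, 5 x 5 = 25 members in the reference protocol — and
collapsing the stack of suitability maps to a single consensus map by
taking the median of each cell across members.

The even-member median is the mean of the two central order statistics
(the reference design always has an odd count, so this case only arises
for user-built stacks).  A cell masked in any member is masked in the
consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid_core import AlignmentError, SuitabilityGrid

__all__ = ["EnsembleStack", "build_ensemble_index", "consensus_median"]


@dataclass
class EnsembleStack:
    """An ordered collection of mutually aligned suitability grids.

    ``labels`` is a parallel sequence of (gcm_id, predictor_set_id) pairs,
    unique across members.
    """

    members: Sequence[SuitabilityGrid]
    labels: Sequence[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble stack must have at least one member")
        if len(self.labels) != len(self.members):
            raise ValueError("labels and members must be parallel")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ensemble member labels must be unique")
        ref = self.members[0]
        for m in self.members[1:]:
            diff = ref.spec.approx_equal(m.spec)
            if diff is not None:
                raise AlignmentError(
                    f"ensemble members are not aligned: specs differ in {diff!r}"
                )


def build_ensemble_index(
    gcm_ids: Sequence[str], predictor_set_ids: Sequence[str]
) -> list[tuple[str, str]]:
    """Enumerate the full GCM x predictor-set design.

    Returns the Cartesian product in row-major order (GCM outer loop,
    predictor set inner), e.g. 5 GCMs x 5 predictor sets -> 25 pairs.
    """
    if not gcm_ids or not predictor_set_ids:
        raise ValueError("gcm_ids and predictor_set_ids must be non-empty")
    if len(set(gcm_ids)) != len(gcm_ids):
        raise ValueError("duplicate GCM identifier")
    if len(set(predictor_set_ids)) != len(predictor_set_ids):
        raise ValueError("duplicate predictor-set identifier")
    return [(g, p) for g in gcm_ids for p in predictor_set_ids]


def consensus_median(stack: EnsembleStack) -> SuitabilityGrid:
    """Per-cell median across ensemble members.

    The output mask is the union of member masks: a cell with NoData in
    any member is NoData in the consensus (conservative choice).
    """
    values = np.stack([m.values for m in stack.members])
    mask = np.logical_or.reduce([m.mask for m in stack.members])
    med = np.median(values, axis=0)
    med = np.where(mask, 0.0, med)
    return SuitabilityGrid(stack.members[0].spec, med, mask)
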