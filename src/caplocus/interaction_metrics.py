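"""Sensitivity/accuracy comparison of predicted vs reference interaction sets.

A locus-capture experiment yields a set of candidate long-range interaction
regions; a 4C-Seq experiment on the same viewpoint yields a reference set.
The two are compared by a single overlap count n_overlap shared between two
ratios:

    SE (sensitivity) = n_overlap / n_reference
    AC (accuracy)    = n_overlap / n_predicted

By default n_overlap counts predicted intervals that overlap at least one
reference interval (each predicted interval counted once); the alternative
convention — counting reference intervals hit — is available via ``side``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import IntervalSet

__all__ = ["InteractionComparison", "count_overlapping", "compare"]


@dataclass(frozen=True)
class InteractionComparison:
    """Result of comparing a predicted interaction set against a reference.

    ``overlap_pairs`` lists (predicted index, reference index) evidence for
    every overlapping pair, indices into the sorted interval order.
    """

    n_predicted: int
    n_reference: int
    n_overlap: int
    se: float
    ac: float
    overlap_pairs: tuple[tuple[int, int], ...]

    @property
    def se_percent(self) -> float:
        """SE as a percentage rounded to one decimal place."""
        return round(self.se * 100, 1)

    @property
    def ac_percent(self) -> float:
        """AC as a percentage rounded to one decimal place."""
        return round(self.ac * 100, 1)


def _overlap_pairs(
    predicted: IntervalSet, reference: IntervalSet, min_bp: int
) -> list[tuple[int, int]]:
    ref_index = {iv: i for i, iv in enumerate(reference)}
    pairs: list[tuple[int, int]] = []
    for i, p in enumerate(predicted):
        for hit in reference.overlapping(p, min_bp):
            pairs.append((i, ref_index[hit]))
    return pairs


def count_overlapping(
    predicted: IntervalSet,
    reference: IntervalSet,
    min_bp: int = 1,
    side: str = "predicted",
) -> int:
    """Number of intervals on ``side`` with at least one cross-set overlap.

    ``side="predicted"`` (default) counts predicted intervals hitting the
    reference; ``side="reference"`` counts reference intervals hit.
    """
    if side == "predicted":
        return sum(1 for p in predicted if reference.any_overlap(p, min_bp))
    if side == "reference":
        return sum(1 for r in reference if predicted.any_overlap(r, min_bp))
    raise ValueError(f"side must be 'predicted' or 'reference', got {side!r}")


def compare(
    predicted: IntervalSet,
    reference: IntervalSet,
    min_bp: int = 1,
    side: str = "predicted",
) -> InteractionComparison:
    """Compute SE and AC between a predicted and a reference interaction set.

    Both sets must be non-empty (the ratios are otherwise undefined).
    """
    if len(predicted) == 0 or len(reference) == 0:
        raise ValueError("compare() requires non-empty predicted and reference sets")
    n_overlap = count_overlapping(predicted, reference, min_bp=min_bp, side=side)
    return InteractionComparison(
        n_predicted=len(predicted),
        n_reference=len(reference),
        n_overlap=n_overlap,
        se=n_overlap / len(reference),
        ac=n_overlap / len(predicted),
        overlap_pairs=tuple(_overlap_pairs(predicted, reference, min_bp)),
    )
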