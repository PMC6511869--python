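"""SILAC heavy/light ratio normalization and enriched-protein calling.

In a SILAC pulldown comparison (heavy = targeting guide, light =
non-targeting control), a curated list of cytoplasmic proteins that cannot
have been biotin-labeled serves as empirical false positives: their H/L
ratios define the background. Each detected protein's raw ratio is divided by
the median raw ratio of the detected false positives, centering the
background at 1; proteins at or above a cutoff (default 1.5) on the
normalized scale are called enriched. The fraction of false positives below
the cutoff is reported as the cutoff's empirical justification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRatio",
    "SilacCallResult",
    "normalize_ratios",
    "fp_fraction_below",
    "call_enriched",
    "derive_cutoff",
]


@dataclass(frozen=True)
class ProteinRatio:
    protein_id: str
    raw_ratio: float
    normalized_ratio: float | None = None
    is_false_positive: bool = False
    is_known_positive: bool | None = None

    def __post_init__(self) -> None:
        if not self.raw_ratio > 0:
            raise ValueError(f"raw_ratio must be > 0, got {self.raw_ratio}")


@dataclass(frozen=True)
class SilacCallResult:
    normalization_median: float
    cutoff: float
    fp_fraction_below_cutoff: float
    enriched: tuple[str, ...]
    enriched_false_positives: tuple[str, ...]


def _to_frame(table: Iterable[ProteinRatio] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in table],
            "raw_ratio": [p.raw_ratio for p in table],
        }
    )


def normalize_ratios(
    table: Iterable[ProteinRatio] | pd.DataFrame,
    fp_ids: Iterable[str],
) -> pd.DataFrame:
    """Divide every raw H/L ratio by the median of the detected false positives.

    ``table`` is a DataFrame with columns ``protein_id`` and ``raw_ratio`` (or
    a list of :class:`ProteinRatio`). Only false positives actually detected
    in the table enter the median; an even-sized set takes the midpoint of
    the central pair. Rows with missing or non-positive ratios are dropped
    with a logged count. Returns the table with ``normalized_ratio`` and
    ``is_false_positive`` columns; the median of the FP normalized ratios is
    1 by construction.
    """
    df = _to_frame(table)
    fp_set = set(fp_ids)
    n_in = len(df)
    df = df[pd.to_numeric(df["raw_ratio"], errors="coerce").gt(0).fillna(False)]
    df = df.assign(raw_ratio=df["raw_ratio"].astype(float))
    if len(df) < n_in:
        logger.info("dropped %d proteins with missing/non-positive ratios", n_in - len(df))
    df["is_false_positive"] = df["protein_id"].isin(fp_set)
    fp_ratios = df.loc[df["is_false_positive"], "raw_ratio"]
    if fp_ratios.empty:
        raise ValueError("no false-positive proteins detected; normalization undefined")
    median = float(np.median(fp_ratios))
    df["normalized_ratio"] = df["raw_ratio"] / median
    df.attrs["normalization_median"] = median
    return df.reset_index(drop=True)


def fp_fraction_below(table: pd.DataFrame, cutoff: float = 1.5) -> Fraction:
    """Fraction of false-positive proteins with normalized ratio strictly
    below ``cutoff``, as an exact rational."""
    fp = table.loc[table["is_false_positive"], "normalized_ratio"]
    if fp.empty:
        raise ValueError("no false-positive proteins in table")
    return Fraction(int((fp < cutoff).sum()), len(fp))


def derive_cutoff(table: pd.DataFrame, leak_quantile: float = 0.17) -> float:
    """Cutoff at the (1 - leak_quantile) quantile of FP normalized ratios.

    An alternative to the fixed default: choose the cutoff so that a fraction
    ``leak_quantile`` of false positives would exceed it.
    """
    fp = table.loc[table["is_false_positive"], "normalized_ratio"]
    if fp.empty:
        raise ValueError("no false-positive proteins in table")
    return float(np.quantile(fp, 1.0 - leak_quantile))


def call_enriched(table: pd.DataFrame, cutoff: float = 1.5) -> SilacCallResult:
    """Call proteins with normalized ratio >= cutoff (inclusive) enriched.

    False positives that clear the cutoff are still listed in ``enriched``
    but additionally reported in ``enriched_false_positives``.
    """
    if "normalized_ratio" not in table.columns:
        raise ValueError("table must be normalized first (see normalize_ratios)")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    mask = table["normalized_ratio"] >= cutoff
    enriched = tuple(table.loc[mask, "protein_id"])
    fp_enriched = tuple(table.loc[mask & table["is_false_positive"], "protein_id"])
    return SilacCallResult(
        normalization_median=float(table.attrs.get("normalization_median", float("nan"))),
        cutoff=cutoff,
        fp_fraction_below_cutoff=float(fp_fraction_below(table, cutoff)),
        enriched=enriched,
        enriched_false_positives=fp_enriched,
    )
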