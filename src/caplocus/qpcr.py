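"""qPCR relative enrichment with double normalization.

The pulldown signal at a target amplicon is first expressed relative to its
input, normalized to the same ratio at a negative-control reference region
(SOX2 by default) to remove background, and then normalized once more to the
identical quantity measured in cells carrying a non-targeting guide (sgGAL4):

    enrichment = [ (T_pd/T_in)/(R_pd/R_in) ]_sgTarget
               / [ (T_pd/T_in)/(R_pd/R_in) ]_sgGAL4

where T is the target amplicon and R the reference amplicon. Quantities may
be supplied directly or derived from raw Ct values through a per-assay
standard curve; the ratio is evaluated in log space so extreme dilutions do
not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "StandardCurve",
    "EnrichmentResult",
    "fit_standard_curve",
    "quantify",
    "relative_enrichment",
    "enrichment_by_replicate",
    "summarize_replicates",
]

TARGET_GUIDE = "sgTarget"
CONTROL_GUIDE = "sgGAL4"
PULLDOWN = "pulldown"
INPUT = "input"


@dataclass(frozen=True)
class QpcrMeasurement:
    """One relative quantity for (region, guide, fraction, replicate)."""

    region: str
    guide: str
    fraction: str
    replicate: int
    quantity: float
    ct: float | None = None

    def __post_init__(self) -> None:
        if not self.quantity > 0:
            raise ValueError(f"quantity must be > 0, got {self.quantity}")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Ct on log10(quantity) for one assay."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float


@dataclass(frozen=True)
class EnrichmentResult:
    region: str
    values: tuple[float, ...]
    mean: float
    sem: float
    p_value: float


def fit_standard_curve(
    dilution_quantities: Sequence[float], cts: Sequence[float]
) -> StandardCurve:
    """Fit Ct = slope * log10(quantity) + intercept over a dilution series.

    Amplification efficiency is ``10**(-1/slope) - 1``; a perfect doubling per
    cycle gives slope -1/log10(2) ≈ -3.32 and efficiency 1.0. Requires at
    least 3 dilution points with non-constant quantities and a negative slope.
    """
    q = np.asarray(dilution_quantities, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if q.size != ct.size:
        raise ValueError("quantities and cts must have the same length")
    if q.size < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    if np.any(q <= 0):
        raise ValueError("dilution quantities must be strictly positive")
    logq = np.log10(q)
    if np.allclose(logq, logq[0]):
        raise ValueError("dilution quantities have zero variance")
    fit = stats.linregress(logq, ct)
    if fit.slope >= 0:
        raise ValueError(f"standard curve slope must be negative, got {fit.slope:g}")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(10 ** (-1.0 / fit.slope) - 1.0),
        r_squared=float(fit.rvalue**2),
    )


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert a standard curve: quantity = 10**((ct - intercept) / slope)."""
    return float(10 ** ((ct - curve.intercept) / curve.slope))


def _as_quantity_map(
    measurements: Iterable[QpcrMeasurement] | pd.DataFrame,
) -> Mapping[tuple[str, str, str], float]:
    out: dict[tuple[str, str, str], float] = {}
    if isinstance(measurements, pd.DataFrame):
        rows = (
            (r.region, r.guide, r.fraction, r.quantity)
            for r in measurements.itertuples(index=False)
        )
    else:
        rows = ((m.region, m.guide, m.fraction, m.quantity) for m in measurements)
    for region, guide, fraction, quantity in rows:
        key = (region, guide, fraction)
        if key in out:
            raise ValueError(f"duplicate measurement for {key}")
        out[key] = quantity
    return out


def relative_enrichment(
    measurements: Iterable[QpcrMeasurement] | pd.DataFrame,
    target_region: str,
    reference_region: str = "SOX2",
    target_guide: str = TARGET_GUIDE,
    control_guide: str = CONTROL_GUIDE,
) -> float:
    """Relative enrichment of ``target_region`` for one replicate.

    All eight quantities (target/reference x targeting/control guide x
    pulldown/input) must be present and positive; a missing term raises an
    error naming the (region, guide, fraction) triple. Computed in log space.
    """
    qmap = _as_quantity_map(measurements)

    def term(region: str, guide: str, fraction: str) -> float:
        key = (region, guide, fraction)
        if key not in qmap:
            raise ValueError(f"missing qPCR quantity for {key}")
        q = qmap[key]
        if not q > 0:
            raise ValueError(f"non-positive quantity for {key}: {q}")
        return math.log(q)

    log_enrichment = 0.0
    for guide, sign in ((target_guide, +1.0), (control_guide, -1.0)):
        log_enrichment += sign * (
            term(target_region, guide, PULLDOWN)
            - term(target_region, guide, INPUT)
            - term(reference_region, guide, PULLDOWN)
            + term(reference_region, guide, INPUT)
        )
    return math.exp(log_enrichment)


def enrichment_by_replicate(
    table: pd.DataFrame,
    target_region: str,
    reference_region: str = "SOX2",
    **kwargs,
) -> pd.Series:
    """Per-replicate relative enrichments from a long-format measurement table.

    ``table`` needs columns region, guide, fraction, replicate, quantity.
    """
    values = {
        rep: relative_enrichment(sub, target_region, reference_region, **kwargs)
        for rep, sub in table.groupby("replicate")
    }
    return pd.Series(values, name="enrichment").sort_index()


def summarize_replicates(values: Sequence[float], region: str = "") -> EnrichmentResult:
    """Mean, SEM and a two-sided one-sample t-test across replicates.

    The test is applied to log2(enrichment) against 0 — i.e. against the null
    of no enrichment on the natural (multiplicative) scale of a ratio that is
    already normalized to the control condition. Requires >= 2 replicates.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("summarize_replicates requires >= 2 replicates")
    if np.any(vals <= 0):
        raise ValueError("enrichment values must be positive")
    sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size))
    log2_vals = np.log2(vals)
    if np.allclose(log2_vals, 0.0) or np.std(log2_vals, ddof=1) == 0.0:
        # degenerate spread: t statistic is 0/0 or +-inf; report p accordingly
        p = 1.0 if np.allclose(log2_vals.mean(), 0.0) else 0.0
    else:
        p = float(stats.ttest_1samp(log2_vals, 0.0).pvalue)
    return EnrichmentResult(
        region=region,
        values=tuple(float(v) for v in vals),
        mean=float(vals.mean()),
        sem=sem,
        p_value=p,
    )
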