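"""Telomeric-motif read counting and per-transcript fold enrichment.

TERRA (telomeric repeat-containing RNA) carries UUAGGG repeats; in sequencing
reads it shows up as (TTAGGG)x4 or, on the opposite strand, (CCCTAA)x4. A
sample's TERRA content is summarized as the fraction of reads carrying either
24-nt motif as an exact contiguous substring.

Transcript-level enrichment compares estimated read counts between a
targeting sample and a non-targeting control; transcripts at or above a fold
threshold (default 3) are called enriched, with ribosomal RNA excluded
before classification.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "MotifCountResult",
    "TranscriptEnrichment",
    "TELOMERIC_MOTIFS",
    "contains_telomeric_motif",
    "read_fastq",
    "count_motif_reads",
    "terra_fold",
    "fold_enrichment_table",
    "biotype_breakdown",
]

# (TTAGGG)x4 and its reverse complement (CCCTAA)x4; because the second IS the
# reverse complement of the first, scanning both covers both read strands.
TELOMERIC_MOTIFS = ("TTAGGG" * 4, "CCCTAA" * 4)

RRNA_BIOTYPE = "rRNA"


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length must match sequence length")


@dataclass(frozen=True)
class MotifCountResult:
    sample: str
    n_motif_reads: int
    n_total_reads: int

    @property
    def fraction(self) -> float:
        return self.n_motif_reads / self.n_total_reads


@dataclass(frozen=True)
class TranscriptEnrichment:
    transcript_id: str
    biotype: str
    count_target: float
    count_control: float
    fold: float
    enriched: bool


def contains_telomeric_motif(sequence: str) -> bool:
    """True iff the read contains (TTAGGG)x4 or (CCCTAA)x4 as an exact,
    contiguous, case-insensitive substring. N never matches."""
    seq = sequence.upper()
    return any(motif in seq for motif in TELOMERIC_MOTIFS)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ file (gzipped accepted)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield ReadRecord(rec.id, str(rec.seq), qual)


def count_motif_reads(reads: Iterable[ReadRecord], sample: str = "") -> MotifCountResult:
    """Single-pass motif scan over a read stream; errors on an empty stream."""
    n_total = 0
    n_motif = 0
    for read in reads:
        n_total += 1
        if contains_telomeric_motif(read.sequence):
            n_motif += 1
    if n_total == 0:
        raise ValueError("count_motif_reads requires at least one read")
    return MotifCountResult(sample=sample, n_motif_reads=n_motif, n_total_reads=n_total)


def terra_fold(target: MotifCountResult, control: MotifCountResult) -> float:
    """Ratio of motif-read fractions, target over control.

    A control fraction of 0 with positive target signal yields +inf (flagged
    infinite enrichment); 0/0 is reported as 1.0 with a warning.
    """
    if control.fraction == 0.0:
        if target.fraction > 0.0:
            return math.inf
        warnings.warn(
            "both samples have zero motif reads; reporting fold 1.0", stacklevel=2
        )
        return 1.0
    return target.fraction / control.fraction


def fold_enrichment_table(
    target: pd.DataFrame,
    control: pd.DataFrame,
    threshold: float = 3.0,
    normalize: bool = True,
    min_count: float = 5.0,
    rrna_biotype: str = RRNA_BIOTYPE,
) -> list[TranscriptEnrichment]:
    """Per-transcript fold enrichment of a targeting sample over its control.

    Both tables need columns ``transcript_id``, ``biotype``, ``count`` over
    the same transcript universe. With ``normalize=True`` counts are scaled
    to counts-per-million before the ratio. rRNA transcripts are dropped
    before classification; a transcript with control count 0 gets fold +inf
    and is called enriched only if its (normalized) target count reaches
    ``min_count``, so noise-level singletons are not promoted. The enriched
    flag is ``fold >= threshold`` (boundary inclusive).
    """
    t = target.set_index("transcript_id")
    c = control.set_index("transcript_id")
    only_t = t.index.difference(c.index)
    only_c = c.index.difference(t.index)
    if len(only_t) or len(only_c):
        raise ValueError(
            "transcript universes differ; only in target: "
            f"{sorted(only_t)[:5]}, only in control: {sorted(only_c)[:5]}"
        )
    if (t["count"] < 0).any() or (c["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    t_counts = t["count"].astype(float)
    c_counts = c.loc[t.index, "count"].astype(float)
    if normalize:
        t_counts = t_counts / t_counts.sum() * 1e6
        c_counts = c_counts / c_counts.sum() * 1e6

    results: list[TranscriptEnrichment] = []
    for tx_id in t.index:
        biotype = t.loc[tx_id, "biotype"]
        if biotype == rrna_biotype:
            continue
        ct, cc = float(t_counts[tx_id]), float(c_counts[tx_id])
        if cc == 0.0:
            fold = math.inf if ct > 0 else 1.0
            enriched = ct >= min_count
        else:
            fold = ct / cc
            enriched = fold >= threshold
        results.append(
            TranscriptEnrichment(
                transcript_id=tx_id,
                biotype=str(biotype),
                count_target=ct,
                count_control=cc,
                fold=fold,
                enriched=enriched,
            )
        )
    return results


def biotype_breakdown(
    enriched: Iterable[TranscriptEnrichment],
) -> dict[str, tuple[int, float]]:
    """Biotype -> (count, fraction of the enriched list)."""
    counts: dict[str, int] = {}
    total = 0
    for te in enriched:
        counts[te.biotype] = counts.get(te.biotype, 0) + 1
        total += 1
    return {bt: (n, n / total) for bt, n in sorted(counts.items())}
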