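"""Seeded generators for every input the pipeline consumes, with truth tables.

Each generator is a pure function of its parameters and seed: calling it
twice with the same arguments yields identical output, and each returns a
truth dictionary sufficient to score any downstream call exactly. The
generators emulate the study design of a locus-capture proximity-labeling
experiment — a targeting guide against an sgGal4 non-targeting control —
without any sequence-level realism:

- ``simulate_capture_peaks``: replicate peak sets containing a planted target
  region and interaction loci, plus background peaks shared with the control
  (so control subtraction removes them).
- ``simulate_telomeric_reads``: reads with (TTAGGG)x4 / (CCCTAA)x4 motifs
  planted at a controlled fraction; background reads are motif-free by
  rejection sampling.
- ``simulate_transcript_counts``: paired count tables with planted
  multiplicative enrichment folds and a biotype mix including an rRNA
  stratum that is never enriched.
- ``simulate_silac_table``: lognormal false-positive H/L ratios around a
  stated median, with true positives shifted by a constant fold.
- ``simulate_qpcr``: the eight quantities per replicate whose noise-free
  relative enrichment equals a chosen true fold.

Noise models (lognormal multiplicative, gamma-Poisson counts) are this
module's own choices; they are documented in the methods note.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .rna_enrichment import TELOMERIC_MOTIFS, ReadRecord, contains_telomeric_motif

__all__ = [
    "simulate_capture_peaks",
    "simulate_telomeric_reads",
    "simulate_transcript_counts",
    "simulate_silac_table",
    "simulate_qpcr",
    "write_fastq",
    "DEFAULT_BIOTYPE_MIX",
]

BASES = np.array(list("ACGT"))

DEFAULT_BIOTYPE_MIX: dict[str, float] = {
    "pseudogene": 0.30,
    "lincRNA": 0.25,
    "antisense": 0.15,
    "snoRNA": 0.10,
    "scaRNA": 0.05,
    "rRNA": 0.05,
    "protein_coding": 0.10,
}


# ---------------------------------------------------------------------------
# Peaks


def _place_disjoint(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    n: int,
    width: int,
    occupied: list[GenomicInterval],
    min_gap: int,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Place ``n`` peaks of ``width`` bp, each >= min_gap away from everything
    already placed, by rejection sampling."""
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed: list[GenomicInterval] = []
    for _ in range(n):
        for _attempt in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
            limit = chrom_sizes[chrom] - width
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            cand = GenomicInterval(chrom, start, start + width)
            if all(
                iv.chrom != cand.chrom
                or cand.start >= iv.end + min_gap
                or cand.end <= iv.start - min_gap
                for iv in occupied + placed
            ):
                placed.append(cand)
                break
        else:
            raise ValueError(
                f"could not place {n} peaks of {width} bp with gap {min_gap} bp "
                "in the given genome (infeasible packing)"
            )
    return placed


def _jitter(iv: GenomicInterval, rng: np.random.Generator, jitter_bp: int) -> GenomicInterval:
    if jitter_bp == 0:
        return iv
    shift = int(rng.integers(-jitter_bp, jitter_bp + 1))
    start = max(0, iv.start + shift)
    return GenomicInterval(iv.chrom, start, start + len(iv), name=iv.name)


def simulate_capture_peaks(
    chrom_sizes: Mapping[str, int],
    target_region: GenomicInterval,
    n_interactions: int = 5,
    n_shared_background: int = 20,
    reproducibility: float = 1.0,
    jitter_bp: int = 0,
    seed: int = 0,
    peak_width: int = 600,
    min_gap: int = 1000,
) -> tuple[IntervalSet, IntervalSet, IntervalSet, dict[str, Any]]:
    """Two replicate peak sets plus a control set, with a truth table.

    Planted peaks (the target region and ``n_interactions`` interaction loci)
    enter each replicate independently with probability ``reproducibility``
    and per-replicate coordinate jitter up to ``jitter_bp``. Background peaks
    appear in both replicates and in the control, so control subtraction
    removes them. Planted and background peaks are pairwise disjoint with at
    least ``min_gap`` bp between any two, keeping the truth unambiguous.
    """
    if not 0.0 <= reproducibility <= 1.0:
        raise ValueError("reproducibility must be in [0, 1]")
    if target_region.end > chrom_sizes.get(target_region.chrom, 0):
        raise ValueError("target_region does not fit within chrom_sizes")
    if jitter_bp >= peak_width:
        raise ValueError("jitter_bp must be smaller than peak_width")
    rng = np.random.default_rng(seed)

    target = GenomicInterval(
        target_region.chrom, target_region.start, target_region.end, name="target"
    )
    interactions = _place_disjoint(
        rng, chrom_sizes, n_interactions, peak_width, [target], min_gap
    )
    interactions = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"interaction_{i}")
        for i, iv in enumerate(interactions)
    ]
    background = _place_disjoint(
        rng, chrom_sizes, n_shared_background, peak_width, [target] + interactions, min_gap
    )
    background = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"background_{i}")
        for i, iv in enumerate(background)
    ]

    planted = [target] + interactions
    reps: list[list[GenomicInterval]] = [[], []]
    for iv in planted:
        for rep in reps:
            if rng.random() < reproducibility:
                rep.append(_jitter(iv, rng, jitter_bp))
    for iv in background:
        for rep in reps:
            rep.append(_jitter(iv, rng, jitter_bp))

    truth: dict[str, Any] = {
        "seed": seed,
        "planted_regions": [(iv.chrom, iv.start, iv.end, iv.name) for iv in planted],
        "background_regions": [(iv.chrom, iv.start, iv.end, iv.name) for iv in background],
        "params": {
            "n_interactions": n_interactions,
            "n_shared_background": n_shared_background,
            "reproducibility": reproducibility,
            "jitter_bp": jitter_bp,
            "peak_width": peak_width,
            "min_gap": min_gap,
        },
    }
    return (
        IntervalSet(reps[0], label="rep1"),
        IntervalSet(reps[1], label="rep2"),
        IntervalSet(background, label="sgGal4"),
        truth,
    )


# ---------------------------------------------------------------------------
# Reads


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def simulate_telomeric_reads(
    n_reads: int = 1000,
    motif_fraction: float = 0.01,
    read_length: int = 100,
    seed: int = 0,
) -> tuple[list[ReadRecord], dict[str, Any]]:
    """Reads with exactly ``round(n_reads * motif_fraction)`` motif carriers.

    Each motif read carries one of the two 24-nt telomeric motifs at a random
    offset; every background read is motif-free by rejection sampling. Truth
    lists the motif-bearing read ids.
    """
    if read_length < 24:
        raise ValueError("read_length must be >= 24 to hold a telomeric motif")
    if not 0.0 <= motif_fraction <= 1.0:
        raise ValueError("motif_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_motif = round(n_reads * motif_fraction)

    motif_slots = set(rng.choice(n_reads, size=n_motif, replace=False).tolist())
    reads: list[ReadRecord] = []
    motif_ids: list[str] = []
    for i in range(n_reads):
        read_id = f"read_{i:06d}"
        if i in motif_slots:
            motif = TELOMERIC_MOTIFS[int(rng.integers(0, 2))]
            offset = int(rng.integers(0, read_length - len(motif) + 1))
            seq = (
                _random_sequence(rng, offset)
                + motif
                + _random_sequence(rng, read_length - offset - len(motif))
            )
            motif_ids.append(read_id)
        else:
            while True:
                seq = _random_sequence(rng, read_length)
                if not contains_telomeric_motif(seq):
                    break
        reads.append(ReadRecord(read_id, seq, "I" * read_length))

    truth = {
        "seed": seed,
        "motif_read_ids": motif_ids,
        "params": {
            "n_reads": n_reads,
            "motif_fraction": motif_fraction,
            "read_length": read_length,
        },
    }
    return reads, truth


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Transcript counts


def simulate_transcript_counts(
    n_transcripts: int = 2000,
    n_enriched: int = 50,
    fold_range: tuple[float, float] = (4.0, 8.0),
    biotype_mix: Mapping[str, float] | None = None,
    dispersion: float = 0.1,
    library_sizes: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Paired target/control count tables with planted enriched transcripts.

    Per-transcript baseline means are lognormal; enriched transcripts (never
    rRNA) get a multiplicative fold drawn uniformly from ``fold_range``.
    Counts are gamma-Poisson with the given dispersion; ``dispersion == 0``
    is the noise-free mode in which counts equal their means exactly. Truth
    lists the enriched transcript ids and their true folds.
    """
    if n_enriched > n_transcripts:
        raise ValueError("n_enriched must be <= n_transcripts")
    if fold_range[0] < 3.0:
        raise ValueError("fold_range minimum must be >= 3 for planted positives")
    mix = dict(biotype_mix) if biotype_mix is not None else dict(DEFAULT_BIOTYPE_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"biotype_mix fractions must sum to 1, got {sum(mix.values())}")
    rng = np.random.default_rng(seed)

    biotypes_sorted = sorted(mix)
    probs = np.array([mix[b] for b in biotypes_sorted])
    biotypes = rng.choice(biotypes_sorted, size=n_transcripts, p=probs)
    ids = np.array([f"TX{i:05d}" for i in range(n_transcripts)])

    non_rrna = np.flatnonzero(biotypes != "rRNA")
    if n_enriched > non_rrna.size:
        raise ValueError("not enough non-rRNA transcripts to plant enrichment")
    enriched_idx = rng.choice(non_rrna, size=n_enriched, replace=False)
    folds = np.ones(n_transcripts)
    folds[enriched_idx] = rng.uniform(fold_range[0], fold_range[1], size=n_enriched)

    baseline = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_transcripts)
    mu_control = baseline * library_sizes[1]
    mu_target = baseline * folds * library_sizes[0]

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion == 0.0:
            return mu.copy()
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        return rng.poisson(lam).astype(float)

    target = pd.DataFrame(
        {"transcript_id": ids, "biotype": biotypes, "count": draw(mu_target)}
    )
    control = pd.DataFrame(
        {"transcript_id": ids, "biotype": biotypes, "count": draw(mu_control)}
    )
    truth = {
        "seed": seed,
        "planted_transcripts": [
            {"transcript_id": ids[i], "true_fold": float(folds[i]), "biotype": str(biotypes[i])}
            for i in sorted(enriched_idx)
        ],
        "params": {
            "n_transcripts": n_transcripts,
            "n_enriched": n_enriched,
            "fold_range": list(fold_range),
            "dispersion": dispersion,
            "library_sizes": list(library_sizes),
            "biotype_mix": mix,
        },
    }
    return target, control, truth


# ---------------------------------------------------------------------------
# SILAC


def simulate_silac_table(
    n_fp: int = 300,
    n_tp: int = 50,
    fp_log_sigma: float = 0.425,
    fp_median: float = 1.0,
    tp_fold: float = 2.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], dict[str, Any]]:
    """SILAC H/L ratio table with lognormal false positives and shifted TPs.

    False-positive raw ratios are lognormal with median ``fp_median``; the
    default log-sigma of 0.425 places about 83% of false positives below a
    normalized ratio of 1.5, the background shape the cutoff is judged
    against. True-positive ratios are a fresh lognormal draw times
    ``tp_fold``. Truth lists the true-positive ids.
    """
    if n_fp < 1 or n_tp < 0:
        raise ValueError("n_fp must be >= 1 and n_tp >= 0")
    if not tp_fold > 1.0:
        raise ValueError("tp_fold must be > 1")
    rng = np.random.default_rng(seed)

    fp_ids = [f"FP{i:04d}" for i in range(n_fp)]
    tp_ids = [f"TP{i:04d}" for i in range(n_tp)]
    fp_ratios = fp_median * np.exp(rng.normal(0.0, fp_log_sigma, size=n_fp))
    tp_ratios = tp_fold * fp_median * np.exp(rng.normal(0.0, fp_log_sigma, size=n_tp))
    table = pd.DataFrame(
        {
            "protein_id": fp_ids + tp_ids,
            "raw_ratio": np.concatenate([fp_ratios, tp_ratios]),
        }
    )
    truth = {
        "seed": seed,
        "planted_proteins": tp_ids,
        "params": {
            "n_fp": n_fp,
            "n_tp": n_tp,
            "fp_log_sigma": fp_log_sigma,
            "fp_median": fp_median,
            "tp_fold": tp_fold,
        },
    }
    return table, fp_ids, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_fold: float = 5.0,
    cv: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    target_region: str = "Target",
    reference_region: str = "SOX2",
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Long-format qPCR quantities whose noise-free enrichment is ``true_fold``.

    Each replicate has the eight quantities (target/reference x
    sgTarget/sgGAL4 x pulldown/input); all are 1 except the target pulldown
    under the targeting guide, which is ``true_fold``. ``cv`` is the
    coefficient of variation of the replicate-level relative enrichment;
    median-preserving lognormal noise with the matching log-variance is
    distributed equally across the eight quantities, so the median recovered
    enrichment stays at ``true_fold`` for any cv.
    """
    if not true_fold > 0:
        raise ValueError("true_fold must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma_total = np.sqrt(np.log1p(cv**2))
    sigma_q = sigma_total / np.sqrt(8.0)

    rows = []
    for rep in range(1, n_replicates + 1):
        for region in (target_region, reference_region):
            for guide in ("sgTarget", "sgGAL4"):
                for fraction in ("pulldown", "input"):
                    base = (
                        true_fold
                        if (region, guide, fraction)
                        == (target_region, "sgTarget", "pulldown")
                        else 1.0
                    )
                    noise = float(np.exp(rng.normal(0.0, sigma_q))) if cv > 0 else 1.0
                    rows.append(
                        {
                            "region": region,
                            "guide": guide,
                            "fraction": fraction,
                            "replicate": rep,
                            "quantity": base * noise,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "seed": seed,
        "true_fold": true_fold,
        "params": {"cv": cv, "n_replicates": n_replicates},
    }
    return table, truth
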