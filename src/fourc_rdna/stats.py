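"""Replicate QC and permutation statistics for gene-list overlap.

Two statistical components live here. Replicate QC removes singleton
contacts (merged fragments supported by exactly one read), bins the
surviving reads, RPKM-normalizes each replicate and reports the
Pearson correlation between replicates. The overlap null draws
equal-size random gene lists from a universe by repeated Fisher–Yates
shuffling and summarizes how much two random lists of size k from N
genes overlap; the exact reference distribution is hypergeometric
(|A ∩ B| ~ Hypergeom(N, k, k)), which serves as a closed-form check
on the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .contact_calling import merge_overlapping_reads
from .io_genomics import ReadAlignment

__all__ = [
    "QcParams",
    "OverlapNullSummary",
    "rpkm_normalize",
    "remove_singleton_reads",
    "replicate_correlation",
    "sample_overlap_null",
    "hypergeometric_overlap_moments",
    "empirical_p",
    "list_overlap",
]

#: RNG algorithm recorded in output metadata; all sampling goes through a
#: seeded generator, never global state.
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class QcParams:
    """Replicate-correlation settings: bin size, singleton handling."""

    bin_size: int = 10_000
    drop_singletons: bool = True
    normalization: str = "RPKM"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.normalization not in ("RPKM", "none"):
            raise ValueError("normalization must be 'RPKM' or 'none'")


@dataclass(frozen=True)
class OverlapNullSummary:
    """Null distribution of overlap between random equal-size gene lists.

    Fractions are of the list size k. ``overlaps`` holds the raw
    per-repetition intersection counts with the fixed reference list.
    """

    universe_size: int
    list_size: int
    n_reps: int
    overlaps: np.ndarray
    mean_fraction: float
    sd_fraction: float
    min_fraction: float
    max_fraction: float
    seed: int
    rng_algorithm: str = RNG_ALGORITHM


def rpkm_normalize(
    counts: np.ndarray | Sequence[float], bin_length: int, total_reads: int
) -> np.ndarray:
    """Reads per kilobase per million mapped reads.

    value = count / ((bin_length/1e3) * (total_reads/1e6)).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0 for RPKM normalization")
    counts = np.asarray(counts, dtype=np.float64)
    return counts / ((bin_length / 1e3) * (total_reads / 1e6))


def remove_singleton_reads(reads: Sequence[ReadAlignment]) -> list[ReadAlignment]:
    """Drop reads in merged fragments supported by exactly one read.

    These single 4C contacts are uninformative for reproducibility and
    are eliminated before correlation.
    """
    merged = merge_overlapping_reads(reads)
    multi = [
        (f.interval.chrom, f.interval.start, f.interval.end)
        for f in merged
        if f.n_reads > 1
    ]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in multi:
        by_chrom.setdefault(chrom, []).append((s, e))
    kept = []
    for r in reads:
        spans = by_chrom.get(r.interval.chrom, ())
        # merged fragments are disjoint; a read lies in exactly one
        if any(s <= r.interval.start and r.interval.end <= e for s, e in spans):
            kept.append(r)
    return kept


def _bin_reads(
    reads: Sequence[ReadAlignment],
    chrom_lengths: dict[str, int],
    bin_size: int,
) -> np.ndarray:
    """Read counts per genomic bin (reads assigned by midpoint)."""
    pieces = []
    for chrom in sorted(chrom_lengths):
        n_bins = -(-chrom_lengths[chrom] // bin_size)
        vec = np.zeros(n_bins, dtype=np.float64)
        pieces.append((chrom, vec))
    index = dict(pieces)
    for r in reads:
        if r.interval.chrom not in index:
            continue
        mid = (r.interval.start + r.interval.end) // 2
        b = min(mid // bin_size, len(index[r.interval.chrom]) - 1)
        index[r.interval.chrom][b] += r.weight
    return np.concatenate([vec for _, vec in pieces])


def replicate_correlation(
    reads_rep1: Sequence[ReadAlignment],
    reads_rep2: Sequence[ReadAlignment],
    chrom_lengths: dict[str, int],
    params: QcParams | None = None,
) -> float:
    """Pearson r between binned, RPKM-normalized replicate coverages.

    Singleton contacts are removed first (when ``drop_singletons``),
    then each replicate is binned over the genome and normalized.
    Raises when either binned vector has zero variance, where the
    correlation is undefined.
    """
    params = params or QcParams()
    r1 = remove_singleton_reads(reads_rep1) if params.drop_singletons else list(reads_rep1)
    r2 = remove_singleton_reads(reads_rep2) if params.drop_singletons else list(reads_rep2)
    v1 = _bin_reads(r1, chrom_lengths, params.bin_size)
    v2 = _bin_reads(r2, chrom_lengths, params.bin_size)
    if params.normalization == "RPKM":
        t1, t2 = v1.sum(), v2.sum()
        if t1 <= 0 or t2 <= 0:
            raise ValueError("a replicate has no reads after singleton removal")
        v1 = rpkm_normalize(v1, params.bin_size, int(t1))
        v2 = rpkm_normalize(v2, params.bin_size, int(t2))
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in a binned replicate: correlation undefined")
    return float(sps.pearsonr(v1, v2).statistic)


def _random_k_subset(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Uniform k-subset of range(n).

    Equivalent to taking the first k elements of a Fisher–Yates
    shuffle; implemented as numpy's partial (Floyd-style) sampler,
    which draws the identical distribution while touching only k
    positions.
    """
    return rng.choice(n, size=k, replace=False)


def sample_overlap_null(
    universe_size: int,
    list_size: int,
    n_reps: int,
    seed: int,
) -> OverlapNullSummary:
    """Simulated null of overlap between random equal-size gene lists.

    One seeded shuffle fixes the reference list (its first
    ``list_size`` elements); each repetition re-shuffles and counts how
    many of its first ``list_size`` elements coincide with the
    reference. Summaries are fractions of the list size.
    """
    n, k, m = universe_size, list_size, n_reps
    if not (0 < k <= n):
        raise ValueError(f"need 0 < list_size <= universe_size, got k={k}, N={n}")
    if m < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    reference = _random_k_subset(rng, n, k)
    is_ref = np.zeros(n, dtype=bool)
    is_ref[reference] = True
    overlaps = np.empty(m, dtype=np.int64)
    for i in range(m):
        overlaps[i] = int(is_ref[_random_k_subset(rng, n, k)].sum())
    fractions = overlaps / k
    return OverlapNullSummary(
        universe_size=n,
        list_size=k,
        n_reps=m,
        overlaps=overlaps,
        mean_fraction=float(fractions.mean()),
        sd_fraction=float(fractions.std(ddof=1)) if m > 1 else 0.0,
        min_fraction=float(fractions.min()),
        max_fraction=float(fractions.max()),
        seed=seed,
    )


def hypergeometric_overlap_moments(
    universe_size: int, list_size: int
) -> tuple[float, float]:
    """Closed-form mean and sd of the overlap fraction.

    For independent uniform k-subsets A, B of an N-universe,
    |A ∩ B| ~ Hypergeom(N, k, k): mean k²/N and
    var k·(k/N)·(1−k/N)·(N−k)/(N−1). Returned as fractions of k.
    """
    n, k = universe_size, list_size
    if not (0 < k <= n):
        raise ValueError(f"need 0 < list_size <= universe_size, got k={k}, N={n}")
    mean = k * k / n
    if n == 1:
        var = 0.0
    else:
        var = k * (k / n) * (1 - k / n) * (n - k) / (n - 1)
    return mean / k, float(np.sqrt(var)) / k


def empirical_p(observed_overlap: int, null: OverlapNullSummary) -> float:
    """One-sided (enrichment) add-one empirical p-value.

    p = (#{reps with overlap >= observed} + 1) / (m + 1); bounded below
    by 1/(m+1), never exactly zero.
    """
    m = null.n_reps
    b = int(np.count_nonzero(null.overlaps >= observed_overlap))
    return (b + 1) / (m + 1)


def list_overlap(
    list_a: Sequence[str], list_b: Sequence[str]
) -> tuple[int, float, float]:
    """Exact intersection count with both normalizations.

    Returns (count, fraction of |A|, fraction of |A ∪ B|). Duplicate
    identifiers within a list are rejected — lists must be
    de-duplicated first.
    """
    a, b = set(list_a), set(list_b)
    if len(a) != len(list_a):
        raise ValueError("duplicate identifiers in first list")
    if len(b) != len(list_b):
        raise ValueError("duplicate identifiers in second list")
    inter = len(a & b)
    union = len(a | b)
    return inter, inter / len(a) if a else 0.0, inter / union if union else 0.0
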