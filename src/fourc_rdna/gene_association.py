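"""Mapping contact fragments to genes and downstream gene tables.

A six-cutter restriction digest localizes a contact to roughly ±2.5 kb,
so each contact fragment is extended by 2,500 nt on each side before
asking which genes it touches. Per-gene totals sum the reads of both
replicates over all associated fragments; genes whose total strictly
exceeds the selection threshold (default 100 reads) form the
rDNA-contacting gene list. Contacts within a configurable radius
(5 Mb at genome scale) of a viewpoint on an acrocentric chromosome are
dominated by proximity ligation in cis and are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contact_calling import ContactFragment
from .io_genomics import GenomicInterval, GeneRecord

__all__ = [
    "AssociationParams",
    "GeneContactCount",
    "CountMatrix",
    "RegionClassAnnotation",
    "extend_fragment",
    "filter_viewpoint_proximity",
    "count_reads_per_gene",
    "select_contact_genes",
    "build_count_matrix",
    "log2fc_table",
    "classify_contact_sites",
]


@dataclass(frozen=True)
class AssociationParams:
    """Fragment-to-gene association settings.

    extension_nt: bases added to EACH side of a fragment before overlap
        (2,500 by default — the digest's ±2.5 kb localization).
    fixed_window: alternative semantics — grow the fragment symmetrically
        to a fixed total width of 2*extension_nt instead of adding
        extension_nt per side.
    gene_read_threshold: strict lower bound on the per-gene read total
        for selection (a gene needs MORE than this many reads).
    viewpoint_radius: half-width of the cis-proximity exclusion zone.
    count_mode: "sum" totals both replicates' reads per gene;
        "mean" averages them.
    """

    extension_nt: int = 2500
    fixed_window: bool = False
    gene_read_threshold: int = 100
    viewpoint_radius: int = 5_000_000
    count_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.extension_nt < 0 or self.gene_read_threshold < 0 or self.viewpoint_radius < 0:
            raise ValueError("association parameters must be >= 0")
        if self.count_mode not in ("sum", "mean"):
            raise ValueError("count_mode must be 'sum' or 'mean'")


@dataclass(frozen=True)
class GeneContactCount:
    """Total contact reads associated with one gene."""

    gene_id: str
    total_reads: int
    fragment_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples integer read-count matrix for export."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix dimensions inconsistent with labels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class RegionClassAnnotation:
    """Ordered (class label, intervals) with precedence for site classes.

    Earlier entries win when a position falls in several classes;
    positions outside every class are reported as ``intergenic``.
    """

    layers: tuple[tuple[str, tuple[GenomicInterval, ...]], ...]
    fallback: str = "intergenic"

    def classify(self, chrom: str, position: int) -> str:
        for label, intervals in self.layers:
            for iv in intervals:
                if iv.chrom == chrom and iv.start <= position < iv.end:
                    return label
        return self.fallback


def extend_fragment(
    frag: ContactFragment | GenomicInterval,
    extension_nt: int,
    chrom_length: int,
    fixed_window: bool = False,
) -> GenomicInterval:
    """Extend a fragment's span, clipped to [0, chrom_length].

    Default semantics add ``extension_nt`` to each side. With
    ``fixed_window`` the fragment is grown symmetrically around its
    midpoint to a total width of 2*extension_nt (if already wider it is
    left unchanged).
    """
    iv = frag if isinstance(frag, GenomicInterval) else frag.interval
    if fixed_window:
        width = 2 * extension_nt
        if iv.end - iv.start >= width:
            start, end = iv.start, iv.end
        else:
            mid = (iv.start + iv.end) // 2
            start, end = mid - width // 2, mid - width // 2 + width
    else:
        start, end = iv.start - extension_nt, iv.end + extension_nt
    return GenomicInterval(iv.chrom, max(0, start), min(chrom_length, end))


def filter_viewpoint_proximity(
    frags: Sequence[ContactFragment],
    viewpoints: Sequence[tuple[str, int]],
    radius: int,
) -> tuple[list[ContactFragment], list[ContactFragment]]:
    """Split fragments into (kept, excluded) around the viewpoints.

    A fragment is excluded when its interval overlaps
    [viewpoint - radius, viewpoint + radius] on the viewpoint's own
    chromosome; fragments on other chromosomes are always kept.
    Kept and excluded partition the input.
    """
    kept: list[ContactFragment] = []
    excluded: list[ContactFragment] = []
    for f in frags:
        near = any(
            f.interval.chrom == chrom
            and f.interval.start <= pos + radius
            and f.interval.end > pos - radius
            for chrom, pos in viewpoints
        )
        (excluded if near else kept).append(f)
    return kept, excluded


def _fragment_reads(frag: ContactFragment, mode: str) -> float:
    if mode == "mean":
        return frag.mean_coverage
    return frag.total_reads


def count_reads_per_gene(
    frags: Sequence[ContactFragment],
    genes: Sequence[GeneRecord],
    params: AssociationParams | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    include_zeros: bool = False,
) -> list[GeneContactCount]:
    """Total associated contact reads for every gene.

    A fragment contributes to every gene its extended interval overlaps
    by >= 1 nt (full multi-overlap counting, no fractional assignment);
    the contribution is the sum of both replicates' reads (or their
    mean with ``count_mode='mean'``). Genes with no associated fragment
    are omitted unless ``include_zeros``.
    """
    params = params or AssociationParams()
    totals: dict[str, float] = {}
    frag_lists: dict[str, list[str]] = {}
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, chrom_genes in genes_by_chrom.items():
        chrom_genes.sort(key=lambda g: (g.interval.start, g.interval.end))
    for frag in frags:
        chrom = frag.interval.chrom
        if chrom not in genes_by_chrom:
            continue
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else max(g.interval.end for g in genes_by_chrom[chrom]) + params.extension_nt + 1
        )
        ext = extend_fragment(frag, params.extension_nt, length, params.fixed_window)
        for g in genes_by_chrom[chrom]:
            if g.interval.start < ext.end and ext.start < g.interval.end:
                totals[g.gene_id] = totals.get(g.gene_id, 0.0) + _fragment_reads(
                    frag, params.count_mode
                )
                frag_lists.setdefault(g.gene_id, []).append(frag.fragment_id)
    out = []
    for g in genes:
        if g.gene_id in totals:
            total = totals[g.gene_id]
            out.append(
                GeneContactCount(
                    g.gene_id,
                    int(round(total)),
                    tuple(frag_lists[g.gene_id]),
                )
            )
        elif include_zeros:
            out.append(GeneContactCount(g.gene_id, 0, ()))
    return out


def select_contact_genes(
    counts: Sequence[GeneContactCount], threshold: int = 100
) -> list[GeneContactCount]:
    """Genes whose read total strictly exceeds the threshold.

    Ranked by total_reads descending; ties broken lexicographically by
    gene_id.
    """
    chosen = [c for c in counts if c.total_reads > threshold]
    return sorted(chosen, key=lambda c: (-c.total_reads, c.gene_id))


def build_count_matrix(
    frags_by_sample: Mapping[str, Sequence[ContactFragment]],
    genes: Sequence[GeneRecord],
    params: AssociationParams | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Genes x samples matrix of associated reads under the extension rule.

    Every annotated gene appears as a row (zeros included) so the
    matrix is directly exportable to external differential tools.
    """
    params = params or AssociationParams()
    if not frags_by_sample:
        raise ValueError("at least one sample required")
    sample_ids = tuple(sorted(frags_by_sample))
    gene_ids = tuple(g.gene_id for g in genes)
    mat = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for j, sample in enumerate(sample_ids):
        counts = count_reads_per_gene(
            frags_by_sample[sample], genes, params, chrom_lengths, include_zeros=False
        )
        for c in counts:
            mat[gene_index[c.gene_id], j] = c.total_reads
    return CountMatrix(gene_ids, sample_ids, mat)


def log2fc_table(
    matrix: CountMatrix,
    condition_of_sample: Mapping[str, str],
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Descriptive per-gene log2 fold change between two condition groups.

    Samples are normalized by per-sample total counts (library size)
    when ``normalize``; the ratio is
    log2((mean cond2 + pseudocount) / (mean cond1 + pseudocount)) with
    conditions taken in sorted label order. No inferential statistics
    are produced — the matrix is meant for export to a dedicated
    differential package.
    """
    conditions = sorted(set(condition_of_sample.values()))
    if len(conditions) != 2:
        raise ValueError(f"exactly two condition groups required, got {conditions}")
    groups = {c: [s for s in matrix.sample_ids if condition_of_sample[s] == c]
              for c in conditions}
    for c, members in groups.items():
        if not members:
            raise ValueError(f"condition {c!r} has no samples in the matrix")
    df = matrix.to_frame().astype(float)
    if normalize:
        libsize = df.sum(axis=0)
        scale = libsize.mean() / libsize.replace(0, np.nan)
        df = df * scale.fillna(0.0)
    mean1 = df[groups[conditions[0]]].mean(axis=1)
    mean2 = df[groups[conditions[1]]].mean(axis=1)
    log2fc = np.log2((mean2 + pseudocount) / (mean1 + pseudocount))
    return pd.DataFrame(
        {
            f"mean_{conditions[0]}": mean1,
            f"mean_{conditions[1]}": mean2,
            "log2fc": log2fc,
        }
    )


def classify_contact_sites(
    centers: Iterable[tuple[str, int]],
    annotation: RegionClassAnnotation,
) -> dict[str, float]:
    """Fraction of contact-site centers in each genomic context class.

    Each center takes the highest-precedence class containing it;
    centers outside all classes fall back to ``intergenic``. Fractions
    sum to 1 over a non-empty input.
    """
    centers = list(centers)
    if not centers:
        return {}
    tally: dict[str, int] = {}
    for chrom, pos in centers:
        label = annotation.classify(chrom, pos)
        tally[label] = tally.get(label, 0) + 1
    n = len(centers)
    return {label: count / n for label, count in sorted(tally.items())}
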