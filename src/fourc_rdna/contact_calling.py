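"""Reproducible contact calling from per-replicate mapped reads.

Reads that intersect by at least one nucleotide belong to the same
contact: within each replicate, reads are merged into the connected
components of their overlap graph. Components supported by both
biological replicates are unioned across replicates into candidate
contact fragments; a candidate's coverage is the arithmetic mean of
the per-replicate read counts and candidates with mean coverage below
the detection threshold (default 40) are discarded.

Under half-open coordinates "intersect by at least one nucleotide"
means overlap length >= 1; book-ended intervals (end == next start) do
not merge unless ``merge_bookended`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_genomics import GenomicInterval, ReadAlignment

__all__ = [
    "ContactFragment",
    "CallingParams",
    "MergedFragment",
    "merge_overlapping_reads",
    "intersect_replicates",
    "score_and_filter",
    "call_contacts",
]


@dataclass(frozen=True)
class MergedFragment:
    """A within-replicate merged read cluster: interval plus read count."""

    interval: GenomicInterval
    n_reads: int
    replicate_id: str = ""


@dataclass(frozen=True)
class ContactFragment:
    """A replicate-reproducible merged contact with per-replicate counts."""

    interval: GenomicInterval
    reads_per_replicate: Mapping[str, int]
    mean_coverage: float
    fragment_id: str = ""

    def __post_init__(self) -> None:
        expected = float(np.mean(list(self.reads_per_replicate.values())))
        if abs(expected - self.mean_coverage) > 1e-9:
            raise ValueError("mean_coverage must equal the mean of replicate counts")

    @property
    def total_reads(self) -> int:
        return sum(self.reads_per_replicate.values())


@dataclass(frozen=True)
class CallingParams:
    """Detection thresholds for contact calling.

    min_mean_coverage: mean-of-replicates read count a fragment must
        reach to be retained (inclusive comparison).
    require_both_replicates: drop fragments supported by one replicate.
    merge_bookended: treat end == start as intersecting when merging.
    """

    min_mean_coverage: float = 40.0
    require_both_replicates: bool = True
    merge_bookended: bool = False

    def __post_init__(self) -> None:
        if self.min_mean_coverage < 0:
            raise ValueError("min_mean_coverage must be >= 0")


def _merge_sorted(
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    weights: np.ndarray,
    bookended: bool,
) -> list[tuple[GenomicInterval, int]]:
    """Sweep sorted intervals into connected components of the overlap graph."""
    out: list[tuple[GenomicInterval, int]] = []
    cur_start = int(starts[0])
    cur_end = int(ends[0])
    cur_n = int(weights[0])
    for s, e, w in zip(starts[1:], ends[1:], weights[1:]):
        joins = s <= cur_end if bookended else s < cur_end
        if joins:
            cur_end = max(cur_end, int(e))
            cur_n += int(w)
        else:
            out.append((GenomicInterval(chrom, cur_start, cur_end), cur_n))
            cur_start, cur_end, cur_n = int(s), int(e), int(w)
    out.append((GenomicInterval(chrom, cur_start, cur_end), cur_n))
    return out


def merge_overlapping_reads(
    reads: Sequence[ReadAlignment], merge_bookended: bool = False
) -> list[MergedFragment]:
    """Merge reads that share at least one base into contact fragments.

    Output fragments are the connected components of the read-overlap
    graph (transitive closure), disjoint within a chromosome and sorted
    by (chrom, start); each carries the summed read weight of its
    component.
    """
    if not reads:
        return []
    rep_ids = {r.replicate_id for r in reads}
    rep_id = rep_ids.pop() if len(rep_ids) == 1 else ""
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    out: list[MergedFragment] = []
    for chrom in sorted(by_chrom):
        rs = by_chrom[chrom]
        starts = np.array([r.interval.start for r in rs], dtype=np.int64)
        ends = np.array([r.interval.end for r in rs], dtype=np.int64)
        weights = np.array([r.weight for r in rs], dtype=np.int64)
        order = np.lexsort((ends, starts))
        for iv, n in _merge_sorted(
            chrom, starts[order], ends[order], weights[order], merge_bookended
        ):
            out.append(MergedFragment(iv, n, rep_id))
    return out


def intersect_replicates(
    frags_rep1: Sequence[MergedFragment],
    frags_rep2: Sequence[MergedFragment],
    rep1_label: str = "rep1",
    rep2_label: str = "rep2",
    merge_bookended: bool = False,
) -> list[ContactFragment]:
    """Keep cross-replicate overlap components supported by both replicates.

    The bipartite overlap graph between the two replicates' merged
    fragments is resolved into connected components; each component
    that contains fragments from both replicates becomes one candidate
    whose interval is the union span and whose per-replicate counts sum
    the contributing fragments. One-replicate components are dropped.
    """
    if rep1_label == rep2_label:
        raise ValueError("replicate labels must differ")
    tagged = [(f, 0) for f in frags_rep1] + [(f, 1) for f in frags_rep2]
    if not tagged:
        return []
    by_chrom: dict[str, list[tuple[MergedFragment, int]]] = {}
    for f, side in tagged:
        by_chrom.setdefault(f.interval.chrom, []).append((f, side))
    out: list[ContactFragment] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].interval.start, t[0].interval.end))
        comp: list[tuple[MergedFragment, int]] = []
        cur_end = -1

        def flush() -> None:
            counts = [0, 0]
            for f, side in comp:
                counts[side] += f.n_reads
            if counts[0] > 0 and counts[1] > 0:
                start = min(f.interval.start for f, _ in comp)
                end = max(f.interval.end for f, _ in comp)
                rpr = {rep1_label: counts[0], rep2_label: counts[1]}
                out.append(
                    ContactFragment(
                        GenomicInterval(chrom, start, end),
                        rpr,
                        float(np.mean(list(rpr.values()))),
                    )
                )

        for f, side in items:
            joins = (
                f.interval.start <= cur_end
                if merge_bookended
                else f.interval.start < cur_end
            )
            if comp and joins:
                comp.append((f, side))
                cur_end = max(cur_end, f.interval.end)
            else:
                if comp:
                    flush()
                comp = [(f, side)]
                cur_end = f.interval.end
        if comp:
            flush()
    return out


def score_and_filter(
    candidates: Sequence[ContactFragment], params: CallingParams
) -> list[ContactFragment]:
    """Retain candidates whose mean replicate coverage meets the threshold."""
    kept = [c for c in candidates if c.mean_coverage >= params.min_mean_coverage]
    return sorted(kept, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))


def call_contacts(
    reads_by_replicate: Mapping[str, Sequence[ReadAlignment]],
    params: CallingParams | None = None,
) -> list[ContactFragment]:
    """Full calling pass: per-replicate merge, cross-replicate
    reproducibility, coverage threshold.

    Exactly two replicates are expected (the two-biological-replicate
    design). Fragment ids are assigned deterministically in sorted
    genomic order.
    """
    params = params or CallingParams()
    labels = sorted(reads_by_replicate)
    if len(labels) != 2 and params.require_both_replicates:
        raise ValueError(
            f"exactly two replicates required, got {len(labels)}: {labels}"
        )
    merged = {
        label: merge_overlapping_reads(
            reads_by_replicate[label], params.merge_bookended
        )
        for label in labels
    }
    candidates = intersect_replicates(
        merged[labels[0]],
        merged[labels[1]],
        rep1_label=labels[0],
        rep2_label=labels[1],
        merge_bookended=params.merge_bookended,
    )
    retained = score_and_filter(candidates, params)
    return [
        ContactFragment(
            f.interval, f.reads_per_replicate, f.mean_coverage, f"frag{i + 1:05d}"
        )
        for i, f in enumerate(retained)
    ]
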