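"""Genomic data model and plain-text format I/O.

All coordinates inside the package are 0-based half-open, the BED
convention. BED and bedGraph are read and written natively; GTF gene
coordinates (1-based closed) are converted on read. Strand is parsed
where present but ignored by all downstream set operations.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "ReadAlignment",
    "SignalTrack",
    "GeneRecord",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_gtf_genes",
    "read_bedgraph",
    "write_bedgraph",
    "check_chromosome_namespace",
]


class FormatError(ValueError):
    """A file violates its format contract (coordinates, overlap, values)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chrom/start/end span, 0-based half-open.

    The atom of every set operation in the pipeline: mapped reads,
    merged contact fragments, gene bodies and signal steps are all
    carried as intervals.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped read: the ingestion boundary for upstream alignment."""

    interval: GenomicInterval
    read_id: str
    replicate_id: str = ""
    weight: int = 1

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("read weight must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its span and class labels (e.g. lincRNA, miRNA, ZNF)."""

    gene_id: str
    name: str
    interval: GenomicInterval
    classes: frozenset = field(default_factory=frozenset)


class SignalTrack:
    """Per-chromosome step function: sorted, non-overlapping (interval, value).

    Stored as numpy arrays (starts, ends, values) keyed by chromosome.
    """

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        for chrom, (starts, ends, values) in steps.items():
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged step arrays")
            if np.any(starts >= ends):
                raise FormatError(f"{chrom}: empty or inverted step interval")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping or unsorted steps")
            if not np.all(np.isfinite(values)):
                raise FormatError(f"{chrom}: non-finite signal value")
        self._steps = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64),
                np.asarray(v, dtype=np.float64))
            for c, (s, e, v) in steps.items()
        }

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        steps = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            steps[chrom] = (starts, ends, values)
        return cls(steps)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps[chrom]

    def n_steps(self) -> int:
        return sum(len(s) for s, _, _ in self._steps.values())

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._steps[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean of the step values over [start, end).

        Bases not covered by any step contribute value 0.
        """
        if end <= start:
            raise ValueError("empty query window")
        if chrom not in self._steps:
            return 0.0
        starts, ends, values = self._steps[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = (np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start))
        return float(np.dot(ov, values[lo:hi]) / (end - start))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, replicate_id: str = "") -> list[ReadAlignment]:
    """Read a BED3/BED4+ file into read alignments.

    The optional 4th column becomes ``read_id``; otherwise an id is
    synthesized from the line number. Coordinates are taken verbatim
    (BED is already 0-based half-open).
    """
    path = Path(path)
    reads: list[ReadAlignment] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            read_id = fields[3] if len(fields) >= 4 and fields[3] else f"read{lineno}"
            reads.append(ReadAlignment(interval, read_id, replicate_id))
    return reads


def write_bed(items: Sequence, path: str | Path) -> None:
    """Write intervals, reads or fragments as BED.

    Accepts GenomicInterval, or any object with an ``interval``
    attribute and optionally a name-like attribute (``read_id`` or
    ``fragment_id``) that becomes column 4. Round-trips exactly
    through :func:`read_bed`.
    """
    path = Path(path)
    with path.open("w") as fh:
        for item in items:
            iv = item if isinstance(item, GenomicInterval) else item.interval
            name = getattr(item, "fragment_id", None) or getattr(item, "read_id", None)
            if name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(path: str | Path) -> list[GeneRecord]:
    """Read gene features from a GTF annotation.

    Only rows whose feature column is ``gene`` are kept. GTF 1-based
    closed coordinates are converted to 0-based half-open, so the
    interval length equals (GTF end − GTF start + 1). ``gene_biotype``
    (or ``gene_type``) is mapped into the class label set.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: gene feature lacks gene_id")
            gene_id = attrs["gene_id"]
            seen[gene_id] = seen.get(gene_id, 0) + 1
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            interval = GenomicInterval(fields[0], start1 - 1, end1)
            classes = set()
            biotype = attrs.get("gene_biotype") or attrs.get("gene_type")
            if biotype:
                classes.add(biotype)
            if "gene_class" in attrs:
                classes.update(attrs["gene_class"].split(","))
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    name=attrs.get("gene_name", gene_id),
                    interval=interval,
                    classes=frozenset(classes),
                )
            )
    dupes = sorted(g for g, n in seen.items() if n > 1)
    if dupes:
        raise FormatError(f"{path}: duplicate gene_id(s): {', '.join(dupes)}")
    return genes


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a step-function track.

    Intervals within a chromosome must not overlap; values must parse
    as finite floats.
    """
    path = Path(path)
    records: list[tuple[str, int, int, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates/value") from exc
            if not np.isfinite(value):
                raise FormatError(f"{path}:{lineno}: non-finite value {fields[3]}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            records.append((fields[0], start, end, value))
    try:
        return SignalTrack.from_records(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def check_chromosome_namespace(
    reads_chroms: Iterable[str], annotation_chroms: Iterable[str]
) -> dict[str, int]:
    """Warn when reads and annotation use disjoint chromosome names.

    Matching is exact string equality — no "chr" aliasing. Returns the
    per-chromosome read counts for the names absent from the annotation.
    """
    read_counts: dict[str, int] = {}
    for c in reads_chroms:
        read_counts[c] = read_counts.get(c, 0) + 1
    ann = set(annotation_chroms)
    missing = {c: n for c, n in read_counts.items() if c not in ann}
    if missing:
        detail = ", ".join(f"{c}: {n}" for c, n in sorted(missing.items()))
        warnings.warn(
            f"chromosome names absent from annotation (exact matching, no "
            f"'chr' aliasing) — {detail}",
            stacklevel=2,
        )
    return missing
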