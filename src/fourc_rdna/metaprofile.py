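"""Signal metaprofiles around contact-fragment centers.

Windows of ±half_width (default 1,500 bp) around fragment centers are
binned, averaged column-wise, and standardized against a seeded
random-window background drawn from the same track, giving a z-scored
enrichment profile. Windows that would run past a chromosome edge are
dropped and counted rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .contact_calling import ContactFragment
from .io_genomics import SignalTrack

__all__ = [
    "ProfileParams",
    "MetaProfile",
    "fragment_center",
    "extract_windows",
    "aggregate_profile",
    "zscore_profile",
    "build_metaprofile",
]


@dataclass(frozen=True)
class ProfileParams:
    """Window geometry and background sampling for metaprofiles."""

    half_width: int = 1500
    bin_size: int = 50
    n_background_windows: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.bin_size <= 0:
            raise ValueError("half_width and bin_size must be positive")
        if self.half_width % self.bin_size != 0:
            raise ValueError("half_width must be divisible by bin_size")
        if self.n_background_windows < 2:
            raise ValueError("need >= 2 background windows for a sd")

    @property
    def n_bins(self) -> int:
        return 2 * self.half_width // self.bin_size


@dataclass(frozen=True)
class MetaProfile:
    """Aggregated profile: per-bin mean signal and z-score vs background."""

    bin_edges: np.ndarray  # left edge offsets relative to center, bp
    n_regions: int
    mean_signal: np.ndarray
    z_signal: np.ndarray
    background_mean: float
    background_sd: float
    n_dropped: int
    seed: int


def fragment_center(frag: ContactFragment) -> tuple[str, int]:
    """Midpoint of a fragment, floor((start+end)/2); always inside it."""
    iv = frag.interval
    return iv.chrom, (iv.start + iv.end) // 2


def _window_row(
    track: SignalTrack, chrom: str, center: int, params: ProfileParams
) -> np.ndarray:
    lo = center - params.half_width
    row = np.empty(params.n_bins, dtype=np.float64)
    for i in range(params.n_bins):
        row[i] = track.mean_in(
            chrom, lo + i * params.bin_size, lo + (i + 1) * params.bin_size
        )
    return row


def extract_windows(
    track: SignalTrack,
    centers: Sequence[tuple[str, int]],
    params: ProfileParams,
    chrom_lengths: Mapping[str, int],
) -> tuple[np.ndarray, int]:
    """Binned signal matrix (regions x bins) around the centers.

    Bin values are length-weighted means of the overlapping track
    steps. Centers whose window would cross a chromosome edge are
    dropped; returns (matrix, n_dropped).
    """
    if not centers:
        raise ValueError("no centers supplied")
    rows = []
    dropped = 0
    for chrom, center in centers:
        length = chrom_lengths.get(chrom)
        if (
            length is None
            or center - params.half_width < 0
            or center + params.half_width > length
        ):
            dropped += 1
            continue
        rows.append(_window_row(track, chrom, center, params))
    matrix = (
        np.vstack(rows) if rows else np.empty((0, params.n_bins), dtype=np.float64)
    )
    return matrix, dropped


def aggregate_profile(matrix: np.ndarray) -> np.ndarray:
    """Column-wise mean over regions; invariant to row order."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("need a non-empty regions x bins matrix")
    return matrix.mean(axis=0)


def zscore_profile(
    mean_signal: np.ndarray,
    track: SignalTrack,
    chrom_lengths: Mapping[str, int],
    params: ProfileParams,
) -> tuple[np.ndarray, float, float]:
    """Standardize a mean profile against random same-width windows.

    The background is the per-window mean binned signal over
    ``n_background_windows`` uniformly placed (seeded) windows of the
    same width; z[i] = (mean_signal[i] − bg_mean)/bg_sd. A constant
    track gives bg_sd = 0, where the z-score is undefined and an error
    is raised.
    """
    rng = np.random.default_rng(params.seed)
    chroms = sorted(c for c, ln in chrom_lengths.items() if ln >= 2 * params.half_width)
    if not chroms:
        raise ValueError("no chromosome long enough for a background window")
    lengths = np.array([chrom_lengths[c] - 2 * params.half_width for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum() if lengths.sum() > 0 else None
    bg = np.empty(params.n_background_windows, dtype=np.float64)
    for i in range(params.n_background_windows):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        center = int(
            rng.integers(params.half_width, chrom_lengths[chrom] - params.half_width + 1)
        )
        bg[i] = _window_row(track, chrom, center, params).mean()
    bg_mean = float(bg.mean())
    bg_sd = float(bg.std(ddof=1))
    if bg_sd == 0:
        raise ValueError(
            "degenerate background (sd = 0, e.g. a constant track): z-score undefined"
        )
    z = (np.asarray(mean_signal, dtype=np.float64) - bg_mean) / bg_sd
    return z, bg_mean, bg_sd


def build_metaprofile(
    track: SignalTrack,
    frags: Sequence[ContactFragment],
    chrom_lengths: Mapping[str, int],
    params: ProfileParams | None = None,
) -> MetaProfile:
    """Full metaprofile pass: centers -> windows -> mean -> z-score."""
    params = params or ProfileParams()
    centers = [fragment_center(f) for f in frags]
    matrix, dropped = extract_windows(track, centers, params, chrom_lengths)
    if matrix.shape[0] == 0:
        raise ValueError("all windows dropped at chromosome edges")
    mean_signal = aggregate_profile(matrix)
    z, bg_mean, bg_sd = zscore_profile(mean_signal, track, chrom_lengths, params)
    edges = np.arange(-params.half_width, params.half_width, params.bin_size)
    return MetaProfile(
        bin_edges=edges,
        n_regions=matrix.shape[0],
        mean_signal=mean_signal,
        z_signal=z,
        background_mean=bg_mean,
        background_sd=bg_sd,
        n_dropped=dropped,
        seed=params.seed,
    )
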