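"""Synthetic 4C-rDNA experiments with known ground truth.

The generator emulates the statistical structure of a two-replicate,
two-condition 4C experiment against an rDNA viewpoint on an
acrocentric chromosome, at desk scale (a few 10 Mb chromosomes):

* a toy genome with restriction-fragment boundaries (a fixed grid by
  default, or exact six-cutter motif matches of a generated sequence);
* a gene annotation with class labels (lincRNA, miRNA, ZNF);
* planted contact fragments of five kinds — reproducible (mean
  coverage above the detection threshold in both replicates),
  sub-threshold (reproducible but mean coverage below threshold),
  one-replicate-only, singleton noise (one read in one replicate), and
  cis-proximal (reproducible contacts inside the viewpoint vicinity);
* reads materializing exactly the planted per-replicate counts, tiled
  so the merged read span reproduces the planted interval;
* condition-dependent rewiring: a configurable fraction of
  reproducible contacts gain or lose coverage in condition 2;
* signal tracks with Gaussian enrichment planted at chosen centers.

Ground truth (fragment labels, planted counts, per-gene read totals
under the association rule, the expected selected gene list) is
computed at generation time from the planted geometry, so downstream
tests can assert exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .contact_calling import ContactFragment
from .gene_association import AssociationParams, count_reads_per_gene, select_contact_genes
from .io_genomics import GeneRecord, GenomicInterval, ReadAlignment, SignalTrack

__all__ = [
    "SyntheticConfig",
    "GenomeModel",
    "PlantedFragment",
    "ContactTruth",
    "build_toy_genome",
    "simulate_gene_annotation",
    "plant_contacts",
    "simulate_reads",
    "simulate_signal_track",
    "write_fixture",
    "REPLICATES",
    "CONDITIONS",
]

REPLICATES = ("rep1", "rep2")
CONDITIONS = ("ctrl", "hs")

#: planted-fragment labels
LABEL_REPRODUCIBLE = "reproducible"
LABEL_SUB_THRESHOLD = "sub_threshold"
LABEL_ONE_REP = "one_replicate_only"
LABEL_SINGLETON = "singleton_noise"
LABEL_CIS = "cis_proximal"

ECORI_MOTIF = "GAATTC"


@dataclass(frozen=True)
class SyntheticConfig:
    """Scales, coverage distributions and effect sizes of the toy study.

    Defaults are a desk-scale analog of the real design: three 10 Mb
    chromosomes (one acrocentric carrying the rDNA viewpoint), 200
    genes, 50 reproducible contacts, and decoy classes on either side
    of the calling thresholds. Per-replicate coverage of reproducible
    contacts is a negative binomial shifted above the detection
    threshold (floor + NB(mean, dispersion)), the standard
    overdispersed model for sequencing counts; high-coverage contacts
    target per-gene totals above the 100-read selection threshold and
    low-coverage ones stay at or below it.
    """

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    n_acrocentric: int = 1
    viewpoint_offset: int = 1_500_000  # viewpoint position on each acrocentric chrom
    viewpoint_radius: int = 500_000    # toy-scale cis-exclusion radius (5 Mb at genome scale)
    grid_spacing: int = 4_000          # restriction-fragment size in grid mode
    sequence_mode: bool = False        # place sites at exact cutter-motif matches instead
    # genes
    n_genes: int = 200
    gene_length_log_mean: float = 9.6  # lognormal ~ median 15 kb
    gene_length_log_sd: float = 0.7
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"lincRNA": 0.10, "miRNA": 0.10, "ZNF": 0.10}
    )
    # planted contacts
    n_reproducible_contacts: int = 50
    frac_high_coverage: float = 0.6    # targeted to exceed the gene selection threshold
    frac_contacts_on_genes: float = 0.7
    high_floor: int = 60               # per-replicate count floor, high class
    high_nb_mean: float = 15.0
    low_count_range: tuple[int, int] = (40, 48)  # per-replicate counts, low class
    nb_dispersion: float = 8.0
    n_subthreshold: int = 10
    sub_count_range: tuple[int, int] = (5, 35)
    n_one_rep_only: int = 10
    one_rep_floor: int = 40
    n_singletons: int = 30
    n_cis_proximal: int = 4
    condition_effect: float = 0.3      # fraction of reproducible contacts rewired in condition 2
    gain_factor: int = 3
    loss_count_range: tuple[int, int] = (5, 15)
    # reads
    read_length: int = 150
    read_jitter: int = 0
    # association (mirrors the analysis defaults at toy scale)
    extension_nt: int = 2500
    gene_read_threshold: int = 100
    # signal tracks
    track_step: int = 100
    track_baseline: float = 1.0
    track_noise_sd: float = 0.25
    enrichment_amplitude: float = 8.0
    enrichment_width: float = 300.0

    def __post_init__(self) -> None:
        if self.n_chroms < 1:
            raise ValueError("need at least one chromosome")
        if not (0 < self.n_acrocentric <= self.n_chroms):
            raise ValueError("n_acrocentric must be in [1, n_chroms]")
        if self.viewpoint_offset >= self.chrom_length:
            raise ValueError("viewpoint_offset beyond chromosome end")
        for name in (
            "n_genes", "n_reproducible_contacts", "n_subthreshold",
            "n_one_rep_only", "n_singletons", "n_cis_proximal",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_high_coverage", "frac_contacts_on_genes", "condition_effect"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    def high_concordance(self) -> "SyntheticConfig":
        """Variant without replicate-specific signal, for replicate QC.

        Biological replicates of the same library share their contact
        set; one-replicate-only fragments are the non-shared component,
        so the high-concordance setting removes them.
        """
        return replace(self, n_one_rep_only=0, n_singletons=10)


@dataclass(frozen=True)
class GenomeModel:
    """Toy genome: chromosome sizes, acrocentrics, viewpoints, cut sites."""

    chrom_sizes: Mapping[str, int]
    acrocentric: frozenset
    viewpoints: tuple[tuple[str, int], ...]
    restriction_sites: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if not set(self.acrocentric) <= set(self.chrom_sizes):
            raise ValueError("acrocentric chroms must be a subset of the genome")
        for chrom, pos in self.viewpoints:
            if chrom not in self.acrocentric:
                raise ValueError(f"viewpoint on non-acrocentric chrom {chrom}")
            if not (0 <= pos < self.chrom_sizes[chrom]):
                raise ValueError(f"viewpoint beyond {chrom} end")
        for chrom, sites in self.restriction_sites.items():
            if len(sites) and (np.any(np.diff(sites) <= 0) or sites[-1] >= self.chrom_sizes[chrom]):
                raise ValueError(f"{chrom}: restriction sites must be sorted, unique, in range")

    def fragments(self, chrom: str) -> np.ndarray:
        """Restriction fragments as an array of (start, end) rows."""
        sites = self.restriction_sites[chrom]
        bounds = np.concatenate(([0], sites, [self.chrom_sizes[chrom]]))
        return np.column_stack([bounds[:-1], bounds[1:]])


@dataclass(frozen=True)
class PlantedFragment:
    """One planted contact: interval, class label, per-(condition, replicate) counts."""

    interval: GenomicInterval
    label: str
    counts: Mapping[str, Mapping[str, int]]  # condition -> replicate -> reads


@dataclass(frozen=True)
class ContactTruth:
    """Planted fragments plus geometry-derived expectations.

    gene_totals / selected_gene_ids are computed per condition from the
    fragments expected to survive calling and the viewpoint filter
    (label ``reproducible``), under the same extension/overlap rule the
    analysis applies, so end-to-end recovery can be asserted exactly.
    """

    fragments: tuple[PlantedFragment, ...]
    associated_gene_ids: Mapping[int, tuple[str, ...]]
    gene_totals: Mapping[str, Mapping[str, int]]  # condition -> gene_id -> reads
    selected_gene_ids: Mapping[str, frozenset]    # condition -> genes with total > threshold
    expected_called_labels: frozenset = frozenset({LABEL_REPRODUCIBLE, LABEL_CIS})

    def expected_called(self, condition: str = "ctrl") -> list[PlantedFragment]:
        """Fragments call_contacts should return for a condition, sorted."""
        out = [
            f
            for f in self.fragments
            if f.label in self.expected_called_labels
            and np.mean([f.counts[condition][r] for r in REPLICATES]) >= 40
            and all(f.counts[condition][r] >= 1 for r in REPLICATES)
        ]
        return sorted(out, key=lambda f: (f.interval.chrom, f.interval.start))

    def planted_counts_total(self, replicate: str, condition: str) -> int:
        return sum(f.counts[condition][replicate] for f in self.fragments)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def build_toy_genome(cfg: SyntheticConfig) -> GenomeModel:
    """Deterministic toy genome from the config.

    Grid mode (default) places restriction sites every ``grid_spacing``
    bases; sequence mode generates a random background sequence with
    the config seed and places a site at every exact EcoRI-motif match.
    """
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    acro = frozenset(f"chr{i + 1}" for i in range(cfg.n_acrocentric))
    viewpoints = tuple((c, cfg.viewpoint_offset) for c in sorted(acro))
    sites: dict[str, np.ndarray] = {}
    if cfg.sequence_mode:
        rng = np.random.default_rng(cfg.seed)
        motif = np.frombuffer(ECORI_MOTIF.encode(), dtype=np.uint8)
        for chrom, length in chrom_sizes.items():
            seq = rng.integers(0, 4, size=length, dtype=np.uint8)
            seq = np.frombuffer(b"ACGT", dtype=np.uint8)[seq]
            hits = np.ones(length - len(motif) + 1, dtype=bool)
            for j, base in enumerate(motif):
                hits &= seq[j : j + len(hits)] == base
            sites[chrom] = np.flatnonzero(hits).astype(np.int64)
    else:
        for chrom, length in chrom_sizes.items():
            sites[chrom] = np.arange(cfg.grid_spacing, length, cfg.grid_spacing, dtype=np.int64)
    return GenomeModel(chrom_sizes, acro, viewpoints, sites)


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def simulate_gene_annotation(
    genome: GenomeModel, cfg: SyntheticConfig, seed: int | None = None
) -> list[GeneRecord]:
    """Random gene annotation with class labels.

    Genes are distributed over chromosomes proportionally to length,
    with lognormal lengths clipped to fit; a configurable fraction of
    genes carries each class label (labels are disjoint here for
    unambiguous composition reports).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chroms = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.float64)
    if cfg.n_genes == 0:
        return []
    chrom_of = rng.choice(len(chroms), size=cfg.n_genes, p=sizes / sizes.sum())
    lengths = np.exp(
        rng.normal(cfg.gene_length_log_mean, cfg.gene_length_log_sd, size=cfg.n_genes)
    ).astype(np.int64)
    lengths = np.clip(lengths, 200, None)
    # disjoint class assignment by running fraction
    labels: list[frozenset] = []
    bounds = []
    acc = 0.0
    for cls, frac in cfg.class_fractions.items():
        bounds.append((acc, acc + frac, cls))
        acc += frac
    if acc > 1.0:
        raise ValueError("class fractions sum above 1")
    u = rng.random(cfg.n_genes)
    for x in u:
        cls = next((c for lo, hi, c in bounds if lo <= x < hi), None)
        labels.append(frozenset({cls}) if cls else frozenset())
    genes = []
    for i in range(cfg.n_genes):
        chrom = chroms[int(chrom_of[i])]
        length = int(min(lengths[i], genome.chrom_sizes[chrom] - 1))
        if length >= genome.chrom_sizes[chrom]:
            raise ValueError(f"gene length {length} exceeds chromosome {chrom}")
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - length))
        genes.append(
            GeneRecord(
                gene_id=f"G{i + 1:04d}",
                name=f"GENE{i + 1}",
                interval=GenomicInterval(chrom, start, start + length),
                classes=labels[i],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _shifted_nb(rng: np.random.Generator, floor: int, mean: float, dispersion: float) -> int:
    """floor + NegBin(mean, dispersion); dispersion is the NB shape (size)."""
    p = dispersion / (dispersion + mean)
    return floor + int(rng.negative_binomial(dispersion, p))


def _fragment_interval(
    rfrag: tuple[int, int], chrom: str, max_count: int, min_count: int, cfg: SyntheticConfig
) -> GenomicInterval:
    """Planted interval inside a restriction fragment, sized so the
    smallest materialized read count can still tile it connectedly."""
    a, b = int(rfrag[0]), int(rfrag[1])
    if min_count <= 1:
        length = cfg.read_length
    else:
        length = min(b - a, cfg.read_length + (min_count - 1) * (cfg.read_length // 2))
    length = min(length, b - a)
    return GenomicInterval(chrom, a, a + max(length, min(cfg.read_length, b - a)))


def plant_contacts(
    genome: GenomeModel,
    genes: Sequence[GeneRecord],
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> ContactTruth:
    """Plant contact fragments of every class on restriction fragments.

    Each planted fragment occupies its own restriction fragment, so
    reads from different fragments can never merge (book-ended spans do
    not intersect under half-open coordinates). Cis-proximal fragments
    are placed inside the viewpoint vicinity; every other class is kept
    outside it by at least the association extension. A configurable
    fraction of reproducible contacts is placed on genes (the
    restriction fragment containing the gene midpoint); per-gene read
    totals and the expected selected gene list are then derived from
    the planted geometry with the same association rule the analysis
    uses.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    vp_zones: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos in genome.viewpoints:
        vp_zones.setdefault(chrom, []).append(
            (pos - cfg.viewpoint_radius, pos + cfg.viewpoint_radius)
        )

    def in_cis(chrom: str, start: int, end: int, margin: int = 0) -> bool:
        return any(
            start <= hi + margin and end > lo - margin
            for lo, hi in vp_zones.get(chrom, ())
        )

    # free restriction fragments, split into cis and far pools
    used: set[tuple[str, int]] = set()
    far_pool: list[tuple[str, int, int, int]] = []  # chrom, idx, start, end
    cis_pool: list[tuple[str, int, int, int]] = []
    for chrom in sorted(genome.chrom_sizes):
        for idx, (a, b) in enumerate(genome.fragments(chrom)):
            a, b = int(a), int(b)
            if in_cis(chrom, a, b):
                cis_pool.append((chrom, idx, a, b))
            elif not in_cis(chrom, a, b, margin=cfg.extension_nt):
                far_pool.append((chrom, idx, a, b))

    n_total_far = (
        cfg.n_reproducible_contacts + cfg.n_subthreshold + cfg.n_one_rep_only + cfg.n_singletons
    )
    if n_total_far > len(far_pool):
        raise ValueError("more planted contacts than available restriction fragments")
    if cfg.n_cis_proximal > len(cis_pool):
        raise ValueError("more cis-proximal contacts than restriction fragments in the vicinity")

    frag_by_key = {(c, i): (c, i, a, b) for c, i, a, b in far_pool}

    # place a fraction of reproducible contacts on genes
    n_on_genes = int(round(cfg.frac_contacts_on_genes * cfg.n_reproducible_contacts))
    eligible_genes = [
        g
        for g in genes
        if not in_cis(g.interval.chrom, g.interval.start, g.interval.end, margin=cfg.extension_nt)
    ]
    rng.shuffle(eligible_genes)
    gene_slots: list[tuple[str, int, int, int]] = []
    for g in eligible_genes:
        if len(gene_slots) == n_on_genes:
            break
        mid = (g.interval.start + g.interval.end) // 2
        sites = genome.restriction_sites[g.interval.chrom]
        idx = int(np.searchsorted(sites, mid, side="right"))
        key = (g.interval.chrom, idx)
        if key in used or key not in frag_by_key:
            continue
        used.add(key)
        gene_slots.append(frag_by_key[key])
    # remaining placements from the free far pool
    free = [t for t in far_pool if (t[0], t[1]) not in used]
    order = rng.permutation(len(free))
    cursor = 0

    def take_far() -> tuple[str, int, int, int]:
        nonlocal cursor
        while cursor < len(order):
            t = free[int(order[cursor])]
            cursor += 1
            if (t[0], t[1]) not in used:
                used.add((t[0], t[1]))
                return t
        raise ValueError("restriction-fragment pool exhausted")

    planted: list[PlantedFragment] = []

    def add(label: str, slot: tuple[str, int, int, int], counts: dict) -> None:
        chrom, _, a, b = slot
        nonzero = [c for cond in counts.values() for c in cond.values() if c > 0]
        interval = _fragment_interval((a, b), chrom, max(nonzero), min(nonzero), cfg)
        planted.append(PlantedFragment(interval, label, counts))

    n_high = int(round(cfg.frac_high_coverage * cfg.n_reproducible_contacts))
    rep_slots = gene_slots + [take_far() for _ in range(cfg.n_reproducible_contacts - len(gene_slots))]
    rng.shuffle(rep_slots)
    n_rewired = int(round(cfg.condition_effect * cfg.n_reproducible_contacts))
    rewire = {i: ("gain" if j % 2 == 0 else "loss")
              for j, i in enumerate(rng.permutation(cfg.n_reproducible_contacts)[:n_rewired])}
    for i, slot in enumerate(rep_slots):
        if i < n_high:
            ctrl = {
                r: _shifted_nb(rng, cfg.high_floor, cfg.high_nb_mean, cfg.nb_dispersion)
                for r in REPLICATES
            }
        else:
            lo, hi = cfg.low_count_range
            ctrl = {r: int(rng.integers(lo, hi + 1)) for r in REPLICATES}
        mode = rewire.get(i)
        if mode == "gain":
            hs = {r: ctrl[r] * cfg.gain_factor for r in REPLICATES}
        elif mode == "loss":
            llo, lhi = cfg.loss_count_range
            hs = {r: int(rng.integers(llo, lhi + 1)) for r in REPLICATES}
        else:
            hs = dict(ctrl)
        add(LABEL_REPRODUCIBLE, slot, {"ctrl": ctrl, "hs": hs})

    for _ in range(cfg.n_subthreshold):
        lo, hi = cfg.sub_count_range
        ctrl = {r: int(rng.integers(lo, hi + 1)) for r in REPLICATES}
        add(LABEL_SUB_THRESHOLD, take_far(), {"ctrl": ctrl, "hs": dict(ctrl)})

    for j in range(cfg.n_one_rep_only):
        rep = REPLICATES[j % 2]
        c = _shifted_nb(rng, cfg.one_rep_floor, cfg.high_nb_mean, cfg.nb_dispersion)
        counts = {r: (c if r == rep else 0) for r in REPLICATES}
        add(LABEL_ONE_REP, take_far(), {"ctrl": counts, "hs": dict(counts)})

    for j in range(cfg.n_singletons):
        rep = REPLICATES[j % 2]
        counts = {r: (1 if r == rep else 0) for r in REPLICATES}
        add(LABEL_SINGLETON, take_far(), {"ctrl": counts, "hs": dict(counts)})

    cis_order = rng.permutation(len(cis_pool))
    for j in range(cfg.n_cis_proximal):
        slot = cis_pool[int(cis_order[j])]
        ctrl = {
            r: _shifted_nb(rng, cfg.high_floor, cfg.high_nb_mean, cfg.nb_dispersion)
            for r in REPLICATES
        }
        add(LABEL_CIS, slot, {"ctrl": ctrl, "hs": dict(ctrl)})

    # geometry-derived expectations, per condition, from fragments that
    # survive calling AND the viewpoint filter (reproducible only)
    assoc = AssociationParams(
        extension_nt=cfg.extension_nt, gene_read_threshold=cfg.gene_read_threshold
    )
    chrom_lengths = dict(genome.chrom_sizes)
    gene_totals: dict[str, dict[str, int]] = {}
    selected: dict[str, frozenset] = {}
    for cond in CONDITIONS:
        frags = [
            ContactFragment(
                f.interval,
                dict(f.counts[cond]),
                float(np.mean(list(f.counts[cond].values()))),
                f"truth{i}",
            )
            for i, f in enumerate(planted)
            if f.label == LABEL_REPRODUCIBLE
            and all(f.counts[cond][r] >= 1 for r in REPLICATES)
            and np.mean([f.counts[cond][r] for r in REPLICATES]) >= 40
        ]
        counts = count_reads_per_gene(frags, genes, assoc, chrom_lengths)
        gene_totals[cond] = {c.gene_id: c.total_reads for c in counts}
        selected[cond] = frozenset(
            c.gene_id for c in select_contact_genes(counts, cfg.gene_read_threshold)
        )
    associated: dict[int, tuple[str, ...]] = {}
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for i, f in enumerate(planted):
        iv = f.interval
        hits = tuple(
            g.gene_id
            for g in genes_by_chrom.get(iv.chrom, ())
            if g.interval.start < iv.end + cfg.extension_nt
            and iv.start - cfg.extension_nt < g.interval.end
        )
        if hits:
            associated[i] = hits
    return ContactTruth(
        fragments=tuple(planted),
        associated_gene_ids=associated,
        gene_totals=gene_totals,
        selected_gene_ids=selected,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    truth: ContactTruth, cfg: SyntheticConfig, seed: int | None = None
) -> dict[tuple[str, str], list[ReadAlignment]]:
    """Materialize planted counts as read alignments.

    For each (replicate, condition), every planted count c becomes c
    reads of ``read_length`` tiled evenly over the planted interval
    (first read at the start, last read ending at the end), so the
    merged read span reproduces the planted interval exactly and the
    per-fragment read count is conserved. Optional jitter perturbs
    interior read positions; keep it below read_length/4 to preserve
    component connectivity.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out: dict[tuple[str, str], list[ReadAlignment]] = {
        (rep, cond): [] for rep in REPLICATES for cond in CONDITIONS
    }
    for fi, frag in enumerate(truth.fragments):
        iv = frag.interval
        span = iv.end - iv.start
        rlen = min(cfg.read_length, span)
        for cond in CONDITIONS:
            for rep in REPLICATES:
                c = frag.counts[cond][rep]
                if c == 0:
                    continue
                if c == 1:
                    positions = np.array([0.0])
                else:
                    positions = np.linspace(0.0, span - rlen, c)
                positions = np.rint(positions).astype(np.int64)
                if cfg.read_jitter > 0 and c > 2:
                    jit = rng.integers(-cfg.read_jitter, cfg.read_jitter + 1, size=c - 2)
                    positions[1:-1] = np.clip(positions[1:-1] + jit, 0, span - rlen)
                    positions[1:-1].sort()
                for ri, p in enumerate(positions):
                    out[(rep, cond)].append(
                        ReadAlignment(
                            GenomicInterval(iv.chrom, iv.start + int(p), iv.start + int(p) + rlen),
                            read_id=f"f{fi}_{cond}_{rep}_r{ri}",
                            replicate_id=rep,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def simulate_signal_track(
    genome: GenomeModel,
    centers: Sequence[tuple[str, int]],
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> SignalTrack:
    """Baseline noise plus Gaussian enrichment at the given centers.

    The track is a step function with ``track_step``-bp steps; each
    step takes baseline + N(0, noise_sd) noise (clipped at 0) plus
    amplitude * exp(-d²/2w²) for every center at distance d. Amplitude
    0 yields a pure-noise baseline.
    """
    for chrom, pos in centers:
        if chrom not in genome.chrom_sizes or not (0 <= pos < genome.chrom_sizes[chrom]):
            raise ValueError(f"center {chrom}:{pos} outside the genome")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    centers_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in centers:
        centers_by_chrom.setdefault(chrom, []).append(pos)
    steps = {}
    for chrom in sorted(genome.chrom_sizes):
        length = genome.chrom_sizes[chrom]
        starts = np.arange(0, length, cfg.track_step, dtype=np.int64)
        ends = np.minimum(starts + cfg.track_step, length)
        mids = (starts + ends) / 2.0
        values = np.clip(
            cfg.track_baseline + rng.normal(0.0, cfg.track_noise_sd, size=len(starts)),
            0.0,
            None,
        )
        for pos in centers_by_chrom.get(chrom, ()):
            d = mids - pos
            values = values + cfg.enrichment_amplitude * np.exp(
                -(d * d) / (2.0 * cfg.enrichment_width**2)
            )
        steps[chrom] = (starts, ends, values)
    return SignalTrack(steps)


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixture(outdir: str | Path, cfg: SyntheticConfig | None = None) -> dict:
    """Generate the full fixture and write it as plain-text files.

    Writes per-(replicate, condition) read BEDs, the gene annotation as
    GTF, a signal track (enriched at reproducible contact centers) as
    bedGraph, viewpoints as YAML, and a truth table TSV. Returns the
    in-memory objects for direct use.
    """
    import yaml

    cfg = cfg or SyntheticConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = build_toy_genome(cfg)
    genes = simulate_gene_annotation(genome, cfg, seed=cfg.seed + 1)
    truth = plant_contacts(genome, genes, cfg, seed=cfg.seed + 2)
    reads = simulate_reads(truth, cfg, seed=cfg.seed + 3)
    centers = [
        (f.interval.chrom, (f.interval.start + f.interval.end) // 2)
        for f in truth.fragments
        if f.label == LABEL_REPRODUCIBLE
    ]
    track = simulate_signal_track(genome, centers, cfg, seed=cfg.seed + 4)

    from .io_genomics import write_bed, write_bedgraph

    paths: dict[str, Path] = {}
    for (rep, cond), rr in reads.items():
        p = outdir / f"reads_{cond}_{rep}.bed"
        write_bed(rr, p)
        paths[f"reads_{cond}_{rep}"] = p
    gtf = outdir / "genes.gtf"
    with gtf.open("w") as fh:
        for g in genes:
            classes = ",".join(sorted(g.classes))
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            if classes:
                attrs += f' gene_class "{classes}";'
            fh.write(
                f"{g.interval.chrom}\tsynthetic\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t+\t.\t{attrs}\n"
            )
    paths["genes"] = gtf
    trackp = outdir / "track.bedgraph"
    write_bedgraph(track, trackp)
    paths["track"] = trackp
    vp = outdir / "viewpoints.yaml"
    vp.write_text(
        yaml.safe_dump(
            {
                "viewpoints": [{"chrom": c, "position": int(p)} for c, p in genome.viewpoints],
                "radius": cfg.viewpoint_radius,
                "chrom_sizes": {c: int(s) for c, s in genome.chrom_sizes.items()},
            }
        )
    )
    paths["viewpoints"] = vp
    tt = outdir / "truth.tsv"
    with tt.open("w") as fh:
        fh.write("chrom\tstart\tend\tlabel\t" + "\t".join(
            f"{cond}_{rep}" for cond in CONDITIONS for rep in REPLICATES) + "\n")
        for f in truth.fragments:
            counts = "\t".join(
                str(f.counts[cond][rep]) for cond in CONDITIONS for rep in REPLICATES
            )
            fh.write(f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}\t{f.label}\t{counts}\n")
    paths["truth"] = tt
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "reads": reads,
        "track": track,
        "paths": paths,
    }
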