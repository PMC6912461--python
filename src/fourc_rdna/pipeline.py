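"""End-to-end pipeline: QC -> calling -> proximity filter -> association
-> selection -> count matrix -> optional profiles and permutation null.

A single YAML config drives every stage; all seeds are recorded and
every output file carries a hash of the validated config, so a rerun
with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contact_calling import CallingParams, ContactFragment, call_contacts
from .gene_association import (
    AssociationParams,
    RegionClassAnnotation,
    build_count_matrix,
    classify_contact_sites,
    count_reads_per_gene,
    filter_viewpoint_proximity,
    log2fc_table,
    select_contact_genes,
)
from .io_genomics import read_bed, read_bedgraph, read_gtf_genes, write_bed
from .metaprofile import ProfileParams, build_metaprofile, fragment_center
from .stats import QcParams, replicate_correlation, sample_overlap_null

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger("fourc_rdna")


class ConfigError(ValueError):
    """One or more invalid fields; the message lists each field path."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with analysis defaults injected."""

    reads: Mapping[str, Mapping[str, str]]  # condition -> replicate -> BED path
    genes: str
    viewpoints_file: str
    outdir: str
    track: str | None = None
    calling: CallingParams = field(default_factory=CallingParams)
    association: AssociationParams = field(default_factory=AssociationParams)
    qc: QcParams = field(default_factory=QcParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    null: dict | None = None  # {universe_size, list_size, n_reps, seed}
    stages: dict = field(
        default_factory=lambda: {
            "qc": True,
            "calling": True,
            "association": True,
            "count_matrix": True,
            "profile": False,
            "null": False,
        }
    )
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "reads": {c: dict(r) for c, r in self.reads.items()},
            "genes": self.genes,
            "viewpoints_file": self.viewpoints_file,
            "track": self.track,
            "calling": asdict(self.calling),
            "association": asdict(self.association),
            "qc": asdict(self.qc),
            "profile": asdict(self.profile),
            "null": self.null,
            "stages": self.stages,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(section: dict, cls, errors: list[str], prefix: str):
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        errors.append(f"{prefix}: {exc}")
        return cls()


def validate_config(raw: Mapping[str, Any] | str | Path) -> PipelineConfig:
    """Validate a config mapping (or YAML path), injecting defaults.

    The analysis defaults — mean-coverage threshold 40, ±2,500 nt
    extension, gene threshold 100, 5 Mb viewpoint radius, ±1,500 bp
    profile half-width — appear whenever the config omits them. All
    violations are reported together, each naming its field path.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    reads = raw.get("reads")
    if not isinstance(reads, Mapping) or not reads:
        errors.append("reads: missing mapping condition -> replicate -> path")
        reads = {}
    else:
        for cond, reps in reads.items():
            if not isinstance(reps, Mapping) or not reps:
                errors.append(f"reads.{cond}: missing replicate -> path mapping")
                continue
            for rep, path in reps.items():
                if not Path(path).exists():
                    errors.append(f"reads.{cond}.{rep}: file not found: {path}")
    for key in ("genes", "viewpoints_file", "outdir"):
        if not raw.get(key):
            errors.append(f"{key}: required field missing")
        elif key != "outdir" and not Path(raw[key]).exists():
            errors.append(f"{key}: file not found: {raw[key]}")
    track = raw.get("track")
    if track and not Path(track).exists():
        errors.append(f"track: file not found: {track}")
    calling = _build(dict(raw.get("calling", {})), CallingParams, errors, "calling")
    association = _build(dict(raw.get("association", {})), AssociationParams, errors, "association")
    qc = _build(dict(raw.get("qc", {})), QcParams, errors, "qc")
    profile = _build(dict(raw.get("profile", {})), ProfileParams, errors, "profile")
    null = raw.get("null")
    if null is not None:
        for key in ("universe_size", "list_size", "n_reps"):
            if key not in null or int(null[key]) < 1:
                errors.append(f"null.{key}: positive integer required")
    stages = {
        "qc": True,
        "calling": True,
        "association": True,
        "count_matrix": True,
        "profile": track is not None,
        "null": null is not None,
    }
    stages.update(raw.get("stages", {}))
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return PipelineConfig(
        reads={c: dict(r) for c, r in reads.items()},
        genes=str(raw["genes"]),
        viewpoints_file=str(raw["viewpoints_file"]),
        outdir=str(raw["outdir"]),
        track=str(track) if track else None,
        calling=calling,
        association=association,
        qc=qc,
        profile=profile,
        null=dict(null) if null else None,
        stages=stages,
        seed=int(raw.get("seed", 0)),
    )


def _load_viewpoints(path: str) -> tuple[list[tuple[str, int]], dict[str, int], int | None]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    vps = [(v["chrom"], int(v["position"])) for v in data["viewpoints"]]
    sizes = {c: int(s) for c, s in data.get("chrom_sizes", {}).items()}
    radius = data.get("radius")
    return vps, sizes, int(radius) if radius is not None else None


def _stamp(path: Path, cfg_hash: str, body: str) -> None:
    path.write_text(f"# config_hash={cfg_hash}\n{body}")


def _fragments_frame(frags: list[ContactFragment]) -> pd.DataFrame:
    rows = []
    for f in frags:
        row = {
            "fragment_id": f.fragment_id,
            "chrom": f.interval.chrom,
            "start": f.interval.start,
            "end": f.interval.end,
        }
        for rep, n in sorted(f.reads_per_replicate.items()):
            row[f"reads_{rep}"] = n
        row["mean_coverage"] = f.mean_coverage
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and write all outputs.

    Returns the run report (also written as report.json). Stage order:
    QC correlation per condition, contact calling per condition,
    viewpoint-proximity filtering, gene association and selection on
    the first condition, the cross-sample count matrix with a
    descriptive log2 fold change, then optional metaprofile and
    permutation-null stages. Deterministic given the config seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "stages": {},
    }
    viewpoints, chrom_sizes, vp_radius = _load_viewpoints(cfg.viewpoints_file)
    radius = vp_radius if vp_radius is not None else cfg.association.viewpoint_radius
    genes = read_gtf_genes(cfg.genes)
    conditions = sorted(cfg.reads)
    reads = {
        cond: {rep: read_bed(path, replicate_id=rep) for rep, path in cfg.reads[cond].items()}
        for cond in conditions
    }
    if not chrom_sizes:
        chrom_sizes = {}
        for cond in conditions:
            for rr in reads[cond].values():
                for r in rr:
                    chrom_sizes[r.interval.chrom] = max(
                        chrom_sizes.get(r.interval.chrom, 0), r.interval.end
                    )
    report["inputs"] = {
        "n_genes": len(genes),
        "n_reads": {
            cond: {rep: len(rr) for rep, rr in reads[cond].items()} for cond in conditions
        },
        "viewpoints": [list(v) for v in viewpoints],
        "viewpoint_radius": radius,
    }

    if cfg.stages.get("qc"):
        log.info("stage qc: replicate correlation")
        qc_out = {}
        for cond in conditions:
            reps = sorted(reads[cond])
            if len(reps) == 2:
                r = replicate_correlation(
                    reads[cond][reps[0]], reads[cond][reps[1]], chrom_sizes, cfg.qc
                )
                qc_out[cond] = {"pearson_r": r, "replicates": reps}
        (outdir / "qc.json").write_text(
            json.dumps({"config_hash": cfg_hash, "qc": qc_out}, sort_keys=True, indent=1)
        )
        report["stages"]["qc"] = qc_out

    kept_by_cond: dict[str, list[ContactFragment]] = {}
    if cfg.stages.get("calling"):
        log.info("stage calling: merge, reproducibility, threshold")
        calling_out = {}
        for cond in conditions:
            called = call_contacts(reads[cond], cfg.calling)
            kept, excluded = filter_viewpoint_proximity(called, viewpoints, radius)
            kept_by_cond[cond] = kept
            calling_out[cond] = {
                "n_called": len(called),
                "n_excluded_viewpoint_proximal": len(excluded),
                "n_kept": len(kept),
            }
            write_bed(kept, outdir / f"fragments_{cond}.bed")
            _stamp(
                outdir / f"fragments_{cond}.tsv",
                cfg_hash,
                _fragments_frame(kept).to_csv(sep="\t", index=False),
            )
        report["stages"]["calling"] = calling_out

    if cfg.stages.get("association") and kept_by_cond:
        cond0 = conditions[0]
        log.info("stage association: %s fragments -> genes", cond0)
        counts = count_reads_per_gene(
            kept_by_cond[cond0], genes, cfg.association, chrom_sizes
        )
        selected = select_contact_genes(counts, cfg.association.gene_read_threshold)
        sel_ids = {c.gene_id for c in selected}
        name_of = {g.gene_id: g.name for g in genes}
        gene_rows = [
            {
                "gene_id": c.gene_id,
                "name": name_of.get(c.gene_id, c.gene_id),
                "total_reads": c.total_reads,
                "n_fragments": len(c.fragment_ids),
                "selected": c.gene_id in sel_ids,
            }
            for c in sorted(counts, key=lambda c: (-c.total_reads, c.gene_id))
        ]
        _stamp(
            outdir / "genes.tsv",
            cfg_hash,
            pd.DataFrame(gene_rows).to_csv(sep="\t", index=False),
        )
        layers = []
        for cls in ("lincRNA", "miRNA", "ZNF"):
            ivs = tuple(g.interval for g in genes if cls in g.classes)
            if ivs:
                layers.append((cls, ivs))
        layers.append(("gene", tuple(g.interval for g in genes)))
        composition = classify_contact_sites(
            [fragment_center(f) for f in kept_by_cond[cond0]],
            RegionClassAnnotation(tuple(layers)),
        )
        _stamp(
            outdir / "composition.tsv",
            cfg_hash,
            "class\tfraction\n"
            + "".join(f"{k}\t{v:.6f}\n" for k, v in composition.items()),
        )
        report["stages"]["association"] = {
            "condition": cond0,
            "n_genes_with_contacts": len(counts),
            "n_genes_selected": len(selected),
            "composition": composition,
        }

    if cfg.stages.get("count_matrix") and kept_by_cond:
        log.info("stage count_matrix: per-sample quantification")
        frags_by_sample: dict[str, list[ContactFragment]] = {}
        condition_of_sample = {}
        for cond in conditions:
            for f in kept_by_cond.get(cond, []):
                for rep, n in f.reads_per_replicate.items():
                    sample = f"{cond}_{rep}"
                    condition_of_sample[sample] = cond
                    frags_by_sample.setdefault(sample, []).append(
                        ContactFragment(f.interval, {rep: n}, float(n), f.fragment_id)
                    )
        for cond in conditions:
            for rep in cfg.reads[cond]:
                frags_by_sample.setdefault(f"{cond}_{rep}", [])
                condition_of_sample.setdefault(f"{cond}_{rep}", cond)
        matrix = build_count_matrix(frags_by_sample, genes, cfg.association, chrom_sizes)
        _stamp(
            outdir / "count_matrix.tsv",
            cfg_hash,
            matrix.to_frame().to_csv(sep="\t", index_label="gene_id"),
        )
        report["stages"]["count_matrix"] = {
            "shape": list(matrix.counts.shape),
            "column_sums": {
                s: int(matrix.counts[:, j].sum()) for j, s in enumerate(matrix.sample_ids)
            },
        }
        if len(set(condition_of_sample.values())) == 2:
            fc = log2fc_table(matrix, condition_of_sample)
            _stamp(
                outdir / "log2fc.tsv", cfg_hash, fc.to_csv(sep="\t", index_label="gene_id")
            )
            report["stages"]["count_matrix"]["n_log2fc_genes"] = int(len(fc))

    if cfg.stages.get("profile") and cfg.track and kept_by_cond:
        cond0 = conditions[0]
        log.info("stage profile: metaprofile around %s contact centers", cond0)
        track = read_bedgraph(cfg.track)
        mp = build_metaprofile(track, kept_by_cond[cond0], chrom_sizes, cfg.profile)
        profdir = outdir / "profiles"
        profdir.mkdir(exist_ok=True)
        body = "offset\tmean\tz\n" + "".join(
            f"{int(o)}\t{m:.6f}\t{z:.6f}\n"
            for o, m, z in zip(mp.bin_edges, mp.mean_signal, mp.z_signal)
        )
        _stamp(profdir / "profile.tsv", cfg_hash, body)
        report["stages"]["profile"] = {
            "n_regions": mp.n_regions,
            "n_dropped": mp.n_dropped,
            "background_mean": mp.background_mean,
            "background_sd": mp.background_sd,
            "max_z": float(np.max(mp.z_signal)),
            "seed": mp.seed,
        }

    if cfg.stages.get("null") and cfg.null:
        log.info("stage null: permutation overlap null")
        null = sample_overlap_null(
            int(cfg.null["universe_size"]),
            int(cfg.null["list_size"]),
            int(cfg.null["n_reps"]),
            int(cfg.null.get("seed", cfg.seed)),
        )
        body = (
            "universe_size\tlist_size\tn_reps\tseed\tmean_fraction\tsd_fraction"
            "\tmin_fraction\tmax_fraction\trng\n"
            f"{null.universe_size}\t{null.list_size}\t{null.n_reps}\t{null.seed}\t"
            f"{null.mean_fraction:.6f}\t{null.sd_fraction:.6f}\t{null.min_fraction:.6f}"
            f"\t{null.max_fraction:.6f}\t{null.rng_algorithm}\n"
        )
        _stamp(outdir / "null.tsv", cfg_hash, body)
        report["stages"]["null"] = {
            "universe_size": null.universe_size,
            "list_size": null.list_size,
            "n_reps": null.n_reps,
            "mean_fraction": null.mean_fraction,
            "sd_fraction": null.sd_fraction,
            "min_fraction": null.min_fraction,
            "max_fraction": null.max_fraction,
            "seed": null.seed,
        }

    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
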