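"""End-to-end orchestration: calibrate -> occupancy -> QC -> scale ->
filter -> structure features -> integration -> association analyses,
with a manifest that makes reruns auditable and reproducible."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import integrate, riboseq, stats, structure

log = logging.getLogger("ribovelo")


@dataclass
class RunConfig:
    """All paths and stage parameters of one pipeline run."""

    reads: str = ""
    gene_table: str = ""
    cds_fasta: str = ""
    structure_map: str = ""          # TSV: gene_id, path
    outdir: str = "ribovelo_out"
    # calibration
    min_fraction: float = 0.5
    offset_window: tuple[int, int] = (8, 18)
    # scaling / filtering
    exclude_first: int = 5
    exclude_last: int = 5
    coverage_threshold: float = 0.6
    # structure features
    probe_radius: float = 1.4
    sphere_points: int = 960
    contact_cutoff: float = 6.0
    min_separation: int = 2
    idr_window: int = 15
    # statistics
    min_positions: int = 30
    n_tests: int | None = None
    metagene_window: int = 30
    residue_lag: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "offset_window" in data:
            data["offset_window"] = tuple(data["offset_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offset_window"] = list(self.offset_window)
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_TSV_HEADER = (
    "# ribovelo v{version}; coordinates 0-based half-open (codon_index), "
    "residue_index 1-based; see manifest.json\n"
)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER.format(version=__version__))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "inputs": {},
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for key in ("reads", "gene_table", "cds_fasta", "structure_map"):
        p = getattr(config, key)
        if p:
            if not Path(p).exists():
                raise PipelineError("inputs", f"{key} file not found: {p}")
            manifest["inputs"][key] = {"path": p, "sha256": _sha256(Path(p))}

    # --- load inputs -------------------------------------------------------
    stage = "load"
    try:
        if str(config.reads).endswith((".bam", ".sam")):
            reads = riboseq.read_alignments(config.reads)
        else:
            reads = riboseq.read_position_table(config.reads)
        gene_table = read_tsv(config.gene_table)
        cds = _read_fasta(config.cds_fasta)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"][stage] = {"n_reads": len(reads), "n_genes": len(gene_table)}
    log.info("[%s] %d reads, %d genes", stage, len(reads), len(gene_table))

    # --- calibrate ---------------------------------------------------------
    stage = "calibrate"
    hist = riboseq.read_length_histogram(reads)
    lengths = riboseq.select_abundant_lengths(hist, config.min_fraction)
    offsets = riboseq.calibrate_psite_offsets(
        reads, gene_table, lengths, config.offset_window
    )
    if not offsets.offsets:
        raise PipelineError(stage, "no read length could be calibrated")
    _write_tsv(offsets.to_frame(), outdir / "offsets.tsv")
    manifest["stages"][stage] = {
        "lengths": sorted(offsets.offsets),
        "offsets": {str(k): v for k, v in sorted(offsets.offsets.items())},
    }
    log.info("[%s] offsets %s", stage, offsets.offsets)

    # --- occupancy + QC + scale + filter -----------------------------------
    stage = "occupancy"
    kept_reads = reads[reads["length"].isin(offsets.offsets)]
    occ, discarded = riboseq.codon_occupancy(kept_reads, offsets, gene_table)
    manifest["stages"][stage] = {
        "n_used": len(kept_reads) - discarded,
        "n_discarded": discarded + (len(reads) - len(kept_reads)),
    }

    stage = "qc"
    qc = riboseq.frame_periodicity_qc(kept_reads, offsets, gene_table)
    (outdir / "qc.json").write_text(json.dumps(qc.to_dict(), indent=1))
    manifest["stages"][stage] = {
        "frame0": qc.frame_fractions[0],
        "status": qc.status,
    }
    log.info("[%s] frame fractions %s (%s)", stage, qc.frame_fractions, qc.status)

    stage = "scale"
    profiles: dict[str, riboseq.ScaledProfile] = {}
    for gene_id, o in occ.items():
        try:
            profiles[gene_id] = riboseq.scale_footprints(
                o, config.exclude_first, config.exclude_last
            )
        except ValueError:
            log.warning("[%s] %s too short for analyzed range; skipped", stage, gene_id)
    _write_tsv(riboseq.occupancy_frame(occ, profiles), outdir / "profiles.tsv")
    manifest["stages"][stage] = {"n_profiles": len(profiles)}

    stage = "filter"
    retained = riboseq.coverage_filter(
        occ, config.coverage_threshold, config.exclude_first, config.exclude_last
    )
    retained = sorted(retained)
    if not retained:
        raise PipelineError(stage, "no genes retained by the coverage filter")
    (outdir / "retained_genes.txt").write_text("\n".join(retained) + "\n")
    manifest["stages"][stage] = {"n_retained": len(retained)}
    log.info("[%s] %d/%d genes retained", stage, len(retained), len(occ))

    # --- structure features -------------------------------------------------
    stage = "features"
    try:
        smap = read_tsv(config.structure_map)
        tables = []
        for row in smap.itertuples():
            if row.gene_id not in retained:
                continue
            struct = structure.load_structure(row.path, gene_id=row.gene_id)
            tables.append(
                structure.residue_feature_table(
                    struct,
                    probe_radius=config.probe_radius,
                    n_points=config.sphere_points,
                    contact_cutoff=config.contact_cutoff,
                    min_separation=config.min_separation,
                    idr_window=config.idr_window,
                )
            )
        if not tables:
            raise ValueError("no structures for retained genes")
        features = pd.concat(tables, ignore_index=True)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    _write_tsv(features, outdir / "features.tsv")
    manifest["stages"][stage] = {"n_residues": len(features)}

    # --- integration --------------------------------------------------------
    stage = "integrate"
    usage = integrate.compute_codon_usage(cds)
    joint = integrate.build_joint_table(
        profiles, features, usage, retained, cds_collection=cds,
        residue_lag=config.residue_lag,
    )
    if joint.empty:
        raise PipelineError(stage, "joint table is empty")
    _write_tsv(joint, outdir / "joint.tsv")
    _write_tsv(integrate.per_gene_summary(joint), outdir / "gene_summary.tsv")
    manifest["stages"][stage] = {"n_records": len(joint)}

    # --- association statistics ---------------------------------------------
    stage = "associate"
    summary = stats.association_summary(
        joint, min_positions=config.min_positions, n_tests=config.n_tests
    )
    _write_tsv(summary, outdir / "association.tsv")
    manifest["stages"][stage] = {"n_features": len(summary)}

    stage = "compare-ss"
    try:
        comparison = stats.structured_vs_coil(joint)
        (outdir / "structured_vs_coil.json").write_text(
            json.dumps(comparison.to_dict(), indent=1)
        )
        manifest["stages"][stage] = {
            "direction": comparison.direction,
            "p_value": comparison.p_value,
        }
    except ValueError as exc:
        log.warning("[%s] skipped: %s", stage, exc)
        manifest["stages"][stage] = {"skipped": str(exc)}

    stage = "metagene"
    for name, cls in (("proline", "P"), ("positive", stats.POSITIVE_CLASS)):
        prof = stats.metagene_profile(joint, cls, config.metagene_window)
        _write_tsv(prof.to_frame(), outdir / f"metagene_{name}.tsv")
        manifest["stages"].setdefault(stage, {})[name] = prof.n_occurrences

    stage = "regions"
    regional = stats.region_stratified_correlations(
        joint, min_positions=max(2, config.min_positions // 3)
    )
    if regional:
        _write_tsv(
            pd.DataFrame([{"region": k, **vars(v)} for k, v in regional.items()]),
            outdir / "regions.tsv",
        )
    manifest["stages"][stage] = {"n_regions": len(regional)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
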