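"""End-to-end run: simulate -> normalize -> call -> summarize -> metagene ->
segment -> cluster, with a checksummed output manifest.

The run is configured by a plain YAML file (see :class:`RunConfig`). Inputs
are either generated by the synthetic-data module (``simulation:`` section)
or loaded from paths; every stage writes TSV/BED/Newick outputs into the
output directory and records a sha256 checksum, so identical config + seed
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation as anno
from . import readthrough as rt
from . import segmentation as seg
from . import signatures as sigs
from . import simulate as sim
from . import tiling

log = logging.getLogger("termscan")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulation: Optional[sim.SimulationConfig] = None
    annotation_path: Optional[str] = None
    annotation_format: str = "BED"
    tracks_path: Optional[str] = None
    expression_path: Optional[str] = None
    samples_path: Optional[str] = None
    params: rt.ReadthroughParams = field(default_factory=rt.ReadthroughParams)
    normalize: str = "median_center"
    neighbor_scope: str = "same_strand"
    mut_samples: Optional[List[str]] = None
    wt_samples: Optional[List[str]] = None
    metagene_upstream: int = 500
    metagene_downstream: int = 500
    segment_kmax: Optional[int] = None
    log_level: str = "INFO"


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation."""


def validate_config(path: str) -> RunConfig:
    """Parse and validate a YAML run config, reporting all violations at once."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: List[str] = []
    cfg = _build_config(raw, errors)
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _build_config(raw: Dict, errors: List[str]) -> RunConfig:
    outdir = raw.get("outdir")
    if not outdir:
        errors.append("outdir is required")
        outdir = "."
    simulation = None
    if "simulation" in raw:
        try:
            simulation = sim.config_from_dict(raw["simulation"] or {})
            errors.extend(simulation.validate())
        except (TypeError, ValueError) as exc:
            errors.append(f"simulation: {exc}")
    params = rt.ReadthroughParams()
    if "readthrough" in raw:
        try:
            params = rt.ReadthroughParams(**(raw["readthrough"] or {}))
        except (TypeError, ValueError) as exc:
            errors.append(f"readthrough: {exc}")
    cfg = RunConfig(
        outdir=str(outdir),
        seed=int(raw.get("seed", 0)),
        simulation=simulation,
        annotation_path=raw.get("annotation"),
        annotation_format=raw.get("annotation_format", "BED"),
        tracks_path=raw.get("tracks"),
        expression_path=raw.get("expression"),
        samples_path=raw.get("samples"),
        params=params,
        normalize=raw.get("normalize", "median_center"),
        neighbor_scope=raw.get("neighbor_scope", "same_strand"),
        mut_samples=raw.get("mut_samples"),
        wt_samples=raw.get("wt_samples"),
        metagene_upstream=int(raw.get("metagene_upstream", 500)),
        metagene_downstream=int(raw.get("metagene_downstream", 500)),
        segment_kmax=raw.get("segment_kmax"),
        log_level=str(raw.get("log_level", "INFO")),
    )
    if cfg.simulation is None:
        for name, p in (
            ("annotation", cfg.annotation_path),
            ("tracks", cfg.tracks_path),
        ):
            if p is None:
                errors.append(f"{name} path required when not simulating")
            elif not Path(p).exists():
                errors.append(f"{name} path does not exist: {p}")
        for name, p in (
            ("expression", cfg.expression_path),
            ("samples", cfg.samples_path),
        ):
            if p is not None and not Path(p).exists():
                errors.append(f"{name} path does not exist: {p}")
    if cfg.normalize not in ("median_center", "none"):
        errors.append(f"unknown normalize method {cfg.normalize!r}")
    if cfg.neighbor_scope not in ("same_strand", "both_strands"):
        errors.append(f"unknown neighbor_scope {cfg.neighbor_scope!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Execute every stage; returns the manifest (file, stage, sha256).

    Raises on the first failing stage; outputs of completed stages are left
    in place.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: List[Dict[str, str]] = []

    def emit(stage: str, name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.append({"file": name, "stage": stage, "sha256": _sha256(path)})
        log.info("stage %s wrote %s", stage, name)
        return path

    # --- stage: inputs (simulate or load) -------------------------------
    if cfg.simulation is not None:
        ann, truth = sim.generate_annotation(cfg.simulation, cfg.seed)
        tracks = sim.generate_tracks(ann, truth, cfg.simulation, cfg.seed + 1)
        mat, expr_truth = sim.generate_expression_matrix(cfg.simulation, cfg.seed + 2)
        emit("simulate", "annotation.bed", lambda p: anno.write_annotation(ann, p))
        emit(
            "simulate",
            "tracks.tsv",
            lambda p: tiling.write_probe_tracks(tracks, p),
        )
        emit(
            "simulate",
            "truth_features.tsv",
            lambda p: truth.to_csv(p, sep="\t", index=False),
        )
        emit(
            "simulate",
            "truth_expression.tsv",
            lambda p: expr_truth.to_csv(p, sep="\t", index=False),
        )
        emit(
            "simulate",
            "expression.tsv",
            lambda p: mat.values.to_csv(p, sep="\t", float_format="%.6f"),
        )
        emit(
            "simulate",
            "samples.tsv",
            lambda p: pd.DataFrame(
                {"sample": mat.groups.index, "group": mat.groups.values}
            ).to_csv(p, sep="\t", index=False),
        )
    else:
        ann = anno.read_annotation(cfg.annotation_path, cfg.annotation_format)
        tracks = tiling.read_probe_tracks(cfg.tracks_path)
        mat = None
        if cfg.expression_path and cfg.samples_path:
            mat = sigs.read_expression_matrix(cfg.expression_path, cfg.samples_path)

    sample_ids = next(iter(tracks.values())).sample_ids
    mut_samples = cfg.mut_samples or [s for s in sample_ids if s.startswith("mut")]
    wt_samples = cfg.wt_samples or [s for s in sample_ids if s.startswith("wt")]
    if not mut_samples or not wt_samples:
        raise ConfigError(
            "cannot infer mutant/wildtype samples; set mut_samples/wt_samples"
        )

    # --- stage: normalize ----------------------------------------------
    tracks = tiling.normalize_tracks(tracks, method=cfg.normalize)

    # --- stage: call readthrough ---------------------------------------
    calls = rt.call_all(
        ann, tracks, mut_samples, wt_samples, cfg.params,
        neighbor_scope=cfg.neighbor_scope,
    )
    emit(
        "call",
        "calls.tsv",
        lambda p: rt.calls_to_frame(calls).to_csv(
            p, sep="\t", index=False, float_format="%.6f"
        ),
    )
    emit(
        "call",
        "readthrough_positive.bed",
        lambda p: rt.positive_calls_bed(calls, ann).to_csv(
            p, sep="\t", index=False, header=False
        ),
    )

    # --- stage: summarize ----------------------------------------------
    summaries = rt.summarize_by_class(calls)
    emit(
        "summarize",
        "class_summary.tsv",
        lambda p: rt.summaries_to_frame(summaries).to_csv(
            p, sep="\t", index=False, float_format="%.6f"
        ),
    )

    # --- stage: metagene -----------------------------------------------
    for cls in ("snoRNA", "ORF"):
        feats = ann.by_class(cls)
        if not feats:
            continue
        df = rt.metagene_difference(
            feats, tracks, mut_samples, wt_samples,
            cfg.metagene_upstream, cfg.metagene_downstream,
            cfg.params.bin_width, ann.chrom_lengths,
        )
        emit(
            "metagene",
            f"metagene_{cls}.tsv",
            lambda p, df=df: df.to_csv(
                p, sep="\t", index=False, float_format="%.6f"
            ),
        )

    # --- stage: segment (first annotated chromosome, both conditions) ---
    f0 = ann.features[0]
    lo = max(0, f0.start - 1000)
    hi = min(ann.chrom_lengths[f0.chrom], f0.end + 2000)
    track0 = tracks[(f0.chrom, f0.strand)]
    seg_rows = []
    for label, samples in (("wt", wt_samples), ("mut", mut_samples)):
        vals = tiling.average_replicates(track0, samples)
        res = seg.segment_region(track0, vals, lo, hi, k_max=cfg.segment_kmax)
        bed = seg.segments_to_bed(res)
        bed.insert(0, "condition", label)
        seg_rows.append(bed)
    emit(
        "segment",
        "segments.tsv",
        lambda p: pd.concat(seg_rows, ignore_index=True).to_csv(
            p, sep="\t", index=False, float_format="%.4f"
        ),
    )

    # --- stage: signatures ---------------------------------------------
    if mat is not None:
        signatures = [sigs.fold_changes(mat, m) for m in mat.mutants]
        for s in signatures:
            sigs.significance_filter(s)
        sig_table = pd.DataFrame({s.mutant: s.M for s in signatures})
        emit(
            "signatures",
            "fold_changes.tsv",
            lambda p: sig_table.to_csv(p, sep="\t", float_format="%.6f"),
        )
        tree = sigs.cosine_cluster(signatures)
        emit(
            "signatures",
            "cluster.nwk",
            lambda p: Path(p).write_text(tree.to_newick() + "\n"),
        )

    manifest_df = pd.DataFrame(manifest)
    manifest_df.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest_df
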