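"""End-to-end orchestration of the environment and laboratory pipelines.

A single YAML config drives everything.  Top-level sections:

``synthetic``
    Parameters of :class:`~epsbloom.simulate.SimulationConfig` (or
    ``study_default: true`` for the planted-effect defaults).  Mutually
    exclusive with ``inputs``.
``inputs``
    Paths to real files: fasta, membership, gff3, annotations, counts,
    samples, markers.
``activity``
    ``scaling`` (zscore|minmax|none), ``n_permutations``, ``alpha``,
    ``log2_threshold``, ``seed``.
``clusters``
    ``max_gap_genes``, ``max_gap_bp``, ``min_fraction`` and optional
    ``modules`` overriding the default EPS module definitions.
``tep``
    ``standards`` and ``plate`` paths (or ``synthetic: true``), ``variant``.

Every run writes a manifest (config hash, seed, package version) and logs
one line per stage with input/output row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__, io, simulate, tep
from .activity import compare_phases, mag_activity, scale_rows
from .clusters import cluster_expression, detect_clusters, modules_from_config
from .normalization import mg_normalize, tpm_normalize

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_env_pipeline", "run_tep_pipeline"]

_ENV_STAGES = ("simulate", "normalize", "activity", "clusters", "expression")
_TOP_KEYS = {"synthetic", "inputs", "activity", "clusters", "tep", "seed", "outdir"}


def load_config(config_path: str | Path) -> dict:
    """Read and validate the YAML config; unknown top-level keys are errors."""
    path = Path(config_path)
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; accepted: {sorted(_TOP_KEYS)}"
        )
    if "synthetic" in config and "inputs" in config:
        raise ValueError("config must name either 'synthetic' or 'inputs', not both")
    if "synthetic" not in config and "inputs" not in config and "tep" not in config:
        raise ValueError("config needs a 'synthetic', 'inputs' or 'tep' section")
    return config


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _build_sim_config(section: Mapping[str, Any], seed: int) -> simulate.SimulationConfig:
    section = dict(section)
    study_default = section.pop("study_default", False)
    if study_default:
        base = simulate.SimulationConfig.study_default(seed=seed)
        if section:
            import dataclasses

            base = dataclasses.replace(base, **section)
        return base
    section.setdefault("seed", seed)
    for key in ("active_mags",):
        if key in section:
            section[key] = tuple(section[key])
    return simulate.SimulationConfig(**section)


def _load_inputs(section: Mapping[str, Any]):
    required = {"fasta", "membership", "gff3", "annotations", "counts", "samples",
                "markers"}
    missing = required - set(section)
    if missing:
        raise ValueError(f"inputs section missing keys: {sorted(missing)}")
    for key in required:
        if not Path(section[key]).exists():
            raise FileNotFoundError(f"input file for {key!r} not found: {section[key]}")
    mags = io.read_mag_catalog(section["fasta"], section["membership"])
    orfs = io.read_orfs(section["gff3"], section["annotations"], mags)
    samples = io.read_samples(section["samples"])
    counts = io.read_counts(section["counts"], orfs=orfs, samples=samples)
    markers = io.read_markers(section["markers"])
    return mags, orfs, counts, samples, markers


def run_env_pipeline(
    config_path: str | Path | Mapping[str, Any],
    outdir: str | Path | None = None,
    upto: str = "expression",
) -> Path:
    """Run the environment-side pipeline: counts -> TPM -> MG -> activity ->
    clusters -> cluster expression, writing each artifact as TSV.

    ``upto`` stops after the named stage.  When the config has no
    ``clusters`` section the pipeline stops after the activity stage.
    Returns the artifact directory.
    """
    if upto not in _ENV_STAGES:
        raise ValueError(f"unknown stage {upto!r}; stages: {_ENV_STAGES}")
    config = (
        load_config(config_path)
        if isinstance(config_path, (str, Path))
        else dict(config_path)
    )
    seed = int(config.get("seed", 0))
    tag = _config_hash(config)[:12]
    out = Path(outdir or config.get("outdir", "epsbloom_out"))
    out.mkdir(parents=True, exist_ok=True)

    if "synthetic" in config:
        sim_config = _build_sim_config(config["synthetic"], seed)
        community = simulate.generate_community(sim_config)
        counts, samples = simulate.generate_counts(community, sim_config)
        mags, orfs, markers = community.mags, community.orfs, community.markers
        io.write_community(community, counts, samples, out / "synthetic",
                           config=sim_config)
        logger.info("stage simulate: %d MAGs, %d ORFs, %d samples",
                    len(mags), len(orfs), len(samples))
    else:
        mags, orfs, counts, samples, markers = _load_inputs(config["inputs"])
        logger.info("stage load: %d MAGs, %d ORFs, %d samples",
                    len(mags), len(orfs), len(samples))
    if upto == "simulate":
        _write_manifest(out, config, seed)
        return out

    act_cfg = config.get("activity", {}) or {}
    scaling = act_cfg.get("scaling", "zscore")
    n_perm = int(act_cfg.get("n_permutations", 10_000))
    perm_seed = int(act_cfg.get("seed", seed))

    tpm = tpm_normalize(counts, orfs)
    io.write_matrix(tpm.matrix, out / "tpm.tsv",
                    comment=f"TPM: per-sample length-normalized counts x 1e6 | config {tag}")
    mg = mg_normalize(counts, orfs, markers)
    io.write_matrix(mg.matrix, out / "mg_normalized.tsv",
                    comment=f"MG normalization: rate over per-MAG marker median | config {tag}")
    logger.info("stage normalize: TPM %s, MG %s", tpm.matrix.shape, mg.matrix.shape)
    if upto == "normalize":
        _write_manifest(out, config, seed)
        return out

    activity = mag_activity(tpm, orfs, mags)
    io.write_matrix(activity.matrix, out / "activity.tsv",
                    comment=f"relative activity: TPM share over length share | config {tag}")
    scaled, _ = scale_rows(activity.matrix, method=scaling)
    io.write_matrix(scaled, out / "activity_scaled.tsv",
                    comment=f"activity scaled per row ({scaling}) | config {tag}")
    act_cmp = compare_phases(activity.matrix, samples, n_permutations=n_perm,
                             seed=perm_seed)
    act_cmp.to_csv(out / "activity_phase_comparison.tsv", sep="\t",
                   index_label="mag_id", float_format="%.12g")
    logger.info("stage activity: %d MAGs compared across phases", len(act_cmp))
    if upto == "activity" or "clusters" not in config:
        if "clusters" not in config:
            logger.info("no clusters section in config: stopping after activity")
        _write_manifest(out, config, seed)
        return out

    cl_cfg = config.get("clusters", {}) or {}
    modules = modules_from_config(cl_cfg.get("modules"),
                                  min_fraction=float(cl_cfg.get("min_fraction", 0.5)))
    max_gap_genes = int(cl_cfg.get("max_gap_genes", 2))
    max_gap_bp = int(cl_cfg.get("max_gap_bp", 5000))
    co_strand = bool(cl_cfg.get("require_co_strand", False))
    clusters = []
    for module in modules:
        clusters.extend(
            detect_clusters(orfs, module, max_gap_genes=max_gap_genes,
                            max_gap_bp=max_gap_bp, require_co_strand=co_strand)
        )
    pd.DataFrame(
        [
            {
                "mag_id": c.mag_id,
                "contig_id": c.contig_id,
                "module": c.module_name,
                "n_orfs": len(c.orf_ids),
                "orf_ids": ",".join(c.orf_ids),
                "matched_genes": ",".join(sorted(c.matched_key_genes)),
                "completeness": c.completeness,
            }
            for c in clusters
        ]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False, float_format="%.12g")
    io.write_clusters_gff3(clusters, orfs, out / "clusters.gff3")
    logger.info("stage clusters: %d cluster(s) across %d module(s)",
                len(clusters), len(modules))
    if upto == "clusters":
        _write_manifest(out, config, seed)
        return out

    expr = cluster_expression(clusters, mg, samples, scaling=scaling,
                              n_permutations=n_perm, seed=perm_seed)
    io.write_matrix(expr["profiles"], out / "cluster_expression.tsv",
                    comment=f"cluster mean MG-normalized expression | config {tag}")
    io.write_matrix(expr["scaled"], out / "cluster_expression_scaled.tsv",
                    comment=f"cluster expression scaled per row ({scaling}) | config {tag}")
    expr["phase_comparison"].to_csv(out / "cluster_phase_comparison.tsv", sep="\t",
                                    index_label="cluster", float_format="%.12g")
    logger.info("stage expression: %d cluster profile(s)", len(expr["profiles"]))
    _write_manifest(out, config, seed)
    return out


def run_tep_pipeline(
    config_path: str | Path | Mapping[str, Any],
    outdir: str | Path | None = None,
) -> Path:
    """Run the laboratory-side pipeline: XG calibration, per-sample TEP,
    group means and one-sided nutrient-regime tests."""
    config = (
        load_config(config_path)
        if isinstance(config_path, (str, Path))
        else dict(config_path)
    )
    section = config.get("tep")
    if not section:
        raise ValueError("config has no 'tep' section")
    seed = int(config.get("seed", 0))
    out = Path(outdir or config.get("outdir", "epsbloom_out"))
    out.mkdir(parents=True, exist_ok=True)

    if section.get("synthetic"):
        standards_df, measurements = simulate.generate_tep_dataset(seed=seed)
        standards = list(zip(standards_df["mass_ug"], standards_df["absorbance"]))
        standards_df.to_csv(out / "standards.tsv", sep="\t", index=False,
                            float_format="%.12g")
    else:
        standards = io.read_tep_standards(section["standards"])
        measurements = io.read_tep_plate(section["plate"])

    curve = tep.calibrate_xg(standards)
    (out / "calibration.json").write_text(
        json.dumps(
            {
                "m787": curve.m787,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "n_standards": curve.n_standards,
            },
            indent=2,
        )
    )
    summary = tep.group_summary(
        measurements, curve, variant=section.get("variant", "pooled")
    )
    summary["per_sample"].to_csv(out / "tep_per_sample.tsv", sep="\t", index=False,
                                 float_format="%.12g")
    summary["groups"].to_csv(out / "tep_groups.tsv", sep="\t", index=False,
                             float_format="%.12g")
    summary["tests"].to_csv(out / "tep_tests.tsv", sep="\t", index=False,
                            float_format="%.12g")
    logger.info("TEP pipeline: %d measurements, %d group(s), %d test(s)",
                len(summary["per_sample"]), len(summary["groups"]),
                len(summary["tests"]))
    _write_manifest(out, config, seed)
    return out


def _write_manifest(outdir: Path, config: Mapping[str, Any], seed: int) -> None:
    manifest = {
        "config_sha256": _config_hash(config),
        "seed": seed,
        "epsbloom_version": __version__,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
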