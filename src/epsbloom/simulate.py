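"""Synthetic bloom study generator.

Emulates the shape of the real dataset the pipeline targets: a catalog of
MAGs with contigs and ORFs, single-copy marker genes on every MAG, planted
EPS biosynthesis gene clusters, and a 30-timepoint metatranscriptomic count
matrix spanning two bloom phases separated by a phosphate/nitrate peak.
Counts are negative-binomial with mean proportional to library size, MAG
abundance, ORF length and a per-ORF relative rate; "active" MAGs have their
abundance multiplied by ``f_act`` in phase 2 and planted EPS-cluster ORFs
have their rate multiplied by ``f_eps`` in phase 2 — the ground truth the
pipeline is expected to recover.  Marker-gene ORFs are constitutive (rate 1,
never perturbed), matching their use as a normalization baseline.

All randomness flows from ``numpy.random.default_rng`` (PCG64) seeded from
``SimulationConfig.seed`` via independent spawned streams for community,
counts and assay, so one config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import study
from .clusters import default_modules
from .model import (
    MARKER_COGS,
    MagRecord,
    MarkerGeneSet,
    OrfRecord,
    SampleInfo,
    TepMeasurement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Community",
    "PlantedCluster",
    "generate_community",
    "generate_counts",
    "generate_tep_dataset",
    "mag_id",
]


def mag_id(index: int) -> str:
    """Deterministic MAG identifier for 0-based index: MAG001, MAG002, ..."""
    return f"MAG{index + 1:03d}"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Fold changes apply in bloom phase 2 only.  ``eps_planted`` maps MAG id to
    module name for clusters that receive ``f_eps``; ``eps_null_planted``
    plants structurally identical clusters whose expression is unchanged, so
    ranking has real competitors.
    """

    seed: int = 0
    n_mags: int = 50
    contigs_per_mag: int = 3
    mean_contig_kb: float = 60.0
    contig_log_sd: float = 0.25
    mean_orf_bp: float = 900.0
    orf_log_sd: float = 0.35
    min_orf_bp: int = 150
    intergenic_mean_bp: float = 120.0
    n_samples: int = study.N_TIMEPOINTS
    phase_boundary: int = 15  # samples 1..15 are phase 1, the rest phase 2
    library_size: float = 1.0e6
    abundance_log_sd: float = 1.0
    rate_log_sd: float = 1.0
    dispersion: float = 2.0  # NB k: variance = mu + mu^2/k
    active_mags: tuple[str, ...] = ()
    f_act: float = 4.0
    eps_planted: Mapping[str, str] = field(default_factory=dict)
    eps_null_planted: Mapping[str, str] = field(default_factory=dict)
    f_eps: float = 4.0
    nutrient_peak_time: int = 16
    phosphate_baseline_uM: float = 0.2
    phosphate_peak_uM: float = 2.0
    nitrate_baseline_uM: float = 4.0
    nitrate_peak_uM: float = 22.0
    peak_width: float = 2.0

    def __post_init__(self) -> None:
        if self.f_act <= 0 or self.f_eps <= 0:
            raise ValueError("fold changes must be positive")
        if self.n_samples > 0 and not 1 <= self.phase_boundary < self.n_samples:
            raise ValueError(
                f"phase boundary {self.phase_boundary} must lie strictly inside "
                f"1..{self.n_samples}"
            )
        overlap = set(self.eps_planted) & set(self.eps_null_planted)
        if overlap:
            raise ValueError(f"MAGs planted both with and without effect: {overlap}")

    @classmethod
    def study_default(cls, seed: int = 0) -> "SimulationConfig":
        """The default planted-effect study: 5 active MAGs and 6 EPS clusters
        (one elevated and one unchanged per module)."""
        return cls(
            seed=seed,
            active_mags=tuple(mag_id(i) for i in range(5)),
            eps_planted={
                mag_id(5): "alginate",
                mag_id(6): "cellulose",
                mag_id(7): "wzx_wzy",
            },
            eps_null_planted={
                mag_id(8): "alginate",
                mag_id(9): "cellulose",
                mag_id(10): "wzx_wzy",
            },
        )


@dataclass(frozen=True)
class PlantedCluster:
    mag_id: str
    contig_id: str
    module_name: str
    orf_ids: tuple[str, ...]
    elevated: bool  # receives f_eps in phase 2


@dataclass
class Community:
    mags: list[MagRecord]
    orfs: list[OrfRecord]
    markers: MarkerGeneSet
    planted: list[PlantedCluster]

    @property
    def orf_ids(self) -> list[str]:
        return [o.orf_id for o in self.orfs]


def _rng_streams(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(child) for child in ss.spawn(3))


def _draw_orf_layout(
    rng: np.random.Generator, contig_len: int, cfg: SimulationConfig
) -> list[tuple[int, int]]:
    """Lay ORFs head-to-tail along a contig with exponential intergenic gaps."""
    spans = []
    pos = 1
    while True:
        length = int(
            np.clip(
                rng.lognormal(np.log(cfg.mean_orf_bp), cfg.orf_log_sd),
                cfg.min_orf_bp,
                6 * cfg.mean_orf_bp,
            )
        )
        if pos + length - 1 > contig_len:
            break
        spans.append((pos, pos + length - 1))
        pos += length + 1 + int(rng.exponential(cfg.intergenic_mean_bp))
    return spans


def generate_community(config: SimulationConfig) -> Community:
    """Build the synthetic MAG catalog, ORFs, marker genes and planted clusters.

    Every MAG carries exactly one ORF per marker COG; each planted cluster is
    a contiguous run of ORFs on one contig annotated with all key genes of
    its module.  Raises ``ValueError`` when a MAG's contigs are too short to
    host the requested marker and cluster ORFs.
    """
    rng, _, _ = _rng_streams(config.seed)
    modules = {m.module_name: m for m in default_modules()}
    for mapping in (config.eps_planted, config.eps_null_planted):
        for mag, mod in mapping.items():
            if mod not in modules:
                raise ValueError(f"unknown EPS module {mod!r} planted in {mag}")

    mags: list[MagRecord] = []
    orfs: list[OrfRecord] = []
    assignments: dict[str, dict[str, str]] = {}
    planted: list[PlantedCluster] = []
    og_counter = 0

    for j in range(config.n_mags):
        mid = mag_id(j)
        contigs = []
        mag_orfs: list[OrfRecord] = []
        for c in range(config.contigs_per_mag):
            cid = f"{mid}_c{c + 1}"
            length = int(
                rng.lognormal(
                    np.log(config.mean_contig_kb * 1000), config.contig_log_sd
                )
            )
            contigs.append((cid, length))
            for k, (start, end) in enumerate(_draw_orf_layout(rng, length, config)):
                strand = "+" if rng.random() < 0.5 else "-"
                mag_orfs.append(
                    OrfRecord(
                        orf_id=f"{cid}_orf{k + 1:04d}",
                        mag_id=mid,
                        contig_id=cid,
                        start=start,
                        end=end,
                        strand=strand,
                    )
                )
        mags.append(
            MagRecord(mag_id=mid, contigs=tuple(contigs),
                      taxonomy=("Bacteria", f"Class{j % 5 + 1}", f"Order{j % 9 + 1}"))
        )

        # Plant the EPS cluster first (needs a contiguous run), then markers.
        module_name = config.eps_planted.get(mid) or config.eps_null_planted.get(mid)
        annotated: dict[str, set[str]] = {o.orf_id: set() for o in mag_orfs}
        reserved: set[str] = set()
        if module_name is not None:
            key_genes = sorted(modules[module_name].key_genes)
            by_contig: dict[str, list[OrfRecord]] = {}
            for o in mag_orfs:
                by_contig.setdefault(o.contig_id, []).append(o)
            host = max(by_contig.values(), key=len)
            if len(host) < len(key_genes):
                raise ValueError(
                    f"MAG {mid}: largest contig hosts {len(host)} ORFs but module "
                    f"{module_name} needs a run of {len(key_genes)}"
                )
            host = sorted(host, key=lambda o: o.start)
            offset = (len(host) - len(key_genes)) // 2
            run = host[offset : offset + len(key_genes)]
            for o, gene in zip(run, key_genes):
                annotated[o.orf_id].add(gene)
                reserved.add(o.orf_id)
            planted.append(
                PlantedCluster(
                    mag_id=mid,
                    contig_id=run[0].contig_id,
                    module_name=module_name,
                    orf_ids=tuple(o.orf_id for o in run),
                    elevated=mid in config.eps_planted,
                )
            )

        free = [o for o in mag_orfs if o.orf_id not in reserved]
        if len(free) < len(MARKER_COGS):
            raise ValueError(
                f"MAG {mid}: only {len(free)} ORFs free for {len(MARKER_COGS)} "
                "marker genes; contigs too short for the requested layout"
            )
        marker_orfs = rng.choice(len(free), size=len(MARKER_COGS), replace=False)
        assignments[mid] = {}
        for cog, idx in zip(MARKER_COGS, sorted(marker_orfs)):
            orf = free[idx]
            annotated[orf.orf_id].add(cog)
            assignments[mid][cog] = orf.orf_id

        for o in mag_orfs:
            extra = annotated[o.orf_id]
            if not extra:
                extra = {f"OG{og_counter:06d}"}
                og_counter += 1
            orfs.append(dataclasses.replace(o, annotations=frozenset(extra)))

    logger.info(
        "synthetic community: %d MAGs, %d ORFs, %d planted cluster(s)",
        len(mags), len(orfs), len(planted),
    )
    return Community(
        mags=mags,
        orfs=orfs,
        markers=MarkerGeneSet(assignments=assignments),
        planted=planted,
    )


def _nutrient_profiles(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(1, config.n_samples + 1, dtype=float)
    bump = np.exp(-0.5 * ((t - config.nutrient_peak_time) / config.peak_width) ** 2)
    p = config.phosphate_baseline_uM + (
        config.phosphate_peak_uM - config.phosphate_baseline_uM
    ) * bump
    n = config.nitrate_baseline_uM + (
        config.nitrate_peak_uM - config.nitrate_baseline_uM
    ) * bump
    return p, n


def generate_counts(
    community: Community, config: SimulationConfig
) -> tuple[pd.DataFrame, list[SampleInfo]]:
    """Negative-binomial count matrix (samples x ORFs) plus sample metadata.

    Mean model: ``mu_is = library_size * w_is / sum_i w_is`` with
    ``w_is = abundance(mag(i), phase(s)) * length_kb(i) * rate(i, phase(s))``.
    """
    if config.dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {config.dispersion}")
    _, rng, _ = _rng_streams(config.seed)
    orfs = community.orfs
    n_orfs = len(orfs)

    mag_ids = [m.mag_id for m in community.mags]
    abundance = {
        m: a for m, a in zip(mag_ids, rng.lognormal(0.0, config.abundance_log_sd,
                                                    size=len(mag_ids)))
    }
    marker_orf_ids = {
        o for mid in mag_ids for o in community.markers.marker_orfs(mid)
    }
    raw_rates = rng.lognormal(0.0, config.rate_log_sd, size=n_orfs)
    rates = np.where([o.orf_id in marker_orf_ids for o in orfs], 1.0, raw_rates)

    lengths = np.array([o.length_kb for o in orfs])
    orf_mag = np.array([o.mag_id for o in orfs])
    active = np.isin(orf_mag, list(config.active_mags))
    elevated_orfs = {
        oid for p in community.planted if p.elevated for oid in p.orf_ids
    }
    eps_mask = np.array([o.orf_id in elevated_orfs for o in orfs])

    base_ab = np.array([abundance[m] for m in orf_mag])
    phosphate, nitrate = _nutrient_profiles(config)

    samples: list[SampleInfo] = []
    counts = np.zeros((config.n_samples, n_orfs), dtype=np.int64)
    k = config.dispersion
    for s in range(config.n_samples):
        phase = 1 if s + 1 <= config.phase_boundary else 2
        w = base_ab * lengths * rates
        if phase == 2:
            w = w * np.where(active, config.f_act, 1.0)
            w = w * np.where(eps_mask, config.f_eps, 1.0)
        mu = config.library_size * w / w.sum() if w.sum() > 0 else np.zeros(n_orfs)
        with np.errstate(divide="ignore"):
            p = k / (k + mu)
        counts[s] = np.where(mu > 0, rng.negative_binomial(k, np.minimum(p, 1.0)), 0)
        samples.append(
            SampleInfo(
                sample_id=f"T{s + 1:02d}",
                time_index=s + 1,
                bloom_phase=phase,
                phosphate_uM=float(phosphate[s]),
                nitrate_uM=float(nitrate[s]),
            )
        )
    matrix = pd.DataFrame(
        counts, index=[s.sample_id for s in samples], columns=community.orf_ids
    )
    logger.info(
        "synthetic counts: %d samples x %d ORFs, median library %d",
        matrix.shape[0], matrix.shape[1], int(matrix.sum(axis=1).median()) if n_orfs else 0,
    )
    return matrix, samples


def generate_tep_dataset(
    seed: int = 0,
    slope: float = 0.02,
    intercept: float = 0.05,
    noise_sd: float = 0.005,
    group_means: Mapping[tuple[str, str], float] | None = None,
    cell_density: Mapping[str, float] | None = None,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, list[TepMeasurement]]:
    """Synthetic XG standards and a Figure-1-shaped TEP plate.

    Standards use the published dilution series (stock 75 ug/mL, volumes
    0.125..1 mL); absorbance = intercept + slope x mass + N(0, noise_sd).
    ``group_means`` maps (organism, regime) to true TEP (ug/mL); defaults
    place algae well above bacteria and the full-strength regime at twice
    the quarter-strength one, with three biological repeats per group.
    Sample absorbances follow the assay model in reverse:
    ``a = intercept + slope * (tep * V) + noise`` with the filter blank at
    the calibration intercept.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    _, _, rng = _rng_streams(seed)
    if group_means is None:
        group_means = {
            ("algae", "quarter_pn"): 20.0,
            ("algae", "1x_pn"): 40.0,
            ("bacteria", "quarter_pn"): 2.0,
            ("bacteria", "1x_pn"): 4.0,
        }
    if cell_density is None:
        cell_density = {"algae": 2000.0, "bacteria": 5000.0}  # cells/uL

    masses = study.xg_standard_masses_ug()
    standards = pd.DataFrame(
        {
            "volume_ml": study.XG_STANDARD_VOLUMES_ML,
            "mass_ug": masses,
            "absorbance": [
                intercept + slope * m + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                for m in masses
            ],
        }
    )

    measurements: list[TepMeasurement] = []
    for (organism, regime), mean_tep in group_means.items():
        volume = study.FILTERED_VOLUME_ML.get(organism, 6.0)
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
            a = intercept + slope * (mean_tep * volume) + noise
            measurements.append(
                TepMeasurement(
                    sample_id=f"{organism}_{regime}_r{rep}",
                    organism=organism,
                    regime=regime,
                    a_sample=a,
                    a_filter_blank=intercept,
                    volume_ml=volume,
                    cell_density=cell_density.get(organism),
                )
            )
    return standards, measurements
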