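"""Domain types for the EPS-bloom analysis pipeline.

The pipeline connects two sides of one question — does bacterial
exopolysaccharide (EPS) production rise after a phosphate/nitrate influx?

* Environment side: metagenome-assembled genomes (MAGs), their open reading
  frames (ORFs) and per-sample transcript counts across a 30-timepoint algal
  bloom split into two phases by a nutrient peak.
* Laboratory side: an Alcian-Blue staining assay in which transparent
  exopolymeric particles (TEP) are quantified as Xanthan-Gum (XG) mass
  equivalents via a calibration curve.

Matrices (counts, TPM, MG-normalized values, MAG activities) are carried as
:class:`pandas.DataFrame` objects with samples as rows and ORFs (or MAGs) as
columns; the small result dataclasses below bundle a matrix with the flags
the computations may raise (all-zero samples, undefined markers, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "MARKER_COGS",
    "MagRecord",
    "OrfRecord",
    "SampleInfo",
    "MarkerGeneSet",
    "EpsModuleDefinition",
    "GeneCluster",
    "CalibrationCurve",
    "TepMeasurement",
    "TepResult",
    "TpmResult",
    "MgResult",
    "ActivityResult",
    "validate_count_matrix",
]

#: The 10 universal single-copy phylogenetic marker-gene COG families used
#: for per-MAG marker-gene (MG) normalization.
MARKER_COGS: tuple[str, ...] = (
    "COG0012",
    "COG0016",
    "COG0018",
    "COG0172",
    "COG0215",
    "COG0495",
    "COG0525",
    "COG0533",
    "COG0541",
    "COG0552",
)


@dataclass(frozen=True)
class MagRecord:
    """A metagenome-assembled genome: its contigs and coarse taxonomy.

    ``contigs`` is an ordered sequence of ``(contig_id, length_bp)`` pairs.
    ``taxonomy`` carries ordered labels (domain, class, order) when known.
    """

    mag_id: str
    contigs: tuple[tuple[str, int], ...]
    taxonomy: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, length in self.contigs:
            if length <= 0:
                raise ValueError(
                    f"MAG {self.mag_id}: contig {cid} has non-positive length {length}"
                )
            if cid in seen:
                raise ValueError(f"MAG {self.mag_id}: duplicate contig id {cid}")
            seen.add(cid)

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.contigs)

    @property
    def length_kb(self) -> float:
        """Total MAG length, Σ contig lengths / 1000 (kb)."""
        return sum(length for _, length in self.contigs) / 1000.0


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on a MAG contig, 1-based inclusive coordinates."""

    orf_id: str
    mag_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"ORF {self.orf_id}: end {self.end} < start {self.start}"
            )
        if self.start < 1:
            raise ValueError(f"ORF {self.orf_id}: start {self.start} < 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"ORF {self.orf_id}: bad strand {self.strand!r}")

    @property
    def length_kb(self) -> float:
        """ORF length in kb, (end - start + 1) / 1000."""
        return (self.end - self.start + 1) / 1000.0


@dataclass(frozen=True)
class SampleInfo:
    """One timepoint of the bloom series with its nutrient context."""

    sample_id: str
    time_index: int
    bloom_phase: int
    phosphate_uM: float = 0.0
    nitrate_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.bloom_phase not in (1, 2):
            raise ValueError(
                f"sample {self.sample_id}: bloom_phase must be 1 or 2, "
                f"got {self.bloom_phase}"
            )
        if self.phosphate_uM < 0 or self.nitrate_uM < 0:
            raise ValueError(f"sample {self.sample_id}: negative nutrient level")


@dataclass(frozen=True)
class MarkerGeneSet:
    """Per-MAG assignment of the 10 single-copy marker COGs to ORFs.

    ``assignments`` maps ``mag_id -> {cog_id -> orf_id}``.  A MAG may have
    fewer than 10 assigned markers (incomplete genomes); downstream code
    warns and uses the median of what is available.
    """

    assignments: Mapping[str, Mapping[str, str]]
    cog_ids: tuple[str, ...] = MARKER_COGS

    def __post_init__(self) -> None:
        if len(set(self.cog_ids)) != 10:
            raise ValueError(
                f"marker set must contain exactly 10 COG families, got {len(set(self.cog_ids))}"
            )
        for mag_id, table in self.assignments.items():
            unknown = set(table) - set(self.cog_ids)
            if unknown:
                raise ValueError(
                    f"MAG {mag_id}: marker assignment for unknown COGs {sorted(unknown)}"
                )

    def marker_orfs(self, mag_id: str) -> tuple[str, ...]:
        return tuple(self.assignments.get(mag_id, {}).values())


@dataclass(frozen=True)
class EpsModuleDefinition:
    """One EPS biosynthesis module: its key genes and reporting thresholds.

    A candidate gene cluster is reported only if it carries every gene of
    ``required_core`` and at least ``min_fraction`` of ``key_genes``.
    """

    module_name: str
    key_genes: frozenset[str]
    required_core: frozenset[str]
    min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.key_genes:
            raise ValueError(f"module {self.module_name}: empty key gene set")
        if not self.required_core <= self.key_genes:
            raise ValueError(
                f"module {self.module_name}: required_core must be a subset of key_genes"
            )
        if not 0 < self.min_fraction <= 1:
            raise ValueError(
                f"module {self.module_name}: min_fraction must lie in (0, 1], "
                f"got {self.min_fraction}"
            )


@dataclass(frozen=True)
class GeneCluster:
    """A run of key-gene-annotated ORFs on one contig, for one EPS module."""

    mag_id: str
    contig_id: str
    module_name: str
    orf_ids: tuple[str, ...]
    matched_key_genes: frozenset[str]
    completeness: float

    def __post_init__(self) -> None:
        if not self.orf_ids:
            raise ValueError("gene cluster with no ORFs")
        if not 0 < self.completeness <= 1:
            raise ValueError(f"completeness {self.completeness} outside (0, 1]")


@dataclass(frozen=True)
class CalibrationCurve:
    """XG calibration line: absorbance at 787 nm = intercept + m787 x mass."""

    m787: float
    intercept: float
    r_squared: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise ValueError("calibration requires >= 2 distinct standard masses")
        if self.m787 <= 0:
            raise ValueError(
                f"invalid assay: calibration slope m787 = {self.m787} is not positive"
            )


@dataclass(frozen=True)
class TepMeasurement:
    """One stained filter: absorbances, filtered volume and cell density."""

    sample_id: str
    organism: str  # "algae" or "bacteria"
    regime: str  # "quarter_pn" or "1x_pn"
    a_sample: float
    a_filter_blank: float
    volume_ml: float
    cell_density: float | None = None  # cells/uL or CFU/uL

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError(
                f"measurement {self.sample_id}: filtered volume must be positive, "
                f"got {self.volume_ml}"
            )
        if self.cell_density is not None and self.cell_density <= 0:
            raise ValueError(
                f"measurement {self.sample_id}: cell density must be positive"
            )


@dataclass(frozen=True)
class TepResult:
    """TEP as XG-equivalent mass per volume unit of V, optionally per cell."""

    sample_id: str
    tep: float
    tep_per_cell: float | None
    clamped: bool = False  # a_sample < a_filter_blank, reported as 0


@dataclass
class TpmResult:
    """TPM matrix (samples x ORFs) plus samples that had all-zero counts."""

    matrix: pd.DataFrame
    zero_samples: tuple[str, ...] = ()


@dataclass
class MgResult:
    """Marker-gene-normalized matrix; NaN where the marker median was zero."""

    matrix: pd.DataFrame
    undefined: pd.DataFrame = field(default=None)  # boolean mask, same shape


@dataclass
class ActivityResult:
    """MAG x sample relative-activity matrix; NaN columns for zero-TPM samples."""

    matrix: pd.DataFrame
    undefined_samples: tuple[str, ...] = ()


def validate_count_matrix(
    counts: pd.DataFrame,
    orfs: Sequence[OrfRecord] | None = None,
    samples: Sequence[SampleInfo] | None = None,
) -> pd.DataFrame:
    """Check count-matrix invariants: integer, non-negative, known ids.

    Returns the validated frame (dtype coerced to int64).  Raises
    ``ValueError`` naming the offending entry, ORF or sample.
    """
    import numpy as np

    if counts.index.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate ORF ids in count matrix")
    values = counts.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
            raise ValueError("count matrix contains non-integer entries")
    if values.size and (values < 0).any():
        bad = counts.columns[(values < 0).any(axis=0)][0]
        raise ValueError(f"negative count in ORF column {bad!r}")
    if orfs is not None:
        known = {o.orf_id for o in orfs}
        unknown = set(counts.columns) - known
        if unknown:
            raise ValueError(f"count columns for unknown ORFs: {sorted(unknown)[:5]}")
    if samples is not None:
        known_s = {s.sample_id for s in samples}
        unknown_s = set(counts.index) - known_s
        if unknown_s:
            raise ValueError(
                f"count rows for samples missing from metadata: {sorted(unknown_s)[:5]}"
            )
    return counts.astype("int64")
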