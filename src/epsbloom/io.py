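"""Readers and writers for every file the pipeline touches.

Formats: FASTA for contigs (Biopython), GFF3 for ORF calls (gffutils,
in-memory db), TSV for everything tabular (contig membership, annotations,
counts, sample metadata, TEP plate and standards).  The count-matrix
dialect is samples as rows, ORFs as columns, UTF-8, '.' decimal separator,
bit-exact integer parsing.  All paths are logged at load.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    MagRecord,
    MarkerGeneSet,
    OrfRecord,
    SampleInfo,
    TepMeasurement,
    validate_count_matrix,
)
from .simulate import Community, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_mag_catalog",
    "read_orfs",
    "read_counts",
    "read_samples",
    "read_markers",
    "read_tep_standards",
    "read_tep_plate",
    "write_counts",
    "write_matrix",
    "write_community",
]


def read_mag_catalog(fasta_path: str | Path, membership_tsv: str | Path) -> list[MagRecord]:
    """Load the MAG catalog from a contig FASTA and a membership table.

    The membership TSV has columns ``contig_id, mag_id`` and optionally
    ``domain, class, order`` taxonomy columns.  Contig lengths are taken
    from the sequences.  Errors: a contig listed in the membership but
    absent from the FASTA, or one contig assigned to two MAGs.
    """
    fasta_path, membership_tsv = Path(fasta_path), Path(membership_tsv)
    logger.info("reading MAG catalog: %s + %s", fasta_path, membership_tsv)
    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(membership_tsv, sep="\t", dtype=str)
    if table.empty:
        logger.warning("empty membership table %s: empty catalog", membership_tsv)
        return []
    required = {"contig_id", "mag_id"}
    if not required <= set(table.columns):
        raise ValueError(f"membership table needs columns {sorted(required)}")
    if table["contig_id"].duplicated().any():
        dup = table.loc[table["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise ValueError(f"contig {dup!r} assigned to more than one MAG")
    missing = [c for c in table["contig_id"] if c not in lengths]
    if missing:
        raise ValueError(f"contig {missing[0]!r} in membership table absent from FASTA")
    tax_cols = [c for c in ("domain", "class", "order") if c in table.columns]
    mags = []
    for mid, sub in table.groupby("mag_id", sort=True):
        taxonomy = ()
        if tax_cols:
            taxonomy = tuple(str(sub.iloc[0][c]) for c in tax_cols)
        mags.append(
            MagRecord(
                mag_id=str(mid),
                contigs=tuple((c, lengths[c]) for c in sub["contig_id"]),
                taxonomy=taxonomy,
            )
        )
    logger.info("loaded %d MAGs, %d contigs", len(mags), len(table))
    return mags


def read_orfs(
    gff3_path: str | Path,
    annotation_tsv: str | Path | None,
    mags: Sequence[MagRecord],
) -> list[OrfRecord]:
    """Load CDS features from GFF3 plus a TSV of functional annotations.

    The annotation table has columns ``orf_id, annotations`` where
    ``annotations`` is a comma-separated list of identifiers (gene symbols,
    KOs, COG/OG numbers).  ORFs without a row get an empty annotation set;
    rows for unknown ORFs are skipped with a warning.  Every CDS must sit on
    a contig of the catalog (its MAG membership comes from there).
    """
    gff3_path = Path(gff3_path)
    logger.info("reading ORFs: %s", gff3_path)
    contig_to_mag = {
        cid: m.mag_id for m in mags for cid in m.contig_ids
    }
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    annotations: dict[str, frozenset[str]] = {}
    if annotation_tsv is not None:
        ann = pd.read_csv(Path(annotation_tsv), sep="\t", dtype=str).fillna("")
        if not {"orf_id", "annotations"} <= set(ann.columns):
            raise ValueError("annotation table needs columns orf_id, annotations")
        for _, row in ann.iterrows():
            idents = frozenset(
                a.strip() for a in str(row["annotations"]).split(",") if a.strip()
            )
            annotations[str(row["orf_id"])] = idents

    orfs = []
    seen: set[str] = set()
    for feature in db.features_of_type("CDS", order_by=("seqid", "start")):
        orf_id = feature.attributes.get("ID", [feature.id])[0]
        if orf_id in seen:
            raise ValueError(f"duplicate ORF id {orf_id!r} in {gff3_path}")
        seen.add(orf_id)
        contig = feature.seqid
        if contig not in contig_to_mag:
            raise ValueError(f"ORF {orf_id!r} on unknown contig {contig!r}")
        orfs.append(
            OrfRecord(
                orf_id=orf_id,
                mag_id=contig_to_mag[contig],
                contig_id=contig,
                start=feature.start,
                end=feature.end,
                strand=feature.strand if feature.strand in "+-" else "+",
                annotations=annotations.get(orf_id, frozenset()),
            )
        )
    orphan = set(annotations) - seen
    if orphan:
        logger.warning(
            "annotation rows for %d ORFs absent from GFF3, skipped (e.g. %s)",
            len(orphan), sorted(orphan)[0],
        )
    logger.info("loaded %d ORFs", len(orfs))
    return orfs


def read_counts(
    tsv_path: str | Path,
    orfs: Sequence[OrfRecord] | None = None,
    samples: Sequence[SampleInfo] | None = None,
) -> pd.DataFrame:
    """Load the samples x ORFs count matrix (TSV, header = ORF ids)."""
    tsv_path = Path(tsv_path)
    logger.info("reading count matrix: %s", tsv_path)
    raw = pd.read_csv(tsv_path, sep="\t", index_col=0, dtype=str)
    if raw.isna().any().any():
        raise ValueError(f"missing cells in count matrix {tsv_path}")
    try:
        counts = raw.astype("int64")
    except ValueError as exc:
        raise ValueError(f"non-integer entry in count matrix {tsv_path}: {exc}") from exc
    return validate_count_matrix(counts, orfs=orfs, samples=samples)


def read_samples(tsv_path: str | Path) -> list[SampleInfo]:
    """Load sample metadata: sample_id, time_index, bloom_phase, P and N."""
    tsv_path = Path(tsv_path)
    logger.info("reading sample metadata: %s", tsv_path)
    table = pd.read_csv(tsv_path, sep="\t")
    required = {"sample_id", "time_index", "bloom_phase"}
    if not required <= set(table.columns):
        raise ValueError(f"sample table needs columns {sorted(required)}")
    if table["time_index"].duplicated().any():
        raise ValueError("duplicate time_index in sample metadata")
    return [
        SampleInfo(
            sample_id=str(r["sample_id"]),
            time_index=int(r["time_index"]),
            bloom_phase=int(r["bloom_phase"]),
            phosphate_uM=float(r.get("phosphate_uM", 0.0)),
            nitrate_uM=float(r.get("nitrate_uM", 0.0)),
        )
        for _, r in table.iterrows()
    ]


def read_markers(tsv_path: str | Path) -> MarkerGeneSet:
    """Load marker assignments: columns mag_id, cog_id, orf_id."""
    table = pd.read_csv(Path(tsv_path), sep="\t", dtype=str)
    assignments: dict[str, dict[str, str]] = {}
    for _, r in table.iterrows():
        assignments.setdefault(r["mag_id"], {})[r["cog_id"]] = r["orf_id"]
    return MarkerGeneSet(assignments=assignments)


def read_tep_standards(tsv_path: str | Path) -> list[tuple[float, float]]:
    """Load XG standards: columns mass_ug, absorbance."""
    table = pd.read_csv(Path(tsv_path), sep="\t")
    if not {"mass_ug", "absorbance"} <= set(table.columns):
        raise ValueError("standards table needs columns mass_ug, absorbance")
    return [(float(r["mass_ug"]), float(r["absorbance"])) for _, r in table.iterrows()]


def read_tep_plate(tsv_path: str | Path) -> list[TepMeasurement]:
    """Load the assay plate: sample_id, organism, regime, a_sample,
    a_filter_blank, volume_ml and optional cell_density."""
    table = pd.read_csv(Path(tsv_path), sep="\t")
    if table.empty:
        raise ValueError(f"empty TEP plate table {tsv_path}")
    return [
        TepMeasurement(
            sample_id=str(r["sample_id"]),
            organism=str(r["organism"]),
            regime=str(r["regime"]),
            a_sample=float(r["a_sample"]),
            a_filter_blank=float(r["a_filter_blank"]),
            volume_ml=float(r["volume_ml"]),
            cell_density=(
                float(r["cell_density"])
                if "cell_density" in table.columns and pd.notna(r["cell_density"])
                else None
            ),
        )
        for _, r in table.iterrows()
    ]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(Path(path), sep="\t", index_label="sample_id")


def write_matrix(matrix: pd.DataFrame, path: str | Path, comment: str = "") -> None:
    """Write a real-valued matrix as TSV at full float precision, with an
    optional leading comment line naming the computation."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        matrix.to_csv(fh, sep="\t", index_label="id", float_format="%.12g")


def write_clusters_gff3(clusters, orfs, path: str | Path) -> None:
    """Write detected gene clusters as GFF3 region features spanning their
    member ORFs."""
    by_id = {o.orf_id: o for o in orfs}
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(clusters, start=1):
            members = [by_id[o] for o in c.orf_ids]
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            fh.write(
                f"{c.contig_id}\tepsbloom\tregion\t{start}\t{end}\t.\t.\t.\t"
                f"ID=cluster{i};module={c.module_name};mag={c.mag_id};"
                f"completeness={c.completeness:.4g};"
                f"genes={'|'.join(sorted(c.matched_key_genes))}\n"
            )


def _random_sequence(rng, length: int) -> str:
    import numpy as np

    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def write_community(
    community: Community,
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    outdir: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write the file set `io` reads back: FASTA, membership, GFF3,
    annotations, counts, samples, markers, plus a manifest with the seed and
    a config hash.  Contig sequences are random but seeded, so repeated
    writes of the same community are byte-identical."""
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "contigs.fasta",
        "membership": outdir / "membership.tsv",
        "gff3": outdir / "orfs.gff3",
        "annotations": outdir / "annotations.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "markers": outdir / "markers.tsv",
        "manifest": outdir / "manifest.json",
    }
    seq_seed = config.seed if config is not None else 0
    rng = np.random.default_rng([seq_seed, 2**20])
    with open(paths["fasta"], "w") as fh:
        for mag in community.mags:
            for cid, length in mag.contigs:
                fh.write(f">{cid}\n")
                seq = _random_sequence(rng, length)
                for i in range(0, length, 80):
                    fh.write(seq[i : i + 80] + "\n")
    rows = []
    for mag in community.mags:
        for cid, _ in mag.contigs:
            row = {"contig_id": cid, "mag_id": mag.mag_id}
            for name, label in zip(("domain", "class", "order"), mag.taxonomy):
                row[name] = label
            rows.append(row)
    pd.DataFrame(rows).to_csv(paths["membership"], sep="\t", index=False)

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for o in sorted(community.orfs, key=lambda o: (o.contig_id, o.start)):
            fh.write(
                f"{o.contig_id}\tepsbloom\tCDS\t{o.start}\t{o.end}\t.\t{o.strand}\t0\t"
                f"ID={o.orf_id}\n"
            )
    pd.DataFrame(
        {
            "orf_id": [o.orf_id for o in community.orfs],
            "annotations": [",".join(sorted(o.annotations)) for o in community.orfs],
        }
    ).to_csv(paths["annotations"], sep="\t", index=False)
    write_counts(counts, paths["counts"])
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "time_index": s.time_index,
                "bloom_phase": s.bloom_phase,
                "phosphate_uM": s.phosphate_uM,
                "nitrate_uM": s.nitrate_uM,
            }
            for s in samples
        ]
    ).to_csv(paths["samples"], sep="\t", index=False, float_format="%.12g")
    pd.DataFrame(
        [
            {"mag_id": mid, "cog_id": cog, "orf_id": orf}
            for mid, table in sorted(community.markers.assignments.items())
            for cog, orf in sorted(table.items())
        ]
    ).to_csv(paths["markers"], sep="\t", index=False)

    config_dict = (
        {k: (list(v) if isinstance(v, tuple) else dict(v) if hasattr(v, "items") else v)
         for k, v in vars(config).items()}
        if config is not None
        else {}
    )
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "seed": seq_seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "n_mags": len(community.mags),
        "n_orfs": len(community.orfs),
        "n_samples": len(samples),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("synthetic study written to %s", outdir)
    return paths
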