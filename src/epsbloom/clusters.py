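"""Detection of EPS biosynthesis gene clusters and their expression profiles.

Three bacterial EPS assembly routes are scanned for: the alginate operon,
the bacterial cellulose synthase operon (bcsABZC), and the widespread
wzx/wzy-dependent pathway (flippase + polymerase + glycosyltransferases and
export components).  Matching is by annotation-identifier equality — gene
symbol, KO or COG/OG number — against each ORF's annotation set; homology
searching is upstream and out of scope.  A cluster is a maximal run of
key-gene-annotated ORFs on one contig with bounded gaps, reported only when
it carries the module's required core genes and a minimum fraction of its
key genes.

The default gene lists reconstruct the standard pathway components and are
fully overridable, so a curated list can be dropped in via configuration.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import compare_phases, scale_rows
from .model import EpsModuleDefinition, GeneCluster, MgResult, OrfRecord, SampleInfo

logger = logging.getLogger(__name__)

__all__ = [
    "default_modules",
    "modules_from_config",
    "detect_clusters",
    "cluster_expression",
]

_DEFAULT_MODULE_DEFS: dict[str, dict] = {
    "alginate": {
        "key_genes": {
            "algA", "algC", "alg8", "alg44", "algK", "algE",
            "algX", "algL", "algI", "algJ", "algF", "algG",
        },
        "required_core": {"alg8", "alg44", "algA"},
    },
    "cellulose": {
        "key_genes": {"bcsA", "bcsB", "bcsZ", "bcsC"},
        "required_core": {"bcsA", "bcsB"},
    },
    "wzx_wzy": {
        # flippase, polymerase, priming glycosyltransferase, a further
        # glycosyltransferase, chain-length co-polymerase, OM export.
        "key_genes": {"wzx", "wzy", "wbaP", "gt2", "wzz", "wza"},
        "required_core": {"wzx", "wzy"},
    },
}


def default_modules(min_fraction: float = 0.5) -> list[EpsModuleDefinition]:
    """The three default EPS module definitions (alginate, cellulose, wzx/wzy)."""
    return [
        EpsModuleDefinition(
            module_name=name,
            key_genes=frozenset(defn["key_genes"]),
            required_core=frozenset(defn["required_core"]),
            min_fraction=min_fraction,
        )
        for name, defn in _DEFAULT_MODULE_DEFS.items()
    ]


def modules_from_config(
    config: Mapping[str, Mapping] | None, min_fraction: float = 0.5
) -> list[EpsModuleDefinition]:
    """Build module definitions from a config mapping, or the defaults.

    ``config`` maps module name to ``{key_genes: [...], required_core: [...],
    min_fraction: float}``; a provided module replaces its default verbatim.
    An explicitly empty mapping is an error — there would be nothing to scan.
    """
    if config is None:
        return default_modules(min_fraction)
    if not config:
        raise ValueError("empty EPS module configuration: nothing to scan")
    modules = []
    for name, defn in config.items():
        modules.append(
            EpsModuleDefinition(
                module_name=name,
                key_genes=frozenset(defn["key_genes"]),
                required_core=frozenset(defn.get("required_core", ())),
                min_fraction=float(defn.get("min_fraction", min_fraction)),
            )
        )
    return modules


def detect_clusters(
    orfs: Sequence[OrfRecord],
    module: EpsModuleDefinition,
    max_gap_genes: int = 2,
    max_gap_bp: int = 5000,
    require_co_strand: bool = False,
) -> list[GeneCluster]:
    """Scan annotated ORFs for gene clusters of one EPS module.

    ORFs are grouped per contig and sorted by start.  Matched ORFs (any
    annotation identifier equal to a key gene) are chained into maximal runs
    where consecutive matches are separated by at most ``max_gap_genes``
    intervening ORFs and at most ``max_gap_bp`` base pairs.  A run becomes a
    reported :class:`GeneCluster` only if its matched genes include all of
    ``module.required_core`` and cover at least ``module.min_fraction`` of
    ``module.key_genes``.  Strand is ignored unless ``require_co_strand``,
    which additionally splits runs at strand changes.
    """
    if max_gap_genes < 0 or max_gap_bp < 0:
        raise ValueError("gap parameters must be non-negative")
    key = module.key_genes
    by_contig: dict[tuple[str, str], list[OrfRecord]] = {}
    for orf in orfs:
        by_contig.setdefault((orf.mag_id, orf.contig_id), []).append(orf)

    clusters: list[GeneCluster] = []
    for (mag_id, contig_id), contig_orfs in by_contig.items():
        contig_orfs = sorted(contig_orfs, key=lambda o: (o.start, o.end))
        matched = [
            (i, o) for i, o in enumerate(contig_orfs) if o.annotations & key
        ]
        if not matched:
            continue
        runs: list[list[OrfRecord]] = [[matched[0][1]]]
        prev_i, prev_o = matched[0]
        for i, o in matched[1:]:
            gap_genes = i - prev_i - 1
            gap_bp = max(0, o.start - prev_o.end - 1)
            if gap_genes <= max_gap_genes and gap_bp <= max_gap_bp:
                runs[-1].append(o)
            else:
                runs.append([o])
            prev_i, prev_o = i, o
        if require_co_strand:
            split: list[list[OrfRecord]] = []
            for run in runs:
                current = [run[0]]
                for o in run[1:]:
                    if o.strand == current[-1].strand:
                        current.append(o)
                    else:
                        split.append(current)
                        current = [o]
                split.append(current)
            runs = split
        for run in runs:
            genes = frozenset().union(*(o.annotations & key for o in run))
            if not module.required_core <= genes:
                continue
            completeness = len(genes) / len(key)
            if completeness < module.min_fraction:
                continue
            clusters.append(
                GeneCluster(
                    mag_id=mag_id,
                    contig_id=contig_id,
                    module_name=module.module_name,
                    orf_ids=tuple(o.orf_id for o in run),
                    matched_key_genes=genes,
                    completeness=completeness,
                )
            )
    logger.info(
        "module %s: %d cluster(s) detected across %d contig(s)",
        module.module_name,
        len(clusters),
        len(by_contig),
    )
    return clusters


def cluster_expression(
    clusters: Iterable[GeneCluster],
    mg: MgResult | pd.DataFrame,
    samples: Sequence[SampleInfo],
    scaling: str = "zscore",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Per-cluster expression profiles from MG-normalized values.

    For each cluster the per-sample profile is the mean of its member ORFs'
    MG-normalized values (NaN-undefined members ignored sample-wise).
    Returns a dict with:

    * ``profiles`` — clusters x samples DataFrame of mean MG values;
    * ``gene_profiles`` — long DataFrame of per-gene values;
    * ``scaled`` — row-scaled profiles (undefined clusters excluded);
    * ``phase_comparison`` — output of :func:`compare_phases` on profiles;
    * ``undefined_clusters`` — cluster labels whose values were all undefined.
    """
    matrix = mg.matrix if isinstance(mg, MgResult) else mg
    clusters = list(clusters)
    profiles = {}
    gene_rows = []
    undefined = []
    for cluster in clusters:
        label = f"{cluster.mag_id}:{cluster.module_name}:{cluster.contig_id}"
        missing = [o for o in cluster.orf_ids if o not in matrix.columns]
        if missing:
            raise ValueError(
                f"cluster {label}: ORFs absent from the MG matrix: {missing[:5]}"
            )
        sub = matrix[list(cluster.orf_ids)]
        if sub.isna().all().all():
            undefined.append(label)
            logger.warning("cluster %s: all values undefined, excluded", label)
            continue
        profiles[label] = sub.mean(axis=1, skipna=True)
        for orf_id in cluster.orf_ids:
            for sample_id, value in sub[orf_id].items():
                gene_rows.append(
                    {
                        "cluster": label,
                        "orf_id": orf_id,
                        "sample_id": sample_id,
                        "mg_value": value,
                    }
                )
    profile_df = pd.DataFrame(profiles).T  # clusters x samples
    if not profile_df.empty:
        scaled, _ = scale_rows(profile_df, method=scaling)
        comparison = compare_phases(
            profile_df, samples, n_permutations=n_permutations, seed=seed
        )
    else:
        scaled = profile_df.copy()
        comparison = pd.DataFrame(
            columns=["mean_phase1", "mean_phase2", "log2_ratio", "stat",
                     "p_value", "rank"]
        )
    return {
        "profiles": profile_df,
        "gene_profiles": pd.DataFrame(gene_rows),
        "scaled": scaled,
        "phase_comparison": comparison,
        "undefined_clusters": tuple(undefined),
    }
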