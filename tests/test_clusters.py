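"""EPS gene-cluster detection and cluster expression profiles."""

import numpy as np
import pandas as pd
import pytest

from epsbloom.clusters import (
    cluster_expression,
    default_modules,
    detect_clusters,
    modules_from_config,
)
from epsbloom.model import EpsModuleDefinition, SampleInfo
from epsbloom.normalization import mg_normalize

from .conftest import make_orf


def _module(name="alginate"):
    return next(m for m in default_modules() if m.module_name == name)


def _lay_orfs(genes, contig="c1", mag="MAGA", start=1, spacing=1500, length_bp=1000):
    """Place one ORF per entry of `genes` head to tail; None means unannotated."""
    orfs = []
    pos = start
    for i, g in enumerate(genes):
        ann = () if g is None else (g,)
        orfs.append(
            make_orf(f"{contig}_o{i+1}", mag=mag, contig=contig, start=pos,
                     length_bp=length_bp, annotations=ann)
        )
        pos += spacing
    return orfs


class TestDefaultModules:
    def test_core_is_subset_of_key_genes(self):
        for m in default_modules():
            assert m.required_core <= m.key_genes
            assert 0 < m.min_fraction <= 1
        assert {m.module_name for m in default_modules()} == {
            "alginate", "cellulose", "wzx_wzy",
        }

    def test_config_override_replaces_defaults_verbatim(self):
        mods = modules_from_config(
            {"cellulose": {"key_genes": ["x1", "x2"], "required_core": ["x1"]}}
        )
        assert len(mods) == 1
        assert mods[0].key_genes == frozenset({"x1", "x2"})

    def test_empty_module_list_is_an_error(self):
        with pytest.raises(ValueError, match="nothing to scan"):
            modules_from_config({})

    def test_invalid_definition_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            EpsModuleDefinition(
                module_name="bad",
                key_genes=frozenset({"a"}),
                required_core=frozenset({"a", "b"}),
            )


class TestDetectClusters:
    def test_planted_ideal_operon_single_complete_cluster(self):
        module = _module("alginate")
        orfs = _lay_orfs(sorted(module.key_genes))
        clusters = detect_clusters(orfs, module)
        assert len(clusters) == 1
        assert clusters[0].completeness == 1.0
        assert clusters[0].matched_key_genes == module.key_genes

    def test_split_operon_keeps_only_the_core_contig(self):
        module = _module("alginate")
        genes = sorted(module.key_genes)
        core_first = sorted(module.required_core) + sorted(
            set(genes) - module.required_core
        )
        on_a, on_b = core_first[:6], core_first[6:]
        orfs = _lay_orfs(on_a, contig="cA") + _lay_orfs(on_b, contig="cB")
        clusters = detect_clusters(orfs, module)
        assert len(clusters) == 1
        assert clusters[0].contig_id == "cA"
        assert clusters[0].completeness == pytest.approx(6 / 12)

    def test_gap_rules_split_runs(self):
        module = _module("cellulose")
        # two bcs pairs separated by 4 unannotated ORFs: two runs, but only
        # the one holding the full core {bcsA, bcsB} is reported
        genes = ["bcsA", "bcsB", None, None, None, None, "bcsZ", "bcsC"]
        orfs = _lay_orfs(genes)
        clusters = detect_clusters(orfs, module, max_gap_genes=2)
        assert len(clusters) == 1
        assert clusters[0].matched_key_genes == frozenset({"bcsA", "bcsB"})
        # with a permissive gap the pieces fuse into one complete cluster
        merged = detect_clusters(orfs, module, max_gap_genes=4, max_gap_bp=10_000)
        assert len(merged) == 1
        assert merged[0].completeness == 1.0

    def test_bp_gap_limit(self):
        module = _module("cellulose")
        orfs = _lay_orfs(["bcsA", "bcsB"], spacing=1500) + _lay_orfs(
            ["bcsZ", "bcsC"], start=50_000
        )
        clusters = detect_clusters(orfs, module, max_gap_genes=10, max_gap_bp=5000)
        assert len(clusters) == 1  # far pair lacks the core

    def test_co_strand_filter_splits_mixed_runs(self):
        module = _module("cellulose")
        orfs = _lay_orfs(["bcsA", "bcsB", "bcsZ", "bcsC"])
        flipped = [
            make_orf(o.orf_id, mag=o.mag_id, contig=o.contig_id, start=o.start,
                     length_bp=o.end - o.start + 1, annotations=o.annotations,
                     strand="-" if i >= 2 else "+")
            for i, o in enumerate(orfs)
        ]
        assert len(detect_clusters(flipped, module)) == 1
        strict = detect_clusters(flipped, module, require_co_strand=True)
        assert len(strict) == 1  # only the + run keeps the bcsA+bcsB core
        assert strict[0].matched_key_genes == frozenset({"bcsA", "bcsB"})

    def test_negative_gap_parameters_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            detect_clusters([], _module(), max_gap_genes=-1)

    def test_shuffled_annotations_null_rate(self):
        """Scattering the 12 alginate genes over 500 ORFs almost never forms
        a reportable cluster (mean < 0.05 clusters per genome, 20 seeds)."""
        module = _module("alginate")
        genes = sorted(module.key_genes)
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            labels: list = [None] * 500
            for pos, gene in zip(
                rng.choice(500, size=len(genes), replace=False), genes
            ):
                labels[pos] = gene
            orfs = _lay_orfs(labels)
            total += len(detect_clusters(orfs, module))
        assert total / 20 < 0.05

    def test_invariant_to_orf_renaming_and_reversal(self):
        module = _module("wzx_wzy")
        orfs = _lay_orfs(sorted(module.key_genes))
        base = detect_clusters(orfs, module)
        renamed = [
            make_orf(f"renamed_{i}", mag=o.mag_id, contig=o.contig_id,
                     start=o.start, length_bp=o.end - o.start + 1,
                     annotations=o.annotations)
            for i, o in enumerate(orfs)
        ]
        assert len(detect_clusters(renamed, module)) == len(base)
        contig_len = max(o.end for o in orfs) + 100
        mirrored = [
            make_orf(o.orf_id, mag=o.mag_id, contig=o.contig_id,
                     start=contig_len - o.end + 1,
                     length_bp=o.end - o.start + 1, annotations=o.annotations)
            for o in orfs
        ]
        flipped = detect_clusters(mirrored, module)
        assert len(flipped) == len(base)
        assert set(flipped[0].orf_ids) == set(base[0].orf_ids)

    def test_gap_monotonicity_single_copy_core(self):
        """With single-copy core genes, widening the gene gap never loses
        clusters."""
        module = _module("alginate")
        genes = sorted(module.key_genes)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels: list = [None] * 60
            for pos, gene in zip(rng.choice(60, size=len(genes), replace=False),
                                 genes):
                labels[pos] = gene
            orfs = _lay_orfs(labels)
            counts = [
                len(detect_clusters(orfs, module, max_gap_genes=g,
                                    max_gap_bp=10**9))
                for g in range(0, 12, 2)
            ]
            assert counts == sorted(counts)


class TestClusterExpression:
    def _mg_setup(self, small_study):
        community, counts, samples = small_study
        mg = mg_normalize(counts, community.orfs, community.markers)
        clusters = [
            c for m in default_modules() for c in detect_clusters(community.orfs, m)
        ]
        return community, mg, clusters, samples

    def test_single_orf_cluster_profile_equals_orf_row(self, small_study):
        community, mg, clusters, samples = self._mg_setup(small_study)
        c = clusters[0]
        single = type(c)(
            mag_id=c.mag_id, contig_id=c.contig_id, module_name=c.module_name,
            orf_ids=c.orf_ids[:1], matched_key_genes=c.matched_key_genes,
            completeness=c.completeness,
        )
        out = cluster_expression([single], mg, samples, n_permutations=200)
        label = f"{c.mag_id}:{c.module_name}:{c.contig_id}"
        np.testing.assert_allclose(
            out["profiles"].loc[label].to_numpy(),
            mg.matrix[c.orf_ids[0]].to_numpy(),
            rtol=1e-12,
        )

    def test_planted_elevated_cluster_ranks_first(self, small_study):
        community, mg, clusters, samples = self._mg_setup(small_study)
        assert len(clusters) == 2  # one elevated, one null alginate cluster
        out = cluster_expression(clusters, mg, samples, n_permutations=500)
        top = out["phase_comparison"].index[0]
        elevated = [p for p in community.planted if p.elevated][0]
        assert top.startswith(f"{elevated.mag_id}:")

    def test_all_zero_cluster_flagged_undefined(self, small_study):
        community, mg, clusters, samples = self._mg_setup(small_study)
        c = clusters[0]
        matrix = mg.matrix.copy()
        matrix.loc[:, list(c.orf_ids)] = np.nan
        from epsbloom.model import MgResult

        out = cluster_expression(
            clusters, MgResult(matrix=matrix, undefined=matrix.isna()), samples,
            n_permutations=200,
        )
        label = f"{c.mag_id}:{c.module_name}:{c.contig_id}"
        assert label in out["undefined_clusters"]
        assert label not in out["profiles"].index
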