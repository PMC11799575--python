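"""MAG relative activity, row scaling and phase comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epsbloom.activity import compare_phases, mag_activity, scale_rows
from epsbloom.model import MagRecord, SampleInfo
from epsbloom.normalization import tpm_normalize

from .conftest import make_orf


def _samples(phases):
    return [
        SampleInfo(sample_id=f"s{i+1}", time_index=i + 1, bloom_phase=p)
        for i, p in enumerate(phases)
    ]


class TestMagActivity:
    def test_single_mag_has_activity_one(self):
        orfs = [make_orf("o1"), make_orf("o2", start=3000)]
        mags = [MagRecord(mag_id="MAGA", contigs=(("c1", 10_000),))]
        counts = pd.DataFrame({"o1": [5, 1], "o2": [7, 9]}, index=["s1", "s2"])
        tpm = tpm_normalize(counts, orfs)
        act = mag_activity(tpm, orfs, mags)
        assert np.allclose(act.matrix.loc["MAGA"], 1.0)

    def test_equal_length_mags_share_hand_example(self):
        # equal-length MAGs with TPM shares 0.75 / 0.25 -> activities 1.5 / 0.5
        orfs = [
            make_orf("a1", mag="MAGA", contig="cA"),
            make_orf("b1", mag="MAGB", contig="cB"),
        ]
        mags = [
            MagRecord(mag_id="MAGA", contigs=(("cA", 5000),)),
            MagRecord(mag_id="MAGB", contigs=(("cB", 5000),)),
        ]
        counts = pd.DataFrame({"a1": [75], "b1": [25]}, index=["s1"])
        act = mag_activity(tpm_normalize(counts, orfs), orfs, mags)
        assert act.matrix.loc["MAGA", "s1"] == pytest.approx(1.5, rel=1e-12)
        assert act.matrix.loc["MAGB", "s1"] == pytest.approx(0.5, rel=1e-12)

    def test_zero_tpm_mag_and_zero_sample(self):
        orfs = [
            make_orf("a1", mag="MAGA", contig="cA"),
            make_orf("b1", mag="MAGB", contig="cB"),
        ]
        mags = [
            MagRecord(mag_id="MAGA", contigs=(("cA", 5000),)),
            MagRecord(mag_id="MAGB", contigs=(("cB", 5000),)),
        ]
        counts = pd.DataFrame({"a1": [10, 0], "b1": [0, 0]}, index=["s1", "s2"])
        act = mag_activity(tpm_normalize(counts, orfs), orfs, mags)
        assert act.matrix.loc["MAGB", "s1"] == 0.0
        assert act.undefined_samples == ("s2",)
        assert act.matrix["s2"].isna().all()

    def test_share_numerators_sum_to_one(self, small_study):
        community, counts, _ = small_study
        tpm = tpm_normalize(counts, community.orfs)
        act = mag_activity(tpm, community.orfs, community.mags)
        lengths = pd.Series({m.mag_id: m.length_kb for m in community.mags})
        length_share = lengths / lengths.sum()
        shares = act.matrix.mul(length_share, axis=0).sum(axis=0)
        assert np.allclose(shares, 1.0, rtol=1e-9)

    def test_invariant_to_uniform_length_rescale(self, small_study):
        community, counts, _ = small_study
        tpm = tpm_normalize(counts, community.orfs)
        act = mag_activity(tpm, community.orfs, community.mags)
        rescaled = [
            MagRecord(
                mag_id=m.mag_id,
                contigs=tuple((c, l * 3) for c, l in m.contigs),
                taxonomy=m.taxonomy,
            )
            for m in community.mags
        ]
        act2 = mag_activity(tpm, community.orfs, rescaled)
        pd.testing.assert_frame_equal(act.matrix, act2.matrix)

    def test_equal_share_mag_has_activity_exactly_one(self):
        # one ORF per MAG, counts proportional to MAG length -> activity 1
        orfs = [
            make_orf("a1", mag="MAGA", contig="cA", length_bp=1000),
            make_orf("b1", mag="MAGB", contig="cB", length_bp=1000),
        ]
        mags = [
            MagRecord(mag_id="MAGA", contigs=(("cA", 2000),)),
            MagRecord(mag_id="MAGB", contigs=(("cB", 6000),)),
        ]
        counts = pd.DataFrame({"a1": [10], "b1": [30]}, index=["s1"])
        act = mag_activity(tpm_normalize(counts, orfs), orfs, mags)
        assert act.matrix.loc["MAGA", "s1"] == pytest.approx(1.0, rel=1e-12)
        assert act.matrix.loc["MAGB", "s1"] == pytest.approx(1.0, rel=1e-12)


class TestScaleRows:
    def test_zscore_hand_example(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
        scaled, flagged = scale_rows(m)
        assert np.allclose(scaled.loc["r"], [-1, 0, 1])
        assert flagged == ()

    def test_constant_row_maps_to_zero_and_flag(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["c", "v"])
        scaled, flagged = scale_rows(m)
        assert (scaled.loc["c"] == 0).all()
        assert flagged == ("c",)

    def test_idempotent_on_standardized_rows(self):
        m = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["r"])
        scaled, _ = scale_rows(m)
        assert np.allclose(scaled.to_numpy(), m.to_numpy(), rtol=1e-12)

    def test_single_sample_zscore_raises(self):
        with pytest.raises(ValueError, match="sd undefined|>= 2 samples"):
            scale_rows(pd.DataFrame([[1.0]]))

    def test_minmax_and_none(self):
        m = pd.DataFrame([[2.0, 4.0, 6.0]], index=["r"])
        scaled, _ = scale_rows(m, method="minmax")
        assert np.allclose(scaled.loc["r"], [0, 0.5, 1])
        same, flagged = scale_rows(m, method="none")
        pd.testing.assert_frame_equal(same, m)
        with pytest.raises(ValueError, match="unknown scaling"):
            scale_rows(m, method="robust")


def brute_force_one_sided_p(values, n1, n2):
    """Enumerate all C(n, n2) phase-2 label choices; independent oracle."""
    n = n1 + n2
    obs = np.mean(values[n1:]) - np.mean(values[:n1])
    stats = []
    for idx in itertools.combinations(range(n), n2):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        stats.append(np.mean(values[sel]) - np.mean(values[~sel]))
    return np.mean([s >= obs for s in stats])


class TestComparePhases:
    def test_identical_phases_ratio_zero_p_large(self):
        m = pd.DataFrame([[3.0, 3.0, 3.0, 3.0, 3.0, 3.0]], index=["r"],
                         columns=[f"s{i+1}" for i in range(6)])
        out = compare_phases(m, _samples([1, 1, 1, 2, 2, 2]))
        assert out.loc["r", "log2_ratio"] == 0.0
        assert out.loc["r", "p_value"] >= 0.5

    def test_exhaustive_p_matches_brute_force_3v3(self):
        rows = [[4.0, 7.0, 5.0, 9.0, 12.0, 8.0], [10.0, 2.0, 6.0, 5.0, 5.0, 5.0]]
        m = pd.DataFrame(rows, index=["up", "flat"],
                         columns=[f"s{i+1}" for i in range(6)])
        out = compare_phases(m, _samples([1, 1, 1, 2, 2, 2]))
        for row in ("up", "flat"):
            expected = brute_force_one_sided_p(np.array(m.loc[row]), 3, 3)
            assert out.loc[row, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_empty_phase_raises(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"],
                         columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="per phase"):
            compare_phases(m, _samples([1, 1, 1]))

    def test_planted_active_mag_ranks_first(self, small_study):
        community, counts, samples = small_study
        tpm = tpm_normalize(counts, community.orfs)
        act = mag_activity(tpm, community.orfs, community.mags)
        out = compare_phases(act.matrix, samples, n_permutations=2000)
        top2 = set(out.index[:2])
        assert top2 == {"MAG001", "MAG002"}  # the two f_act = 4 MAGs
        assert (out.loc[list(top2), "p_value"] < 0.05).all()
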