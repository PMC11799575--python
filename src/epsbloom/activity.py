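"""Per-MAG relative activity, row scaling, and bloom-phase comparison.

Relative activity asks whether a genome transcribes more or less than its
genomic representation predicts:

    activity_js = (TPM share of MAG j in sample s) / (length share of MAG j)

A value of 1 means transcription exactly proportional to genome length;
values above 1 flag disproportionately active MAGs.  Activity profiles are
typically visualized after per-row scaling, and phase-2-vs-phase-1 shifts
are tested with a one-sided permutation test on the phase means.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ActivityResult, MagRecord, OrfRecord, SampleInfo, TpmResult

logger = logging.getLogger(__name__)

__all__ = ["mag_activity", "scale_rows", "compare_phases"]


def mag_activity(
    tpm: TpmResult | pd.DataFrame,
    orfs: Sequence[OrfRecord],
    mags: Sequence[MagRecord],
) -> ActivityResult:
    """Relative activity of every MAG in every sample (MAGs x samples).

    ``activity_js = [sum TPM of MAG j's ORFs / sum TPM in sample s]
    / [length_kb of MAG j / total length_kb of all MAGs]``.

    Samples with zero total TPM have undefined activity (NaN column,
    flagged).  A MAG with zero TPM in a defined sample has activity 0.
    """
    matrix = tpm.matrix if isinstance(tpm, TpmResult) else tpm
    orf_to_mag = {o.orf_id: o.mag_id for o in orfs}
    missing = [c for c in matrix.columns if c not in orf_to_mag]
    if missing:
        raise ValueError(f"TPM columns without an ORF record: {missing[:5]}")
    mag_ids = [m.mag_id for m in mags]
    lengths = pd.Series({m.mag_id: m.length_kb for m in mags})
    total_length = lengths.sum()
    if total_length <= 0:
        raise ValueError("MAG catalog has zero total length")

    unknown = {orf_to_mag[c] for c in matrix.columns} - set(mag_ids)
    if unknown:
        raise ValueError(f"ORFs mapped to MAGs absent from catalog: {sorted(unknown)[:5]}")

    # Sum TPM per MAG: samples x mags, then reindex to the full catalog so
    # MAGs without any ORF in the matrix get zero TPM.
    groups = pd.Series([orf_to_mag[c] for c in matrix.columns], index=matrix.columns)
    per_mag = matrix.T.groupby(groups).sum().T.reindex(columns=mag_ids, fill_value=0.0)

    totals = per_mag.sum(axis=1)
    zero = totals == 0
    tpm_share = per_mag.div(totals.where(~zero, 1.0), axis=0)
    tpm_share.loc[zero] = np.nan
    length_share = lengths[mag_ids] / total_length
    activity = tpm_share.div(length_share, axis=1).T  # MAGs x samples
    undefined = tuple(matrix.index[zero])
    if undefined:
        logger.warning("samples with zero total TPM, activity undefined: %s", undefined)
    return ActivityResult(matrix=activity, undefined_samples=undefined)


def scale_rows(
    matrix: pd.DataFrame, method: str = "zscore"
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Scale each row of a profile matrix for heatmap display.

    ``zscore`` (default) centers each row to mean 0 and scales to sample
    standard deviation 1 (ddof=1); ``minmax`` maps each row to [0, 1];
    ``none`` returns a copy.  Constant rows map to all zeros under either
    scaling and are returned in the flagged tuple.
    """
    if method == "none":
        return matrix.copy(), ()
    if method not in {"zscore", "minmax"}:
        raise ValueError(f"unknown scaling method {method!r}; use zscore|minmax|none")
    if method == "zscore" and matrix.shape[1] < 2:
        raise ValueError("z-score scaling needs >= 2 samples (sd undefined)")
    values = matrix.to_numpy(dtype=float)
    if method == "zscore":
        center = np.nanmean(values, axis=1, keepdims=True)
        spread = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    else:
        center = np.nanmin(values, axis=1, keepdims=True)
        spread = np.nanmax(values, axis=1, keepdims=True) - center
    constant = (spread == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (values - center) / np.where(spread == 0, 1.0, spread)
    scaled[constant] = 0.0
    flagged = tuple(matrix.index[constant])
    if flagged:
        logger.warning("constant rows scaled to all-zero: %s", flagged[:10])
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns), flagged


def _phase_columns(
    matrix: pd.DataFrame, samples: Sequence[SampleInfo]
) -> tuple[list[str], list[str]]:
    by_id = {s.sample_id: s for s in samples}
    missing = [c for c in matrix.columns if c not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    p1 = [c for c in matrix.columns if by_id[c].bloom_phase == 1]
    p2 = [c for c in matrix.columns if by_id[c].bloom_phase == 2]
    if len(p1) < 2 or len(p2) < 2:
        raise ValueError(
            f"phase comparison needs >= 2 samples per phase (got {len(p1)} and {len(p2)})"
        )
    return p1, p2


def compare_phases(
    matrix: pd.DataFrame,
    samples: Sequence[SampleInfo],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Phase-2 vs phase-1 shift per row: log2 ratio of means and permutation p.

    The test statistic is the difference of phase means; the one-sided p-value
    is the fraction of label permutations whose statistic is at least the
    observed one (alternative: phase-2 mean greater).  Whenever the number of
    distinct label splits C(n, n2) does not exceed ``n_permutations`` the
    splits are enumerated exhaustively, making the p-value exact; otherwise
    ``n_permutations`` random permutations are drawn with the given seed and
    the p-value uses the add-one estimator.

    Returns a DataFrame (rows sorted by descending log2 ratio) with columns
    ``mean_phase1, mean_phase2, log2_ratio, stat, p_value, rank``.
    """
    p1, p2 = _phase_columns(matrix, samples)
    cols = p1 + p2
    values = matrix[cols].to_numpy(dtype=float)
    n1, n2 = len(p1), len(p2)
    n = n1 + n2

    mean1 = np.nanmean(values[:, :n1], axis=1)
    mean2 = np.nanmean(values[:, n1:], axis=1)
    obs = mean2 - mean1
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(mean2 / mean1)

    n_splits = math.comb(n, n2)
    if n_splits <= n_permutations:
        # Exhaustive: every way of labelling n2 of the n samples as phase 2.
        count = np.zeros(len(obs))
        for idx in combinations(range(n), n2):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = np.nanmean(values[:, mask], axis=1) - np.nanmean(
                values[:, ~mask], axis=1
            )
            count += stat >= obs - 1e-12
        p = count / n_splits
        logger.info("phase comparison: exhaustive over %d label splits", n_splits)
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(obs))
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            stat = np.nanmean(values[:, perm[n1:]], axis=1) - np.nanmean(
                values[:, perm[:n1]], axis=1
            )
            count += stat >= obs - 1e-12
        p = (count + 1) / (n_permutations + 1)
        logger.info(
            "phase comparison: %d random permutations, seed %d", n_permutations, seed
        )

    out = pd.DataFrame(
        {
            "mean_phase1": mean1,
            "mean_phase2": mean2,
            "log2_ratio": log2_ratio,
            "stat": obs,
            "p_value": p,
        },
        index=matrix.index,
    )
    out = out.sort_values("log2_ratio", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
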