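"""Count normalizations: TPM and per-MAG marker-gene (MG) normalization.

Both operate on a samples x ORFs count matrix and are purely within-sample:

* TPM divides each ORF's count by its length in kb, then rescales each
  sample so the length-normalized rates sum to 10^6.
* MG normalization divides an ORF's length-normalized rate by the median
  rate of its MAG's 10 universal single-copy marker genes in the same
  sample, giving a relative per-MAG transcript number ("transcripts of
  this gene per genome").  The ratio is computed on raw rates; any common
  per-sample factor (such as the TPM 10^6 rescale) cancels, so the result
  is identical whether rates or TPM feed the ratio.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    MarkerGeneSet,
    MgResult,
    OrfRecord,
    TpmResult,
)

logger = logging.getLogger(__name__)

__all__ = ["tpm_normalize", "mg_normalize", "length_normalized_rates"]


def _orf_lengths_kb(counts: pd.DataFrame, orfs: Sequence[OrfRecord]) -> pd.Series:
    by_id = {o.orf_id: o.length_kb for o in orfs}
    missing = [c for c in counts.columns if c not in by_id]
    if missing:
        raise ValueError(f"no ORF record for count columns: {missing[:5]}")
    lengths = pd.Series([by_id[c] for c in counts.columns], index=counts.columns)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"ORF {bad!r} has non-positive length")
    return lengths


def length_normalized_rates(
    counts: pd.DataFrame, orfs: Sequence[OrfRecord]
) -> pd.DataFrame:
    """Per-sample reads per kb: counts divided by ORF length in kb."""
    lengths = _orf_lengths_kb(counts, orfs)
    return counts.astype(float).div(lengths, axis=1)


def tpm_normalize(counts: pd.DataFrame, orfs: Sequence[OrfRecord]) -> TpmResult:
    """Transcripts-per-million normalization of a samples x ORFs count matrix.

    For sample *s*: ``TPM_i = (c_is / L_i) / sum_j (c_js / L_j) * 1e6`` with
    ``L_i`` the ORF length in kb.  Samples whose counts are all zero yield an
    all-zero TPM row and are listed in ``TpmResult.zero_samples``.
    """
    rates = length_normalized_rates(counts, orfs)
    totals = rates.sum(axis=1)
    zero = totals == 0
    safe_totals = totals.where(~zero, 1.0)
    tpm = rates.div(safe_totals, axis=0) * 1.0e6
    tpm.loc[zero] = 0.0
    zero_samples = tuple(tpm.index[zero])
    if zero_samples:
        logger.warning(
            "samples with zero total counts, TPM row set to 0: %s", zero_samples
        )
    return TpmResult(matrix=tpm, zero_samples=zero_samples)


def mg_normalize(
    counts: pd.DataFrame,
    orfs: Sequence[OrfRecord],
    markers: MarkerGeneSet,
) -> MgResult:
    """Marker-gene normalization: rate of each ORF over its MAG's marker median.

    ``value_is = (c_is / L_i) / median_m (c_ms / L_m)`` where *m* runs over
    the marker-gene ORFs of the ORF's MAG.  Where the marker median is 0 the
    value is undefined: stored as NaN and flagged in ``MgResult.undefined``.

    Raises ``ValueError`` for any MAG whose ORFs appear in the matrix but
    which has no assigned marker ORFs present.  A MAG with fewer than the
    full 10 markers detected is normalized by the median of the available
    ones, with a warning (incomplete genomes are the norm in MAG catalogs).
    """
    rates = length_normalized_rates(counts, orfs)
    orf_to_mag = {o.orf_id: o.mag_id for o in orfs}
    mags_present = sorted({orf_to_mag[c] for c in counts.columns})

    medians = pd.DataFrame(index=counts.index, columns=mags_present, dtype=float)
    n_markers = len(markers.cog_ids)
    for mag_id in mags_present:
        marker_orfs = [
            o for o in markers.marker_orfs(mag_id) if o in rates.columns
        ]
        if not marker_orfs:
            raise ValueError(
                f"MAG {mag_id} has no marker-gene ORFs in the count matrix; "
                "MG normalization is undefined for it"
            )
        if len(marker_orfs) < n_markers:
            logger.warning(
                "MAG %s: only %d of %d marker genes present; using their median",
                mag_id,
                len(marker_orfs),
                n_markers,
            )
        medians[mag_id] = rates[marker_orfs].median(axis=1)

    mag_of_col = pd.Series([orf_to_mag[c] for c in counts.columns],
                           index=counts.columns)
    denom = medians[mag_of_col.to_numpy()].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        values = rates.to_numpy() / denom
    undefined = denom == 0
    values[undefined] = np.nan
    matrix = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    mask = pd.DataFrame(undefined, index=counts.index, columns=counts.columns)
    if undefined.any():
        logger.warning(
            "MG normalization undefined (zero marker median) for %d cells",
            int(undefined.sum()),
        )
    return MgResult(matrix=matrix, undefined=mask)
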