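"""Alcian-Blue TEP quantification with Xanthan-Gum calibration.

Transparent exopolymeric particles retained on a 0.4 um filter are stained
with Alcian Blue; the extracted dye's absorbance at 787 nm is converted to
Xanthan-Gum (XG) mass equivalents through a calibration line fitted to XG
standards, and then to a concentration:

    TEP = (A_sample - A_filter_blank) / (m787 * V)

with m787 the calibration slope (absorbance per ug XG) and V the filtered
volume.  Dividing by the cell density gives TEP per cell.  Group contrasts
(nutrient regimes, organisms) use a one-tailed two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CalibrationCurve, TepMeasurement, TepResult

logger = logging.getLogger(__name__)

__all__ = [
    "calibrate_xg",
    "tep_concentration",
    "one_tailed_ttest",
    "TTestResult",
    "group_summary",
]


def calibrate_xg(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares calibration line from (mass ug, absorbance) pairs.

    Raises ``ValueError`` for fewer than 2 distinct masses or a non-positive
    fitted slope (an invalid assay).
    """
    masses = np.asarray([m for m, _ in standards], dtype=float)
    absorbances = np.asarray([a for _, a in standards], dtype=float)
    if len(np.unique(masses)) < 2:
        raise ValueError("calibration requires >= 2 distinct standard masses")
    fit = stats.linregress(masses, absorbances)
    if fit.slope <= 0:
        raise ValueError(
            f"invalid assay: fitted calibration slope {fit.slope:.4g} is not positive"
        )
    curve = CalibrationCurve(
        m787=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_standards=len(np.unique(masses)),
    )
    logger.info(
        "XG calibration: m787=%.6g abs/ug, intercept=%.6g, r^2=%.6f",
        curve.m787, curve.intercept, curve.r_squared,
    )
    return curve


def tep_concentration(m: TepMeasurement, curve: CalibrationCurve) -> TepResult:
    """TEP concentration of one measurement via the calibration slope.

    ``tep = (a_sample - a_filter_blank) / (m787 * volume)`` in ug XG
    equivalents per volume unit of V.  A sample darker in blank than in
    signal (negative numerator) is reported as 0 and flagged.  The per-cell
    value is ``tep / cell_density`` when a density is given.
    """
    raw = (m.a_sample - m.a_filter_blank) / (curve.m787 * m.volume_ml)
    clamped = raw < 0
    tep = 0.0 if clamped else raw
    if clamped:
        logger.warning(
            "measurement %s: absorbance below filter blank, TEP clamped to 0",
            m.sample_id,
        )
    per_cell = tep / m.cell_density if m.cell_density is not None else None
    return TepResult(
        sample_id=m.sample_id, tep=tep, tep_per_cell=per_cell, clamped=clamped
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False  # both groups constant and equal


def one_tailed_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    direction: str = "greater",
    variant: str = "pooled",
) -> TTestResult:
    """One-sided two-sample t-test that group_a's mean exceeds (or is below)
    group_b's.

    ``variant='pooled'`` (default) assumes equal variances; ``'welch'``
    does not.  When both groups are constant with equal values the test is
    degenerate and ``(t=0, p=0.5)`` is returned flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if direction not in {"greater", "less"}:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    if variant not in {"pooled", "welch"}:
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        logger.warning("degenerate t-test: both groups constant and equal")
        return TTestResult(t=0.0, p=0.5, degenerate=True)
    res = stats.ttest_ind(
        a, b, equal_var=(variant == "pooled"), alternative=direction
    )
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))


def group_summary(
    measurements: Iterable[TepMeasurement],
    curve: CalibrationCurve,
    variant: str = "pooled",
) -> dict:
    """Per-sample TEP, group means, and the high-vs-low-nutrient contrast.

    For each organism the one-sided test asks whether TEP per cell under the
    full-strength regime exceeds that under the quarter-strength regime.
    Returns ``{"per_sample": DataFrame, "groups": DataFrame, "tests": DataFrame}``.
    """
    rows = []
    for m in measurements:
        r = tep_concentration(m, curve)
        rows.append(
            {
                "sample_id": m.sample_id,
                "organism": m.organism,
                "regime": m.regime,
                "tep": r.tep,
                "tep_per_cell": r.tep_per_cell,
                "clamped": r.clamped,
            }
        )
    per_sample = pd.DataFrame(rows)
    if per_sample.empty:
        raise ValueError("no TEP measurements supplied")
    groups = (
        per_sample.groupby(["organism", "regime"])
        .agg(
            n=("tep", "size"),
            mean_tep=("tep", "mean"),
            mean_tep_per_cell=("tep_per_cell", "mean"),
        )
        .reset_index()
    )
    tests = []
    for organism, sub in per_sample.groupby("organism"):
        high = sub.loc[sub["regime"] == "1x_pn", "tep_per_cell"].dropna()
        low = sub.loc[sub["regime"] == "quarter_pn", "tep_per_cell"].dropna()
        if len(high) < 2 or len(low) < 2:
            logger.warning("organism %s: not enough replicates for the t-test", organism)
            continue
        res = one_tailed_ttest(high, low, direction="greater", variant=variant)
        tests.append(
            {
                "organism": organism,
                "t": res.t,
                "p_one_sided": res.p,
                "degenerate": res.degenerate,
            }
        )
    return {
        "per_sample": per_sample,
        "groups": groups,
        "tests": pd.DataFrame(tests),
    }
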