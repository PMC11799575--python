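"""Study-scale constants: nutrient regimes, assay standards, MAG bookkeeping.

These are the published inputs of the analysis — medium composition, the
Xanthan-Gum standard series, and the size of the MAG catalog — kept in one
place so the simulator and the assay code draw from the same numbers.
"""

from __future__ import annotations

__all__ = [
    "L1_PHOSPHATE_UM",
    "L1_NITRATE_UM",
    "QUARTER_PN_FACTOR",
    "quarter_pn_phosphate_uM",
    "quarter_pn_nitrate_uM",
    "XG_STOCK_UG_PER_ML",
    "XG_STANDARD_VOLUMES_ML",
    "xg_standard_masses_ug",
    "TOTAL_MAGS",
    "ARCHAEAL_MAGS",
    "bacterial_mag_count",
    "N_TIMEPOINTS",
    "FILTERED_VOLUME_ML",
]

# L1-Si medium phosphate and nitrate, the 1xPN regime.
L1_PHOSPHATE_UM = 36.0
L1_NITRATE_UM = 882.0

# The reduced regime supplies one quarter of the L1 concentrations.
QUARTER_PN_FACTOR = 0.25


def quarter_pn_phosphate_uM() -> float:
    """Phosphate concentration of the quarter-strength (1/4 x PN) regime."""
    return L1_PHOSPHATE_UM * QUARTER_PN_FACTOR


def quarter_pn_nitrate_uM() -> float:
    """Nitrate concentration of the quarter-strength (1/4 x PN) regime."""
    return L1_NITRATE_UM * QUARTER_PN_FACTOR


# Xanthan-Gum calibration: 75 mg XG dissolved in 1 L gives 75 ug/mL stock;
# serial dilutions take these volumes of stock to a 1 mL final volume.
XG_STOCK_UG_PER_ML = 75.0
XG_STANDARD_VOLUMES_ML = (0.125, 0.250, 0.500, 0.750, 1.0)


def xg_standard_masses_ug() -> tuple[float, ...]:
    """XG mass (ug) in each calibration standard: stock concentration x volume."""
    return tuple(XG_STOCK_UG_PER_ML * v for v in XG_STANDARD_VOLUMES_ML)


# The MAG catalog the transcriptomes were mapped to: 251 representative
# MAGs of which 7 are archaeal, the rest bacterial.
TOTAL_MAGS = 251
ARCHAEAL_MAGS = 7


def bacterial_mag_count() -> int:
    """Number of bacterial MAGs in the catalog."""
    return TOTAL_MAGS - ARCHAEAL_MAGS


# The bloom time series spans 30 sampled timepoints.
N_TIMEPOINTS = 30

# Volume of culture filtered per organism in the TEP assay (mL).
FILTERED_VOLUME_ML = {"bacteria": 6.0, "algae": 2.0}
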