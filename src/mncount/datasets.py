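"""Bundled reference dataset: manual micronucleus scoring of CHL/IU cells.

A published in vitro micronucleus experiment on Chinese hamster lung
fibroblasts (CHL/IU) exposed for 24 h to four genotoxicants — hydrogen
peroxide, potassium chromate, mitomycin C and methyl methanesulfonate —
plus an untreated control.  For each dose group the table carries the
number of photographed fields, the manually counted total and
micronucleated cells, and the MN% and relative-viability percentages as
printed in the original report, so the package's arithmetic can be
exercised against fully worked reference rows.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["chl_iu_manual_counts"]

# chemical, dose (ug/mL), n_images, total_cells, mn_cells,
# published MN%, published relative viability %
_ROWS = [
    ("control", "0", 45, 1555, 11, 0.71, 100),
    ("H2O2", "3.75", 55, 1340, 35, 2.61, 71),
    ("H2O2", "7.5", 57, 1292, 68, 5.26, 66),
    ("H2O2", "15", 43, 1250, 95, 7.60, 84),
    ("H2O2", "30", 79, 2040, 189, 9.26, 75),
    ("K2CrO4", "1.2", 50, 1353, 36, 2.66, 78),
    ("K2CrO4", "2.4", 60, 1436, 91, 6.34, 69),
    ("K2CrO4", "4.9", 66, 1270, 139, 10.94, 56),
    ("MMC", "0.0125", 49, 1919, 62, 3.23, 113),
    ("MMC", "0.025", 36, 1661, 69, 4.15, 134),
    ("MMC", "0.05", 30, 1465, 199, 13.58, 141),
    ("MMC", "0.1", 80, 1203, 472, 39.24, 44),
    ("MMC", "0.2", 65, 1684, 326, 19.36, 75),
    ("MMS", "10", 49, 1658, 76, 4.58, 98),
    ("MMS", "20", 50, 1147, 106, 9.24, 66),
    ("MMS", "40", 73, 1347, 250, 18.56, 53),
    ("MMS", "80", 187, 1155, 50, 4.33, 18),
]


def chl_iu_manual_counts() -> pd.DataFrame:
    """Manual dose-group counts from the CHL/IU genotoxicant experiment."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "chemical",
            "dose_ug_ml",
            "n_images",
            "total_cells",
            "mn_cells",
            "mn_percent_published",
            "viability_percent_published",
        ],
    )
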