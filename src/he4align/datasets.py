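"""Bundled example data.

The package ships the ten-sample HE4 calibration dilution series measured by
six Italian clinical laboratories on five automated immunoassay platforms
(Lumipulse G1200II/G600II CLEIA, Cobas E601 ECLIA, Architect and Alinity I
CMIA).  A single shared dilution series, spanning roughly 30 to 1075 pmol/L,
was assayed by every laboratory; Lab1 (Lumipulse G1200II) is the reference.
Systematic disagreement between the columns is exactly what the ordinary
least product calibration in :mod:`he4align.olp` quantifies and corrects.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["multicenter_calibration", "REFERENCE_LAB", "PLATFORM_CVS"]

REFERENCE_LAB = "lab1"

#: Manufacturer-declared total coefficients of variation per platform,
#: mapped to the six laboratories (Lumipulse 3.2%, Cobas 10%, Architect 10%,
#: Alinity 4.9%).
PLATFORM_CVS = {
    "lab1": 0.032,
    "lab2": 0.10,
    "lab3": 0.10,
    "lab4": 0.049,
    "lab5": 0.032,
    "lab6": 0.032,
}

_CALIBRATION_ROWS = [
    ("A", 1074.4, 981.4, 927.1, 1008.6, 1049.0, 1027.7),
    ("B", 574.9, 497.3, 492.5, 513.2, 501.5, 532.1),
    ("C", 384.1, 326.4, 282.4, 347.8, 314.4, 349.7),
    ("D", 322.4, 266.4, 244.5, 293.8, 248.5, 239.7),
    ("E", 219.6, 183.3, 163.4, 209.6, 174.4, 202.3),
    ("F", 186.5, 155.9, 148.3, 175.7, 143.0, 169.4),
    ("G", 121.9, 105.2, 88.8, 115.0, 95.6, 112.7),
    ("H", 88.9, 74.55, 64.2, 82.7, 68.7, 82.9),
    ("I", 68.0, 56.55, 51.7, 65.4, 53.2, 60.5),
    ("J", 30.3, 25.8, 26.4, 26.4, 28.1, 26.8),
]


def multicenter_calibration() -> pd.DataFrame:
    """Return the six-laboratory HE4 calibration table (wide format).

    Columns: ``sample_id`` plus ``lab1`` … ``lab6``; values in pmol/L.
    ``lab1`` is the reference laboratory that prepared the dilution series.
    """
    return pd.DataFrame(
        _CALIBRATION_ROWS,
        columns=["sample_id", "lab1", "lab2", "lab3", "lab4", "lab5", "lab6"],
    )
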