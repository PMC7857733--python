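"""Bundled example data.

A small published-style loading table from a preclinical spinal cord
injury study: 18 motor-function outcomes measured in rats six weeks
after cervical injury, with the standardized loadings of the first three
principal components.  It doubles as the canonical template of the
loading-table layout every reader/visualizer in the package expects
(first column ``Variables``, then ``PC1``..``PCk``).
"""

from __future__ import annotations

import numpy as np

from .pca import LoadingsTable

__all__ = ["sci_motor_loadings", "sci_motor_vaf"]

_SCI_MOTOR = [
    ("wtChng", -0.34, -0.37, 0.46),
    ("TotalSubscore", -0.56, -0.48, 0.22),
    ("StepDistRH", 0.89, -0.07, 0.23),
    ("StepDistRF", -0.65, 0.28, -0.19),
    ("StepDistLH", -0.28, -0.66, 0.23),
    ("StepDistLF", 0.54, 0.27, 0.50),
    ("RHSL", -0.76, 0.34, 0.12),
    ("RHPA", -0.85, -0.30, 0.26),
    ("RFSL", 0.74, 0.40, 0.32),
    ("RFPA", -0.25, 0.21, 0.41),
    ("PawPL", -0.76, -0.30, 0.35),
    ("LHSL", 0.62, 0.42, 0.48),
    ("LHPA", -0.24, 0.12, 0.62),
    ("LFSL", 0.38, -0.62, -0.05),
    ("LFPA", -0.54, 0.63, -0.12),
    ("Groom", 0.49, -0.65, 0.03),
    ("ForelimbOpenField", 0.20, -0.59, -0.14),
    ("BBB_FergTrans", 0.51, -0.32, -0.03),
]


def sci_motor_loadings() -> LoadingsTable:
    """Standardized loadings (PC1-PC3) of 18 motor outcomes after cervical SCI."""
    return LoadingsTable(
        [row[0] for row in _SCI_MOTOR],
        ["PC1", "PC2", "PC3"],
        np.array([row[1:] for row in _SCI_MOTOR], dtype=float),
    )


def sci_motor_vaf() -> list[float]:
    """Percent variance accounted for by PC1-PC3 of the example solution."""
    return [32.9, 18.3, 9.8]
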