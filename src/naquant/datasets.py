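"""Bundled example data.

Twelve offshore produced-water samples analysed at a 20x dilution:
instrument-level model predictions (pred1, mg/L in the diluted extract) and
the LC-MS reference concentration of the undiluted sample (mg/L).
"""

from __future__ import annotations

import pandas as pd

_PRODUCED_WATER = [
    # sample, pred1 (mg/L, diluted), lcms reference (mg/L, undiluted)
    ("S01", 4.89, 84.48),
    ("S02", 12.09, 209.52),
    ("S03", 3.12, 61.50),
    ("S04", 16.02, 308.61),
    ("S05", 8.19, 158.73),
    ("S06", 1.56, 28.28),
    ("S07", 2.03, 35.75),
    ("S08", 1.98, 35.28),
    ("S09", 1.87, 35.80),
    ("S10", 9.47, 165.60),
    ("S11", 2.09, 35.64),
    ("S12", 3.49, 62.28),
]

PRODUCED_WATER_DILUTION_FACTOR = 20.0


def load_produced_water_reference() -> pd.DataFrame:
    """Instrument-level predictions and LC-MS references for 12 samples."""
    return pd.DataFrame(_PRODUCED_WATER, columns=["sample_id", "pred1", "lcms"])
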