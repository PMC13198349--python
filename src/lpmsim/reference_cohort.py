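"""Published demographics of the dilated-RV heart-failure calibration cohort.

Ten male patients with heart failure whose RV papillary muscles could be
segmented; the synthetic-anatomy defaults (EDV 283 mL, EF 22%) are the
summary of this table. Volumes in mL, age in years, RVEF in %.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # patient, age, nyha, rv_esv_ml, rv_edv_ml, rvef_pct
    (1, 83, 2, 228, 303, 25),
    (2, 67, 3, 272, 344, 21),
    (3, 50, 3, 237, 324, 27),
    (4, 85, 3, 216, 235, 8),
    (5, 38, 2, 231, 311, 26),
    (6, 79, 2, 186, 217, 14),
    (7, 41, 3, 220, 285, 23),
    (8, 76, 2, 219, 283, 23),
    (9, 76, 3, 184, 276, 33),
    (10, 72, 3, 200, 252, 21),
]


def reference_cohort() -> pd.DataFrame:
    """Per-patient table: age, NYHA class, RV ESV/EDV (mL), RVEF (%)."""
    return pd.DataFrame(
        _ROWS, columns=["patient", "age", "nyha", "rv_esv_ml", "rv_edv_ml", "rvef_pct"]
    )
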