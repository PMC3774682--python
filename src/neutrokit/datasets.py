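"""Small built-in datasets for worked examples and validation.

The one dataset here is the per-spot statistics table from a published
2D-DIGE comparison of control versus leptin-stimulated human neutrophils
(paired design, DeCyder-convention signed ratios). It is used to exercise
the differential filter on real reported numbers: applying
|ratio| >= 1.3 AND p < 0.01 to the rows that carry both statistics marks
10 of 16 spots differential.

Presence fractions were not reported per spot; every listed spot passed the
original presence filter, so presence is set to 1.0 here by assumption.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["leptin_dige_spot_stats"]

# spot number, protein annotation, paired-t p, signed fold change
_ROWS = [
    (1, "Myosin-9 isoform 1", 5.21e-04, -2.23),
    (2, "Myosin-9 isoform 1", 1.83e-03, -1.48),
    (3, "Not identified", 4.52e-01, -1.14),
    (4, "Transketolase isoform 2", 8.70e-03, 1.34),
    (5, "cDNA FLJ52902 (Rab GDI alpha-like)", 2.01e-01, -1.15),
    (6, "Not identified", 3.58e-03, -1.39),
    (7, "Protein disulfide-isomerase", 6.22e-03, -1.43),
    (8, "Protein disulfide-isomerase A3", 4.08e-03, -1.33),
    (9, "Thioredoxin domain-containing protein 4", 6.56e-03, -1.73),
    (10, "Not identified", 4.33e-03, -1.75),
    (11, "Actin cytoplasmic 2", 1.06e-02, -2.38),
    (12, "Serpin B1", 2.36e-02, 3.16),
    (13, "Serpin B1", 6.13e-04, -1.49),
    (14, "Gelsolin-like capping protein", np.nan, -1.17),  # no t-test reported
    (15, "Sorbitol dehydrogenase", 2.62e-03, 2.02),
    (16, "p40 phox", 1.59e-02, 3.28),
    (17, "Not identified", 2.01e-02, -3.13),
]


def leptin_dige_spot_stats() -> pd.DataFrame:
    """Published per-spot DIGE statistics (leptin-stimulated neutrophils).

    Columns: ``spot_id, protein, raw_p, signed_ratio, presence``. Spot 14
    has no reported t-test p-value (NaN).
    """
    df = pd.DataFrame(_ROWS, columns=["spot_id", "protein", "raw_p", "signed_ratio"])
    df["presence"] = 1.0
    return df
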