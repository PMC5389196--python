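"""WHO toxic-equivalency-factor (TEF) comparison table.

The seven chlorinated congeners with official WHO TEF values serve as the
cross-tab between predicted adsorption energies and regulatory toxicity
weights: TEF = 1 for 2,3,7,8-TCDD down to 0.0003 for the octachlorinated
congener.  The ``calculated`` column carries the reference (DFT-level)
adsorption energy where one exists for the calibration subset; for the
packaged fixture that is only TCDD (0.958 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

#: (name, WHO TEF, calculated E_ads in kcal/mol or None) for the seven
#: congeners carrying official WHO TEF values.
WHO_TEF_FIXTURE: tuple[tuple[str, float, float | None], ...] = (
    ("2,3,7,8-tetrachlorodibenzo-p-dioxin", 1.0, 0.958),
    ("1,2,3,7,8-pentachlorodibenzo-p-dioxin", 1.0, None),
    ("1,2,3,4,7,8-hexachlorodibenzo-p-dioxin", 0.1, None),
    ("1,2,3,6,7,8-hexachlorodibenzo-p-dioxin", 0.1, None),
    ("1,2,3,7,8,9-hexachlorodibenzo-p-dioxin", 0.1, None),
    ("1,2,3,4,6,7,8-heptachlorodibenzo-p-dioxin", 0.01, None),
    ("1,2,3,4,6,7,8,9-octachlorodibenzo-p-dioxin", 0.0003, None),
)


@dataclass(frozen=True)
class TEFRecord:
    """One congener's WHO TEF next to its (calculated and) predicted E_ads."""

    name: str
    who_tef: float
    calculated_E_ads: float | None
    predicted_E_ads: float


def tef_comparison(predictions: pd.DataFrame) -> tuple[list[TEFRecord], float]:
    """Join model predictions against the WHO TEF fixture, by congener name.

    *predictions* must have ``name`` and ``predicted_E_ads_kcal_mol``
    columns covering the seven fixture congeners.  Returns the records and
    the Spearman rank correlation between TEF and predicted E_ads.
    """
    lookup = dict(
        zip(predictions["name"], predictions["predicted_E_ads_kcal_mol"])
    )
    missing = [name for name, _, _ in WHO_TEF_FIXTURE if name not in lookup]
    if missing:
        raise KeyError(f"predictions lack TEF fixture congener(s): {missing}")
    records = [
        TEFRecord(name, tef, calc, float(lookup[name]))
        for name, tef, calc in WHO_TEF_FIXTURE
    ]
    rho = stats.spearmanr(
        [r.who_tef for r in records], [r.predicted_E_ads for r in records]
    ).statistic
    return records, float(rho)


def tef_records_frame(records: list[TEFRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in records],
            "who_tef": [r.who_tef for r in records],
            "calculated_E_ads_kcal_mol": [r.calculated_E_ads for r in records],
            "predicted_E_ads_kcal_mol": [r.predicted_E_ads for r in records],
        }
    )
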