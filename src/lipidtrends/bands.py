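"""Shared vocabulary: metrics, age bands, plausibility windows, units.

Analysis age bands are 18-19 years, 20-29 years, then 10-year bands up to
70-79, and 80+. All lipid concentrations are in mmol/l throughout the
package; conversion to mg/dl happens only on rendering.
"""

from __future__ import annotations

import numpy as np

#: Conversion factor for cholesterol: 1 mmol/l = 38.61 mg/dl.
MMOL_TO_MGDL = 38.61

METRICS = ("total", "hdl", "non_hdl")
SEXES = ("female", "male")

#: Closed integer age ranges; the last band is open-ended (80+).
AGE_BANDS: tuple[tuple[int, int | None], ...] = (
    (18, 19),
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
    (80, None),
)

AGE_BAND_LABELS = tuple(
    f"{lo}-{hi}" if hi is not None else f"{lo}+" for lo, hi in AGE_BANDS
)

#: Representative age per band, used for spline evaluation and conversion
#: regressions. The open-ended 80+ band is represented by age 85.
AGE_BAND_MIDPOINTS = np.array([18.5, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0])

#: Plausibility windows (exclusive bounds, mmol/l). Values strictly outside
#: are implausible; values exactly at a bound are retained.
PLAUSIBLE_RANGE = {
    "total": (1.75, 20.0),
    "hdl": (0.4, 5.0),
}


def band_index_for_age(age: np.ndarray | int) -> np.ndarray:
    """Map integer ages (>= 18) to age-band indices; -1 for under-18."""
    edges = np.array([18, 20, 30, 40, 50, 60, 70, 80])
    age = np.asarray(age)
    idx = np.searchsorted(edges, age, side="right") - 1
    return np.where(age < 18, -1, idx)


def band_label_for_age(age: int) -> str:
    idx = int(band_index_for_age(age))
    if idx < 0:
        raise ValueError(f"age {age} is below the adult range")
    return AGE_BAND_LABELS[idx]
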