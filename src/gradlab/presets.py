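"""Published per-condition summaries used as generator calibration targets.

Condition labels:

* ``C``  — control (media only, no gradient)
* ``E``  — EGF gradient field
* ``V``  — VEGF gradient field
* ``VE`` — cells pre-treated with VEGF, then exposed to an EGF field
* ``EV`` — cells pre-treated with EGF, then exposed to a VEGF field

The values are the printed mean ± SD path lengths (µm, microfluidic device,
motile cells), motile-cell percentages, per-device transwell motile counts,
and the receptor-expression fold-change matrix relative to control.  They
are calibration *targets* for the synthetic generator, not recomputable
measurements.
"""

from __future__ import annotations

import pandas as pd

CONDITIONS = ("C", "E", "V", "VE", "EV")

#: microfluidic-device path length, mean ± SD in µm per condition
GLL_PATH_LENGTH_UM: dict[str, tuple[float, float]] = {
    "C": (14.2, 5.7),
    "E": (39.7, 8.96),
    "V": (74.7, 17.7),
    "VE": (56.3, 6.64),
    "EV": (28.96, 5.6),
}

#: percentage of motile cells in the microfluidic device (EV not reported)
GLL_MOTILE_FRACTION_PCT: dict[str, float] = {
    "C": 46.67,
    "E": 93.33,
    "V": 100.0,
    "VE": 93.33,
}

#: transwell per-device motile-cell counts, mean ± SD
TA_COUNTS: dict[str, tuple[float, float]] = {
    "C": (12.1, 4.23),
    "E": (36.0, 12.8),
    "V": (87.2, 25.8),
    "VE": (77.1, 44.4),
    "EV": (39.7, 17.7),
}

#: receptor fold-change matrix relative to control (stimulus rows)
RECEPTOR_FOLD_CHANGES = pd.DataFrame(
    {
        "EGF-R": [2.2, 2.7, 9.3, 18.9],
        "FGFR-2": [2.5, 1.3, 2.0, 5.2],
        "FGFR-8": [0.7, 0.9, 1.3, 6.0],
        "VEGF-R": [0.2, 0.7, 0.4, 2.8],
    },
    index=pd.Index(["EGF", "FGF2", "FGF8", "VEGF"], name="stimulus"),
)

#: imaging cadence of the trajectory recordings
N_STEPS = 12
FRAME_INTERVAL_MIN = 30.0

#: cohort sizes: 10-15 cells per device, 5-7 devices per condition
CELLS_PER_DEVICE = 15
DEVICES_PER_CONDITION = 6
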