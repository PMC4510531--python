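"""Physical constants and package-wide defaults."""

from __future__ import annotations

import datetime
import math

#: I-131 physical half-life in days (NNDC Nuclear Wallet Cards).
I131_HALF_LIFE_DAYS: float = 8.0252

#: I-131 physical decay constant, 1/day.
I131_DECAY_CONSTANT: float = math.log(2.0) / I131_HALF_LIFE_DAYS

#: Calendar date anchoring t = 0 of internal day-number time (accident day).
DEFAULT_ORIGIN: datetime.date = datetime.date(2011, 3, 11)

#: Reference daily secreted breast-milk mass, kg/day (800 ml).
DAILY_MILK_MASS_KG: float = 0.8

#: Default fixed integration step, days.
DEFAULT_STEP_DAYS: float = 0.001

#: Default trajectory output grid spacing, days.
DEFAULT_OUTPUT_SPACING_DAYS: float = 0.01

#: Indoor inhalation reduction factor.
DEFAULT_INDOOR_REDUCTION_FACTOR: float = 0.75
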