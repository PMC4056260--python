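"""Comparator arm: intravenous sliding-scale insulin driven by hourly glucose.

The scale maps blood-glucose bands (printed at 0.1-mM resolution) to fixed
infusion rates; several bands additionally require the nurse to inform a
physician. Values are rounded half-up to one decimal before lookup so the
printed bands tile (0, inf) without gaps. An optional deterministic
"physician escalation" shifts the whole scale one row after two consecutive
hourly values above 12 mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["ScaleRow", "DEFAULT_SCALE", "LookupResult", "lookup_rate",
           "NurseProtocol"]


@dataclass(frozen=True)
class ScaleRow:
    lower: float  # mM, inclusive after rounding (-inf for the bottom row)
    upper: float  # mM, inclusive after rounding (inf for the top row)
    rate: float  # U/h
    notify: bool = False
    notify_above: float | None = None  # notify only when glucose exceeds this


#: The local intravenous insulin titration protocol, bottom row first.
DEFAULT_SCALE: tuple[ScaleRow, ...] = (
    ScaleRow(-math.inf, 3.9, 0.0, notify=True),
    ScaleRow(4.0, 5.5, 0.5),
    ScaleRow(5.6, 7.0, 1.0),
    ScaleRow(7.1, 8.5, 1.5),
    ScaleRow(8.6, 11.0, 2.0, notify=True, notify_above=10.0),
    ScaleRow(11.1, 14.0, 2.5, notify=True),
    ScaleRow(14.1, 17.0, 3.0, notify=True),
    ScaleRow(17.1, 20.0, 4.0, notify=True),
    ScaleRow(20.1, math.inf, 6.0, notify=True),
)


@dataclass(frozen=True)
class LookupResult:
    rate: float  # U/h
    notify: bool
    row_index: int


def _round_half_up_1dp(x: float) -> float:
    return math.floor(x * 10.0 + 0.5) / 10.0


def lookup_rate(BG: float, scale_shift: int = 0,
                scale: tuple[ScaleRow, ...] = DEFAULT_SCALE) -> LookupResult:
    """Insulin rate for a blood glucose value, with optional scale shift.

    ``scale_shift`` moves the dose one row per level (+1 = more aggressive:
    the rate of the next-higher band is used), clamped to [-2, +2].
    """
    if BG <= 0:
        raise ValueError("BG must be positive")
    if not -2 <= scale_shift <= 2:
        raise ValueError("scale_shift outside [-2, +2]")
    r = _round_half_up_1dp(BG)
    idx = None
    for i, row in enumerate(scale):
        if row.lower - 1e-9 <= r <= row.upper + 1e-9 or \
                (row.lower == -math.inf and r <= row.upper + 1e-9):
            idx = i
            break
    if idx is None:
        raise ValueError(f"no band covers glucose {BG}")
    base = scale[idx]
    eff = scale[min(max(idx + scale_shift, 0), len(scale) - 1)]
    notify = base.notify and (base.notify_above is None or r > base.notify_above)
    return LookupResult(rate=eff.rate, notify=notify, row_index=idx)


@dataclass
class NurseProtocol:
    """Hourly nurse cycle: look up the rate, hold it until the next sample.

    With ``escalation`` enabled, two consecutive hourly values above 12 mM
    shift the scale one level up (at most +2), modelling a
    physician-prescribed scale alteration; off by default.
    """

    escalation: bool = False
    escalation_threshold: float = 12.0
    scale_shift: int = 0
    current_rate: float = 0.0
    _streak: int = field(default=0, repr=False)
    notify_log: list = field(default_factory=list)

    def hourly(self, t: float, BG: float) -> float:
        if self.escalation:
            if BG > self.escalation_threshold:
                self._streak += 1
                if self._streak >= 2 and self.scale_shift < 2:
                    self.scale_shift += 1
                    self._streak = 0
            else:
                self._streak = 0
        res = lookup_rate(BG, self.scale_shift)
        if res.notify:
            self.notify_log.append((t, BG))
        self.current_rate = res.rate
        return self.current_rate
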