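"""Deterministic missing-data masking: phenotypes and condition grids.

Two missing-data phenotypes are simulated. ZERO replaces epochs with genuine
zeros (a sensor off the wrist but still recording); ABSENT replaces them with
NaN (a sensor that stopped recording). Grids of masking conditions sweep a
single gap over start time and duration, or a pair of short gaps over start
time and the separation between them; grid cells whose bouts would run past
the end of the record are omitted (they later surface as empty heatmap cells).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .timeseries import EpochSeries

__all__ = [
    "ZERO",
    "ABSENT_PHENOTYPE",
    "MaskSpec",
    "apply_mask",
    "single_gap_grid",
    "double_gap_grid",
    "DEFAULT_DURATIONS_H",
    "DEFAULT_START_HOURS",
    "DEFAULT_SEPARATIONS_H",
]

ZERO = "zero"
ABSENT_PHENOTYPE = "absent"
_PHENOTYPES = (ZERO, ABSENT_PHENOTYPE)

# Single gaps: 1-23 h in 2-h steps; start times every 2 h across the day.
DEFAULT_DURATIONS_H = tuple(range(1, 24, 2))
DEFAULT_START_HOURS = tuple(range(0, 24, 2))
# Double gaps: 115- and 140-min bouts separated by 3-47 h in 2-h steps.
DEFAULT_GAP1_MIN = 115
DEFAULT_GAP2_MIN = 140
DEFAULT_SEPARATIONS_H = tuple(range(3, 48, 2))


@dataclass(frozen=True)
class MaskSpec:
    """One masking condition: a phenotype plus an ordered list of bouts.

    Bouts are (start_offset_minutes, duration_minutes) pairs measured from the
    start of the record; they must be non-overlapping, increasing, and multiples
    of the epoch length. ``label`` carries the grid coordinates (start_day,
    start_hour, and duration_h or separation_h) for heatmap assembly.
    """

    phenotype: str
    bouts: tuple
    label: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.phenotype not in _PHENOTYPES:
            raise ValueError(f"phenotype must be one of {_PHENOTYPES}")
        bouts = tuple((int(s), int(d)) for s, d in self.bouts)
        object.__setattr__(self, "bouts", bouts)
        prev_end = -1
        for start, dur in bouts:
            if start < 0 or dur <= 0:
                raise ValueError(f"invalid bout ({start}, {dur})")
            if (start * 60) % 30 or (dur * 60) % 30:
                raise ValueError("bout offsets/durations must align to 30-s epochs")
            if start <= prev_end:
                raise ValueError("bouts must be non-overlapping and increasing")
            prev_end = start + dur - 1

    def epoch_slices(self, epoch_seconds: int) -> list[slice]:
        """Bout extents as epoch-index slices."""
        per_min = 60 // epoch_seconds if epoch_seconds <= 60 else None
        if per_min is None or 60 % epoch_seconds:
            raise ValueError("epoch length must divide one minute")
        return [
            slice(start * per_min, (start + dur) * per_min) for start, dur in self.bouts
        ]

    def total_minutes(self) -> int:
        return sum(d for _, d in self.bouts)

    def to_json(self) -> str:
        return json.dumps(
            {"phenotype": self.phenotype, "bouts": list(self.bouts), "label": self.label}
        )

    @classmethod
    def from_json(cls, text: str) -> "MaskSpec":
        obj = json.loads(text)
        return cls(obj["phenotype"], tuple(tuple(b) for b in obj["bouts"]), obj["label"])


def apply_mask(series: EpochSeries, mask: MaskSpec) -> EpochSeries:
    """Copy of the series with every epoch inside a bout zeroed or made ABSENT."""
    fill = 0.0 if mask.phenotype == ZERO else np.nan
    values = series.values.copy()
    for sl in mask.epoch_slices(series.epoch_seconds):
        if sl.stop > series.n_epochs:
            raise ValueError(f"bout {sl} extends past the record end ({series.n_epochs})")
        values[sl] = fill
    return series.with_values(values)


def single_gap_grid(
    days: int = 7,
    durations_h=DEFAULT_DURATIONS_H,
    start_hours=DEFAULT_START_HOURS,
    start_days=None,
    phenotypes=_PHENOTYPES,
) -> list[MaskSpec]:
    """Factorial grid of single-gap masks.

    One bout per mask; the gap starts at ``(start_day-1)*24 + start_hour`` and
    lasts ``duration_h`` hours. Cells whose gap would extend past the
    ``days``-day record are omitted. Deterministic ordering: phenotype, then
    start_day, then duration, then start hour.
    """
    if start_days is None:
        start_days = range(1, days + 1)
    record_min = days * 24 * 60
    specs = []
    for phen in phenotypes:
        for day in start_days:
            for dur in durations_h:
                for sh in start_hours:
                    start = ((day - 1) * 24 + sh) * 60
                    if start + dur * 60 > record_min:
                        continue
                    specs.append(
                        MaskSpec(
                            phen,
                            ((start, dur * 60),),
                            {"start_day": day, "start_hour": sh, "duration_h": dur},
                        )
                    )
    return specs


def double_gap_grid(
    days: int = 7,
    gap1_min: int = DEFAULT_GAP1_MIN,
    gap2_min: int = DEFAULT_GAP2_MIN,
    separations_h=DEFAULT_SEPARATIONS_H,
    start_hours=DEFAULT_START_HOURS,
    start_days=None,
    phenotypes=_PHENOTYPES,
) -> list[MaskSpec]:
    """Factorial grid of two-bout masks.

    The separation is measured from the end of bout 1 to the start of bout 2
    (the data-present interval between the gaps). Cells whose second bout would
    run past the record end are omitted and later surface as empty heatmap
    cells.
    """
    if start_days is None:
        start_days = range(1, days + 1)
    record_min = days * 24 * 60
    specs = []
    for phen in phenotypes:
        for day in start_days:
            for sep in separations_h:
                for sh in start_hours:
                    start1 = ((day - 1) * 24 + sh) * 60
                    start2 = start1 + gap1_min + sep * 60
                    if start2 + gap2_min > record_min:
                        continue
                    specs.append(
                        MaskSpec(
                            phen,
                            ((start1, gap1_min), (start2, gap2_min)),
                            {"start_day": day, "start_hour": sh, "separation_h": sep},
                        )
                    )
    return specs
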