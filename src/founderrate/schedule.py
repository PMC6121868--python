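"""Serial (heterochronous) sampling schedules.

Samples are dated in calibrated years before present (calBP, present = 1950 AD;
larger values are older).  All conversion between calendar years and coalescent
generations happens here and nowhere else, via a single female generation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ScheduleError(ValueError):
    """Invalid sampling schedule (negative, non-finite or duplicated entries)."""


@dataclass(frozen=True)
class SampleSchedule:
    """Sampling design of a serially sampled (heterochronous) data set.

    Parameters
    ----------
    entries:
        ``(sample_id, age_calBP)`` pairs, sorted by age ascending (youngest
        first).  Ages are calibrated years before 1950 and must be >= 0.
    generation_time_years:
        Female generation time used to convert years to coalescent
        generations.  Default 15 years.
    """

    entries: tuple[tuple[str, float], ...]
    generation_time_years: float = 15.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ScheduleError("schedule must contain at least one sample")
        if self.generation_time_years <= 0 or not math.isfinite(self.generation_time_years):
            raise ScheduleError("generation time must be a positive, finite number of years")
        ids = [sid for sid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ScheduleError("sample ids must be unique")
        for sid, age in self.entries:
            if not math.isfinite(age):
                raise ScheduleError(f"non-finite age for sample {sid!r}")
            if age < 0:
                raise ScheduleError(f"negative age {age} for sample {sid!r}")
        ages = [age for _, age in self.entries]
        if ages != sorted(ages):
            raise ScheduleError("entries must be sorted by age ascending")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    @property
    def ages(self) -> list[float]:
        """Sample ages in years calBP, ascending."""
        return [age for _, age in self.entries]

    @property
    def max_age(self) -> float:
        return self.entries[-1][1]

    def age_in_generations(self, sample_id: str) -> float:
        """Age of one sample converted to generations (age / generation time)."""
        for sid, age in self.entries:
            if sid == sample_id:
                return age / self.generation_time_years
        raise KeyError(sample_id)

    @property
    def ages_in_generations(self) -> list[float]:
        g = self.generation_time_years
        return [age / g for _, age in self.entries]


def build_schedule(ages, generation_time: float = 15.0, sample_ids=None) -> SampleSchedule:
    """Build a :class:`SampleSchedule` from raw ages.

    Ages may be given in any order; the schedule is sorted youngest-first.
    If ``sample_ids`` is omitted, ids ``s00, s01, ...`` are assigned in the
    sorted order.
    """
    ages = [float(a) for a in ages]
    for a in ages:
        if not math.isfinite(a):
            raise ScheduleError(f"non-finite age {a!r}")
        if a < 0:
            raise ScheduleError(f"negative age {a!r}")
    order = sorted(range(len(ages)), key=lambda i: ages[i])
    if sample_ids is None:
        entries = tuple((f"s{k:02d}", ages[i]) for k, i in enumerate(order))
    else:
        sample_ids = list(sample_ids)
        if len(sample_ids) != len(ages):
            raise ScheduleError("sample_ids and ages must have equal length")
        entries = tuple((sample_ids[i], ages[i]) for i in order)
    return SampleSchedule(entries=entries, generation_time_years=float(generation_time))


#: Median calibrated ages (years calBP) of the 14 Holocene samples from the
#: island population; the study's serial sampling design.
WRANGEL_HOLOCENE_AGES: tuple[float, ...] = (
    4024, 4079, 4336, 4354, 4643, 4726, 4969, 6380, 7060, 7194, 7336, 7470, 8318, 8491,
)


def wrangel_schedule(generation_time: float = 15.0) -> SampleSchedule:
    """The 14-sample Holocene Wrangel Island sampling schedule."""
    return build_schedule(WRANGEL_HOLOCENE_AGES, generation_time)
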