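"""Drug-utilization pattern classification.

Each new user of an antihypertensive monotherapy is classified on four
non-exclusive patterns over follow-up:

discontinuation
    A supply gap of the initial drug class exceeding 180 days: the first
    covered-interval end ``e`` (end of held supply) with no same-class
    dispensing in ``(e, e + 180]``.  A gap of exactly 180 days is *not* a
    discontinuation.
switch
    First dispensing of a different exposure class or antihypertensive
    fixed-dose combination within the 180 days after a discontinuation,
    i.e. on a day in ``(disc_day, disc_day + 180]``.
add-on
    First dispensing of a different exposure class or FDC on a day strictly
    inside the initial class's covered supply (half-open intervals, so a
    dispensing on the exact end-of-supply day falls outside coverage and is
    switch-side), before any discontinuation.
continuation
    Baseline monotherapy held to the end of observation with none of the
    three events.

Switch and add-on may both occur for one patient (at different times);
continuation is mutually exclusive with all events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .coverage import Interval

GAP_DAYS = 180
SWITCH_WINDOW = 180


@dataclass
class PatternProfile:
    patient_id: object
    continuation: bool
    discontinuation_day: int | None = None
    switch_day: int | None = None
    switch_target: str | None = None
    addon_day: int | None = None
    addon_target: str | None = None

    def __post_init__(self) -> None:
        events = (self.discontinuation_day, self.switch_day, self.addon_day)
        if self.continuation and any(e is not None for e in events):
            raise ValueError("continuation excludes all pattern events")


def detect_discontinuation(
    intervals: Sequence[Interval],
    same_class_days: Iterable[int],
    gap_days: int = GAP_DAYS,
    observe_end: int | None = None,
) -> int | None:
    """First end-of-supply day followed by a >``gap_days`` same-class gap.

    ``observe_end`` bounds the event day: coverage running to (or past) the
    end of observation is continuation, not discontinuation.
    """
    days = sorted(int(d) for d in same_class_days)
    for _, e in intervals:
        if observe_end is not None and e >= observe_end:
            return None
        if not any(e < d <= e + gap_days for d in days):
            return e
    return None


def detect_switch_addon(
    intervals: Sequence[Interval],
    discontinuation_day: int | None,
    other_dispensings: Iterable[tuple[int, str]],
    window: int = SWITCH_WINDOW,
    observe_end: int | None = None,
) -> tuple[tuple[int, str] | None, tuple[int, str] | None]:
    """Return ``(switch, addon)`` events, each ``(day, target)`` or None.

    ``other_dispensings`` are dispensings of exposure classes other than the
    initial one, or of FDC products, labelled with their target class.
    """
    others = sorted((int(d), str(t)) for d, t in other_dispensings)

    addon = None
    for d, t in others:
        if observe_end is not None and d >= observe_end:
            break
        if discontinuation_day is not None and d >= discontinuation_day:
            break
        if any(s <= d < e for s, e in intervals):
            addon = (d, t)
            break

    switch = None
    if discontinuation_day is not None:
        for d, t in others:
            if observe_end is not None and d >= observe_end:
                break
            if discontinuation_day < d <= discontinuation_day + window:
                switch = (d, t)
                break
    return switch, addon


def classify_patient(
    patient_id: object,
    intervals: Sequence[Interval],
    same_class_days: Iterable[int],
    other_dispensings: Iterable[tuple[int, str]],
    observe_end: int | None,
    gap_days: int = GAP_DAYS,
    window: int = SWITCH_WINDOW,
) -> PatternProfile:
    """Full pattern profile for one patient's follow-up."""
    disc = detect_discontinuation(intervals, same_class_days, gap_days, observe_end)
    switch, addon = detect_switch_addon(
        intervals, disc, other_dispensings, window, observe_end
    )
    continuation = disc is None and switch is None and addon is None
    return PatternProfile(
        patient_id=patient_id,
        continuation=continuation,
        discontinuation_day=disc,
        switch_day=switch[0] if switch else None,
        switch_target=switch[1] if switch else None,
        addon_day=addon[0] if addon else None,
        addon_target=addon[1] if addon else None,
    )
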