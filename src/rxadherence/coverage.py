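"""Supply-coverage timelines and proportion-of-days-covered (PDC).

All times are integer days since the index date (day 0 = index).  A supply
interval is half-open: a dispensing on day ``d`` with ``s`` days of supply
covers days ``[d, d+s)``.  Two overlap policies are supported:

``carryover``
    An early refill is banked — its start is shifted to the end of the
    previously held supply, so no dispensed day is lost.  This is the common
    PDC convention and the package default.
``truncate``
    Overlapping supply is discarded; covered days are the plain set union of
    the dispensing intervals.

``annual_pdc`` implements the year-k adherence rate with a fixed 360-day
denominator; ``overall_pdc`` the whole-of-follow-up rate with the follow-up
length as denominator.  Both are capped at 1 and binarized as high adherence
at >= 0.8 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]

YEAR_DAYS = 360
HIGH_ADHERENCE_THRESHOLD = 0.8

POLICIES = ("carryover", "truncate")


def covered_intervals(
    dispensings: Iterable[tuple[int, int]], policy: str = "carryover"
) -> list[Interval]:
    """Merge dispensings ``(day, days_supply)`` into disjoint covered intervals.

    Abutting intervals are merged, so the result is a minimal sorted list of
    disjoint half-open ``(start, end)`` pairs.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    disp = sorted((int(d), int(s)) for d, s in dispensings)
    if any(s <= 0 for _, s in disp):
        raise ValueError("days_supply must be positive")
    out: list[list[int]] = []
    if policy == "carryover":
        for d, s in disp:
            if out and d <= out[-1][1]:
                # refill at or before current supply exhaustion: bank it
                out[-1][1] += s
            else:
                out.append([d, d + s])
    else:  # truncate: plain union
        for d, s in disp:
            if out and d <= out[-1][1]:
                out[-1][1] = max(out[-1][1], d + s)
            else:
                out.append([d, d + s])
    return [(a, b) for a, b in out]


def covered_days(
    intervals: Sequence[Interval], lo: int | None = None, hi: int | None = None
) -> int:
    """Number of covered days within the window ``[lo, hi)``."""
    total = 0
    for s, e in intervals:
        a = s if lo is None else max(s, lo)
        b = e if hi is None else min(e, hi)
        if b > a:
            total += b - a
    return total


@dataclass
class CoverageTimeline:
    """Covered-day timeline for one patient and drug class."""

    patient_id: object
    drug_class: str
    intervals: list[Interval] = field(default_factory=list)
    policy: str = "carryover"

    @classmethod
    def from_dispensings(
        cls,
        patient_id: object,
        drug_class: str,
        dispensings: Iterable[tuple[int, int]],
        policy: str = "carryover",
    ) -> "CoverageTimeline":
        return cls(patient_id, drug_class, covered_intervals(dispensings, policy), policy)

    def covered_days(self, lo: int | None = None, hi: int | None = None) -> int:
        return covered_days(self.intervals, lo, hi)


def annual_pdc(
    intervals: Sequence[Interval] | CoverageTimeline,
    k: int,
    followup_end_day: int | None = None,
    year_days: int = YEAR_DAYS,
) -> float | None:
    """PDC of treatment year ``k`` (k >= 1) with a fixed ``year_days`` denominator.

    Returns ``None`` (not evaluable) when the year window ``[360(k-1), 360k)``
    is not fully inside follow-up, rather than diluting the estimate with
    uncovered censored time.
    """
    if k < 1:
        raise ValueError("year index k must be >= 1")
    if isinstance(intervals, CoverageTimeline):
        intervals = intervals.intervals
    lo, hi = year_days * (k - 1), year_days * k
    if followup_end_day is not None and followup_end_day < hi:
        return None
    return min(1.0, covered_days(intervals, lo, hi) / year_days)


def overall_pdc(
    intervals: Sequence[Interval] | CoverageTimeline, followup_end_day: int
) -> float:
    """PDC over the whole follow-up ``[0, followup_end_day)``."""
    if followup_end_day < 1:
        raise ValueError("followup_end_day must be >= 1")
    if isinstance(intervals, CoverageTimeline):
        intervals = intervals.intervals
    return min(1.0, covered_days(intervals, 0, followup_end_day) / followup_end_day)


def binarize_adherence(pdc: float) -> str:
    """'high' iff pdc >= 0.8 (inclusive), else 'low'."""
    if not 0.0 <= pdc <= 1.0:
        raise ValueError(f"pdc must lie in [0, 1], got {pdc}")
    return "high" if pdc >= HIGH_ADHERENCE_THRESHOLD else "low"
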