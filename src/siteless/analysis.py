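"""Cohort analyses: funnel, summary tables, retention, ROM-vs-pain.

All analyses are descriptive; every "n/N (x%)" figure is produced by
:func:`pct` with half-up rounding at the requested precision, and every
summary reports its own denominator (item-level nonresponse means
denominators differ between tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .joints import max_wrist_severity
from .records import FunnelCounts, ParticipantRecord

RetentionDefinition = Literal["monotone", "weekly"]


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100*numerator/denominator, rounded half-up.

    Half-up (not banker's) rounding matches how clinical tables are
    conventionally printed, e.g. 399/1170 -> 34.10 at two decimals.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# funnel

def funnel_summary(counts: FunnelCounts, decimals: int = 2) -> pd.DataFrame:
    """Stage counts and percentages of downloads for the enrollment funnel."""
    stages = [
        ("downloads", counts.downloads),
        ("consented", counts.consented),
        ("consented_outside_window", counts.consented_outside_window),
        ("enrolled", counts.enrolled),
    ]
    return pd.DataFrame(
        {
            "stage": [s for s, _ in stages],
            "n": [n for _, n in stages],
            "pct_of_downloads": [
                pct(n, counts.downloads, decimals) for _, n in stages
            ],
        }
    )


def recount_funnel(records: Sequence[ParticipantRecord],
                   counts: FunnelCounts) -> FunnelCounts:
    """Cross-check: replace the enrolled count with a recount of records."""
    return FunnelCounts(downloads=counts.downloads, consented=counts.consented,
                        consented_outside_window=counts.consented_outside_window,
                        enrolled=len(records))


# ---------------------------------------------------------------------------
# summary tables

def _group_frames(records: Sequence[ParticipantRecord]) -> dict[str, list[ParticipantRecord]]:
    groups: dict[str, list[ParticipantRecord]] = {"A": [], "B": [], "Total": []}
    for r in records:
        groups[r.group].append(r)
        groups["Total"].append(r)
    return {g: members for g, members in groups.items() if members}


def demographic_table(records: Sequence[ParticipantRecord],
                      decimals: int = 1) -> pd.DataFrame:
    """Baseline demographics by arm and total.

    Categorical rows give ``n`` and percent of the arm; age and BMI give
    mean (SD).  Long (tidy) format: variable, category, group, n, pct,
    mean, sd.
    """
    if not records:
        raise ValueError("no records")
    groups = _group_frames(records)
    categorical = [
        ("sex", lambda r: r.demographics.sex),
        ("ethnicity", lambda r: r.demographics.ethnicity),
        ("education", lambda r: r.demographics.education),
        ("smoking", lambda r: r.demographics.smoking),
        ("disease_duration", lambda r: r.demographics.disease_duration),
    ]
    continuous = [
        ("age", lambda r: r.demographics.age),
        ("bmi", lambda r: r.demographics.bmi),
    ]
    rows = []
    for gname, members in groups.items():
        denom = len(members)
        for var, getter in categorical:
            values = [getter(r) for r in members]
            for cat in sorted(set(values)):
                n = values.count(cat)
                rows.append(dict(variable=var, category=cat, group=gname,
                                 n=n, pct=pct(n, denom, decimals) if denom else None,
                                 mean=None, sd=None))
        for var, getter in continuous:
            vals = np.array([getter(r) for r in members], dtype=float)
            rows.append(dict(variable=var, category="", group=gname,
                             n=denom, pct=None,
                             mean=round_half_up(float(vals.mean()), decimals),
                             sd=round_half_up(float(vals.std(ddof=1)), decimals + 1)
                             if denom > 1 else None))
    return pd.DataFrame(rows)


def medication_table(records: Sequence[ParticipantRecord],
                     decimals: int = 1) -> pd.DataFrame:
    """Current medications by arm; the denominator is the number of
    participants who answered the medication question, per arm."""
    if not records:
        raise ValueError("no records")
    groups = _group_frames(records)
    meds: list[str] = sorted({m for r in records if r.medications is not None
                              for m in r.medications})
    rows = []
    for gname, members in groups.items():
        respondents = [r for r in members if r.medications is not None]
        denom = len(respondents)
        rows.append(dict(medication="_respondents", group=gname,
                         n=denom, pct=None))
        for med in meds:
            n = sum(1 for r in respondents if med in r.medications)
            rows.append(dict(medication=med, group=gname, n=n,
                             pct=pct(n, denom, decimals) if denom else None))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# retention

def retention_curve(records: Sequence[ParticipantRecord],
                    n_weeks: int = 12,
                    definition: RetentionDefinition = "monotone",
                    decimals: int = 1) -> pd.DataFrame:
    """Participants retained per week, by arm and overall.

    ``monotone`` (default): retained at week w means any completed
    assessment at week w or later (last-activity definition; guarantees a
    non-increasing curve).  ``weekly``: completed at least one assessment
    in week w itself, which can fluctuate.  Fractions are over the
    enrolled count of the arm.
    """
    if not records:
        raise ValueError("no enrolled records")
    groups = _group_frames(records)
    rows = []
    for week in range(1, n_weeks + 1):
        for gname, members in groups.items():
            if definition == "monotone":
                n = sum(1 for r in members if r.active_at(week))
            else:
                n = sum(1 for r in members
                        if any(w.week == week and w.completed for w in r.weekly))
            denom = len(members)
            rows.append(dict(week=week, group=gname, retained=n,
                             enrolled=denom,
                             fraction=n / denom,
                             pct=pct(n, denom, decimals)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROM vs reported wrist pain

@dataclass(frozen=True)
class BoxStats:
    """Five-number summary of measured ROM for one wrist-severity group."""

    severity: int
    n: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) with linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def rom_pain_association(records: Sequence[ParticipantRecord],
                         week: int = 1,
                         side: Literal["left", "right"] = "right"
                         ) -> list[BoxStats]:
    """Box statistics of measured wrist ROM grouped by reported wrist-pain
    severity (0-3) at the given week.

    Only participants with both a joint map and a measured ROM session at
    that week contribute.  Severity groups with no data are omitted.
    """
    by_severity: dict[int, list[float]] = {0: [], 1: [], 2: [], 3: []}
    for r in records:
        pain_map = r.joint_map_at(week)
        session = r.rom_session_at(week)
        if pain_map is None or session is None or session.measured is None:
            continue
        if session.side != side:
            continue
        sev = max_wrist_severity(pain_map, side)
        by_severity[sev].append(session.measured.rom)

    stats = []
    for sev in (0, 1, 2, 3):
        vals = by_severity[sev]
        if not vals:
            continue
        q1, med, q3 = quartiles(vals)
        stats.append(BoxStats(severity=sev, n=len(vals), median=med,
                              q1=q1, q3=q3,
                              minimum=float(min(vals)),
                              maximum=float(max(vals))))
    return stats


# ---------------------------------------------------------------------------
# study-mode preference

def preference_summary(records: Sequence[ParticipantRecord],
                       decimals: int = 1) -> pd.DataFrame:
    """Four-way split of study-mode preference with percent of enrolled."""
    if not records:
        raise ValueError("no records")
    denom = len(records)
    rows = []
    for choice in ("app", "clinic", "both", "none", "missing"):
        n = sum(1 for r in records if r.preference == choice)
        rows.append(dict(preference=choice, n=n, pct=pct(n, denom, decimals)))
    return pd.DataFrame(rows)
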