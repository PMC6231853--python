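"""Deterministic record sets reconstructed from marginal counts.

Descriptive study reports print statistics as "n/N (x%)" without the
record-level data behind them.  These helpers build a minimal record set
that is exactly consistent with a given collection of marginal counts
(arm sizes, preference split, weekly retention, per-joint pain counts),
so that the table/summary computations can be verified to reproduce each
ratio at its printed precision.  Assignments are deterministic: the first
k records in id order receive each attribute.
"""

from __future__ import annotations

from .joints import JointPainMap
from .records import Demographics, ParticipantRecord, WeeklyResponse

_DEFAULT_DEMOGRAPHICS = dict(
    age=48.0, ethnicity="white", bmi=29.5, education="college",
    smoking="never", disease_duration="2-5",
)


def records_from_marginals(
    *,
    group_sizes: dict[str, int],
    preference_counts: dict[str, int] | None = None,
    week12_retained: dict[str, int] | None = None,
    week2_retained_total: int | None = None,
    n_female: int | None = None,
) -> list[ParticipantRecord]:
    """Build enrolled records matching the given marginal counts exactly.

    ``group_sizes`` maps arm ("A"/"B") to enrolled n.  Optional marginals:
    ``preference_counts`` (app/clinic/both/none; the remainder is
    missing), ``week12_retained`` per arm, ``week2_retained_total``
    across arms (participants active at week >= 2), and ``n_female``.
    Retention is expressed through ``last_active_week``: 12 for the
    week-12 retained, 2 for the additional week-2 retained, 1 otherwise.
    """
    total = sum(group_sizes.values())
    week12_retained = week12_retained or {g: 0 for g in group_sizes}
    if week2_retained_total is None:
        week2_retained_total = sum(week12_retained.values())
    extra_week2 = week2_retained_total - sum(week12_retained.values())
    if extra_week2 < 0:
        raise ValueError("week-2 retained cannot be below week-12 retained")

    # per-arm last_active assignment: week-12 retained first, then fill
    # the remaining week-2-only retained from arm A onward
    last_active: dict[str, list[int]] = {}
    remaining = extra_week2
    for g in sorted(group_sizes):
        n, w12 = group_sizes[g], week12_retained.get(g, 0)
        if w12 > n:
            raise ValueError(f"arm {g}: week-12 retained exceeds arm size")
        w2 = min(remaining, n - w12)
        remaining -= w2
        last_active[g] = [12] * w12 + [2] * w2 + [1] * (n - w12 - w2)
    if remaining:
        raise ValueError("week-2 retained exceeds enrolled")

    prefs: list[str] = []
    if preference_counts:
        for choice in ("app", "clinic", "both", "none"):
            prefs += [choice] * preference_counts.get(choice, 0)
    prefs += ["missing"] * (total - len(prefs))
    if len(prefs) != total:
        raise ValueError("preference counts exceed enrolled")

    sexes = ["female"] * (n_female if n_female is not None else 0)
    sexes += ["male"] * (total - len(sexes))

    records = []
    i = 0
    for g in sorted(group_sizes):
        for law in last_active[g]:
            records.append(ParticipantRecord(
                id=f"p{i:04d}", group=g,
                demographics=Demographics(sex=sexes[i], **_DEFAULT_DEMOGRAPHICS),
                preference=prefs[i],
                weekly=[WeeklyResponse(week=w) for w in range(1, law + 1)],
                last_active_week=law,
            ))
            i += 1
    return records


def maps_from_prevalence_counts(n_maps: int,
                                counts: dict[str, int],
                                week: int = 1,
                                severity: int = 1) -> list[JointPainMap]:
    """Build ``n_maps`` joint-pain maps where exactly ``counts[joint]`` of
    them report the given severity in that joint (the first k maps, per
    joint, independently)."""
    for joint, k in counts.items():
        if not 0 <= k <= n_maps:
            raise ValueError(f"count for {joint} outside [0, {n_maps}]")
    maps = []
    for i in range(n_maps):
        scores = {joint: severity for joint, k in counts.items() if i < k}
        maps.append(JointPainMap(participant_id=f"m{i:04d}", week=week,
                                 scores=scores))
    return maps
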