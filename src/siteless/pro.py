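"""Scoring for the deployed patient-reported outcome (PRO) instruments.

The study collected, besides weekly 0-10 semiquantitative scales and a
0-100 patient global assessment, three validated instruments at weeks
1, 4, 8 and 12:

* HAQ-DI  - Health Assessment Questionnaire Disability Index: 20 items in
  8 categories, each item 0-3; higher = worse physical function.
* FACIT-Fatigue - 13 items, 0-4 each; total 0-52, higher = less fatigue.
* EQ-5D-5L - five dimensions at five levels plus a 0-100 visual analogue
  scale (VAS).  Only the profile and VAS are computed; a country-specific
  index value requires a value-set table, which may be supplied.

Scoring follows the instruments' published standard rules.
"""

from __future__ import annotations

from typing import Mapping, Sequence

#: HAQ-DI categories and the number of items in each (20 items total).
HAQDI_CATEGORIES: tuple[tuple[str, int], ...] = (
    ("dressing", 2),
    ("arising", 2),
    ("eating", 3),
    ("walking", 2),
    ("hygiene", 3),
    ("reach", 2),
    ("grip", 3),
    ("activities", 3),
)

HAQDI_N_ITEMS = sum(n for _, n in HAQDI_CATEGORIES)

#: Zero-based positions of the two positively-worded FACIT-Fatigue items
#: ("I have energy", "I am able to do my usual activities"); they are
#: scored as answered, all other items are reverse-scored.
FACITF_POSITIVE_ITEMS = (7, 8)
FACITF_N_ITEMS = 13


def score_haqdi(
    items: Sequence[int | None],
    aids_flags: Sequence[bool] | None = None,
) -> float | None:
    """Standard HAQ-DI score in [0, 3], or None if insufficiently answered.

    Parameters
    ----------
    items
        20 item responses (0-3) in category order, ``None`` for missing.
    aids_flags
        8 booleans, one per category: whether aids/devices or help from
        another person were used for that category.  A flagged category's
        score is raised to at least 2.

    The category score is the maximum of its answered items (missing if
    none answered); the total is the mean over answered categories, and is
    missing when fewer than 6 of the 8 categories are answered.
    """
    if len(items) != HAQDI_N_ITEMS:
        raise ValueError(f"expected {HAQDI_N_ITEMS} HAQ-DI items, got {len(items)}")
    if aids_flags is None:
        aids_flags = [False] * len(HAQDI_CATEGORIES)
    if len(aids_flags) != len(HAQDI_CATEGORIES):
        raise ValueError("aids_flags must have one entry per category (8)")

    category_scores: list[int] = []
    pos = 0
    for (name, n), aided in zip(HAQDI_CATEGORIES, aids_flags):
        cat_items = items[pos:pos + n]
        pos += n
        answered = [x for x in cat_items if x is not None]
        for x in answered:
            if not isinstance(x, int) or not 0 <= x <= 3:
                raise ValueError(f"HAQ-DI item in {name} out of range 0-3: {x!r}")
        if not answered:
            continue
        score = max(answered)
        if aided:
            score = max(score, 2)
        category_scores.append(score)

    if len(category_scores) < 6:
        return None
    return sum(category_scores) / len(category_scores)


def score_facitf(items: Sequence[int | None]) -> float | None:
    """Standard FACIT-Fatigue score in [0, 52]; higher means less fatigue.

    The 11 negatively-worded items are reversed (4 - x); the two
    positively-worded items are taken as answered.  The sum is prorated by
    13 / answered; the score is missing when fewer than 7 items are
    answered.
    """
    if len(items) != FACITF_N_ITEMS:
        raise ValueError(f"expected {FACITF_N_ITEMS} FACIT-F items, got {len(items)}")
    total = 0
    answered = 0
    for i, x in enumerate(items):
        if x is None:
            continue
        if not isinstance(x, int) or not 0 <= x <= 4:
            raise ValueError(f"FACIT-F item {i} out of range 0-4: {x!r}")
        total += x if i in FACITF_POSITIVE_ITEMS else 4 - x
        answered += 1
    if answered < 7:
        return None
    return total * FACITF_N_ITEMS / answered


def eq5d_profile(
    dimensions: Sequence[int],
    vas: int,
    value_set: Mapping[str, float] | None = None,
) -> tuple[str, int, float | None]:
    """EQ-5D-5L profile string, VAS, and optional value-set index.

    ``dimensions`` are the five responses (mobility, self-care, usual
    activities, pain/discomfort, anxiety/depression), each 1-5; ``vas`` is
    the 0-100 health-today rating.  The index is looked up in
    ``value_set`` (profile string -> utility) when one is supplied,
    otherwise ``None`` -- no country value set is bundled.
    """
    if len(dimensions) != 5:
        raise ValueError("EQ-5D-5L has exactly 5 dimensions")
    for d in dimensions:
        if not isinstance(d, int) or not 1 <= d <= 5:
            raise ValueError(f"EQ-5D-5L dimension out of range 1-5: {d!r}")
    if not isinstance(vas, int) or not 0 <= vas <= 100:
        raise ValueError(f"EQ VAS out of range 0-100: {vas!r}")
    profile = "".join(str(d) for d in dimensions)
    index = None
    if value_set is not None:
        try:
            index = value_set[profile]
        except KeyError:
            raise KeyError(f"profile {profile} not in supplied value set") from None
    return profile, vas, index
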