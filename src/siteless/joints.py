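"""Joint-pain body map: the 55-joint canon and per-joint pain summaries.

Participants score each of 55 prespecified joints on an interactive body
map as 0 (no pain), 1 (mild), 2 (moderate) or 3 (severe).  The canon used
here is 27 bilateral pairs plus the midline neck; the exact joint list is
this package's documented convention:

    per side: temporomandibular, shoulder, elbow, wrist,
              MCP 1-5, PIP 1-5, DIP 2-5 (the thumb has no DIP),
              hip, knee, ankle, MTP 1-5, midfoot
    midline:  neck

Joint identifiers are strings such as ``"right_wrist"``, ``"left_mcp3"``
or ``"neck"``.
"""

from __future__ import annotations

from typing import Iterable, Literal

from pydantic import BaseModel, Field, field_validator

_PAIRED_BASES: tuple[str, ...] = (
    "temporomandibular",
    "shoulder",
    "elbow",
    "wrist",
    "mcp1", "mcp2", "mcp3", "mcp4", "mcp5",
    "pip1", "pip2", "pip3", "pip4", "pip5",
    "dip2", "dip3", "dip4", "dip5",
    "hip",
    "knee",
    "ankle",
    "mtp1", "mtp2", "mtp3", "mtp4", "mtp5",
    "midfoot",
)

#: Canonical ordered tuple of the 55 joint identifiers.
JOINT_CANON: tuple[str, ...] = tuple(
    f"{side}_{base}" for base in _PAIRED_BASES for side in ("left", "right")
) + ("neck",)

_JOINT_SET = frozenset(JOINT_CANON)

assert len(JOINT_CANON) == 55

Side = Literal["left", "right", "midline"]


def joint_side(joint: str) -> Side:
    """Return which side of the body a canonical joint identifier names."""
    if joint not in _JOINT_SET:
        raise ValueError(f"unknown joint: {joint!r}")
    if joint.startswith("left_"):
        return "left"
    if joint.startswith("right_"):
        return "right"
    return "midline"


class JointPainMap(BaseModel):
    """One participant's body-map response at one visit.

    ``scores`` maps canonical joint ids to severities 0-3.  Joints absent
    from the mapping are treated as severity 0 (no pain) by convention.
    """

    participant_id: str
    week: int = Field(ge=1, le=12)
    scores: dict[str, int] = Field(default_factory=dict)

    @field_validator("scores")
    @classmethod
    def _check_scores(cls, scores: dict[str, int]) -> dict[str, int]:
        for joint, sev in scores.items():
            if joint not in _JOINT_SET:
                raise ValueError(f"unknown joint: {joint!r}")
            if not isinstance(sev, int) or not 0 <= sev <= 3:
                raise ValueError(
                    f"severity for {joint} must be an integer in [0, 3], got {sev!r}"
                )
        return scores

    def severity(self, joint: str) -> int:
        if joint not in _JOINT_SET:
            raise ValueError(f"unknown joint: {joint!r}")
        return self.scores.get(joint, 0)


def prevalence_any_pain(maps: Iterable[JointPainMap]) -> dict[str, float]:
    """Fraction of respondents reporting any pain (severity >= 1) per joint.

    All maps must come from the same study week; the denominator is the
    number of maps supplied (respondents, not enrolled participants).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("prevalence_any_pain requires at least one map")
    weeks = {m.week for m in maps}
    if len(weeks) > 1:
        raise ValueError(f"maps span multiple weeks: {sorted(weeks)}")
    n = len(maps)
    return {
        joint: sum(1 for m in maps if m.severity(joint) >= 1) / n
        for joint in JOINT_CANON
    }


def painful_joint_count(pain_map: JointPainMap, min_severity: int = 1) -> int:
    """Number of joints at or above ``min_severity`` (1=mild .. 3=severe)."""
    if not 1 <= min_severity <= 3:
        raise ValueError("min_severity must be 1, 2 or 3")
    return sum(1 for j in JOINT_CANON if pain_map.severity(j) >= min_severity)


def max_wrist_severity(pain_map: JointPainMap, side: Literal["left", "right"]) -> int:
    """Severity recorded for the given wrist; 0 if the joint was not marked."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    return pain_map.severity(f"{side}_wrist")
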