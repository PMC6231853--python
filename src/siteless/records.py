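"""Participant record schema: the JSON-lines study data model.

One :class:`ParticipantRecord` per enrolled participant holds
demographics, the A/B arm, current medications, the four-way study-mode
preference, weekly responses, the week-1/8 joint-pain maps, the week-1/12
wrist ROM sessions, and the last study week with any activity.  All
validation is delegated to pydantic; records serialize one-per-line as
JSON (see :mod:`siteless.io`).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .joints import JointPainMap

Group = Literal["A", "B"]
Preference = Literal["app", "clinic", "both", "none", "missing"]


class Demographics(BaseModel):
    sex: Literal["female", "male"]
    age: float = Field(ge=21, le=110)
    ethnicity: Literal["white", "african_american", "hispanic", "asian", "other"]
    bmi: float = Field(gt=10, lt=80)
    education: Literal["middle_school", "high_school", "college", "graduate_school"]
    smoking: Literal["current", "previous", "never"]
    disease_duration: Literal["<2", "2-5", "5-10", ">10"]


class WeeklyResponse(BaseModel):
    """One week's subjective tasks: 0-100 patient global assessment plus
    0-10 semiquantitative pain/stiffness/mood scales and app satisfaction."""

    week: int = Field(ge=1, le=12)
    completed: bool = True
    global_assessment: Optional[int] = Field(default=None, ge=0, le=100)
    pain: Optional[int] = Field(default=None, ge=0, le=10)
    stiffness: Optional[int] = Field(default=None, ge=0, le=10)
    mood: Optional[int] = Field(default=None, ge=0, le=10)
    satisfaction: Optional[int] = Field(default=None, ge=0, le=10)


class ProPanel(BaseModel):
    """The validated instruments collected at weeks 1, 4, 8 and 12."""

    week: int = Field(ge=1, le=12)
    eq5d_dimensions: Optional[list[int]] = None      # 5 values, 1-5
    eq5d_vas: Optional[int] = Field(default=None, ge=0, le=100)
    haqdi_items: Optional[list[Optional[int]]] = None    # 20 values, 0-3
    haqdi_aids: Optional[list[bool]] = None              # 8 flags
    facitf_items: Optional[list[Optional[int]]] = None   # 13 values, 0-4

    @model_validator(mode="after")
    def _check_lengths(self) -> "ProPanel":
        if self.eq5d_dimensions is not None:
            if len(self.eq5d_dimensions) != 5 or any(
                    not 1 <= d <= 5 for d in self.eq5d_dimensions):
                raise ValueError("eq5d_dimensions must be 5 values in 1-5")
        if self.haqdi_items is not None and len(self.haqdi_items) != 20:
            raise ValueError("haqdi_items must have 20 entries")
        if self.haqdi_aids is not None and len(self.haqdi_aids) != 8:
            raise ValueError("haqdi_aids must have 8 entries")
        if self.facitf_items is not None and len(self.facitf_items) != 13:
            raise ValueError("facitf_items must have 13 entries")
        return self


class RomMeasurement(BaseModel):
    """Serialized summary of an imu.ROMResult (degrees)."""

    flexion: float = Field(ge=0)
    extension: float = Field(ge=0)
    rom: float = Field(ge=0)
    quality_flags: list[str] = Field(default_factory=list)


class RomSession(BaseModel):
    """One wrist ROM exercise: the simulator's ground truth plus, once the
    pipeline has run, the measured result.  ``trace_seed`` reproduces the
    raw IMU trace deterministically; ``trace_path`` points at an exported
    CSV when one was written."""

    week: int = Field(ge=1, le=12)
    side: Literal["left", "right"] = "right"
    true_flexion: float = Field(ge=0, lt=180)
    true_extension: float = Field(ge=0, lt=180)
    trace_seed: int = Field(ge=0)
    trace_path: Optional[str] = None
    measured: Optional[RomMeasurement] = None


class ParticipantRecord(BaseModel):
    id: str
    group: Group
    demographics: Demographics
    medications: Optional[list[str]] = None     # None = question skipped
    preference: Preference = "missing"
    weekly: list[WeeklyResponse] = Field(default_factory=list)
    pro_panels: list[ProPanel] = Field(default_factory=list)
    joint_maps: list[JointPainMap] = Field(default_factory=list)
    rom_sessions: list[RomSession] = Field(default_factory=list)
    last_active_week: int = Field(ge=0, le=12)

    @model_validator(mode="after")
    def _check_weeks(self) -> "ParticipantRecord":
        for w in self.weekly:
            if w.week > self.last_active_week:
                raise ValueError(
                    f"weekly response at week {w.week} after "
                    f"last_active_week {self.last_active_week}")
        return self

    def joint_map_at(self, week: int) -> JointPainMap | None:
        for m in self.joint_maps:
            if m.week == week:
                return m
        return None

    def rom_session_at(self, week: int) -> RomSession | None:
        for s in self.rom_sessions:
            if s.week == week:
                return s
        return None

    def active_at(self, week: int) -> bool:
        """Monotone retention indicator: any activity at week >= ``week``."""
        return self.last_active_week >= week


class FunnelCounts(BaseModel):
    """Enrollment funnel: app downloads -> consented -> enrolled, with
    consents outside the recruitment window excluded from enrollment."""

    downloads: int = Field(ge=0)
    consented: int = Field(ge=0)
    consented_outside_window: int = Field(ge=0)
    enrolled: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_order(self) -> "FunnelCounts":
        if not (self.downloads >= self.consented >= self.enrolled):
            raise ValueError("funnel must satisfy downloads >= consented >= enrolled")
        if self.enrolled > self.consented - self.consented_outside_window:
            raise ValueError("enrolled cannot exceed in-window consents")
        return self
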