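"""Static description of a hospital scenario.

A scenario bundles everything the simulator needs to know about a hospital
before any patient walks in: the rooms and their care-station capacity, the
specialty each room requires, the triangular service-time distributions of
every attendance performed there, the probabilistic flow graph patients follow
between care stages, the staff roster (12 h on / 36 h off shift pattern, four
professionals per post), and the movement delays of the elasticity actions.

The built-in :func:`polyclinic` fixture describes a Brazilian polyclinic with
seven rooms and eleven staffed posts: reception (2 attendants), triage
(1 nurse), doctor treatment (2 doctors), laboratory collection (2 nurses),
medication (2 nurses), electrocardiogram (1 nurse) and X-ray (1 radiology
technician).  Patient flow: everyone passes reception, triage and a first
doctor consultation; afterwards 24% go to X-ray, 37% to laboratory exams,
8% to ECG and 31% proceed without exams.  Of the medication path, 1% are
released with a prescription only, 50% receive intravenous medication, 30% an
intramuscular injection and 19% inhalation.  After exams, 60% return to the
doctor and 40% are released; after a return consultation 78% are released,
2% need new exams and 20% new medication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

EXIT = "EXIT"

#: Minutes of waiting that the scenario treats as 100% load.  Threshold
#: combinations are expressed as percentages of this value.
MAX_LOAD_MINUTES = 30.0


class ScenarioError(ValueError):
    """A scenario file or object violates the schema."""


class FlowError(ScenarioError):
    """Outgoing routing probabilities of a stage are inconsistent."""


class RoutingError(KeyError):
    """A stage label is unknown to the flow graph."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttendanceType:
    """One kind of care, with a triangular duration distribution (minutes)."""

    name: str
    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.mode <= self.upper):
            raise ScenarioError(
                f"attendance {self.name!r}: need 0 < lower <= mode <= upper, "
                f"got ({self.lower}, {self.mode}, {self.upper})"
            )

    @property
    def mean(self) -> float:
        """Closed-form mean of the triangular distribution."""
        return (self.lower + self.mode + self.upper) / 3.0


@dataclass(frozen=True)
class FlowEdge:
    from_stage: str
    to_stage: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise FlowError(
                f"edge {self.from_stage}->{self.to_stage}: probability "
                f"{self.probability} outside [0, 1]"
            )


@dataclass(frozen=True)
class Stage:
    """A node of the patient-flow graph.

    A stage either maps to a physical room together with the recipe of
    attendance types performed in sequence during one service (e.g. the
    intravenous-medication stage is a preparation followed by the infusion),
    or it is virtual (``room is None``): a pure branching point resolved
    instantly by routing.
    """

    name: str
    room: str | None = None
    recipe: tuple[str, ...] = ()


@dataclass(frozen=True)
class Room:
    name: str
    required_specialty: str
    station_limit: int = 4
    upper_threshold: float = 0.7 * MAX_LOAD_MINUTES
    lower_threshold: float = 0.3 * MAX_LOAD_MINUTES
    attendance_types: tuple[AttendanceType, ...] = ()
    allocation_only: bool = False

    def __post_init__(self) -> None:
        if self.station_limit < 1:
            raise ScenarioError(f"room {self.name!r}: station_limit must be >= 1")
        if not self.lower_threshold < self.upper_threshold:
            raise ScenarioError(
                f"room {self.name!r}: lower threshold must be below upper"
            )

    def attendance(self, name: str) -> AttendanceType:
        for at in self.attendance_types:
            if at.name == name:
                return at
        raise ScenarioError(f"room {self.name!r} has no attendance {name!r}")


@dataclass(frozen=True)
class ShiftRoster:
    """12-hours-on / 36-hours-off shift anchor for one professional.

    ``offset_hours`` places the professional's on-duty window at
    ``[offset + 48k, offset + 12 + 48k)`` hours of simulated time.  Four
    staggered offsets (0, 12, 24, 36) per post give uninterrupted 24/7
    coverage with exactly one professional on duty and three resting.
    """

    post: str
    offset_hours: int

    def __post_init__(self) -> None:
        if not 0 <= self.offset_hours < 48:
            raise ScenarioError("roster offset must lie in [0, 48) hours")


@dataclass(frozen=True)
class StaffMember:
    id: str
    specialties: frozenset[str]
    roster: ShiftRoster

    def __post_init__(self) -> None:
        if not self.specialties:
            raise ScenarioError(f"staff {self.id!r} has no specialty")


@dataclass
class ScenarioConfig:
    """Validated static description of the hospital."""

    rooms: dict[str, Room]
    staff: list[StaffMember]
    stages: dict[str, Stage]
    flow: dict[str, list[FlowEdge]]
    posts: dict[str, str]  # post label -> home room
    entry_stage: str = "reception"
    reallocation_minutes: float = 10.0
    allocation_minutes: float = 60.0
    cycle_minutes: float = 10.0
    max_load_minutes: float = MAX_LOAD_MINUTES

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        labels = [r.name for r in self.rooms.values()]
        if len(set(labels)) != len(labels):
            raise ScenarioError("room names must be unique")
        for name, room in self.rooms.items():
            if name != room.name:
                raise ScenarioError(f"room key {name!r} != room.name {room.name!r}")
        ids = [s.id for s in self.staff]
        if len(set(ids)) != len(ids):
            raise ScenarioError("staff ids must be unique")

        for stage in self.stages.values():
            if stage.room is not None:
                if stage.room not in self.rooms:
                    raise ScenarioError(
                        f"stage {stage.name!r} references unknown room {stage.room!r}"
                    )
                room = self.rooms[stage.room]
                for at_name in stage.recipe:
                    room.attendance(at_name)

        for origin, edges in self.flow.items():
            if origin not in self.stages:
                raise FlowError(f"flow origin {origin!r} is not a stage")
            total = sum(e.probability for e in edges)
            if abs(total - 1.0) > 1e-9:
                raise FlowError(
                    f"outgoing probabilities of {origin!r} sum to {total}, not 1"
                )
            for e in edges:
                if e.to_stage != EXIT and e.to_stage not in self.stages:
                    raise FlowError(
                        f"edge {origin!r}->{e.to_stage!r} targets unknown stage"
                    )
        if self.entry_stage not in self.stages:
            raise ScenarioError(f"entry stage {self.entry_stage!r} unknown")

        for post, room in self.posts.items():
            if room not in self.rooms:
                raise ScenarioError(f"post {post!r} references unknown room {room!r}")
            members = [s for s in self.staff if s.roster.post == post]
            if len(members) != 4:
                raise ScenarioError(
                    f"post {post!r} has {len(members)} staff, need exactly 4 "
                    "for 24/7 coverage under the 12x36 regime"
                )
            offsets = sorted(s.roster.offset_hours % 48 for s in members)
            if offsets != [0, 12, 24, 36]:
                raise ScenarioError(
                    f"post {post!r}: roster offsets {offsets} do not cover 24/7"
                )
        for s in self.staff:
            if s.roster.post not in self.posts:
                raise ScenarioError(f"staff {s.id!r} on unknown post {s.roster.post!r}")

        for room in self.rooms.values():
            if room.allocation_only:
                continue
            if not any(room.required_specialty in s.specialties for s in self.staff):
                raise ScenarioError(
                    f"room {room.name!r} requires specialty "
                    f"{room.required_specialty!r} held by no staff member and is "
                    "not flagged allocation-only"
                )

    # -- convenience accessors --------------------------------------------
    def home_room(self, staff: StaffMember) -> str:
        return self.posts[staff.roster.post]

    def stage_for_room(self) -> dict[str, list[Stage]]:
        out: dict[str, list[Stage]] = {name: [] for name in self.rooms}
        for stage in self.stages.values():
            if stage.room is not None:
                out[stage.room].append(stage)
        return out

    def recipe_mean(self, stage: Stage) -> float:
        room = self.rooms[stage.room]
        return sum(room.attendance(n).mean for n in stage.recipe)

    def expected_service_minutes(self, room_name: str) -> float:
        """Static expected service duration for a room.

        Plain average of the triangular means of the stage recipes served in
        the room.  Used only as a fallback when no care has completed yet and
        the empirical average care time is undefined.
        """
        stages = [s for s in self.stages.values() if s.room == room_name]
        if not stages:
            raise ScenarioError(f"no stage served in room {room_name!r}")
        return float(np.mean([self.recipe_mean(s) for s in stages]))

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "entry_stage": self.entry_stage,
            "reallocation_minutes": self.reallocation_minutes,
            "allocation_minutes": self.allocation_minutes,
            "cycle_minutes": self.cycle_minutes,
            "max_load_minutes": self.max_load_minutes,
            "posts": dict(self.posts),
            "rooms": {
                name: {
                    "required_specialty": r.required_specialty,
                    "station_limit": r.station_limit,
                    "upper_threshold": r.upper_threshold,
                    "lower_threshold": r.lower_threshold,
                    "allocation_only": r.allocation_only,
                    "attendance_types": {
                        at.name: [at.lower, at.mode, at.upper]
                        for at in r.attendance_types
                    },
                }
                for name, r in self.rooms.items()
            },
            "stages": {
                name: {"room": s.room, "recipe": list(s.recipe)}
                for name, s in self.stages.items()
            },
            "flow": {
                origin: {e.to_stage: e.probability for e in edges}
                for origin, edges in self.flow.items()
            },
            "staff": [
                {
                    "id": s.id,
                    "specialties": sorted(s.specialties),
                    "post": s.roster.post,
                    "offset_hours": s.roster.offset_hours,
                }
                for s in self.staff
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        try:
            rooms = {
                name: Room(
                    name=name,
                    required_specialty=entry["required_specialty"],
                    station_limit=int(entry.get("station_limit", 4)),
                    upper_threshold=float(
                        entry.get("upper_threshold", 0.7 * MAX_LOAD_MINUTES)
                    ),
                    lower_threshold=float(
                        entry.get("lower_threshold", 0.3 * MAX_LOAD_MINUTES)
                    ),
                    allocation_only=bool(entry.get("allocation_only", False)),
                    attendance_types=tuple(
                        AttendanceType(at_name, *params)
                        for at_name, params in entry.get(
                            "attendance_types", {}
                        ).items()
                    ),
                )
                for name, entry in data["rooms"].items()
            }
            stages = {
                name: Stage(
                    name=name,
                    room=entry.get("room"),
                    recipe=tuple(entry.get("recipe", ())),
                )
                for name, entry in data["stages"].items()
            }
            flow = {
                origin: [
                    FlowEdge(origin, to, float(p)) for to, p in targets.items()
                ]
                for origin, targets in data["flow"].items()
            }
            staff = [
                StaffMember(
                    id=s["id"],
                    specialties=frozenset(s["specialties"]),
                    roster=ShiftRoster(s["post"], int(s["offset_hours"])),
                )
                for s in data["staff"]
            ]
        except KeyError as exc:  # pragma: no cover - error text checked in tests
            raise ScenarioError(f"missing scenario field: {exc}") from exc
        return cls(
            rooms=rooms,
            staff=staff,
            stages=stages,
            flow=flow,
            posts=dict(data["posts"]),
            entry_stage=data.get("entry_stage", "reception"),
            reallocation_minutes=float(data.get("reallocation_minutes", 10.0)),
            allocation_minutes=float(data.get("allocation_minutes", 60.0)),
            cycle_minutes=float(data.get("cycle_minutes", 10.0)),
            max_load_minutes=float(data.get("max_load_minutes", MAX_LOAD_MINUTES)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario description from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ScenarioError(f"{path}: scenario file does not contain a mapping")
    return ScenarioConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def sample_care_time(at: AttendanceType, rng: np.random.Generator) -> float:
    """Draw one care duration (minutes) from the triangular distribution."""
    if at.upper == at.lower:
        return float(at.lower)
    return float(rng.triangular(at.lower, at.mode, at.upper))


def route_after(
    flow: Mapping[str, Sequence[FlowEdge]] | "ScenarioConfig",
    stage: str,
    rng: np.random.Generator,
) -> str:
    """Sample the next stage label after completing ``stage``."""
    if isinstance(flow, ScenarioConfig):
        flow = flow.flow
    try:
        edges = flow[stage]
    except KeyError:
        raise RoutingError(f"stage {stage!r} has no outgoing edges") from None
    probs = np.array([e.probability for e in edges])
    idx = int(rng.choice(len(edges), p=probs / probs.sum()))
    return edges[idx].to_stage


# ---------------------------------------------------------------------------
# Built-in polyclinic fixture
# ---------------------------------------------------------------------------

NURSING_SPECIALTIES = frozenset(
    {"nursing", "triage-nurse", "collection-nurse", "medication-nurse", "ecg-nurse"}
)


def polyclinic(
    first_care_no_exam_to: str = "medication",
    station_limit: int = 4,
) -> ScenarioConfig:
    """Build the built-in polyclinic scenario.

    Parameters
    ----------
    first_care_no_exam_to
        Where the 31% of patients who need no exam after the first doctor
        consultation go: ``"medication"`` routes them through the medication
        split (1% of whom are released with a prescription only), ``"exit"``
        releases them directly.
    station_limit
        Maximum simultaneous care stations per room.
    """
    if first_care_no_exam_to not in ("medication", "exit"):
        raise ScenarioError("first_care_no_exam_to must be 'medication' or 'exit'")

    rooms = {
        "reception": Room(
            "reception",
            required_specialty="reception-attendant",
            station_limit=station_limit,
            attendance_types=(AttendanceType("phr_preparation", 2, 3, 5),),
        ),
        "triage": Room(
            "triage",
            required_specialty="triage-nurse",
            station_limit=station_limit,
            attendance_types=(AttendanceType("triage_process", 5, 8, 10),),
        ),
        "doctor": Room(
            "doctor",
            required_specialty="doctor",
            station_limit=station_limit,
            attendance_types=(
                AttendanceType("first_care", 5, 11, 16),
                AttendanceType("return_care", 4, 7, 10),
            ),
        ),
        "xray": Room(
            "xray",
            required_specialty="radiology-technician",
            station_limit=station_limit,
            attendance_types=(AttendanceType("xray_exam", 10, 15, 23),),
        ),
        "collection": Room(
            "collection",
            required_specialty="collection-nurse",
            station_limit=station_limit,
            attendance_types=(AttendanceType("laboratory_exams", 6, 8, 13),),
        ),
        "ecg": Room(
            "ecg",
            required_specialty="ecg-nurse",
            station_limit=station_limit,
            attendance_types=(AttendanceType("ecg_exam", 30, 45, 60),),
        ),
        "medication": Room(
            "medication",
            required_specialty="medication-nurse",
            station_limit=station_limit,
            attendance_types=(
                AttendanceType("intramuscular_injection", 3, 3.5, 5),
                AttendanceType("iv_inhalation_preparation", 0.5, 1.5, 2.5),
                AttendanceType("intravenous_medication", 40, 70, 120),
                AttendanceType("inhalation_medication", 8, 10, 13),
            ),
        ),
    }

    stages = {
        "reception": Stage("reception", "reception", ("phr_preparation",)),
        "triage": Stage("triage", "triage", ("triage_process",)),
        "doctor_first": Stage("doctor_first", "doctor", ("first_care",)),
        "doctor_return": Stage("doctor_return", "doctor", ("return_care",)),
        "xray": Stage("xray", "xray", ("xray_exam",)),
        "lab": Stage("lab", "collection", ("laboratory_exams",)),
        "ecg": Stage("ecg", "ecg", ("ecg_exam",)),
        "med_intravenous": Stage(
            "med_intravenous",
            "medication",
            ("iv_inhalation_preparation", "intravenous_medication"),
        ),
        "med_intramuscular": Stage(
            "med_intramuscular", "medication", ("intramuscular_injection",)
        ),
        "med_inhalation": Stage(
            "med_inhalation",
            "medication",
            ("iv_inhalation_preparation", "inhalation_medication"),
        ),
        # virtual branching points
        "no_exam": Stage("no_exam"),
        "after_exams": Stage("after_exams"),
        "new_exams": Stage("new_exams"),
        "new_medication": Stage("new_medication"),
    }

    def edges(origin: str, targets: dict[str, float]) -> list[FlowEdge]:
        return [FlowEdge(origin, to, p) for to, p in targets.items()]

    flow: dict[str, list[FlowEdge]] = {
        "reception": edges("reception", {"triage": 1.0}),
        "triage": edges("triage", {"doctor_first": 1.0}),
        "doctor_first": edges(
            "doctor_first",
            {"xray": 0.24, "lab": 0.37, "ecg": 0.08, "no_exam": 0.31},
        ),
        "xray": edges("xray", {"after_exams": 1.0}),
        "lab": edges("lab", {"after_exams": 1.0}),
        "ecg": edges("ecg", {"after_exams": 1.0}),
        "after_exams": edges("after_exams", {"doctor_return": 0.60, EXIT: 0.40}),
        "doctor_return": edges(
            "doctor_return", {EXIT: 0.78, "new_exams": 0.02, "new_medication": 0.20}
        ),
        "new_exams": edges(
            "new_exams", {"xray": 24 / 69, "lab": 37 / 69, "ecg": 8 / 69}
        ),
        "new_medication": edges(
            "new_medication",
            {
                "med_intravenous": 50 / 99,
                "med_intramuscular": 30 / 99,
                "med_inhalation": 19 / 99,
            },
        ),
        "med_intravenous": edges("med_intravenous", {EXIT: 1.0}),
        "med_intramuscular": edges("med_intramuscular", {EXIT: 1.0}),
        "med_inhalation": edges("med_inhalation", {EXIT: 1.0}),
    }
    if first_care_no_exam_to == "medication":
        flow["no_exam"] = edges(
            "no_exam",
            {
                EXIT: 0.01,
                "med_intravenous": 0.50,
                "med_intramuscular": 0.30,
                "med_inhalation": 0.19,
            },
        )
    else:
        flow["no_exam"] = edges("no_exam", {EXIT: 1.0})

    posts = {
        "reception-1": "reception",
        "reception-2": "reception",
        "triage-1": "triage",
        "doctor-1": "doctor",
        "doctor-2": "doctor",
        "collection-1": "collection",
        "collection-2": "collection",
        "medication-1": "medication",
        "medication-2": "medication",
        "ecg-1": "ecg",
        "xray-1": "xray",
    }
    specialty_of_post = {
        "reception": frozenset({"reception-attendant"}),
        "triage": NURSING_SPECIALTIES,
        "doctor": frozenset({"doctor"}),
        "collection": NURSING_SPECIALTIES,
        "medication": NURSING_SPECIALTIES,
        "ecg": NURSING_SPECIALTIES,
        "xray": frozenset({"radiology-technician"}),
    }
    staff = [
        StaffMember(
            id=f"{post}-{letter}",
            specialties=specialty_of_post[room],
            roster=ShiftRoster(post, offset),
        )
        for post, room in posts.items()
        for letter, offset in zip("abcd", (0, 12, 24, 36))
    ]

    return ScenarioConfig(
        rooms=rooms, staff=staff, stages=stages, flow=flow, posts=posts
    )
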