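"""Exergame and test schedules, angle→screen mappings, and sonification.

Two games drive the training: a closed-kinetic-chain squatting game (the
player holds half or deep squats to collect groups of carrots) and an
open-kinetic-chain stretching game (the player moves a hook between four
trails, matched to included knee angles of 90°, 120°, 150° and 180°, to
catch fish).  Pre/post tests prompt 10 squats (half TKA 90° / deep TKA 130°
flexion) and 10 seated stretches (TKA 135° / 180° included) in randomized
order.  Auditory feedback maps the vertical game position to pitch and
loudness; the control group plays with sound off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

FISH_TRAIL_ANGLES = (90.0, 120.0, 150.0, 180.0)   # included, lowest→highest trail
SQUAT_TARGETS_FLEXION = (90.0, 130.0)              # half, deep
STRETCH_TARGETS_INCLUDED = (135.0, 180.0)          # half ("45°" prompt), full

#: flexion depth mapped to the top of the bunny's jump
_BUNNY_MAX_FLEXION = 130.0


@dataclass
class GameEvent:
    t: float
    kind: str                      # carrot_collected | fish_caught | fish_missed | prompt_shown
    trail: int | None = None
    group: int | None = None
    ordinal: int | None = None
    prompt: str | None = None

    _KINDS = ("carrot_collected", "fish_caught", "fish_missed", "prompt_shown")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.trail is not None and self.trail not in (0, 1, 2, 3):
            raise ValueError(f"trail index {self.trail} outside 0..3")
        if self.ordinal is not None and not 1 <= self.ordinal <= 9:
            raise ValueError(f"carrot ordinal {self.ordinal} outside 1..9")


@dataclass
class ScheduleEntry:
    """One prescribed movement: hold ``target`` over ``[start, end]``."""

    start: float
    end: float
    target_deg: float
    convention: str                # "flexion" | "included"
    movement_class: str            # half_squat | deep_squat | stretch_45 | stretch_0 | fish trail
    label: str = ""

    @property
    def target_included(self) -> float:
        return self.target_deg if self.convention == "included" else 180.0 - self.target_deg


@dataclass
class ProtocolSchedule:
    game: str                      # bunny | fish | pretest_squat | pretest_stretch
    entries: list[ScheduleEntry] = field(default_factory=list)

    def __post_init__(self):
        starts = [e.start for e in self.entries]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule entries must be in non-decreasing time order")

    @property
    def span(self) -> tuple[float, float]:
        return (self.entries[0].start, self.entries[-1].end) if self.entries else (0.0, 0.0)


@dataclass
class SonificationFrame:
    position: float
    pitch_index: int
    amplitude: float
    duration: float


def bunny_schedule(
    groups: int = 12,
    carrots_per_group: int = 9,
    hold: float = 2.5,
    gap: float = 20.0,
    rng_seed: int | np.random.Generator = 0,
) -> ProtocolSchedule:
    """Squatting-game round: ``groups`` carrot groups, each collected by
    holding a (randomly half or deep) squat for ``hold`` seconds, separated
    by ``gap`` seconds of standing rest."""
    if groups < 1 or carrots_per_group < 1 or hold <= 0 or gap < 0:
        raise ValueError("schedule parameters must be positive")
    rng = np.random.default_rng(rng_seed)
    entries = []
    for g in range(groups):
        start = g * (hold + gap)
        deep = bool(rng.integers(0, 2))
        flexion = SQUAT_TARGETS_FLEXION[1] if deep else SQUAT_TARGETS_FLEXION[0]
        entries.append(
            ScheduleEntry(
                start=start,
                end=start + hold,
                target_deg=flexion,
                convention="flexion",
                movement_class="deep_squat" if deep else "half_squat",
                label=f"group_{g}",
            )
        )
    return ProtocolSchedule(game="bunny", entries=entries)


def fish_schedule(
    n_fish: int = 12,
    hold: float = 2.0,
    escape: float = 10.0,
    rng_seed: int | np.random.Generator = 0,
    spawn_gap: float = 2.0,
) -> ProtocolSchedule:
    """Stretching-game round: ``n_fish`` fish on trails drawn uniformly from
    the four trail angles.  A fish is caught after the hook holds its trail
    for ``hold`` s and escapes after ``escape`` s; spawns are spaced
    ``escape + spawn_gap`` apart so windows never overlap."""
    if n_fish < 1 or hold <= 0 or escape <= hold:
        raise ValueError("schedule parameters must be positive with escape > hold")
    rng = np.random.default_rng(rng_seed)
    entries = []
    for i in range(n_fish):
        start = i * (escape + spawn_gap)
        trail = int(rng.integers(0, 4))
        entries.append(
            ScheduleEntry(
                start=start,
                end=start + escape,
                target_deg=FISH_TRAIL_ANGLES[trail],
                convention="included",
                movement_class=f"trail_{trail}",
                label=f"fish_{i}",
            )
        )
    return ProtocolSchedule(game="fish", entries=entries)


def test_schedule(
    kind: str,
    n: int = 10,
    hold: float = 5.0,
    rng_seed: int | np.random.Generator = 0,
    transition: float = 1.0,
    rest: float = 2.0,
) -> ProtocolSchedule:
    """Pre/post test block: ``n`` prompted movements held ~``hold`` s each,
    with the two target classes in randomized order."""
    if kind not in ("pretest_squat", "pretest_stretch"):
        raise ValueError(f"unknown test kind {kind!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    entries = []
    period = transition + hold + rest
    for i in range(n):
        start = i * period + transition
        second = bool(rng.integers(0, 2))
        if kind == "pretest_squat":
            target = SQUAT_TARGETS_FLEXION[1] if second else SQUAT_TARGETS_FLEXION[0]
            conv = "flexion"
            cls = "deep_squat" if second else "half_squat"
            prompt = "deep squat" if second else "half squat"
        else:
            target = STRETCH_TARGETS_INCLUDED[1] if second else STRETCH_TARGETS_INCLUDED[0]
            conv = "included"
            cls = "stretch_0" if second else "stretch_45"
            prompt = "totally stretch (0°)" if second else "half stretch (45°)"
        entries.append(
            ScheduleEntry(start=start, end=start + hold, target_deg=target,
                          convention=conv, movement_class=cls, label=prompt)
        )
    return ProtocolSchedule(game=kind, entries=entries)


def angle_to_position(included_angle: float, game: str) -> float:
    """Map a knee angle to the vertical game position in [0, 1].

    Squat game: deeper squat → higher jump (monotone in flexion, deep-squat
    depth at the top).  Stretch game: the four trail angles 90/120/150/180°
    map affinely to 0, 1/3, 2/3, 1 (lowest → highest trail).
    """
    a = float(included_angle)
    if not 0.0 <= a <= 180.0:
        a = min(max(a, 0.0), 180.0)
    if game == "bunny":
        flexion = 180.0 - a
        return float(np.clip(flexion / _BUNNY_MAX_FLEXION, 0.0, 1.0))
    if game == "fish":
        return float(np.clip((a - FISH_TRAIL_ANGLES[0]) / 90.0, 0.0, 1.0))
    raise ValueError(f"unknown game {game!r}")


def quantize_trail(position: float) -> int:
    """Nearest trail index for a hook position; exact midpoints round to the
    lower trail."""
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must lie in [0, 1]")
    anchors = np.array([0.0, 1.0, 2.0, 3.0]) / 3.0
    dists = np.abs(anchors - position)
    best = float(dists.min())
    # ties (within float eps) go to the lower index
    return int(np.nonzero(dists <= best + 1e-12)[0][0])


def sonify(
    position: float,
    enabled: bool = True,
    n_steps: int = 25,
    duration: float = 0.15,
) -> SonificationFrame | None:
    """Auditory-feedback frame for a vertical position.

    Amplitude scales linearly from silence at the bottom to the maximum
    non-clipping volume at the top; pitch steps up a fixed monotone
    semitone ladder (default 25 chromatic steps, two octaves).  Stimuli are
    brief (0.1–0.2 s).  Returns ``None`` (silence) when feedback is off,
    i.e. for the control group.
    """
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must lie in [0, 1]")
    if not 0.1 <= duration <= 0.2:
        raise ValueError("stimulus duration must lie in [0.1, 0.2] s")
    if not enabled:
        return None
    pitch = int(np.floor(position * (n_steps - 1)))
    return SonificationFrame(
        position=float(position),
        pitch_index=min(pitch, n_steps - 1),
        amplitude=float(position),
        duration=float(duration),
    )


# ---------------------------------------------------------------------------
# JSON-lines event log I/O

_EVENT_FIELDS = ("t", "kind", "trail", "group", "ordinal", "prompt")


def write_events(path, events: list[GameEvent]) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps({k: getattr(ev, k) for k in _EVENT_FIELDS}) + "\n")


def read_events(path) -> list[GameEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                events.append(GameEvent(**{k: obj.get(k) for k in _EVENT_FIELDS}))
            except (json.JSONDecodeError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed event line ({exc})") from exc
    times = [e.t for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError(f"{path}: event times must be non-decreasing")
    return events


def schedule_to_dict(schedule: ProtocolSchedule) -> dict:
    return {"game": schedule.game, "entries": [asdict(e) for e in schedule.entries]}


def schedule_from_dict(obj: dict) -> ProtocolSchedule:
    return ProtocolSchedule(
        game=obj["game"], entries=[ScheduleEntry(**e) for e in obj["entries"]]
    )


def write_schedules(path, schedules: dict[str, ProtocolSchedule]) -> None:
    with open(path, "w") as fh:
        json.dump({k: schedule_to_dict(s) for k, s in schedules.items()}, fh, indent=1)


def read_schedules(path) -> dict[str, ProtocolSchedule]:
    with open(path) as fh:
        return {k: schedule_from_dict(v) for k, v in json.load(fh).items()}


def schedule_to_events(schedule: ProtocolSchedule) -> list[GameEvent]:
    """Serialize a schedule as prompt events (one per entry at its start)."""
    return [
        GameEvent(t=e.start, kind="prompt_shown", prompt=e.label or e.movement_class)
        for e in schedule.entries
    ]
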