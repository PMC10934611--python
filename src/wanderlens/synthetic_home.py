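"""Synthetic smart-home: labeled sensor event streams from simulated residents.

The simulator emulates the kind of ambient infrastructure used in smart-home
cognitive-assessment studies: a single-resident apartment instrumented with
52 ceiling PIR motion sensors at roughly one-meter spatial resolution, plus
door contacts and RFID-tagged everyday objects.  Simulated residents walk
the four Martino-Saltzman travel patterns — direct (efficient point-to-point
walks, typical of cognitively healthy residents), random (wandering between
arbitrary locations), pacing (back-and-forth between two spots) and lapping
(repeated closed loops); the latter three are the patterns enriched in
residents with dementia.

Each PIR is modelled as a binary presence disk (radius 0.7 m, nearest sensor
wins on overlap) that fires ``ON`` when the resident enters its field and
``OFF`` on exit, producing discrete event streams in the same line dialect
the ingestion module parses.  The generator is fully deterministic under a
seed and writes per-subject event files, the sensor-position table, and a
ground-truth manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .sensing_io import SensorPositionTable

PATTERN_KINDS = ("direct", "random", "pacing", "lapping")

#: Default walking-speed model: mean 0.8 m/s, sd 0.2, clipped to a plausible
#: indoor range — far below the 15 m/s noise gate, so clean synthetic data
#: survive preprocessing intact.
SPEED_MEAN, SPEED_SD = 0.8, 0.2
SPEED_CLIP = (0.1, 2.0)

BASE_TIME = datetime(2024, 1, 1, 8, 0, 0)


@dataclass
class HomeLayout:
    """Virtual apartment: bounds, PIR grid, door and object sensors."""

    bounds: tuple[float, float] = (10.0, 9.0)
    motion_sensors: list[tuple[str, float, float]] = field(default_factory=list)
    door_sensors: list[tuple[str, float, float]] = field(default_factory=list)
    object_sensors: list[tuple[str, float, float]] = field(default_factory=list)
    radius: float = 0.7  # PIR detection-disk radius, m

    @property
    def centroid(self) -> tuple[float, float]:
        xs = [x for _, x, _ in self.motion_sensors]
        ys = [y for _, _, y in self.motion_sensors]
        return sum(xs) / len(xs), sum(ys) / len(ys)

    def all_sensors(self):
        return self.motion_sensors + self.door_sensors + self.object_sensors

    def to_position_table(self) -> SensorPositionTable:
        table = SensorPositionTable()
        for s_id, x, y in self.all_sensors():
            table[s_id] = (x, y)
        return table

    def write_position_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sensor_id,x,y\n")
            for s_id, x, y in self.all_sensors():
                fh.write(f"{s_id},{x:.2f},{y:.2f}\n")


def make_layout(
    bounds: tuple[float, float] = (10.0, 9.0),
    n_motion: int = 52,
    spacing_m: float = 1.0,
    radius_m: float = 0.7,
    n_doors: int = 3,
    n_objects: int = 5,
    seed: int = 0,
) -> HomeLayout:
    """Build the virtual apartment's sensor layout.

    Motion sensors fill a regular grid at ``spacing_m`` starting one meter
    inside the walls, truncated to ``n_motion`` ids in row-major order; door
    and object sensors sit at deterministic wall/fixture positions.  Fully
    deterministic for given parameters (the seed is reserved for optional
    placement jitter and is recorded for provenance).
    """
    w, h = bounds
    if spacing_m > min(w, h):
        raise ValueError("sensor spacing exceeds the home bounds")
    n_cols = int((w - 2.0) / spacing_m) + 1
    n_rows = int((h - 2.0) / spacing_m) + 1
    if n_cols * n_rows < n_motion:
        raise ValueError(
            f"grid of {n_cols}x{n_rows} cannot host {n_motion} motion sensors"
        )
    motion = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if k >= n_motion:
                break
            k += 1
            motion.append((f"M{k:03d}", 1.0 + c * spacing_m, 1.0 + r * spacing_m))
    doors = [
        (f"D{i + 1:03d}", x, y)
        for i, (x, y) in enumerate(
            [(0.3, h / 2), (w / 2, 0.3), (w - 0.3, h / 2), (w / 2, h - 0.3), (0.3, 0.3)][:n_doors]
        )
    ]
    objects = [
        (f"I{i + 1:03d}", x, y)
        for i, (x, y) in enumerate(
            [
                (1.2, h - 1.2),
                (2.2, h - 1.2),
                (w - 1.2, 1.2),
                (w - 1.2, h - 1.2),
                (1.2, 1.2),
                (w / 2, h / 2),
            ][:n_objects]
        )
    ]
    return HomeLayout(
        bounds=bounds,
        motion_sensors=motion,
        door_sensors=doors,
        object_sensors=objects,
        radius=radius_m,
    )


# --------------------------------------------------------------------------
# movement patterns


@dataclass
class MovementPattern:
    """One episode's travel plan: kind, waypoints and speed/dwell models."""

    kind: str
    waypoints: list[tuple[float, float]]
    speed_mean: float = SPEED_MEAN
    speed_sd: float = SPEED_SD
    dwell_mean: float = 1.0  # s paused at each waypoint
    repetitions: int = 1

    def __post_init__(self):
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")


def _interior_point(layout: HomeLayout, rng: np.random.Generator) -> tuple[float, float]:
    w, h = layout.bounds
    return (rng.uniform(1.0, w - 1.0), rng.uniform(1.0, h - 1.0))


def sample_pattern(kind: str, layout: HomeLayout, rng: np.random.Generator) -> MovementPattern:
    """Draw a concrete movement plan of the requested kind."""
    if kind == "direct":
        a = _interior_point(layout, rng)
        while True:
            b = _interior_point(layout, rng)
            if math.dist(a, b) > 3.0:
                break
        return MovementPattern(kind="direct", waypoints=[a, b])
    if kind == "random":
        n = int(rng.integers(6, 12))
        return MovementPattern(
            kind="random", waypoints=[_interior_point(layout, rng) for _ in range(n)]
        )
    if kind == "pacing":
        a = _interior_point(layout, rng)
        angle = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(2.5, 4.5)
        w, h = layout.bounds
        b = (
            min(max(a[0] + length * math.cos(angle), 1.0), w - 1.0),
            min(max(a[1] + length * math.sin(angle), 1.0), h - 1.0),
        )
        return MovementPattern(
            kind="pacing", waypoints=[a, b], repetitions=int(rng.integers(5, 9))
        )
    if kind == "lapping":
        cx, cy = _interior_point(layout, rng)
        radius = rng.uniform(1.2, 2.2)
        w, h = layout.bounds
        n_nodes = int(rng.integers(4, 7))
        loop = []
        for j in range(n_nodes):
            ang = 2 * math.pi * j / n_nodes
            loop.append(
                (
                    min(max(cx + radius * math.cos(ang), 1.0), w - 1.0),
                    min(max(cy + radius * math.sin(ang), 1.0), h - 1.0),
                )
            )
        return MovementPattern(kind="lapping", waypoints=loop, repetitions=int(rng.integers(3, 6)))
    raise ValueError(f"unknown pattern kind {kind!r}")


def _waypoint_sequence(pattern: MovementPattern) -> list[tuple[float, float]]:
    wp = pattern.waypoints
    if pattern.kind == "pacing":
        if len(wp) != 2:
            raise ValueError("pacing needs exactly 2 alternating waypoints")
        seq = [wp[0]]
        for leg in range(pattern.repetitions):
            seq.append(wp[1] if leg % 2 == 0 else wp[0])
        return seq
    if pattern.kind == "lapping":
        if len(wp) < 3:
            raise ValueError("lapping needs a closed loop of >= 3 waypoints")
        seq = [wp[0]]
        for _ in range(pattern.repetitions):
            seq.extend(wp[1:])
            seq.append(wp[0])
        return seq
    return list(wp)


def simulate_path(
    pattern: MovementPattern,
    layout: HomeLayout,
    dt: float = 0.5,
    seed: int = 0,
    t0: float = 0.0,
) -> np.ndarray:
    """Continuous resident path as an (n, 3) array of (x, y, t).

    Piecewise-linear motion between the pattern's waypoints at a per-leg
    speed drawn from the walking-speed model, with an exponential dwell
    pause (capped at 10 s) at each waypoint.  Time is strictly increasing
    and sampled every ``dt`` seconds along each leg.
    """
    rng = np.random.default_rng(seed)
    seq = _waypoint_sequence(pattern)
    pts: list[tuple[float, float, float]] = []
    t = t0
    x, y = seq[0]
    pts.append((x, y, t))
    for target in seq[1:]:
        dwell = min(float(rng.exponential(pattern.dwell_mean)), 10.0)
        if dwell > dt:
            t += dwell
            pts.append((x, y, t))
        speed = float(np.clip(rng.normal(pattern.speed_mean, pattern.speed_sd), *SPEED_CLIP))
        dist = math.dist((x, y), target)
        if dist == 0:
            continue
        n_steps = max(int(math.ceil(dist / (speed * dt))), 1)
        for s in range(1, n_steps + 1):
            f = s / n_steps
            t += dt
            pts.append((x + f * (target[0] - x), y + f * (target[1] - y), t))
        x, y = target
    return np.array(pts)


# --------------------------------------------------------------------------
# event emission


def _format_event(t: datetime, s_id: str, value: str) -> str:
    return f"{t.strftime('%Y-%m-%d %H:%M:%S.%f')}\t{s_id}\t{value}"


def emit_events(
    path: np.ndarray,
    layout: HomeLayout,
    seed: int = 0,
    interactions: list[tuple[float, str]] = (),
    base_time: datetime = BASE_TIME,
) -> list[str]:
    """Discrete sensor event lines for one continuous path.

    A motion sensor fires ``ON`` when the resident enters its detection disk
    (nearest sensor wins where disks overlap) and ``OFF`` on exit — no
    re-triggering while the resident stays inside one field.  Optional
    ``interactions`` are (time-offset, sensor-id) pairs that inject a
    door ``OPEN``/``CLOSE`` or object ``PRESENT``/``ABSENT`` pair.
    Timestamps are non-decreasing.
    """
    sensors = layout.motion_sensors
    pos = np.array([(x, y) for _, x, y in sensors])
    ids = [s for s, _, _ in sensors]

    events: list[tuple[float, str, str]] = []
    active: str | None = None
    for x, y, t in path:
        d = np.hypot(pos[:, 0] - x, pos[:, 1] - y)
        nearest = int(np.argmin(d))
        inside = d[nearest] <= layout.radius
        current = ids[nearest] if inside else None
        if current != active:
            if active is not None:
                events.append((t, active, "OFF"))
            if current is not None:
                events.append((t, current, "ON"))
            active = current
    if active is not None:
        events.append((path[-1, 2] + 0.5, active, "OFF"))

    for t_off, s_id in interactions:
        if s_id.startswith("D"):
            on_v, off_v = "OPEN", "CLOSE"
        else:
            on_v, off_v = "PRESENT", "ABSENT"
        events.append((t_off, s_id, on_v))
        events.append((t_off + 2.0, s_id, off_v))

    events.sort(key=lambda e: e[0])
    return [
        _format_event(base_time + timedelta(seconds=float(t)), s_id, v)
        for t, s_id, v in events
    ]


# --------------------------------------------------------------------------
# cohorts


#: Pattern mixtures per class: healthy residents walk mostly direct paths;
#: residents with dementia are enriched in random/pacing/lapping travel.
DEFAULT_CH_MIXTURE = {"direct": 0.9, "random": 0.1}
DEFAULT_PWD_MIXTURE = {"direct": 0.1, "random": 0.3, "pacing": 0.3, "lapping": 0.3}


@dataclass
class CohortSpec:
    """Study-population recipe for the synthetic cohort."""

    n_ch: int = 40
    n_pwd: int = 10
    ch_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CH_MIXTURE))
    pwd_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PWD_MIXTURE))
    episodes_mean: float = 12.0
    episodes_sd: float = 2.0
    episodes_min: int = 3
    inter_episode_gap_s: tuple[float, float] = (600.0, 1200.0)
    interaction_prob: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for mix in (self.ch_mixture, self.pwd_mixture):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"pattern mixture must sum to 1, got {total}")
            for k in mix:
                if k not in PATTERN_KINDS:
                    raise ValueError(f"unknown pattern kind {k!r}")


def _draw_pattern_kind(mixture: dict[str, float], rng: np.random.Generator) -> str:
    kinds = sorted(mixture)
    probs = np.array([mixture[k] for k in kinds])
    return str(rng.choice(kinds, p=probs))


def simulate_subject(
    label: str,
    mixture: dict[str, float],
    layout: HomeLayout,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Event lines plus per-episode ground-truth pattern kinds for one subject."""
    n_episodes = max(spec.episodes_min, int(round(rng.normal(spec.episodes_mean, spec.episodes_sd))))
    lines: list[str] = []
    kinds: list[str] = []
    t_cursor = 0.0
    door_ids = [s for s, _, _ in layout.door_sensors]
    object_ids = [s for s, _, _ in layout.object_sensors]
    for _ in range(n_episodes):
        kind = _draw_pattern_kind(mixture, rng)
        kinds.append(kind)
        pattern = sample_pattern(kind, layout, rng)
        path = simulate_path(
            pattern, layout, dt=0.5, seed=int(rng.integers(2**31)), t0=t_cursor
        )
        interactions = []
        if door_ids and rng.uniform() < spec.interaction_prob:
            interactions.append((float(path[0, 2]) + 1.0, str(rng.choice(door_ids))))
        if object_ids and rng.uniform() < spec.interaction_prob:
            mid = float(path[len(path) // 2, 2])
            interactions.append((mid, str(rng.choice(object_ids))))
        lines.extend(
            emit_events(path, layout, seed=spec.seed, interactions=interactions)
        )
        t_cursor = float(path[-1, 2]) + rng.uniform(*spec.inter_episode_gap_s)
    return lines, kinds


def generate_cohort(
    spec: CohortSpec, layout: HomeLayout, out_dir
) -> "pd.DataFrame":
    """Write one CASAS-dialect event file per synthetic subject plus a manifest.

    Outputs under ``out_dir``: ``<subject>.txt`` event streams,
    ``positions.csv`` (the sensor table), and ``manifest.csv`` with columns
    ``subject_id, label, n_episodes, pattern_kinds`` (semicolon-joined ground
    truth).  Deterministic under ``spec.seed``.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout.write_position_csv(out_dir / "positions.csv")

    rng = np.random.default_rng(spec.seed)
    rows = []
    roster = [("CH", i, spec.ch_mixture) for i in range(spec.n_ch)] + [
        ("PwD", i, spec.pwd_mixture) for i in range(spec.n_pwd)
    ]
    for label, i, mixture in roster:
        subject = f"{label.lower()}{i + 1:03d}"
        lines, kinds = simulate_subject(label, mixture, layout, spec, rng)
        with open(out_dir / f"{subject}.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
        rows.append(
            {
                "subject_id": subject,
                "label": label,
                "n_episodes": len(kinds),
                "pattern_kinds": ";".join(kinds),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
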