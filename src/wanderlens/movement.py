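"""Locomotion episode segmentation and visual trajectory encoding.

A position history is split into locomotion episodes wherever no sensor
fires for more than the segmentation threshold ``Ts`` (the study varies Ts
over 60–480 s).  Each episode is rendered as a small annotated RGB image:
the walked path is a blue line whose shade encodes speed (lighter = faster)
and whose thickness grows with repeated traversal; overlaid single-pixel
markers flag events of interest — turn direction at sensor positions,
door/object interactions, stationarity over 2 s, and sharp (>= 90 degree)
direction changes.  These images are the input to the downstream shape and
visual-word feature extractors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sensing_io import PositionHistory, PositionRecord, SensorPositionTable

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# types


@dataclass
class Trajectory:
    """One locomotion episode with derived per-step kinematics.

    ``speeds`` and ``headings`` have length ``len(records) - 1``; step ``i``
    connects record ``i`` to record ``i + 1``.  Headings are degrees in the
    y-up metric frame (0 = +x, 90 = +y).
    """

    records: list[PositionRecord]
    subject_id: str = ""
    label: str = "unknown"
    speeds: np.ndarray | None = None
    headings: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(r.x, r.y) for r in self.records], dtype=float)

    @property
    def times(self) -> np.ndarray:
        t0 = self.records[0].t
        return np.array([(r.t - t0).total_seconds() for r in self.records])

    @property
    def start(self):
        return self.records[0].t

    @property
    def end(self):
        return self.records[-1].t


@dataclass(frozen=True)
class CanvasSpec:
    """Metric-to-raster mapping for trajectory images.

    The metric frame is y-up; raster row 0 is the top of the image, so
    ``row = height_px - 1 - round((y - y_min) / meters_per_pixel)`` and
    ``col = round((x - x_min) / meters_per_pixel)``.
    """

    width_px: int = 130
    height_px: int = 100
    meters_per_pixel: float = 0.1
    x_min: float = 0.0
    y_min: float = 0.0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.meters_per_pixel <= 0:
            raise ValueError("meters_per_pixel must be positive")

    @classmethod
    def fit(
        cls,
        table_or_bbox: SensorPositionTable | tuple[float, float, float, float],
        width_px: int = 130,
        height_px: int = 100,
        margin_px: int = 1,
    ) -> "CanvasSpec":
        """Derive the scale from a sensor table's bounding box plus a margin."""
        if isinstance(table_or_bbox, SensorPositionTable):
            x0, y0, x1, y1 = table_or_bbox.bounding_box()
        else:
            x0, y0, x1, y1 = table_or_bbox
        span_x = max(x1 - x0, 1e-9)
        span_y = max(y1 - y0, 1e-9)
        s = max(
            span_x / max(width_px - 1 - 2 * margin_px, 1),
            span_y / max(height_px - 1 - 2 * margin_px, 1),
        )
        return cls(
            width_px=width_px,
            height_px=height_px,
            meters_per_pixel=s,
            x_min=x0 - margin_px * s,
            y_min=y0 - margin_px * s,
        )

    def to_pixel(self, x: float, y: float) -> tuple[int, int]:
        """Map metric (x, y) to (row, col); raises if outside the canvas."""
        col = int(round((x - self.x_min) / self.meters_per_pixel))
        row = self.height_px - 1 - int(round((y - self.y_min) / self.meters_per_pixel))
        if not (0 <= row < self.height_px and 0 <= col < self.width_px):
            raise ValueError(
                f"point ({x}, {y}) maps to pixel ({row}, {col}) outside the "
                f"{self.height_px}x{self.width_px} canvas"
            )
        return row, col


def bresenham_line(r0: int, c0: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical midpoint (Bresenham) line: integer pixels from (r0,c0) to (r1,c1)."""
    rr, cc = [], []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    r, c = r0, c0
    if dc >= dr:
        err = dc // 2
        for _ in range(dc + 1):
            rr.append(r)
            cc.append(c)
            err -= dr
            if err < 0:
                r += sr
                err += dc
            c += sc
    else:
        err = dr // 2
        for _ in range(dr + 1):
            rr.append(r)
            cc.append(c)
            err -= dc
            if err < 0:
                c += sc
                err += dr
            r += sr
    return np.asarray(rr), np.asarray(cc)


@dataclass(frozen=True)
class Palette:
    """Colors for the trajectory ramp and event-of-interest markers.

    Path-ramp endpoints must keep BT.601 luminance above the 0.5
    binarization threshold so the walked path survives as foreground;
    stationary (red) and sharp-angle (black) markers fall below it and
    punch holes into the binary path mask.
    """

    ramp_slow: tuple[int, int, int] = (100, 150, 200)
    ramp_fast: tuple[int, int, int] = (200, 230, 255)
    v_cap: float = 3.0  # m/s mapped to the lightest ramp shade
    left_turn: tuple[int, int, int] = (139, 69, 19)  # brown
    center_ward: tuple[int, int, int] = (159, 0, 255)  # vivid violet
    right_turn: tuple[int, int, int] = (255, 255, 255)  # white
    stationary: tuple[int, int, int] = (255, 0, 0)  # red
    sharp_angle: tuple[int, int, int] = (0, 0, 0)  # black
    door: tuple[int, int, int] = (0, 200, 0)
    object_: tuple[int, int, int] = (255, 165, 0)
    background: tuple[int, int, int] = (0, 0, 0)

    def ramp(self, speed: float) -> tuple[int, int, int]:
        """Speed-shaded path color: linear slow->fast ramp, clamped at v_cap."""
        f = min(max(speed, 0.0), self.v_cap) / self.v_cap
        return tuple(
            int(round(a + f * (b - a))) for a, b in zip(self.ramp_slow, self.ramp_fast)
        )


@dataclass
class TrajectoryImage:
    """Rendered episode: RGB raster plus per-pixel traversal bookkeeping."""

    rgb: np.ndarray  # (H, W, 3) uint8
    traversal_count: np.ndarray  # (H, W) int
    last_speed: np.ndarray  # (H, W) float, m/s

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


# --------------------------------------------------------------------------
# segmentation and kinematics


def segment_trajectories(
    history: PositionHistory,
    ts: float = 60.0,
    min_records: int = 3,
    return_discarded: bool = False,
):
    """Split a position history into locomotion episodes at sensing gaps.

    A gap strictly greater than ``ts`` seconds ends the current episode (a
    gap of exactly ``ts`` stays inside one episode).  Fragments with fewer
    than ``min_records`` records cannot support a turn angle and are
    discarded; with ``return_discarded=True`` they are returned as a second
    list so callers can verify the split is a partition.
    """
    if ts <= 0:
        raise ValueError("segmentation threshold must be positive")
    fragments: list[list[PositionRecord]] = []
    current: list[PositionRecord] = []
    for rec in history.records:
        if current and (rec.t - current[-1].t).total_seconds() > ts:
            fragments.append(current)
            current = []
        current.append(rec)
    if current:
        fragments.append(current)

    episodes, discarded = [], []
    for frag in fragments:
        if len(frag) >= min_records:
            episodes.append(
                Trajectory(records=frag, subject_id=history.subject_id, label=history.label)
            )
        else:
            discarded.append(frag)
    if discarded:
        logger.debug("discarded %d fragment(s) with < %d records", len(discarded), min_records)
    if return_discarded:
        return episodes, discarded
    return episodes


def derive_kinematics(traj: Trajectory) -> Trajectory:
    """Attach per-step speeds (m/s) and headings (degrees, y-up frame).

    Zero-length steps inherit the previous step's heading; a zero time step
    yields infinite speed (such records should not survive the noise filter).
    """
    if len(traj) < 2:
        raise ValueError("kinematics need at least 2 records")
    xy = traj.xy
    t = traj.times
    d = np.diff(xy, axis=0)
    dist = np.hypot(d[:, 0], d[:, 1])
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        speeds = np.where(dt > 0, dist / np.where(dt > 0, dt, 1.0), np.where(dist > 0, np.inf, 0.0))
    headings = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    for i in range(len(headings)):
        if dist[i] == 0:
            headings[i] = headings[i - 1] if i > 0 else 0.0
    traj.speeds = speeds
    traj.headings = headings
    if np.isinf(speeds).any():
        logger.warning("trajectory contains steps with zero duration (infinite speed)")
    return traj


def _require_kinematics(traj: Trajectory) -> None:
    if traj.speeds is None or traj.headings is None:
        raise ValueError("call derive_kinematics first")


def detect_stationary(traj: Trajectory, dwell_min: float = 2.0) -> set[int]:
    """Indices where the resident dwells at one spot for more than ``dwell_min`` s.

    A dwell is a maximal run of records with identical coordinates; the run's
    first index is marked when its total duration strictly exceeds the
    threshold (a dwell of exactly ``dwell_min`` is not marked).
    """
    _require_kinematics(traj)
    marked: set[int] = set()
    xy = traj.xy
    t = traj.times
    i = 0
    n = len(traj)
    while i < n - 1:
        j = i
        while j + 1 < n and xy[j + 1, 0] == xy[i, 0] and xy[j + 1, 1] == xy[i, 1]:
            j += 1
        if j > i and (t[j] - t[i]) > dwell_min:
            marked.add(i)
        i = max(j, i + 1)
    return marked


def heading_change(h_in: float, h_out: float) -> float:
    """Absolute heading change in degrees, wrapped to [0, 180]."""
    d = abs(h_out - h_in) % 360.0
    return 360.0 - d if d > 180.0 else d


def detect_sharp_angles(traj: Trajectory, theta_min: float = 90.0) -> set[int]:
    """Interior indices with an absolute direction change >= ``theta_min`` degrees."""
    _require_kinematics(traj)
    marked: set[int] = set()
    for i in range(1, len(traj) - 1):
        if heading_change(traj.headings[i - 1], traj.headings[i]) >= theta_min:
            marked.add(i)
    return marked


def classify_turn_direction(
    traj: Trajectory,
    i: int,
    layout_centroid: tuple[float, float],
    turn_min: float = 30.0,
    center_tol: float = 30.0,
) -> str:
    """Classify the turn at interior record ``i``: left / center_ward / right / none.

    Sub-threshold turns (< ``turn_min`` degrees) are ``none``.  A turn whose
    outgoing heading points within ``center_tol`` degrees of the direction to
    the home's layout centroid is ``center_ward``; otherwise the sign of the
    cross product of incoming and outgoing step vectors (y-up frame)
    separates left (positive) from right (negative).
    """
    _require_kinematics(traj)
    if not (0 < i < len(traj) - 1):
        raise IndexError("turn classification needs an interior record index")
    h_in, h_out = traj.headings[i - 1], traj.headings[i]
    if heading_change(h_in, h_out) < turn_min:
        return "none"
    x, y = traj.records[i].x, traj.records[i].y
    to_center = math.degrees(math.atan2(layout_centroid[1] - y, layout_centroid[0] - x))
    if heading_change(h_out, to_center) <= center_tol:
        return "center_ward"
    cross = math.sin(math.radians(h_out - h_in))
    return "left" if cross > 0 else "right"


# --------------------------------------------------------------------------
# rasterization


MAX_LINE_WIDTH_PX = 3  # cap so heavy pacing cannot flood a small canvas


def _thicken_offsets(r0, c0, r1, c1, width):
    """Perpendicular unit offsets used to widen a step's line."""
    dr, dc = r1 - r0, c1 - c0
    if dr == 0 and dc == 0:
        perp = (0, 1)
    elif abs(dr) >= abs(dc):
        perp = (0, 1)
    else:
        perp = (1, 0)
    offsets = [(0, 0)]
    if width >= 2:
        offsets.append(perp)
    if width >= 3:
        offsets.append((-perp[0], -perp[1]))
    return offsets


def rasterize_trajectory(
    traj: Trajectory,
    canvas: CanvasSpec,
    palette: Palette | None = None,
    stationary: set[int] | None = None,
    sharp_angles: set[int] | None = None,
    turn_directions: dict[int, str] | None = None,
    interactions: Sequence[PositionRecord] = (),
) -> TrajectoryImage:
    """Render one episode as an annotated RGB image.

    Each step is drawn as a Bresenham line colored by the speed ramp
    (lighter = faster).  Per-pixel traversal counts grow with repeated
    coverage; the rendered line width is ``min(count, 3)`` px and repeated
    coverage overwrites the pixel with the latest step's speed shade.
    Markers are stamped last as single pixels in a fixed z-order — turn
    points, interaction markers, stationary, sharp angle — so later layers
    win.  A trajectory coordinate outside the canvas is a fatal error.
    """
    _require_kinematics(traj)
    palette = palette or Palette()
    h, w = canvas.height_px, canvas.width_px
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[:, :] = palette.background
    count = np.zeros((h, w), dtype=int)
    last_speed = np.zeros((h, w), dtype=float)

    try:
        pixels = [canvas.to_pixel(r.x, r.y) for r in traj.records]
    except ValueError as exc:
        raise ValueError(f"trajectory leaves the canvas: {exc}") from exc

    for i in range(len(pixels) - 1):
        (r0, c0), (r1, c1) = pixels[i], pixels[i + 1]
        rr, cc = bresenham_line(r0, c0, r1, c1)
        speed = float(traj.speeds[i])
        color = palette.ramp(speed)
        # skip the shared start pixel of every step after the first so one
        # pass over the path does not double-count junction pixels
        start = 1 if i > 0 and (rr[0], cc[0]) == pixels[i] else 0
        for r, c in zip(rr[start:], cc[start:]):
            count[r, c] += 1
            last_speed[r, c] = speed
            width = min(count[r, c], MAX_LINE_WIDTH_PX)
            for dr, dc in _thicken_offsets(r0, c0, r1, c1, width):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    rgb[r2, c2] = color

    marker_color = {
        "left": palette.left_turn,
        "center_ward": palette.center_ward,
        "right": palette.right_turn,
    }
    for i, direction in sorted((turn_directions or {}).items()):
        if direction in marker_color:
            r, c = pixels[i]
            rgb[r, c] = marker_color[direction]
    for rec in interactions:
        r, c = canvas.to_pixel(rec.x, rec.y)
        rgb[r, c] = palette.door if rec.category == "door" else palette.object_
    for i in sorted(stationary or ()):
        r, c = pixels[i]
        rgb[r, c] = palette.stationary
    for i in sorted(sharp_angles or ()):
        r, c = pixels[i]
        rgb[r, c] = palette.sharp_angle

    return TrajectoryImage(rgb=rgb, traversal_count=count, last_speed=last_speed)


def encode_trajectory_image(
    traj: Trajectory,
    canvas: CanvasSpec,
    palette: Palette | None = None,
    layout_centroid: tuple[float, float] | None = None,
    interactions: Sequence[PositionRecord] = (),
    dwell_min: float = 2.0,
    theta_min: float = 90.0,
    turn_min: float = 30.0,
    center_tol: float = 30.0,
) -> TrajectoryImage:
    """Run all event-of-interest detectors and rasterize one episode."""
    if traj.speeds is None:
        derive_kinematics(traj)
    stationary = detect_stationary(traj, dwell_min=dwell_min)
    sharp = detect_sharp_angles(traj, theta_min=theta_min)
    turns: dict[int, str] = {}
    if layout_centroid is not None:
        for i in range(1, len(traj) - 1):
            d = classify_turn_direction(
                traj, i, layout_centroid, turn_min=turn_min, center_tol=center_tol
            )
            if d != "none":
                turns[i] = d
    return rasterize_trajectory(
        traj,
        canvas,
        palette,
        stationary=stationary,
        sharp_angles=sharp,
        turn_directions=turns,
        interactions=interactions,
    )


# --------------------------------------------------------------------------
# color conversions

BT601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: TrajectoryImage | np.ndarray) -> np.ndarray:
    """BT.601 luminance in [0, 1]: 0.299 R + 0.587 G + 0.114 B."""
    rgb = img.rgb if isinstance(img, TrajectoryImage) else np.asarray(img)
    return (rgb.astype(float) / 255.0) @ BT601


def to_binary(gray: np.ndarray, thr: float = 0.5) -> np.ndarray:
    """Foreground mask: 1 where luminance is strictly greater than ``thr``."""
    return (np.asarray(gray) > thr).astype(np.uint8)


# --------------------------------------------------------------------------
# episode export


def save_episode_png(img: TrajectoryImage, path) -> None:
    from PIL import Image

    Image.fromarray(img.rgb, mode="RGB").save(path)


def episode_metadata(traj: Trajectory, episode_index: int) -> dict:
    return {
        "subject_id": traj.subject_id,
        "episode": episode_index,
        "label": traj.label,
        "start": traj.records[0].t.isoformat(),
        "end": traj.records[-1].t.isoformat(),
        "n_records": len(traj),
    }


def save_episode_sidecar(traj: Trajectory, episode_index: int, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(episode_metadata(traj, episode_index), fh, indent=2)
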