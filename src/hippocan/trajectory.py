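"""Synthetic arena trajectories, noisy odometry, and boundary-contact events.

The simulated robot roams a bounded rectangular arena with per-step random
speed and heading increments, emulating a rat's irregular free exploration.
Trajectories are exchanged as delimited-text files with columns
``t,x,y,speed,heading``.

Conventions
-----------
* Arena origin is the lower-left corner; x grows east, y grows north.
* Headings are radians in (-pi, pi], counter-clockwise from the +x axis.
* ``speed[i]`` and ``heading[i]`` describe the motion carrying the robot from
  sample ``i`` to sample ``i+1``; the final sample repeats the last values so
  all columns have equal length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "TrajectorySeries",
    "BoundaryEvent",
    "generate_random_walk",
    "simulate_odometry",
    "detect_boundary_events",
    "write_trajectory",
    "read_trajectory",
    "write_boundary_events",
    "read_boundary_events",
    "TrajectoryFormatError",
]

TRAJECTORY_COLUMNS = ("t", "x", "y", "speed", "heading")


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file violates the on-disk contract."""


def wrap_angle(a):
    """Map angles to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class Arena:
    """Rectangular bounded arena with the origin at the lower-left corner."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("arena width and height must be positive")

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.width + self.height)

    def contains(self, xy, margin: float = 0.0) -> np.ndarray:
        """Element-wise containment test for an (N, 2) array of positions."""
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= -margin)
            & (xy[:, 0] <= self.width + margin)
            & (xy[:, 1] >= -margin)
            & (xy[:, 1] <= self.height + margin)
        )

    def perimeter_segments(self, segment_length: float) -> np.ndarray:
        """Split the perimeter into near-equal segments, walking counter-
        clockwise from the origin corner.

        Returns an (n_segments, 2, 2) array of segment endpoints. The number
        of segments is ``round(perimeter / segment_length)`` and must be at
        least 4.
        """
        if segment_length <= 0:
            raise ValueError("segment_length must be positive")
        n_seg = int(round(self.perimeter / segment_length))
        if n_seg < 4:
            raise ValueError(
                "segment_length must divide the perimeter into >= 4 segments"
            )
        w, h = self.width, self.height
        corners = np.array([[0, 0], [w, 0], [w, h], [0, h], [0, 0]], dtype=float)
        # arc-length positions of the segment boundaries along the perimeter
        s = np.linspace(0.0, self.perimeter, n_seg + 1)
        pts = np.empty((n_seg + 1, 2))
        edge_len = np.array([w, h, w, h])
        edge_start = np.concatenate([[0.0], np.cumsum(edge_len)])
        for i, si in enumerate(s):
            e = min(np.searchsorted(edge_start, si, side="right") - 1, 3)
            frac = (si - edge_start[e]) / edge_len[e]
            pts[i] = corners[e] + frac * (corners[e + 1] - corners[e])
        return np.stack([pts[:-1], pts[1:]], axis=1)


@dataclass
class TrajectorySeries:
    """Timestamped ground-truth motion of the simulated robot."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray
    heading: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = len(self.t)
        if any(len(a) != n for a in (self.x, self.y, self.speed, self.heading)):
            raise ValueError("all trajectory columns must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise TrajectoryFormatError("time column must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        if len(self) < 2:
            raise ValueError("need at least two samples to define dt")
        return float(self.t[1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of positions."""
        return np.stack([self.x, self.y], axis=1)

    @property
    def velocities(self) -> np.ndarray:
        """(N, 2) array of per-step velocity vectors ``speed * u(heading)``."""
        return self.speed[:, None] * np.stack(
            [np.cos(self.heading), np.sin(self.heading)], axis=1
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "speed": self.speed,
                "heading": self.heading,
            }
        )

    def equals(self, other: "TrajectorySeries") -> bool:
        return all(
            np.array_equal(getattr(self, c), getattr(other, c))
            for c in TRAJECTORY_COLUMNS
        )


@dataclass(frozen=True)
class BoundaryEvent:
    """A single entry of the wall-sensing band of one perimeter segment."""

    t: float
    segment_id: int
    cx: float
    cy: float


def generate_random_walk(
    arena: Arena,
    duration: float,
    dt: float = 0.1,
    speed_range: tuple[float, float] = (0.0, 0.5),
    heading_step_range: tuple[float, float] = (-np.pi / 2, np.pi / 2),
    seed: int | None = None,
    start: tuple[float, float] | None = None,
) -> TrajectorySeries:
    """Random roam inside the arena.

    Each step draws a speed uniformly from ``speed_range`` and a heading
    increment uniformly from ``heading_step_range``; the position advances by
    ``speed * dt`` along the new heading. Whenever the step would leave the
    arena, the heading is resampled uniformly among directions that keep the
    robot inside (the speed draw is kept, so the speed distribution is
    unaffected by wall handling).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if speed_range[0] < 0 or speed_range[1] < speed_range[0]:
        raise ValueError("speed_range must be a non-negative interval")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    t = dt * np.arange(n_steps + 1)
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    speed = np.empty(n_steps + 1)
    heading = np.empty(n_steps + 1)
    pos = (
        np.array(start, dtype=float)
        if start is not None
        else np.array([arena.width / 2.0, arena.height / 2.0])
    )
    if not arena.contains(pos)[0]:
        raise ValueError("start position lies outside the arena")
    th = rng.uniform(-np.pi, np.pi)
    for i in range(n_steps):
        v = rng.uniform(*speed_range)
        th = wrap_angle(th + rng.uniform(*heading_step_range))
        step = v * dt * np.array([np.cos(th), np.sin(th)])
        tries = 0
        while not arena.contains(pos + step)[0]:
            th = rng.uniform(-np.pi, np.pi)
            step = v * dt * np.array([np.cos(th), np.sin(th)])
            tries += 1
            if tries > 1000:  # pragma: no cover - arena smaller than one step
                raise RuntimeError("cannot keep the walk inside the arena")
        x[i], y[i] = pos
        speed[i], heading[i] = v, th
        pos = pos + step
    x[n_steps], y[n_steps] = pos
    speed[n_steps] = speed[n_steps - 1] if n_steps else 0.0
    heading[n_steps] = heading[n_steps - 1] if n_steps else 0.0
    return TrajectorySeries(t, x, y, speed, heading, seed=seed)


def simulate_odometry(
    traj: TrajectorySeries,
    speed_noise_sd: float = 0.0,
    heading_noise_sd: float = 0.0,
    seed: int | None = None,
) -> TrajectorySeries:
    """Dead-reckoned path from per-step speed/heading after Gaussian noise.

    ``speed_noise_sd`` is a fraction (multiplicative noise on each step's
    speed); ``heading_noise_sd`` is radians (additive on each step's heading).
    With both zero the output reproduces the input path exactly.
    """
    if speed_noise_sd < 0 or heading_noise_sd < 0:
        raise ValueError("noise standard deviations must be non-negative")
    n = len(traj)
    if n == 0:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(seed)
    dt = np.diff(traj.t)
    sp = traj.speed[:-1].copy()
    hd = traj.heading[:-1].copy()
    if speed_noise_sd > 0:
        sp = sp * (1.0 + rng.normal(0.0, speed_noise_sd, sp.shape))
    if heading_noise_sd > 0:
        hd = wrap_angle(hd + rng.normal(0.0, heading_noise_sd, hd.shape))
    steps = (sp * dt)[:, None] * np.stack([np.cos(hd), np.sin(hd)], axis=1)
    pos = np.empty((n, 2))
    pos[0] = traj.positions[0]
    np.cumsum(steps, axis=0, out=pos[1:])
    pos[1:] += pos[0]
    speed = np.append(sp, sp[-1] if len(sp) else 0.0)
    heading = np.append(hd, hd[-1] if len(hd) else 0.0)
    return TrajectorySeries(traj.t.copy(), pos[:, 0], pos[:, 1], speed, heading, seed=seed)


def _point_segment_distance(p: np.ndarray, seg: np.ndarray) -> tuple[float, np.ndarray]:
    a, b = seg
    ab = b - a
    denom = float(ab @ ab)
    u = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    c = a + u * ab
    return float(np.linalg.norm(p - c)), c


def detect_boundary_events(
    traj: TrajectorySeries,
    arena: Arena,
    sensing_distance: float = 0.2,
    segment_length: float = 1.0,
) -> list[BoundaryEvent]:
    """One event per entry of the wall-sensing band of each perimeter segment.

    The contact position is the nearest point of the segment at the moment of
    entry. Segment ids index ``arena.perimeter_segments(segment_length)`` and
    are stable for a fixed arena and segment length.
    """
    if sensing_distance <= 0:
        raise ValueError("sensing_distance must be positive")
    segments = arena.perimeter_segments(segment_length)
    inside_band = np.zeros(len(segments), dtype=bool)
    events: list[BoundaryEvent] = []
    for i in range(len(traj)):
        p = np.array([traj.x[i], traj.y[i]])
        for d, seg in enumerate(segments):
            dist, c = _point_segment_distance(p, seg)
            if dist <= sensing_distance:
                if not inside_band[d]:
                    events.append(BoundaryEvent(float(traj.t[i]), d, c[0], c[1]))
                inside_band[d] = True
            else:
                inside_band[d] = False
    return events


def write_trajectory(traj: TrajectorySeries, path) -> None:
    """Write a trajectory as delimited text (shortest round-trip floats)."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> TrajectorySeries:
    """Read a trajectory file, validating header and monotone time."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # malformed rows
        raise TrajectoryFormatError(f"cannot parse trajectory file: {exc}") from exc
    if list(df.columns) != list(TRAJECTORY_COLUMNS):
        raise TrajectoryFormatError(
            f"expected header {','.join(TRAJECTORY_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    for col in TRAJECTORY_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise TrajectoryFormatError(
                f"non-numeric value in column '{col}' at line {bad[0] + 2}"
            )
    t = df["t"].to_numpy(float)
    if len(t) > 1:
        nonmono = np.nonzero(np.diff(t) <= 0)[0]
        if len(nonmono):
            raise TrajectoryFormatError(
                f"time not strictly increasing at line {nonmono[0] + 3}"
            )
    return TrajectorySeries(
        t,
        df["x"].to_numpy(float),
        df["y"].to_numpy(float),
        df["speed"].to_numpy(float),
        df["heading"].to_numpy(float),
    )


def write_boundary_events(events: list[BoundaryEvent], path) -> None:
    pd.DataFrame(
        {
            "t": [e.t for e in events],
            "segment_id": [e.segment_id for e in events],
            "cx": [e.cx for e in events],
            "cy": [e.cy for e in events],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_boundary_events(path) -> list[BoundaryEvent]:
    df = pd.read_csv(path)
    if list(df.columns) != ["t", "segment_id", "cx", "cy"]:
        raise TrajectoryFormatError("boundary-event file must have header t,segment_id,cx,cy")
    return [
        BoundaryEvent(float(r.t), int(r.segment_id), float(r.cx), float(r.cy))
        for r in df.itertuples()
    ]
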