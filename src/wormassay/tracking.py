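"""Locomotion-track quantification: speed, angular velocity, roam/dwell
partition, and grid-entry exploration scoring.

Angular velocity is the turn angle per frame computed from two consecutive
displacement vectors: with positions p1, p2, p3 define v12 = p2 - p1 and
v23 = p3 - p2; the cosine of the turn is (v12 . v23) / (|v12| |v23|), and the
reported angular velocity is arccos of that cosine in degrees (0 = straight,
180 = reversal).  Frames where either displacement is below a stationary
threshold have undefined turn angle and are excluded from bin means rather
than zero-filled, which would bias dwelling bins toward low turning.

Bins of 10 s (30 frames at 3 fps) are labeled roaming when mean speed
exceeds ``slope`` times mean angular velocity on the working unit scale
(speed in um/s vs degrees/frame by default; the unit multipliers are
configurable because the separating line is defined on plotted axes whose
units are an assay convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

__all__ = [
    "Track",
    "TrackBin",
    "ClassifierConfig",
    "GridConfig",
    "GridScore",
    "speed",
    "angular_velocity",
    "bin_track",
    "classify_bins",
    "fraction_roaming",
    "grid_entry_score",
    "read_track_table",
    "write_track_table",
    "realize_grid",
]

ROAM, DWELL, UNDEFINED = "roam", "dwell", "undefined"


@dataclass
class Track:
    """Timestamped 2-D positions of one worm (center of mass, mm)."""

    worm_id: str
    fps: float
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    true_state: np.ndarray | None = None  # synthetic ground truth only

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        n = len(self.t_s)
        if len(self.x_mm) != n or len(self.y_mm) != n:
            raise ValidationError("t_s, x_mm, y_mm must have equal length")
        dt = np.diff(self.t_s)
        if np.any(dt <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if n >= 2:
            nominal = 1.0 / self.fps
            if np.any(np.abs(dt - nominal) > 0.1 * nominal):
                raise ValidationError(
                    "frame spacing deviates more than 10% from 1/fps"
                )

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])


@dataclass
class TrackBin:
    """Per-bin summary: mean speed, mean angular velocity, state label."""

    t_start: float
    mean_speed: float
    mean_angular_velocity: float
    n_frames: int
    label: str = UNDEFINED


@dataclass
class ClassifierConfig:
    """Roam/dwell partition parameters.

    ``slope`` is the separating line on the (angular velocity, speed) plane:
    bins above the line (speed > slope x angular velocity, in working units)
    are roaming.  ``speed_scale`` converts mm/s to the working speed unit
    (default 1000 -> um/s); ``angvel_scale`` likewise for degrees/frame.
    """

    slope: float = 2.0
    bin_seconds: float = 10.0
    min_speed_mm_s: float = 1e-4
    boundary_rule: str = "dwell_on_line"  # or "roam_on_line"
    speed_scale: float = 1000.0
    angvel_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.bin_seconds <= 0:
            raise ConfigError("slope and bin_seconds must be positive")
        if self.boundary_rule not in ("dwell_on_line", "roam_on_line"):
            raise ConfigError(f"unknown boundary_rule {self.boundary_rule!r}")


def speed(track: Track) -> np.ndarray:
    """Per-frame speed in mm/s (length = frames - 1)."""
    if len(track) < 2:
        raise ValidationError("speed needs at least 2 frames")
    d = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm))
    dt = np.diff(track.t_s)
    return d / dt


def angular_velocity(
    track: Track, min_speed_mm_s: float = 1e-4
) -> np.ndarray:
    """Turn angle per frame in degrees (length = frames - 2).

    Frames where either adjacent displacement is below the stationary
    threshold (min_speed / fps, in mm) are NaN (undefined).
    """
    if len(track) < 3:
        raise ValidationError("angular velocity needs at least 3 frames")
    p = track.positions
    v = np.diff(p, axis=0)  # displacement vectors, length N-1
    v1, v2 = v[:-1], v[1:]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    thresh = min_speed_mm_s / track.fps
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    cosang = np.clip(cosang, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang[(n1 < thresh) | (n2 < thresh)] = np.nan
    return ang


def turn_cosine(track: Track, min_speed_mm_s: float = 1e-4) -> np.ndarray:
    """The raw cosine of the per-frame turn angle (audit channel)."""
    ang = angular_velocity(track, min_speed_mm_s)
    return np.cos(np.radians(ang))


def bin_track(track: Track, config: ClassifierConfig | None = None) -> list[TrackBin]:
    """Partition a track into consecutive complete bins of ``bin_seconds``.

    Per-bin means are taken over defined per-frame values only; a trailing
    partial bin is dropped; bins with more than half of their turn angles
    undefined are labeled undefined.
    """
    config = config or ClassifierConfig()
    nb = int(round(config.bin_seconds * track.fps))
    n_bins = len(track) // nb
    if n_bins < 1:
        raise ValidationError("track shorter than one bin")
    sp = speed(track)  # index i: step i -> i+1
    av = angular_velocity(track, config.min_speed_mm_s)  # index i: frame i+1
    bins: list[TrackBin] = []
    for b in range(n_bins):
        lo, hi = b * nb, (b + 1) * nb
        sp_slice = sp[lo : min(hi, len(sp))]
        # angular velocity of frame f lives at index f-1
        av_slice = av[max(lo - 1, 0) : min(hi - 1, len(av))]
        defined = av_slice[~np.isnan(av_slice)]
        undef_frac = 1.0 - len(defined) / max(len(av_slice), 1)
        mean_av = float(np.mean(defined)) if len(defined) else float("nan")
        label = UNDEFINED if undef_frac > 0.5 else ""
        bins.append(
            TrackBin(
                t_start=float(track.t_s[lo]),
                mean_speed=float(np.mean(sp_slice)),
                mean_angular_velocity=mean_av,
                n_frames=nb,
                label=label or UNDEFINED,
            )
        )
    return classify_bins(bins, config)


def classify_bins(
    bins: Sequence[TrackBin], config: ClassifierConfig | None = None
) -> list[TrackBin]:
    """Label bins roam/dwell by the slope line; undefined bins are kept."""
    config = config or ClassifierConfig()
    out = []
    for b in bins:
        if math.isnan(b.mean_angular_velocity) or (
            b.label == UNDEFINED and math.isnan(b.mean_speed)
        ):
            label = UNDEFINED
        else:
            s = b.mean_speed * config.speed_scale
            a = b.mean_angular_velocity * config.angvel_scale
            line = config.slope * a
            if s > line:
                label = ROAM
            elif s < line:
                label = DWELL
            else:
                label = DWELL if config.boundary_rule == "dwell_on_line" else ROAM
        out.append(
            TrackBin(
                t_start=b.t_start,
                mean_speed=b.mean_speed,
                mean_angular_velocity=b.mean_angular_velocity,
                n_frames=b.n_frames,
                label=label,
            )
        )
    return out


def fraction_roaming(bins: Iterable[TrackBin]) -> float:
    """Fraction of defined bins labeled roaming (undefined excluded).

    Accepts bins pooled across the worms of one assay.  Returns NaN with a
    warning when every bin is undefined.
    """
    labels = [b.label for b in bins]
    n_roam = labels.count(ROAM)
    n_dwell = labels.count(DWELL)
    if n_roam + n_dwell == 0:
        warnings.warn("all bins undefined; roaming fraction is missing")
        return float("nan")
    return n_roam / (n_roam + n_dwell)


# ---------------------------------------------------------------------------
# grid-entry exploration scoring
# ---------------------------------------------------------------------------


@dataclass
class GridConfig:
    """Square-lattice grid over a circular arena.

    The realized lattice keeps cells whose centers fall inside the circle;
    the cell size is chosen so the kept-cell count is closest to
    ``n_cells_target``.  ``cap`` is the maximum countable entries per cell.
    """

    n_cells_target: int = 188
    cap: int = 10
    center: tuple[float, float] = (0.0, 0.0)
    radius_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ConfigError("cap must be >= 1")
        if self.n_cells_target < 1 or self.radius_mm <= 0:
            raise ConfigError("n_cells_target and radius_mm must be positive")


@dataclass
class GridScore:
    """Per-cell entry counts (capped) and their total."""

    total: int
    counts: dict[tuple[int, int], int]
    realized_n_cells: int
    cell_size_mm: float
    n_clipped: int = 0


def realize_grid(config: GridConfig) -> tuple[float, set[tuple[int, int]]]:
    """Choose the cell size whose kept-cell count is closest to target.

    Returns (cell size, set of kept (ix, iy) cells).  Cells are indexed on a
    lattice anchored at the arena bounding-box corner (-R, -R).
    """
    R = config.radius_mm
    best: tuple[int, float, set[tuple[int, int]]] | None = None
    # cell count ~ pi R^2 / s^2; scan sizes around the analytic solution
    s_mid = R * math.sqrt(math.pi / config.n_cells_target)
    for s in np.linspace(0.7 * s_mid, 1.4 * s_mid, 400):
        n_side = int(math.ceil(2 * R / s))
        idx = np.arange(n_side)
        cx = -R + (idx + 0.5) * s
        gx, gy = np.meshgrid(cx, cx)
        inside = gx**2 + gy**2 <= R**2
        n = int(inside.sum())
        if best is None or abs(n - config.n_cells_target) < abs(
            best[0] - config.n_cells_target
        ):
            cells = {
                (int(i), int(j))
                for j, i in zip(*np.nonzero(inside))
            }
            best = (n, float(s), cells)
        if n == config.n_cells_target:
            break
    assert best is not None
    return best[1], best[2]


def _cell_of(
    x: float, y: float, config: GridConfig, s: float, kept: set[tuple[int, int]]
) -> tuple[tuple[int, int], bool]:
    cx, cy = config.center
    R = config.radius_mm
    dx, dy = x - cx, y - cy
    clipped = False
    r = math.hypot(dx, dy)
    if r > R:
        scale = (R * (1 - 1e-9)) / r
        dx *= scale
        dy *= scale
        clipped = True
    ix = int((dx + R) // s)
    iy = int((dy + R) // s)
    cell = (ix, iy)
    if cell not in kept:
        # corner position whose cell center lies outside the circle: snap to
        # the nearest kept cell by center distance
        cell = min(
            kept,
            key=lambda c: (c[0] * s - R + s / 2 - dx) ** 2
            + (c[1] * s - R + s / 2 - dy) ** 2,
        )
    return cell, clipped


def grid_entry_score(track: Track, config: GridConfig | None = None) -> GridScore:
    """Count capped grid-cell entries along a track.

    An entry is a transition into a cell from a different cell, plus one
    entry for the starting cell; per-cell counts are capped at ``cap`` and
    the total is the sum of capped counts.  The score depends only on the
    sequence of distinct cells visited, so it is invariant to temporal
    upsampling of the same geometric path.
    """
    config = config or GridConfig()
    s, kept = realize_grid(config)
    n_clipped = 0
    counts: dict[tuple[int, int], int] = {}
    prev: tuple[int, int] | None = None
    for x, y in zip(track.x_mm, track.y_mm):
        cell, clipped = _cell_of(x, y, config, s, kept)
        n_clipped += clipped
        if cell != prev:
            counts[cell] = counts.get(cell, 0) + 1
            prev = cell
    if n_clipped:
        warnings.warn(
            f"{n_clipped} positions outside the arena were clipped to the rim"
        )
    total = int(sum(min(c, config.cap) for c in counts.values()))
    return GridScore(
        total=total,
        counts=counts,
        realized_n_cells=len(kept),
        cell_size_mm=s,
        n_clipped=n_clipped,
    )


# ---------------------------------------------------------------------------
# track table I/O (schema shared with the simulator)
# ---------------------------------------------------------------------------


def write_track_table(tracks: Iterable[Track], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        df = pd.DataFrame(
            {
                "worm": tr.worm_id,
                "frame": np.arange(len(tr)),
                "t_s": tr.t_s,
                "x_mm": tr.x_mm,
                "y_mm": tr.y_mm,
            }
        )
        if tr.true_state is not None:
            df["true_state"] = tr.true_state
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_track_table(path: str | Path, fps: float = 3.0) -> list[Track]:
    df = pd.read_csv(path)
    for col in ("worm", "t_s", "x_mm", "y_mm"):
        if col not in df.columns:
            raise ValidationError(f"track table missing column {col!r}")
    tracks = []
    for worm, g in df.groupby("worm", sort=False):
        g = g.sort_values("t_s")
        tracks.append(
            Track(
                worm_id=str(worm),
                fps=fps,
                t_s=g["t_s"].to_numpy(),
                x_mm=g["x_mm"].to_numpy(),
                y_mm=g["y_mm"].to_numpy(),
                true_state=(
                    g["true_state"].to_numpy()
                    if "true_state" in g.columns
                    else None
                ),
            )
        )
    return tracks
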