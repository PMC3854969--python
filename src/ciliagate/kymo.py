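"""Kymograph particle tracking and IFT velocimetry.

A kymograph is a time × position intensity map in which a particle moving
at constant speed traces a line whose slope is its velocity.  Particles are
detected per frame as local maxima above a robust (median + k·MAD)
threshold with sub-pixel parabolic refinement, linked frame-to-frame by
greedy nearest-neighbour association with one-frame gap tolerance, and each
track's signed velocity is the least-squares slope of position against
time (positive = anterograde, i.e. base → tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Kymograph",
    "Track",
    "VelocitySummary",
    "detect_particles",
    "link_tracks",
    "extract_tracks",
    "summarize_velocities",
]

MIN_TRACK_LEN = 4
MAX_JUMP_PX = 5.0
SNR_THRESH = 5.0


@dataclass
class Kymograph:
    """Time × position intensity matrix (rows = frames, cols = pixels)."""

    data: np.ndarray
    frame_interval: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2D (frames x pixels)")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        if np.any(self.data < 0):
            raise ValueError("kymograph data must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class Track:
    """An extracted (or ground-truth) particle trajectory.

    ``points`` is an ordered list of (frame index, position in px);
    ``velocity`` is the signed speed in µm/s; ``residual`` the RMS deviation
    (px) of the points about the fitted line.
    """

    points: list[tuple[int, float]]
    velocity: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return np.array([f for f, _ in self.points])

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.points])


@dataclass(frozen=True)
class VelocitySummary:
    """Mean ± SEM of track velocities after direction filtering."""

    mean: float
    sem: float
    n: int
    velocities: tuple[float, ...] = field(default=())


def detect_particles(kym: Kymograph, snr_thresh: float = SNR_THRESH) -> list[np.ndarray]:
    """Per-frame sub-pixel particle positions.

    Local maxima above (median + snr_thresh * MAD) of the frame, refined by
    3-point parabolic interpolation.  The median/MAD threshold makes the
    detections invariant to a uniform background offset.  Empty frames give
    empty arrays.
    """
    out: list[np.ndarray] = []
    for row in kym.data:
        med = float(np.median(row))
        mad = float(np.median(np.abs(row - med)))
        thresh = med + snr_thresh * mad
        n = row.size
        if n < 3:
            out.append(np.empty(0))
            continue
        inner = row[1:-1]
        is_peak = (
            (inner > row[:-2]) & (inner >= row[2:]) & (inner > thresh)
        )
        idx = np.flatnonzero(is_peak) + 1
        # edge pixels see a truncated point-spread function, which biases
        # the parabolic localization; drop them
        idx = idx[(idx >= 2) & (idx <= n - 3)]
        if idx.size == 0:
            out.append(np.empty(0))
            continue
        # 3-point parabolic sub-pixel refinement
        y0, y1, y2 = row[idx - 1], row[idx], row[idx + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        out.append(idx + np.clip(delta, -0.5, 0.5))
    return out


def _fit_track(points: list[tuple[int, float]], frame_interval: float,
               pixel_size: float) -> tuple[float, float]:
    frames = np.array([f for f, _ in points], dtype=float)
    pos = np.array([p for _, p in points], dtype=float)
    slope, intercept = np.polyfit(frames, pos, 1)  # px per frame
    resid = float(np.sqrt(np.mean((pos - (slope * frames + intercept)) ** 2)))
    velocity = slope * pixel_size / frame_interval
    return velocity, resid


def link_tracks(
    detections: list[np.ndarray],
    max_jump: float = MAX_JUMP_PX,
    min_track_len: int = MIN_TRACK_LEN,
    frame_interval: float = 1.0,
    pixel_size: float = 1.0,
) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Open tracks claim the nearest unclaimed detection within ``max_jump``
    px, ties broken by smallest displacement then leftmost position; a
    track survives a single empty/missed frame (gap tolerance 1).  Tracks
    shorter than ``min_track_len`` points are discarded.
    """
    open_tracks: list[dict] = []  # {'points': [...], 'last_frame': int}
    closed: list[list[tuple[int, float]]] = []

    for f, pos in enumerate(detections):
        pos = np.sort(np.asarray(pos, dtype=float))
        claimed = np.zeros(pos.size, dtype=bool)
        # candidate (distance, position, track, det_index), greedy by
        # smallest displacement then leftmost detection
        cands = []
        for tr in open_tracks:
            last_pos = tr["points"][-1][1]
            for j, p in enumerate(pos):
                d = abs(p - last_pos)
                if d <= max_jump:
                    cands.append((d, p, j, tr))
        cands.sort(key=lambda c: (c[0], c[1]))
        linked_tracks = set()
        for d, p, j, tr in cands:
            if claimed[j] or id(tr) in linked_tracks:
                continue
            tr["points"].append((f, float(p)))
            tr["last_frame"] = f
            claimed[j] = True
            linked_tracks.add(id(tr))
        # expire tracks that have missed more than one frame
        still_open = []
        for tr in open_tracks:
            if f - tr["last_frame"] > 1:
                closed.append(tr["points"])
            else:
                still_open.append(tr)
        open_tracks = still_open
        # unclaimed detections start new tracks
        for j, p in enumerate(pos):
            if not claimed[j]:
                open_tracks.append({"points": [(f, float(p))], "last_frame": f})
    closed.extend(tr["points"] for tr in open_tracks)

    tracks: list[Track] = []
    for pts in closed:
        if len(pts) < min_track_len:
            continue
        velocity, resid = _fit_track(pts, frame_interval, pixel_size)
        tracks.append(Track(points=pts, velocity=velocity, residual=resid))
    return tracks


def extract_tracks(
    kym: Kymograph,
    snr_thresh: float = SNR_THRESH,
    max_jump: float = MAX_JUMP_PX,
    min_track_len: int = MIN_TRACK_LEN,
) -> list[Track]:
    """Full pipeline: detect particles per frame, then link into tracks."""
    detections = detect_particles(kym, snr_thresh=snr_thresh)
    return link_tracks(
        detections,
        max_jump=max_jump,
        min_track_len=min_track_len,
        frame_interval=kym.frame_interval,
        pixel_size=kym.pixel_size,
    )


def summarize_velocities(
    tracks: list[Track], direction: str = "anterograde"
) -> VelocitySummary:
    """Mean, SEM and count of track velocities of the requested sign.

    direction: 'anterograde' (v > 0), 'retrograde' (v < 0) or 'all'.
    SEM is sd/sqrt(n) (0 by convention for n = 1).
    """
    if direction == "anterograde":
        vs = [t.velocity for t in tracks if t.velocity > 0]
    elif direction == "retrograde":
        vs = [t.velocity for t in tracks if t.velocity < 0]
    elif direction == "all":
        vs = [t.velocity for t in tracks]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not vs:
        return VelocitySummary(mean=float("nan"), sem=float("nan"), n=0)
    v = np.asarray(vs)
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return VelocitySummary(
        mean=float(v.mean()), sem=sem, n=int(v.size), velocities=tuple(vs)
    )
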