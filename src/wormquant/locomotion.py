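"""Multi-worm video tracking and velocity statistics.

Each frame is binarized and region-labeled; worm-like objects are kept
by size and elongation.  Tracks are grown by greedy nearest-centroid
association gated by a maximum step and by relative area change; a
track ends when its worm collides with another (two tracks claim one
region, or the region balloons past the merge heuristic), touches the
frame boundary, disappears, or the video ends.  Centroid trails are
smoothed by piecewise cubic least-squares (Bezier) fitting to suppress
video flicker noise, and mean velocity is the smoothed path length
divided by the elapsed time.  Trails confined to a tiny bounding box
are stationary objects and are excluded from population statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GrayImage, Region, adaptive_threshold, label_regions

__all__ = [
    "TrackerParams",
    "Track",
    "VelocitySummary",
    "detect_frame_objects",
    "build_tracks",
    "smooth_track",
    "track_velocity",
    "track_speed_px_per_frame",
    "is_stationary",
    "summarize_velocities",
    "analyze_video",
]


@dataclass
class TrackerParams:
    """Tracking configuration.

    ``max_step`` gates centroid association (px/frame);
    ``min_track_frames`` discards transient tracks (default 14 = 2 s at
    7 fps); ``stationary_box`` is the bounding-box side (px) below
    which a whole trail counts as a non-moving object;
    ``area_change_max`` is the relative area jump treated as a merge
    (collision); ``velocity_stride`` resamples the smoothed path when
    integrating its length (default 14 frames = 2 s at 7 fps) so that
    residual jitter, which inflates a sum of sub-pixel steps, does not
    bias slow worms.
    """

    min_worm_area: int = 40
    max_worm_area: int = 2000
    max_step: float = 10.0
    min_track_frames: int = 14
    stationary_box: float = 5.0
    fps: float = 7.0
    scale: float = 20.0
    min_eccentricity: float = 0.7
    area_change_max: float = 1.6
    smooth_window: int = 7
    smooth_overlap: int = 3
    velocity_stride: int = 14

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")
        if self.min_track_frames < 2:
            raise ValueError("min_track_frames must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")


@dataclass
class Track:
    """Time-ordered centroid sequence of one worm."""

    id: int
    frames: list[int]
    raw_centroids: np.ndarray            # (N, 2) float px
    areas: list[int]
    end_reason: str                      # collision | boundary | video_end | lost
    smoothed_path: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def detect_frame_objects(frame: GrayImage, p: TrackerParams) -> list[Region]:
    """Worm-like regions in one frame: binarize, label, filter by area
    band and elongation (round debris fails the eccentricity floor)."""
    mask = adaptive_threshold(frame)
    out = []
    for r in label_regions(mask, intensity=frame):
        if not (p.min_worm_area <= r.area <= p.max_worm_area):
            continue
        if r.eccentricity < p.min_eccentricity:
            continue
        out.append(r)
    return out


class _Active:
    __slots__ = ("id", "frames", "centroids", "areas")

    def __init__(self, tid: int, frame: int, region: Region):
        self.id = tid
        self.frames = [frame]
        self.centroids = [np.asarray(region.centroid, dtype=float)]
        self.areas = [region.area]

    def median_area(self) -> float:
        return float(np.median(self.areas))

    def extend(self, frame: int, region: Region) -> None:
        self.frames.append(frame)
        self.centroids.append(np.asarray(region.centroid, dtype=float))
        self.areas.append(region.area)

    def close(self, reason: str) -> Track:
        return Track(id=self.id, frames=self.frames,
                     raw_centroids=np.asarray(self.centroids),
                     areas=self.areas, end_reason=reason)


def build_tracks(frames: list[list[Region]], p: TrackerParams,
                 frame_shape: tuple[int, int] | None = None) -> list[Track]:
    """Associate per-frame detections into worm tracks.

    Greedy nearest-centroid matching, ties broken by smaller area
    difference, gated by ``max_step`` and by relative area change.
    When two active tracks claim the same region both end with
    ``collision`` (identity is never re-linked through a collision);
    a track whose only reachable region has ballooned past
    ``area_change_max`` x its median area also ends with ``collision``
    (merge).  Regions touching the frame edge terminate their track
    with ``boundary`` and never seed a new one.  Tracks shorter than
    ``min_track_frames`` are discarded.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    done: list[Track] = []
    active: list[_Active] = []
    next_id = 0

    def region_ok_for(track: _Active, region: Region) -> bool:
        med = track.median_area()
        return med / p.area_change_max <= region.area <= med * p.area_change_max

    for t, regions in enumerate(frames):
        if t == 0:
            for r in regions:
                if frame_shape is not None and r.touches_edge(frame_shape):
                    continue
                active.append(_Active(next_id, 0, r))
                next_id += 1
            continue

        # each active track's gated candidates, nearest first
        cands: dict[int, list[tuple[float, float, int]]] = {}
        for ti, tr in enumerate(active):
            last = tr.centroids[-1]
            lst = []
            for ri, r in enumerate(regions):
                d = float(np.hypot(*(np.asarray(r.centroid) - last)))
                if d > p.max_step or not region_ok_for(tr, r):
                    continue
                lst.append((d, abs(r.area - tr.areas[-1]), ri))
            lst.sort()
            cands[ti] = lst

        # collision: two tracks whose nearest candidate is the same region
        first_choice: dict[int, list[int]] = {}
        for ti, lst in cands.items():
            if lst:
                first_choice.setdefault(lst[0][2], []).append(ti)
        collided: set[int] = set()
        claimed_regions: set[int] = set()
        for ri, tis in first_choice.items():
            if len(tis) >= 2:
                collided.update(tis)
                claimed_regions.add(ri)

        assigned_r: set[int] = set(claimed_regions)
        assigned_t: set[int] = set(collided)
        pairs = sorted(
            (d, da, ti, ri)
            for ti, lst in cands.items() if ti not in collided
            for d, da, ri in lst
        )
        matches: dict[int, int] = {}
        for d, da, ti, ri in pairs:
            if ti in assigned_t or ri in assigned_r:
                continue
            matches[ti] = ri
            assigned_t.add(ti)
            assigned_r.add(ri)

        survivors: list[_Active] = []
        for ti, tr in enumerate(active):
            if ti in collided:
                done.append(tr.close("collision"))
                continue
            ri = matches.get(ti)
            if ri is None:
                # merge heuristic: an oversized region has swallowed the
                # worm.  The merged blob's centroid can jump by half a
                # body length, so the test is proximity to the region's
                # bounding box, not to its centroid.
                last = tr.centroids[-1]
                merged = False
                for r in regions:
                    if r.area <= tr.median_area() * p.area_change_max:
                        continue
                    r0, c0, r1, c1 = r.bbox
                    if (r0 - p.max_step <= last[0] <= r1 + p.max_step
                            and c0 - p.max_step <= last[1] <= c1 + p.max_step):
                        merged = True
                        break
                done.append(tr.close("collision" if merged else "lost"))
                continue
            r = regions[ri]
            tr.extend(t, r)
            if frame_shape is not None and r.touches_edge(frame_shape):
                done.append(tr.close("boundary"))
            else:
                survivors.append(tr)
        active = survivors

        for ri, r in enumerate(regions):
            if ri in assigned_r:
                continue
            if frame_shape is not None and r.touches_edge(frame_shape):
                continue
            active.append(_Active(next_id, t, r))
            next_id += 1

    done.extend(tr.close("video_end") for tr in active)
    tracks = [tr for tr in done if tr.n_frames >= p.min_track_frames]
    for tr in tracks:
        tr.smoothed_path = smooth_track(tr.raw_centroids)
    return tracks


def smooth_track(raw_centroids: np.ndarray, window: int = 7,
                 overlap: int = 3) -> np.ndarray:
    """Piecewise cubic least-squares (Bezier) smoothing of a trail.

    A cubic Bezier segment under uniform parameterization is a cubic
    polynomial curve, so least-squares control points are obtained by
    per-coordinate cubic polynomial fits over sliding windows
    (``window`` samples, overlapping by ``overlap``); overlapping
    window evaluations are averaged.  The sample count is preserved.
    Collinear input is reproduced exactly (a cubic contains the line);
    fewer than 3 points pass through unchanged.
    """
    pts = np.asarray(raw_centroids, dtype=float)
    n = len(pts)
    if n < 3:
        return pts.copy()
    if n <= window:
        deg = min(3, n - 1)
        x = np.arange(n)
        return np.stack([np.polyval(np.polyfit(x, pts[:, k], deg), x)
                         for k in range(2)], axis=1)
    step = max(1, window - overlap)
    acc = np.zeros_like(pts)
    cnt = np.zeros(n)
    starts = list(range(0, n - window + 1, step))
    if starts[-1] != n - window:
        starts.append(n - window)
    x = np.arange(window)
    for s in starts:
        seg = pts[s:s + window]
        for k in range(2):
            coef = np.polyfit(x, seg[:, k], 3)
            acc[s:s + window, k] += np.polyval(coef, x)
        cnt[s:s + window] += 1
    return acc / cnt[:, None]


def _path_length_px(path: np.ndarray, stride: int) -> float:
    idx = list(range(0, len(path), max(1, stride)))
    if idx[-1] != len(path) - 1:
        idx.append(len(path) - 1)
    sub = path[idx]
    seg = np.diff(sub, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def track_velocity(t: Track, p: TrackerParams) -> float:
    """Mean velocity in um/s: smoothed path length x scale / elapsed time."""
    if t.frames[-1] == t.frames[0]:
        raise ValueError("zero-duration track")
    path = t.smoothed_path if t.smoothed_path is not None else smooth_track(
        t.raw_centroids, p.smooth_window, p.smooth_overlap)
    length_um = _path_length_px(path, p.velocity_stride) * p.scale
    duration_s = (t.frames[-1] - t.frames[0]) / p.fps
    return length_um / duration_s


def track_speed_px_per_frame(t: Track, p: TrackerParams) -> float:
    path = t.smoothed_path if t.smoothed_path is not None else smooth_track(
        t.raw_centroids, p.smooth_window, p.smooth_overlap)
    return _path_length_px(path, p.velocity_stride) / (t.frames[-1] - t.frames[0])


def is_stationary(t: Track, p: TrackerParams) -> bool:
    """A trail confined in a tiny bounding box is a non-moving object."""
    path = t.smoothed_path if t.smoothed_path is not None else t.raw_centroids
    span = path.max(axis=0) - path.min(axis=0)
    return bool(max(span) < p.stationary_box)


@dataclass
class VelocitySummary:
    """Population velocity statistics over the included tracks."""

    n_tracks: int
    velocities_um_per_s: list[float]
    mean: float | None
    sd: float | None
    n_excluded_stationary: int
    histogram: tuple[list[float], list[int]] = field(default=None)  # (bin edges, counts)
    cumulative: tuple[list[float], list[float]] = field(default=None)  # (v sorted, ecdf)
    empty: bool = False


def summarize_velocities(tracks: list[Track], p: TrackerParams,
                         n_bins: int = 20) -> VelocitySummary:
    """Per-track velocities, population mean/sd, histogram and ECDF.

    Stationary trails are excluded from the statistics but counted.
    Zero included tracks yields an explicitly flagged empty summary.
    """
    included, n_stat = [], 0
    for t in tracks:
        if is_stationary(t, p):
            n_stat += 1
        else:
            included.append(t)
    if not included:
        return VelocitySummary(0, [], None, None, n_stat, empty=True)
    v = np.array([track_velocity(t, p) for t in included])
    counts, edges = np.histogram(v, bins=n_bins)
    vs = np.sort(v)
    ecdf = (np.arange(1, len(vs) + 1) / len(vs)).tolist()
    return VelocitySummary(
        n_tracks=len(v),
        velocities_um_per_s=v.tolist(),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        n_excluded_stationary=n_stat,
        histogram=(edges.tolist(), counts.tolist()),
        cumulative=(vs.tolist(), ecdf),
    )


def analyze_video(frames: np.ndarray, p: TrackerParams | None = None
                  ) -> tuple[list[Track], VelocitySummary]:
    """Full pipeline: detect per frame, build tracks, summarize."""
    if p is None:
        p = TrackerParams()
    shape = frames[0].shape
    per_frame = [detect_frame_objects(GrayImage(f, scale=p.scale), p)
                 for f in frames]
    tracks = build_tracks(per_frame, p, frame_shape=shape)
    return tracks, summarize_velocities(tracks, p)
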