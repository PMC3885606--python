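"""Synthetic plate/video generator with exact ground truth.

Every analysis engine in this package is validated against data whose
truth is known by construction: videos of sinusoidal virtual worms
gliding straight at constant speed in random directions, still plates
of worms with analytically known arc length, egg plates with touching
clusters and non-egg debris, and two-image time-lapse pairs with a
known number of moving worms.  Each renderer returns the asset plus a
:class:`GroundTruth` manifest.

Worm bodies are sine curves whose amplitude and phase are modulated
frame to frame; sub-pixel positions are kept in floating point and
rounded only at draw time, so slow worms (0.25 px/frame) accumulate
true displacement.  The body polyline is re-centered on its own
(arc-length weighted) center of mass every frame, so the configured
trajectory is exactly the centroid trajectory — the quantity the
tracker estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .core import GrayImage

__all__ = [
    "SimWorm",
    "SimConfig",
    "GroundTruth",
    "worm_centerline",
    "render_worm_video",
    "make_video_config",
    "movie_s1_config",
    "render_length_plate",
    "render_egg_plate",
    "render_lifespan_pair",
    "save_frames",
]


@dataclass
class SimWorm:
    """One virtual worm: a sine-shaped body translating at constant speed."""

    id: int
    start: tuple[float, float]      # (row, col) centroid at frame 0
    heading: float                  # radians; 0 = +col direction
    speed: float                    # px per frame
    body_length: float = 40.0       # px
    amplitude: float = 5.0          # px
    wavelength: float | None = None  # px; default = body_length (one period)
    phase: float = 0.0              # radians at frame 0
    phase_rate: float = 0.45        # radians per frame (~0.5 Hz at 7 fps)
    thickness: float = 3.0          # px

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.body_length <= 0:
            raise ValueError("body_length must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1")


@dataclass
class SimConfig:
    """Video rendering configuration."""

    frame_size: tuple[int, int] = (480, 640)   # (h, w)
    fps: float = 7.0
    n_frames: int = 210
    worms: list[SimWorm] = field(default_factory=list)
    background_level: int = 220
    worm_level: int = 30
    noise_sd: float = 6.0
    debris: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    scale: float = 20.0                        # um per px, for manifest speeds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for lv in (self.background_level, self.worm_level):
            if not 0 <= lv <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")


@dataclass
class GroundTruth:
    """Manifest pairing a rendered asset with its known truth.

    ``objects`` holds one dict per rendered object (worm/egg); ``counts``
    holds per-asset totals; ``files`` records paths of written assets.
    """

    kind: str
    objects: list[dict] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=_json_default)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


# ----------------------------------------------------------------- geometry


def worm_centerline(worm: SimWorm, frame_idx: int, samples_per_px: float = 4.0) -> np.ndarray:
    """Dense (N, 2) float polyline of the worm body at a given frame.

    The body is a sine curve along the heading axis whose phase
    advances by ``phase_rate`` per frame; the polyline is re-centered
    so its arc-length-weighted centroid sits exactly at the worm's
    configured position for that frame.
    """
    L = worm.body_length
    lam = worm.wavelength if worm.wavelength is not None else L
    phi = worm.phase + worm.phase_rate * frame_idx
    n = max(16, int(L * samples_per_px))
    s = np.linspace(0.0, L, n)
    lateral = worm.amplitude * np.sin(2 * np.pi * s / lam + phi)
    u = np.array([np.sin(worm.heading), np.cos(worm.heading)])   # along-axis
    v = np.array([np.cos(worm.heading), -np.sin(worm.heading)])  # normal
    pts = s[:, None] * u[None, :] + lateral[:, None] * v[None, :]
    pts -= _polyline_centroid(pts)
    anchor = np.asarray(worm.start, dtype=float) + worm.speed * frame_idx * u
    return pts + anchor


def _polyline_centroid(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    w = np.hypot(seg[:, 0], seg[:, 1])
    mid = 0.5 * (pts[:-1] + pts[1:])
    total = w.sum()
    if total == 0:
        return pts.mean(axis=0)
    return (mid * w[:, None]).sum(axis=0) / total


def polyline_length(pts: np.ndarray) -> float:
    seg = np.diff(np.asarray(pts, dtype=float), axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def stamp_polyline(mask: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Mark every pixel within ``radius`` of the polyline samples (in place).

    Sub-pixel sample positions are honored: the disk membership test is
    evaluated against the fractional center, so rounding happens only
    at the pixel-grid level.  Sweeping a disk along the dense polyline
    yields a constant-thickness band with rounded caps.
    """
    h, w = mask.shape
    pts = np.asarray(pts, dtype=float)
    r_int = int(np.ceil(radius)) + 1
    off = np.arange(-r_int, r_int + 1)
    orr, occ = np.meshgrid(off, off, indexing="ij")
    offsets = np.stack([orr.ravel(), occ.ravel()], axis=1)          # (K, 2)
    base = np.floor(pts).astype(int)                                # (N, 2)
    frac = pts - base                                               # (N, 2)
    d2 = (offsets[None, :, 0] - frac[:, None, 0]) ** 2 + (
        offsets[None, :, 1] - frac[:, None, 1]) ** 2                # (N, K)
    sel = d2 <= radius * radius
    rows = (base[:, None, 0] + offsets[None, :, 0])[sel]
    cols = (base[:, None, 1] + offsets[None, :, 1])[sel]
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    mask[rows[ok], cols[ok]] = True


def _stamp_blob(mask: np.ndarray, center: tuple[float, float], radius: float,
                rng: np.random.Generator, n_lobes: int = 6) -> None:
    """Irregular dark debris blob: union of disks along a short random walk."""
    pos = np.asarray(center, dtype=float)
    pts = [pos.copy()]
    for _ in range(n_lobes - 1):
        pos = pos + rng.normal(0, radius * 0.8, size=2)
        pts.append(pos.copy())
    for p in pts:
        stamp_polyline(mask, p[None, :], radius * rng.uniform(0.5, 1.0))


def _render_plate(shape: tuple[int, int], layers: list[tuple[np.ndarray, float]],
                  background: float, noise_sd: float,
                  rng: np.random.Generator,
                  gradient: float = 0.0) -> np.ndarray:
    """Compose intensity layers over a background, add noise, quantize."""
    h, w = shape
    canvas = np.full(shape, float(background))
    if gradient:
        ramp = np.linspace(-gradient / 2, gradient / 2, w)[None, :]
        canvas = canvas + ramp
    for mask, level in layers:
        canvas[mask] = level
    if noise_sd > 0:
        canvas = canvas + rng.normal(0, noise_sd, size=shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


# -------------------------------------------------------------------- video


def render_worm_video(cfg: SimConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render all frames of a worm video plus its manifest.

    Returns ``(frames, truth)`` where ``frames`` is a (T, H, W) uint8
    array.  The manifest records, per worm, the configured speed in
    px/frame and um/s and the exact per-frame centroid positions.
    Raises if any worm body extends outside the frame at frame 0.
    """
    h, w = cfg.frame_size
    rng = np.random.default_rng(cfg.seed)
    for worm in cfg.worms:
        pts = worm_centerline(worm, 0)
        r = worm.thickness / 2
        if (pts[:, 0].min() < r or pts[:, 1].min() < r
                or pts[:, 0].max() > h - 1 - r or pts[:, 1].max() > w - 1 - r):
            raise ValueError(f"worm {worm.id} placed outside the frame")
    debris_mask = np.zeros((h, w), dtype=bool)
    for (center, radius) in cfg.debris:
        stamp_polyline(debris_mask, np.asarray(center, float)[None, :], radius)
    frames = np.empty((cfg.n_frames, h, w), dtype=np.uint8)
    centroids = {worm.id: [] for worm in cfg.worms}
    u_of = {worm.id: np.array([np.sin(worm.heading), np.cos(worm.heading)])
            for worm in cfg.worms}
    for t in range(cfg.n_frames):
        worm_mask = debris_mask.copy()
        for worm in cfg.worms:
            pts = worm_centerline(worm, t)
            stamp_polyline(worm_mask, pts, worm.thickness / 2)
            anchor = np.asarray(worm.start) + worm.speed * t * u_of[worm.id]
            centroids[worm.id].append(anchor.tolist())
        frames[t] = _render_plate((h, w), [(worm_mask, cfg.worm_level)],
                                  cfg.background_level, cfg.noise_sd, rng)
    objects = [
        {
            "id": worm.id,
            "speed_px_per_frame": worm.speed,
            "speed_um_per_s": worm.speed * cfg.fps * cfg.scale,
            "heading": worm.heading,
            "start": list(worm.start),
            "body_length": worm.body_length,
            "centroids": centroids[worm.id],
        }
        for worm in cfg.worms
    ]
    truth = GroundTruth(
        kind="video",
        objects=objects,
        counts={"n_worms": len(cfg.worms)},
        params={"fps": cfg.fps, "n_frames": cfg.n_frames, "scale": cfg.scale,
                "frame_size": list(cfg.frame_size), "seed": cfg.seed},
    )
    return frames, truth


def make_video_config(
    speeds: list[float],
    seed: int,
    frame_size: tuple[int, int] = (480, 640),
    fps: float = 7.0,
    n_frames: int = 210,
    black_white: bool = True,
    avoid_collisions: bool = True,
    max_tries: int = 50_000,
    **worm_kwargs,
) -> SimConfig:
    """Place one worm per requested speed at a random heading/position.

    Start positions and headings are rejection-sampled so every worm's
    straight-line path stays inside the frame for the whole video and —
    when ``avoid_collisions`` (the default) — so no two worms ever come
    within a body length of each other *at the same instant* (their
    paths may still cross at different times).  Collision-free
    placement keeps per-worm ground truth unambiguous for velocity
    validation; pass ``avoid_collisions=False`` (or construct a
    :class:`SimConfig` directly) to study collisions.

    Rendering defaults to binary black-and-white frames (dark worms on
    a white field, no noise), the style of a pure simulation video.
    """
    rng = np.random.default_rng(seed)
    h, w = frame_size
    proto = SimWorm(id=-1, start=(0, 0), heading=0, speed=0, **worm_kwargs)
    margin = proto.body_length / 2 + proto.amplitude + proto.thickness + 2
    sep = proto.body_length + 2 * proto.amplitude
    T = n_frames - 1

    def min_simultaneous_dist(s1, v1, s2, v2) -> float:
        # |(s1 - s2) + t (v1 - v2)| minimized over t in [0, T]
        d0 = np.asarray(s1) - np.asarray(s2)
        dv = np.asarray(v1) - np.asarray(v2)
        denom = float(dv @ dv)
        t = 0.0 if denom == 0 else float(np.clip(-(d0 @ dv) / denom, 0.0, T))
        return float(np.hypot(*(d0 + t * dv)))

    worms: list[SimWorm] = []
    for restart in range(40):
        rng_r = np.random.default_rng(rng.integers(2**31))
        worms, motions = [], []
        tries = 0
        ok = True
        for i, speed in enumerate(speeds):
            placed = False
            while tries < max_tries // 4:
                tries += 1
                r0 = rng_r.uniform(margin, h - 1 - margin)
                c0 = rng_r.uniform(margin, w - 1 - margin)
                heading = rng_r.uniform(0, 2 * np.pi)
                u = np.array([np.sin(heading), np.cos(heading)])
                vel = speed * u
                end = np.array([r0, c0]) + T * vel
                if not (margin <= end[0] <= h - 1 - margin
                        and margin <= end[1] <= w - 1 - margin):
                    continue
                if avoid_collisions and any(
                        min_simultaneous_dist((r0, c0), vel, s2, v2) < sep
                        for s2, v2 in motions):
                    continue
                worms.append(SimWorm(id=i, start=(r0, c0), heading=heading,
                                     speed=speed,
                                     phase=rng_r.uniform(0, 2 * np.pi),
                                     **worm_kwargs))
                motions.append((np.array([r0, c0]), vel))
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not place worms without collisions")
    bg, fg, noise = (255, 0, 0.0) if black_white else (220, 30, 6.0)
    return SimConfig(frame_size=frame_size, fps=fps, n_frames=n_frames,
                     worms=worms, background_level=bg, worm_level=fg,
                     noise_sd=noise, seed=seed)


def movie_s1_config(seed: int, n_frames: int = 210) -> SimConfig:
    """The published simulation-video configuration: a 7 fps video of
    10 virtual worms at 1 px/frame plus 10 at 0.25 px/frame."""
    return make_video_config([1.0] * 10 + [0.25] * 10, seed=seed,
                             fps=7.0, n_frames=n_frames)


def save_frames(frames: np.ndarray, outdir: str | Path,
                write_avi: bool = False, fps: float = 7.0) -> list[str]:
    """Write frames as numbered PNGs (bit-exact, codec independent);
    optionally also an AVI if an ffmpeg backend is available."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for t, frame in enumerate(frames):
        p = outdir / f"frame_{t:04d}.png"
        iio.imwrite(p, frame)
        files.append(str(p))
    if write_avi:
        try:
            import imageio.v2 as iio2

            avi = outdir / "video.avi"
            iio2.mimwrite(avi, list(frames), fps=fps)
            files.append(str(avi))
        except Exception:
            pass  # frame PNGs remain the canonical output
    return files


def load_frames(path: str | Path) -> np.ndarray:
    """Load a video from a directory of numbered images or an AVI file."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no frame images found in {path}")
        return np.stack([GrayImage.from_file(p).pixels for p in files])
    arr = iio.imread(path)
    if arr.ndim == 4:  # T,H,W,C
        arr = arr[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


# ------------------------------------------------------------- still plates


def _curved_centerline(length_px: float, rng: np.random.Generator,
                       step: float = 0.05) -> np.ndarray:
    """A smooth random sine arc cut to an exactly known arc length.

    The generating curve is sampled at ``step`` px resolution and the
    cumulative chord length is truncated (with interpolation of the
    final vertex) at ``length_px``, so the polyline's arc length equals
    the target to within the chord-approximation error (< 1e-5
    relative at this sampling density).
    """
    amp = rng.uniform(0.02, 0.14) * length_px
    lam = length_px / rng.uniform(0.7, 1.6)
    phi = rng.uniform(0, 2 * np.pi)
    theta = rng.uniform(0, np.pi)
    t = np.arange(0.0, length_px * 1.6, step)
    base = np.stack([amp * np.sin(2 * np.pi * t / lam + phi), t], axis=1)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    pts = base @ rot.T
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < length_px:
        raise RuntimeError("generating curve shorter than target length")
    k = int(np.searchsorted(cum, length_px))
    frac = (length_px - cum[k - 1]) / (cum[k] - cum[k - 1])
    last = pts[k - 1] + frac * (pts[k] - pts[k - 1])
    return np.vstack([pts[:k], last])


def render_length_plate(
    n_worms: int,
    length_range_um: tuple[float, float] = (600.0, 1500.0),
    seed: int = 0,
    scale: float = 6.25,
    frame_size: tuple[int, int] = (960, 1280),
    thickness_um: float = 45.0,
    background_level: int = 210,
    worm_level: int = 50,
    noise_sd: float = 5.0,
    max_tries: int = 20_000,
) -> tuple[GrayImage, GroundTruth]:
    """Still plate of non-overlapping worms with known arc lengths.

    Worms are constant-thickness bands (round caps) swept along smooth
    random arcs; the manifest records each centerline arc length in px
    and um.  The default 6.25 um/px matches a body-size scan at higher
    magnification than the whole-well lifespan tiling.  Raises if the
    requested density cannot be placed without overlap.
    """
    if n_worms < 0:
        raise ValueError("n_worms must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = frame_size
    radius = thickness_um / scale / 2
    occupancy = np.zeros((h, w), dtype=bool)
    objects = []
    layers_mask = np.zeros((h, w), dtype=bool)
    tries = 0
    for i in range(n_worms):
        L_um = rng.uniform(*length_range_um)
        L_px = L_um / scale
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError("cannot place worms without overlap at this density")
            pts = _curved_centerline(L_px, rng)
            pts = pts - pts.mean(axis=0)
            margin = radius + 3
            lo_r, hi_r = -pts[:, 0].min() + margin, h - 1 - pts[:, 0].max() - margin
            lo_c, hi_c = -pts[:, 1].min() + margin, w - 1 - pts[:, 1].max() - margin
            if lo_r >= hi_r or lo_c >= hi_c:
                continue
            center = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            placed = pts + center
            cand = np.zeros((h, w), dtype=bool)
            stamp_polyline(cand, placed[::8], radius + 3)  # dilated footprint
            if (cand & occupancy).any():
                continue
            worm_mask = np.zeros((h, w), dtype=bool)
            stamp_polyline(worm_mask, placed, radius)
            layers_mask |= worm_mask
            occupancy |= cand
            objects.append({
                "id": i,
                "length_px": L_px,
                "length_um": L_um,
                "centroid": placed.mean(axis=0).tolist(),
            })
            break
    pixels = _render_plate((h, w), [(layers_mask, worm_level)],
                           background_level, noise_sd, rng)
    truth = GroundTruth(kind="length_plate", objects=objects,
                        counts={"n_worms": n_worms},
                        params={"scale": scale, "seed": seed,
                                "thickness_px": 2 * radius})
    return GrayImage(pixels, scale=scale), truth


def render_egg_plate(
    n_eggs: int,
    cluster_fraction: float = 0.3,
    debris_count: int = 8,
    seed: int = 0,
    frame_size: tuple[int, int] = (480, 640),
    scale: float = 5.0,
    background_level: int = 200,
    noise_sd: float = 4.0,
    gradient: float = 20.0,
) -> tuple[GrayImage, GroundTruth]:
    """Still plate of dark elliptical eggs plus non-egg debris.

    Eggs are ellipses with a ~2:1.3 axis ratio (a C. elegans egg is
    roughly 50x30 um; at the default 5 um/px the semi-axes are ~5x3.2
    px) and per-egg gray level drawn from a wide band, so faint eggs
    are visible only in a subset of threshold levels.
    ``cluster_fraction`` of the eggs are placed touching a neighbor.
    Debris comprises irregular dark blobs and thin curvilinear track
    marks; neither appears in the egg count.
    """
    if not 0 <= cluster_fraction <= 1:
        raise ValueError("cluster_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = frame_size
    margin = 20
    layers: list[tuple[np.ndarray, float]] = []
    eggs = []
    n_clustered = int(round(n_eggs * cluster_fraction))
    centers: list[np.ndarray] = []
    shapes: list[tuple[float, float, float]] = []   # (a, b, orientation)

    def _radius_along(shape_: tuple[float, float, float], ang: float) -> float:
        # center-to-boundary radius along absolute direction (sin ang, cos ang)
        # for an ellipse drawn with semi-axes (a_, b_) and rotation o_,
        # whose major axis points along (cos o_, sin o_) in (row, col)
        a_, b_, o_ = shape_
        psi = ang + o_
        return a_ * b_ / np.hypot(b_ * np.sin(psi), a_ * np.cos(psi))

    for i in range(n_eggs):
        a = rng.uniform(4.5, 5.5)
        b = a * rng.uniform(0.6, 0.7)
        gray = rng.uniform(70, 140)
        orient = rng.uniform(0, np.pi)
        attach = i >= n_eggs - n_clustered and centers
        for _ in range(4000):
            if attach:
                hi = int(rng.integers(len(centers)))
                host = centers[hi]
                ang = rng.uniform(0, 2 * np.pi)
                # outlines touch: centers one summed directional radius apart
                d = 1.02 * (_radius_along(shapes[hi], ang)
                            + _radius_along((a, b, orient), ang))
                cen = host + d * np.array([np.sin(ang), np.cos(ang)])
                min_sep = 0.0
            else:
                cen = np.array([rng.uniform(margin, h - margin),
                                rng.uniform(margin, w - margin)])
                min_sep = 3.5 * a
            if not (margin <= cen[0] <= h - margin and margin <= cen[1] <= w - margin):
                continue
            if min_sep and centers and min(
                    np.hypot(*(cen - c)) for c in centers) < min_sep:
                continue
            break
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = skdraw.ellipse(cen[0], cen[1], a, b, shape=(h, w), rotation=orient)
        mask[rr, cc] = True
        layers.append((mask, gray))
        centers.append(cen)
        shapes.append((a, b, orient))
        eggs.append({"id": i, "centroid": cen.tolist(), "area": int(mask.sum()),
                     "gray": gray, "clustered": bool(attach)})
    debris = []
    for j in range(debris_count):
        cen = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        mask = np.zeros((h, w), dtype=bool)
        if j % 2 == 0:  # irregular blob
            _stamp_blob(mask, cen, rng.uniform(6, 12), rng)
            gray = rng.uniform(15, 50)
        else:  # curvilinear worm-track mark
            track = _curved_centerline(rng.uniform(60, 150), rng)
            track = track - track.mean(axis=0) + np.asarray(cen)
            stamp_polyline(mask, track, rng.uniform(0.8, 1.4))
            gray = rng.uniform(90, 150)
        layers.append((mask, gray))
        debris.append({"centroid": list(cen), "kind": "blob" if j % 2 == 0 else "track"})
    pixels = _render_plate((h, w), layers, background_level, noise_sd, rng,
                           gradient=gradient)
    truth = GroundTruth(kind="egg_plate", objects=eggs,
                        counts={"n_eggs": n_eggs, "n_debris": debris_count},
                        params={"scale": scale, "seed": seed,
                                "cluster_fraction": cluster_fraction,
                                "debris": debris})
    return GrayImage(pixels, scale=scale), truth


def render_lifespan_pair(
    n_moving: int,
    n_still: int,
    displacement: float = 60.0,
    seed: int = 0,
    frame_size: tuple[int, int] = (960, 1280),
    debris_count: int = 5,
    scale: float = 20.0,
    background_level: int = 215,
    worm_level: int = 60,
    noise_sd: float = 6.0,
    max_tries: int = 200_000,
) -> tuple[GrayImage, GrayImage, GroundTruth]:
    """Two-scan time-lapse pair with a known number of moving worms.

    Moving worms are displaced along their heading by ``displacement``
    px and change body phase between the scans; still worms are drawn
    from identical masks in both images (only sensor noise differs).
    Dark debris blobs are identical in both scans.  The default 60 px
    (1.2 mm at 20 um/px over the 2-minute interval, i.e. 10 um/s) is a
    conservative lower bound on how far a living worm crawls between
    scans.
    """
    if n_moving > 0 and displacement <= 0:
        raise ValueError("displacement must be > 0 when there are movers")
    rng = np.random.default_rng(seed)
    h, w = frame_size
    occupancy = np.zeros((h, w), dtype=bool)
    mask1 = np.zeros((h, w), dtype=bool)
    mask2 = np.zeros((h, w), dtype=bool)
    objects = []
    tries = 0

    def place(moving: bool, idx: int) -> None:
        nonlocal tries, occupancy
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("cannot place worms without overlap")
            worm = SimWorm(id=idx,
                           start=(rng.uniform(40, h - 40), rng.uniform(40, w - 40)),
                           heading=rng.uniform(0, 2 * np.pi),
                           speed=displacement if moving else 0.0,
                           phase=rng.uniform(0, 2 * np.pi),
                           phase_rate=rng.uniform(1.5, 4.5) if moving else 0.0)
            p1 = worm_centerline(worm, 0)
            p2 = worm_centerline(worm, 1)  # one "frame" = the 2-min interval
            both = np.vstack([p1, p2])
            r = worm.thickness / 2
            if (both.min() < 10 or both[:, 0].max() > h - 10
                    or both[:, 1].max() > w - 10):
                continue
            cand = np.zeros((h, w), dtype=bool)
            stamp_polyline(cand, both[::6], r + 4)
            if (cand & occupancy).any():
                continue
            stamp_polyline(mask1, p1, r)
            stamp_polyline(mask2, p2, r)
            occupancy |= cand
            objects.append({"id": idx, "moving": moving,
                            "centroid1": _polyline_centroid(p1).tolist(),
                            "centroid2": _polyline_centroid(p2).tolist()})
            return

    idx = 0
    for _ in range(n_moving):
        place(True, idx)
        idx += 1
    for _ in range(n_still):
        place(False, idx)
        idx += 1
    debris_mask = np.zeros((h, w), dtype=bool)
    for _ in range(debris_count):
        for _ in range(2000):
            cen = (rng.uniform(40, h - 40), rng.uniform(40, w - 40))
            cand = np.zeros((h, w), dtype=bool)
            _stamp_blob(cand, cen, rng.uniform(8, 16), rng)
            if not (ndi.binary_dilation(cand, iterations=4) & occupancy).any():
                debris_mask |= cand
                occupancy |= cand
                break
    img1 = _render_plate((h, w), [(mask1, worm_level), (debris_mask, 30)],
                         background_level, noise_sd, rng)
    img2 = _render_plate((h, w), [(mask2, worm_level), (debris_mask, 30)],
                         background_level, noise_sd, rng)
    truth = GroundTruth(kind="lifespan_pair", objects=objects,
                        counts={"n_moving": n_moving, "n_still": n_still,
                                "n_debris": debris_count},
                        params={"displacement": displacement, "seed": seed,
                                "scale": scale})
    return GrayImage(img1, scale=scale), GrayImage(img2, scale=scale), truth
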