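"""Low-level imaging primitives shared by every analysis engine.

All engines operate on 8-bit grayscale plate images in which objects
(worms, eggs, debris) are dark on a bright agar background.  The
primitives here are deliberately small: adaptive local-mean (Bradley)
thresholding, connected-component labeling with morphology statistics,
topological skeletonization, Canny edge detection, and morphological
gap/hole filling.  Coordinates are (row, col), 0-based; bounding boxes
are half-open ``(min_row, min_col, max_row, max_col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage import morphology as skmorph

__all__ = [
    "GrayImage",
    "BinaryImage",
    "Region",
    "Skeleton",
    "adaptive_threshold",
    "threshold_difference",
    "label_regions",
    "skeletonize_mask",
    "canny_edges",
    "fill_gaps_and_holes",
    "default_window",
]


@dataclass(frozen=True)
class GrayImage:
    """A calibrated 8-bit grayscale raster.

    Parameters
    ----------
    pixels : ndarray
        2D uint8 array of intensities in [0, 255].
    scale : float
        Spatial calibration in micrometers per pixel.  The default of
        20 um/px corresponds to a dissecting-scope rig imaging a whole
        multi-well plate well at 640x480 per tile.
    """

    pixels: np.ndarray
    scale: float = 20.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("GrayImage requires a non-empty 2D array")
        if px.dtype != np.uint8:
            if np.any(px < 0) or np.any(px > 255):
                raise ValueError("intensities must lie in [0, 255]")
            if not np.allclose(px, np.round(px)):
                raise ValueError("intensities must be integral")
            px = px.astype(np.uint8)
        if not self.scale > 0:
            raise ValueError("scale must be positive (um per pixel)")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @classmethod
    def from_file(cls, path: str | Path, scale: float = 20.0) -> "GrayImage":
        """Read a PNG/TIFF image, converting color to luminance."""
        import imageio.v3 as iio

        arr = iio.imread(path)
        return cls.from_array(arr, scale=scale)

    @classmethod
    def from_array(cls, arr: np.ndarray, scale: float = 20.0) -> "GrayImage":
        arr = np.asarray(arr)
        if arr.ndim == 3:  # RGB(A) -> ITU-R 601 luminance
            rgb = arr[..., :3].astype(np.float64)
            arr = rgb @ np.array([0.299, 0.587, 0.114])
        if arr.dtype != np.uint8:
            arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
        return cls(arr, scale=scale)

    def save(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, self.pixels)


@dataclass(frozen=True)
class BinaryImage:
    """A boolean mask; ``True`` marks object (foreground) pixels.

    The foreground convention for this package is dark-on-bright:
    worms and eggs are darker than the agar, so thresholding marks
    dark pixels as ``True`` unless explicitly inverted.
    """

    mask: np.ndarray
    foreground_is_object: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("BinaryImage requires a 2D array")
        if m.dtype != bool:
            if not np.isin(m, (0, 1)).all():
                raise ValueError("mask values must be strictly boolean")
            m = m.astype(bool)
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Region:
    """One labeled connected component with morphology descriptors."""

    label: int
    area: int
    centroid: tuple[float, float]          # (row, col)
    bbox: tuple[int, int, int, int]        # half-open (r0, c0, r1, c1)
    perimeter: float
    eccentricity: float
    solidity: float
    mean_intensity: float
    coords: np.ndarray = field(repr=False, default=None)  # (N, 2) pixel coords

    @property
    def bbox_height(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def bbox_width(self) -> int:
        return self.bbox[3] - self.bbox[1]

    def bbox_intersects(self, other: "Region") -> bool:
        r0, c0, r1, c1 = self.bbox
        s0, d0, s1, d1 = other.bbox
        return r0 < s1 and s0 < r1 and c0 < d1 and d0 < c1

    def touches_edge(self, shape: tuple[int, int]) -> bool:
        r0, c0, r1, c1 = self.bbox
        return r0 == 0 or c0 == 0 or r1 == shape[0] or c1 == shape[1]


@dataclass(frozen=True)
class Skeleton:
    """Single-pixel-wide medial curve of one object.

    ``path`` is ordered head-to-tail only when the skeleton is a simple
    open curve (``branch_count == 0`` and exactly two endpoints);
    otherwise it is an unordered pixel list.  A valid worm skeleton is
    branch-free with two endpoints.
    """

    path: np.ndarray                      # (N, 2) int pixel coords
    branch_count: int
    endpoints: np.ndarray                 # (K, 2) int pixel coords

    @property
    def n_pixels(self) -> int:
        return len(self.path)

    @property
    def is_worm_like(self) -> bool:
        return self.branch_count == 0 and len(self.endpoints) == 2 and self.n_pixels >= 5


def default_window(shape: tuple[int, int]) -> int:
    """Default adaptive-threshold window: min image dimension / 8, odd."""
    w = max(3, min(shape) // 8)
    return w if w % 2 == 1 else w + 1


def _local_mean(pixels: np.ndarray, window: int) -> np.ndarray:
    # uniform_filter with 'nearest' replication matches a clamped
    # integral-image window at the borders.
    return ndi.uniform_filter(pixels.astype(np.float64), size=window, mode="nearest")


def adaptive_threshold(
    img: GrayImage,
    window: int | None = None,
    offset_fraction: float = 0.15,
    dark_objects: bool = True,
) -> BinaryImage:
    """Bradley-style local-mean binarization.

    A pixel is foreground iff its intensity is below ``local_mean *
    (1 - offset_fraction)`` (dark objects), where the local mean is a
    square window centered on the pixel, border-clamped.  Being
    relative to the local mean, the rule tolerates smooth illumination
    gradients and shadowed plates that defeat any global threshold.

    With ``dark_objects=False`` the polarity inverts: foreground iff
    intensity above ``local_mean * (1 + offset_fraction)``.
    """
    if window is None:
        window = default_window(img.shape)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > img.height or window > img.width:
        raise ValueError(
            f"window {window} exceeds image dimensions {img.shape}"
        )
    if not 0 <= offset_fraction < 1:
        raise ValueError("offset_fraction must lie in [0, 1)")
    mean = _local_mean(img.pixels, window)
    if dark_objects:
        mask = img.pixels < mean * (1.0 - offset_fraction)
    else:
        mask = img.pixels > mean * (1.0 + offset_fraction)
    return BinaryImage(mask)


def threshold_difference(
    diff: np.ndarray,
    noise_floor: float = 30.0,
    rel_factor: float = 2.0,
    window: int | None = None,
    open_size: int = 3,
) -> BinaryImage:
    """Binarize an absolute-difference image: changed pixels are bright.

    A pixel counts as changed iff it exceeds both an absolute sensor
    noise floor and ``rel_factor`` times the local mean difference (the
    local term adapts to flicker/illumination drift between the two
    scans).  A small opening removes isolated noise speckle.
    """
    diff = np.asarray(diff, dtype=np.float64)
    if window is None:
        window = default_window(diff.shape)
    mean = _local_mean(diff, window)
    mask = (diff > noise_floor) & (diff > rel_factor * mean)
    if open_size > 1:
        mask = ndi.binary_opening(mask, structure=np.ones((open_size, open_size)))
    return BinaryImage(mask)


def label_regions(
    mask: BinaryImage,
    connectivity: int = 8,
    intensity: GrayImage | np.ndarray | None = None,
) -> list[Region]:
    """Connected-component labeling with morphology statistics.

    ``connectivity`` is 4 or 8 (pixel adjacency).  Returns one
    :class:`Region` per component, empty list for an all-background
    mask.  ``intensity`` supplies the source image for
    ``mean_intensity`` (0.0 when absent).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    m = mask.mask
    if not m.any():
        return []
    skc = 1 if connectivity == 4 else 2
    labels = skmeasure.label(m, connectivity=skc)
    if intensity is not None:
        inten = intensity.pixels if isinstance(intensity, GrayImage) else np.asarray(intensity)
    else:
        inten = None
    out: list[Region] = []
    for rp in skmeasure.regionprops(labels, intensity_image=inten):
        out.append(
            Region(
                label=int(rp.label),
                area=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=tuple(int(v) for v in rp.bbox),  # type: ignore[arg-type]
                perimeter=float(rp.perimeter),
                eccentricity=float(rp.eccentricity),
                solidity=float(rp.solidity),
                mean_intensity=float(rp.intensity_mean) if inten is not None else 0.0,
                coords=rp.coords,
            )
        )
    return out


_NEIGH = np.ones((3, 3), dtype=int)
_NEIGH[1, 1] = 0


def skeletonize_mask(region_mask: BinaryImage) -> Skeleton:
    """Thin a single connected component to its medial curve.

    Returns the skeleton with its branch points (pixels with >= 3
    skeleton neighbors in 8-connectivity) counted and its endpoints
    (pixels with exactly 1 neighbor) listed.  For a branch-free open
    curve the path is ordered endpoint-to-endpoint.
    """
    m = region_mask.mask
    if not m.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skmorph.skeletonize(m)
    if not skel.any():
        raise ValueError("mask eroded to an empty skeleton")
    return _skeleton_from_pixels(skel)


def _skeleton_from_pixels(skel: np.ndarray) -> Skeleton:
    nb = ndi.convolve(skel.astype(int), _NEIGH, mode="constant")
    nb_counts = nb[skel]
    coords = np.argwhere(skel)
    endpoints = coords[nb_counts == 1]
    branch_count = int(np.sum(nb_counts >= 3))
    if branch_count == 0 and len(endpoints) == 2 and len(coords) >= 2:
        path = _walk_path(skel, tuple(endpoints[0]))
    else:
        path = coords
    return Skeleton(path=np.asarray(path), branch_count=branch_count,
                    endpoints=np.asarray(endpoints))


def _walk_path(skel: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Order an open branch-free skeleton by walking from one endpoint."""
    h, w = skel.shape
    visited = np.zeros_like(skel, dtype=bool)
    path = [start]
    visited[start] = True
    cur = start
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while True:
        nxt = None
        for dr, dc in offsets:
            r, c = cur[0] + dr, cur[1] + dc
            if 0 <= r < h and 0 <= c < w and skel[r, c] and not visited[r, c]:
                nxt = (r, c)
                break
        if nxt is None:
            break
        visited[nxt] = True
        path.append(nxt)
        cur = nxt
    return np.asarray(path, dtype=int)


def canny_edges(img: GrayImage, low: float, high: float, sigma: float = 1.4) -> BinaryImage:
    """Canny edge detection with hysteresis linking.

    ``low``/``high`` are gradient-magnitude thresholds in intensity
    units (0-255 scale).
    """
    if not (0 <= low < high <= 255):
        raise ValueError("require 0 <= low < high <= 255")
    edges = skfeature.canny(
        img.pixels.astype(np.float64),
        sigma=sigma,
        low_threshold=low,
        high_threshold=high,
    )
    return BinaryImage(edges)


def fill_gaps_and_holes(edges: BinaryImage, max_gap: int = 3) -> BinaryImage:
    """Bridge edge breaks up to ``max_gap`` px and fill closed contours.

    Dilating by ``ceil(max_gap / 2)`` closes breaks up to ``max_gap``;
    holes of the (now closed) contours are flood-filled while dilated,
    and the erosion that undoes the dilation leaves the interior solid.
    Plain morphological closing fails here: the thin bridge it builds
    across a gap in a one-pixel curve does not survive the erosion.
    Curves with breaks wider than ``max_gap`` stay open and unfilled.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    m = edges.mask
    if max_gap > 0:
        selem = skmorph.disk(int(np.ceil(max_gap / 2)))
        dilated = ndi.binary_dilation(m, structure=selem)
        filled = ndi.binary_fill_holes(dilated)
        m = ndi.binary_erosion(filled, structure=selem) | m
    filled = ndi.binary_fill_holes(m)
    return BinaryImage(filled)
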