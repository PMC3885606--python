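"""Parameter-free egg counting by multi-level thresholding.

Egg plates are hard to segment at a single threshold: eggs vary in
darkness, worm tracks scar the agar, and touching eggs merge.  The
pipeline therefore (1) finds isolated single eggs by edge detection
and fills them to blobs, (2) learns reference priors (gray level,
area, ellipse shape) from those singles, (3) binarizes the image at
many global gray levels (>= 10; e.g. 30..230 step 10), (4) keeps
egg-shaped blobs at each level, splitting clumps whose area is close
to an integer multiple of the single-egg area, and (5) clusters the
pooled detections across levels by location, counting each spatial
cluster that appears at enough distinct levels as one egg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import (
    BinaryImage,
    GrayImage,
    Region,
    canny_edges,
    fill_gaps_and_holes,
    label_regions,
)

__all__ = [
    "EggPriors",
    "EggDetection",
    "EggCountResult",
    "EggConfig",
    "EggPriorsError",
    "find_single_eggs",
    "multi_threshold_detect",
    "cluster_detections",
    "count_eggs",
]


class EggPriorsError(RuntimeError):
    """No isolated single egg could be found to calibrate detection."""


@dataclass
class EggConfig:
    """Tunables for the egg counter.

    ``levels`` defaults to gray values 30..230 in steps of 10 (21
    binary images).  ``merge_radius`` defaults to 0.55x the equivalent
    diameter of the reference egg — comfortably above replicate-finding
    scatter yet below the center spacing of two genuinely touching
    eggs, which must stay distinct; ``min_occurrences`` is the number
    of distinct levels a spatial cluster must appear at to count as an
    egg.
    """

    levels: tuple[int, ...] = tuple(range(30, 231, 10))
    min_occurrences: int = 3
    merge_radius: float | None = None
    canny_low: float = 10.0
    canny_high: float = 30.0
    canny_sigma: float = 1.5
    max_gap: int = 3
    single_area_range: tuple[int, int] = (15, 300)
    single_ecc_range: tuple[float, float] = (0.4, 0.93)
    single_min_solidity: float = 0.9
    gray_tolerance: float = 45.0
    clump_max_multiple: float = 5.0
    clump_min_solidity: float = 0.6
    clump_k_bias: float = 0.08
    pair_ecc: float = 0.86
    pair_solidity: float = 0.85


@dataclass
class EggPriors:
    """Reference morphology of a single egg, learned from the image."""

    ref_gray: float
    ref_area: float
    area_band: tuple[float, float]
    ellipse_band: tuple[float, float]
    n_singles: int
    low_confidence: bool = False

    @property
    def equivalent_diameter(self) -> float:
        return 2.0 * float(np.sqrt(self.ref_area / np.pi))


@dataclass
class EggDetection:
    """One unique egg after clustering."""

    centroid: tuple[float, float]
    area: float
    occurrences: int
    source_levels: list[int]


@dataclass
class EggCountResult:
    n_eggs: int
    detections: list[EggDetection]
    n_candidates_prefilter: int
    priors_used: EggPriors | None


@dataclass
class _RawDetection:
    centroid: np.ndarray
    area: float
    level: int


def find_single_eggs(img: GrayImage, cfg: EggConfig | None = None
                     ) -> tuple[list[Region], EggPriors]:
    """Locate isolated single eggs and learn detection priors from them.

    Canny edges -> gap/hole filling -> labeling -> keep blobs matching
    an egg template (broad area range, elliptical eccentricity, high
    solidity).  Priors are the medians of the accepted singles; a
    single-egg sample of one is flagged low-confidence.  Raises
    :class:`EggPriorsError` when nothing egg-like is found.
    """
    if cfg is None:
        cfg = EggConfig()
    edges = canny_edges(img, cfg.canny_low, cfg.canny_high, sigma=cfg.canny_sigma)
    filled = fill_gaps_and_holes(edges, cfg.max_gap)
    singles = []
    for r in label_regions(filled, intensity=img):
        if not cfg.single_area_range[0] <= r.area <= cfg.single_area_range[1]:
            continue
        if not cfg.single_ecc_range[0] <= r.eccentricity <= cfg.single_ecc_range[1]:
            continue
        if r.solidity < cfg.single_min_solidity:
            continue
        singles.append(r)
    if not singles:
        raise EggPriorsError(
            "no isolated single egg found; cannot calibrate egg detection")
    # the filled edge contour includes the smeared boundary ring, which
    # inflates both the area and the mean gray of a single egg; area is
    # corrected by the standard half-perimeter boundary term and gray is
    # measured on the eroded core
    ref_area = float(np.median([r.area - r.perimeter / 2 for r in singles]))
    ref_gray = float(np.median([_core_gray(r, img) for r in singles]))
    eccs = [r.eccentricity for r in singles]
    ellipse_band = (max(0.0, min(eccs) - 0.15), min(0.98, max(eccs) + 0.10))
    priors = EggPriors(
        ref_gray=ref_gray,
        ref_area=ref_area,
        area_band=(0.5 * ref_area, 1.5 * ref_area),
        ellipse_band=ellipse_band,
        n_singles=len(singles),
        low_confidence=len(singles) == 1,
    )
    return singles, priors


def _core_gray(r: Region, img: GrayImage) -> float:
    r0, c0, r1, c1 = r.bbox
    sub = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    sub[r.coords[:, 0] - r0 + 1, r.coords[:, 1] - c0 + 1] = True
    core = ndi.binary_erosion(sub)
    if not core.any():
        return r.mean_intensity
    rr, cc = np.nonzero(core)
    return float(img.pixels[rr + r0 - 1, cc + c0 - 1].mean())


def _split_clump(coords: np.ndarray, k: int) -> np.ndarray:
    """Deterministic k-means split of a clump's pixels into k centroids,
    initialized by quantiles along the clump's principal axis."""
    pts = coords.astype(float)
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    qs = np.quantile(proj, (np.arange(k) + 0.5) / k)
    centers = mean + qs[:, None] * vt[0]
    for _ in range(15):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d2.argmin(axis=1)
        new = np.array([pts[lab == j].mean(axis=0) if np.any(lab == j)
                        else centers[j] for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def multi_threshold_detect(img: GrayImage, priors: EggPriors,
                           levels: tuple[int, ...] | None = None,
                           cfg: EggConfig | None = None) -> list[_RawDetection]:
    """Detect egg-shaped blobs at every global threshold level.

    Each level's binary image is opened (3x3) to strip noise speckle,
    labeled, and filtered against the priors: mean gray near the
    reference egg gray, area within the single-egg band (one
    detection), or an aggregate up to ``clump_max_multiple`` x the
    reference area, which is split into ``round(area / ref_area)``
    sub-detections.  Obscured eggs surface at whichever subset of
    levels separates them from their background.
    """
    if cfg is None:
        cfg = EggConfig()
    if levels is None:
        levels = cfg.levels
    if len(levels) < 10:
        raise ValueError("multi-thresholding requires >= 10 levels")
    px = img.pixels
    raw: list[_RawDetection] = []
    structure = np.ones((3, 3), dtype=bool)
    for level in levels:
        mask = ndi.binary_opening(px < level, structure=structure)
        for r in label_regions(BinaryImage(mask), intensity=img):
            if abs(r.mean_intensity - priors.ref_gray) > cfg.gray_tolerance:
                continue
            if priors.area_band[0] <= r.area <= priors.area_band[1]:
                # a blob up to 1.5x the reference can also be two small
                # touching eggs; a genuine pair is more elongated or more
                # waisted than any single egg
                is_pair = (r.area > 1.2 * priors.ref_area
                           and (r.eccentricity > cfg.pair_ecc
                                or r.solidity < cfg.pair_solidity))
                if is_pair:
                    for cen in _split_clump(r.coords, 2):
                        raw.append(_RawDetection(cen, float(r.area) / 2, level))
                    continue
                if not priors.ellipse_band[0] <= r.eccentricity <= priors.ellipse_band[1]:
                    continue
                if r.solidity < 0.70:
                    continue
                raw.append(_RawDetection(np.asarray(r.centroid), float(r.area), level))
            elif priors.area_band[1] < r.area <= cfg.clump_max_multiple * priors.ref_area:
                if r.solidity < cfg.clump_min_solidity:
                    continue
                # touching eggs lose a little joint area at their contact
                # waist, so the multiplicity estimate is nudged upward
                k = int(round(r.area / priors.ref_area + cfg.clump_k_bias))
                if k < 2:
                    k = 2
                for cen in _split_clump(r.coords, k):
                    raw.append(_RawDetection(cen, float(r.area) / k, level))
    return raw


def cluster_detections(raw: list[_RawDetection], priors: EggPriors,
                       min_occurrences: int = 3,
                       merge_radius: float | None = None) -> EggCountResult:
    """Merge replicate findings across levels into unique eggs.

    Detections within ``merge_radius`` of a cluster's running-mean
    centroid join that cluster, with one constraint: a cluster may hold
    at most one detection per threshold level, because two detections
    in the same binary image are by construction distinct objects.
    Without this exclusivity the replicates of two adjacent eggs chain
    into a single cluster.  Clusters seen at fewer than
    ``min_occurrences`` distinct levels are dropped as spurious.
    """
    if merge_radius is None:
        merge_radius = 0.55 * priors.equivalent_diameter
    if merge_radius <= 0:
        raise ValueError("merge_radius must be > 0")
    centers: list[np.ndarray] = []
    sums: list[np.ndarray] = []
    members: list[list[_RawDetection]] = []
    levels_in: list[set[int]] = []
    for det in sorted(raw, key=lambda d: (d.level, d.centroid[0], d.centroid[1])):
        best, best_d = -1, merge_radius
        for i, cen in enumerate(centers):
            if det.level in levels_in[i]:
                continue
            d = float(np.hypot(*(det.centroid - cen)))
            if d <= best_d:
                best, best_d = i, d
        if best < 0:
            centers.append(det.centroid.copy())
            sums.append(det.centroid.copy())
            members.append([det])
            levels_in.append({det.level})
        else:
            members[best].append(det)
            sums[best] += det.centroid
            centers[best] = sums[best] / len(members[best])
            levels_in[best].add(det.level)
    detections = []
    for cen, mem in zip(centers, members):
        levels = sorted({d.level for d in mem})
        if len(levels) < min_occurrences:
            continue
        detections.append(EggDetection(
            centroid=(float(cen[0]), float(cen[1])),
            area=float(np.median([d.area for d in mem])),
            occurrences=len(levels),
            source_levels=levels,
        ))
    return EggCountResult(n_eggs=len(detections), detections=detections,
                          n_candidates_prefilter=len(raw), priors_used=priors)


def count_eggs(img: GrayImage, cfg: EggConfig | None = None) -> EggCountResult:
    """Full egg count: priors from singles, multi-threshold detection,
    duplicate-removing clustering.

    A plate with no dark foreground at all counts zero; a plate with
    dark objects but no valid single egg raises
    :class:`EggPriorsError` (an explicit failure, never a silent 0).
    """
    if cfg is None:
        cfg = EggConfig()
    try:
        _, priors = find_single_eggs(img, cfg)
    except EggPriorsError:
        if _has_dark_objects(img):
            raise
        return EggCountResult(n_eggs=0, detections=[],
                              n_candidates_prefilter=0, priors_used=None)
    raw = multi_threshold_detect(img, priors, cfg.levels, cfg)
    return cluster_detections(raw, priors, cfg.min_occurrences, cfg.merge_radius)


def _has_dark_objects(img: GrayImage, min_area: int = 25) -> bool:
    """Compact dark blobs present?  Thin curvilinear track marks are
    erased by the 5x5 opening — a plate bearing only tracks needs no
    egg priors and legitimately counts zero."""
    px = img.pixels.astype(float)
    bg = np.median(px)
    mask = ndi.binary_opening(px < bg - 30, structure=np.ones((5, 5)))
    if not mask.any():
        return False
    lab, n = ndi.label(mask)
    sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return bool(np.any(sizes >= min_area))
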