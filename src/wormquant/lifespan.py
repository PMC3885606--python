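"""Moving-worm counting for lifespan assays.

A well is scanned twice ~2 minutes apart; living worms reveal
themselves by changed pixels.  The engine binarizes the absolute
difference of the two scans, detects candidate worms in the second
scan, flags a candidate as moving when enough changed pixels fall
inside it, and recovers movers hidden against large dark objects from
the difference image alone.  Daily counts are then forced monotone
(step-wise decrease filter) and summarized into a death-day
distribution and mean lifespan, with day 0 the first day of adulthood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BinaryImage,
    GrayImage,
    Region,
    adaptive_threshold,
    label_regions,
    threshold_difference,
)

__all__ = [
    "LifespanParams",
    "MovingWormResult",
    "SurvivalSeries",
    "count_moving_worms",
    "stepwise_decrease_filter",
    "survival_summary",
]


@dataclass
class LifespanParams:
    """Detection parameters for the two-scan moving-worm count.

    ``min_changed_fraction`` is the movement-evidence threshold as a
    fraction of each candidate's area (scales across worm sizes); set
    ``min_changed_pixels`` to use an absolute pixel count instead.
    Size limits default to 40-2000 px, bracketing L4-adult worms at
    20 um/px.
    """

    min_worm_area: int = 40
    max_worm_area: int = 2000
    min_changed_pixels: int | None = None
    min_changed_fraction: float = 0.25
    interval_s: float = 120.0
    offset_fraction: float = 0.15
    diff_noise_floor: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.min_worm_area < self.max_worm_area:
            raise ValueError("require 0 < min_worm_area < max_worm_area")
        if self.min_changed_pixels is not None and self.min_changed_pixels < 1:
            raise ValueError("min_changed_pixels must be >= 1")

    def changed_threshold(self, roi_area: int) -> int:
        if self.min_changed_pixels is not None:
            return self.min_changed_pixels
        return max(1, int(round(self.min_changed_fraction * roi_area)))


@dataclass
class MovingWormResult:
    """Outcome of one two-scan count."""

    n_moving: int
    rois: list[Region]
    moving_flags: list[bool]
    extra_movers: list[Region]
    diff_mask: BinaryImage = field(repr=False, default=None)


def count_moving_worms(img1: GrayImage, img2: GrayImage,
                       p: LifespanParams | None = None) -> MovingWormResult:
    """Count moving worms between two scans of the same field.

    Pipeline: (1) binarize ``|img1 - img2|`` (changed pixels white);
    (2) detect candidate worms in the second scan by adaptive
    thresholding and size filtering; (3) flag a candidate as moving iff
    the changed pixels inside it reach the movement-evidence threshold;
    (4) add worm-sized difference components that overlap no candidate
    as extra movers (worms pressed against large dark objects are
    invisible to the candidate detector but still leave a difference
    footprint).  The absolute difference makes the result independent
    of scan order.
    """
    if p is None:
        p = LifespanParams()
    if img1.shape != img2.shape:
        raise ValueError("the two scans must have the same shape")
    diff = np.abs(img1.pixels.astype(np.int16) - img2.pixels.astype(np.int16))
    diff_mask = threshold_difference(diff, noise_floor=p.diff_noise_floor)

    worm_mask = adaptive_threshold(img2, offset_fraction=p.offset_fraction)
    candidates = [r for r in label_regions(worm_mask, intensity=img2)
                  if p.min_worm_area <= r.area <= p.max_worm_area]

    dm = diff_mask.mask
    flags: list[bool] = []
    for roi in candidates:
        changed = int(dm[roi.coords[:, 0], roi.coords[:, 1]].sum())
        flags.append(changed >= p.changed_threshold(roi.area))

    # movers invisible to the candidate detector: worm-sized difference
    # components disjoint (by bbox) from every candidate ROI.  A mover's
    # difference footprint spans both body positions, hence up to ~2x
    # the worm area.  A well-displaced worm leaves two disjoint
    # components — the vacated site (dark in scan 1 only) and the
    # occupied site (dark in scan 2) — so only components that are
    # substantially dark in the second scan count, which tallies each
    # hidden mover exactly once.
    wm2 = worm_mask.mask
    extra: list[Region] = []
    for comp in label_regions(diff_mask):
        if not (p.min_worm_area <= comp.area <= 2 * p.max_worm_area):
            continue
        if any(comp.bbox_intersects(roi) for roi in candidates):
            continue
        occupied_frac = float(wm2[comp.coords[:, 0], comp.coords[:, 1]].mean())
        if occupied_frac < 0.3:
            continue
        extra.append(comp)

    n_moving = int(sum(flags)) + len(extra)
    return MovingWormResult(n_moving=n_moving, rois=candidates,
                            moving_flags=flags, extra_movers=extra,
                            diff_mask=diff_mask)


def stepwise_decrease_filter(raw_counts: list[int]) -> list[int]:
    """Force daily living-worm counts to be non-increasing.

    Image analysis can detect more worms on a later day than an earlier
    one, which is biologically impossible under a fixed population; the
    correction raises any earlier count to the largest count observed
    from that day onward.  Equivalent to a right-to-left running
    maximum; idempotent.
    """
    if any(c < 0 for c in raw_counts):
        raise ValueError("counts must be >= 0")
    if not raw_counts:
        return []
    arr = np.asarray(raw_counts)
    return np.maximum.accumulate(arr[::-1])[::-1].tolist()


@dataclass
class SurvivalSeries:
    """Per-day living-worm counts with the derived death-day distribution."""

    days: list[int]
    raw_counts: list[int]
    filtered_counts: list[int]
    deaths_per_day: dict[int, int]
    mean_lifespan: float | None          # None when no deaths observed
    censored: bool

    def survival_fraction(self) -> list[float]:
        n0 = self.filtered_counts[0]
        if n0 == 0:
            return [0.0 for _ in self.filtered_counts]
        return [c / n0 for c in self.filtered_counts]


def survival_summary(counts: list[int], days: list[int] | None = None,
                     raw_counts: list[int] | None = None) -> SurvivalSeries:
    """Summarize a (filtered, non-increasing) count series.

    A worm dies on the first day its moving count drops, so the
    ``counts[t-1] - counts[t]`` deaths are assigned to day ``t``.  Mean
    lifespan is the death-count-weighted mean death day.  A series with
    no observed deaths is flagged censored with undefined mean.
    """
    if days is None:
        days = list(range(len(counts)))
    if len(days) != len(counts):
        raise ValueError("days and counts must have equal length")
    if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
        raise ValueError("counts must be non-increasing; apply "
                         "stepwise_decrease_filter first")
    deaths: dict[int, int] = {}
    for i in range(1, len(counts)):
        d = counts[i - 1] - counts[i]
        if d > 0:
            deaths[days[i]] = d
    total = sum(deaths.values())
    if total == 0:
        mean = None
        censored = True
    else:
        mean = sum(day * n for day, n in deaths.items()) / total
        censored = counts[-1] > 0
    return SurvivalSeries(days=list(days), raw_counts=list(raw_counts or counts),
                          filtered_counts=list(counts), deaths_per_day=deaths,
                          mean_lifespan=mean, censored=censored)
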