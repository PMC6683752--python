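"""Colocalization statistics: spatial Pearson shift-correlation profiles
and binary-mask overlap fractions.

The shift-correlation profile is the dual-label reconstruction control: a
line profile is drawn through a labeled structure in each of two channels
(averaged over a small perpendicular width to suppress noise without
averaging out heterogeneity), the two profiles are correlated, and one is
shifted against the other sample by sample.  Genuinely colocalized signal
peaks at zero shift; a registration error moves the peak to the offset.
The mask-overlap fraction quantifies how much of a reference structure
(rDNA) falls inside a comparison structure (nucleolin).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .imaging import (
    gaussian_blur,
    label_components,
    otsu_threshold,
    rolling_ball_subtract,
)

__all__ = [
    "LineProfileSpec",
    "CorrelationProfile",
    "OverlapResult",
    "line_profile",
    "pearson_shift_profile",
    "average_profiles",
    "nucleolin_overlap_mask",
    "rdna_mask",
    "overlap_fraction",
]


@dataclasses.dataclass
class LineProfileSpec:
    """A line through the image: two (row, col) endpoints, sampled at unit
    spacing and averaged over ``width_px`` perpendicular offsets."""

    start: tuple[float, float]
    end: tuple[float, float]
    width_px: int = 3

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise ValueError("endpoints must be distinct")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError("width_px must be odd and >= 1")


@dataclasses.dataclass
class CorrelationProfile:
    """Pearson r per integer shift, symmetric about zero.  ``r`` entries are
    NaN where a shifted overlap had zero variance."""

    shifts_px: np.ndarray
    r: np.ndarray
    n_loci: int = 1

    def __post_init__(self) -> None:
        self.shifts_px = np.asarray(self.shifts_px, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        if self.shifts_px.shape != self.r.shape:
            raise ValueError("shifts and r must align")
        if not np.array_equal(self.shifts_px, -self.shifts_px[::-1]):
            raise ValueError("shift grid must be symmetric about 0")

    @property
    def peak_shift(self) -> int:
        return int(self.shifts_px[np.nanargmax(self.r)])


@dataclasses.dataclass
class OverlapResult:
    numerator_px: int
    denominator_px: int

    @property
    def fraction(self) -> float:
        return self.numerator_px / self.denominator_px


def line_profile(channel: np.ndarray, spec: LineProfileSpec) -> np.ndarray:
    """Sample intensity along the line at unit spacing with bilinear
    interpolation, averaging across perpendicular offsets."""
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("line_profile expects a 2D channel")
    p0 = np.asarray(spec.start, dtype=float)
    p1 = np.asarray(spec.end, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n_samples = int(np.floor(length)) + 1
    t = np.linspace(0.0, length, n_samples) / length
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    half = (spec.width_px - 1) // 2
    offsets = np.arange(-half, half + 1)

    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    samples = np.empty((len(offsets), n_samples))
    for i, d in enumerate(offsets):
        rr = rows + d * normal[0]
        cc = cols + d * normal[1]
        if (rr.min() < 0 or cc.min() < 0
                or rr.max() > channel.shape[0] - 1 or cc.max() > channel.shape[1] - 1):
            raise ValueError("line (after widening) exits the image")
        samples[i] = ndi.map_coordinates(channel, [rr, cc], order=1, mode="nearest")
    return samples.mean(axis=0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # NaN for zero-variance segments: undefined r is missing, never 0
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pearson_shift_profile(
    prof_a: np.ndarray, prof_b: np.ndarray, max_shift: int = 20
) -> CorrelationProfile:
    """Pearson r of the overlapping segments of two equal-length profiles at
    every integer relative shift in -max_shift..max_shift.  Positive shift d
    correlates ``prof_a[i]`` against ``prof_b[i+d]``, so a copy of A delayed
    by d samples in B peaks at +d."""
    a = np.asarray(prof_a, dtype=float)
    b = np.asarray(prof_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1D and equal length")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if len(a) <= max_shift + 2:
        raise ValueError("profiles too short for the requested shift range")
    shifts = np.arange(-max_shift, max_shift + 1)
    r = np.empty(len(shifts))
    for i, d in enumerate(shifts):
        if d >= 0:
            seg_a, seg_b = a[: len(a) - d or None], b[d:]
        else:
            seg_a, seg_b = a[-d:], b[:d]
        if len(seg_a) < 3:
            raise ValueError("overlap shorter than 3 samples")
        r[i] = _pearson(seg_a, seg_b)
    return CorrelationProfile(shifts, r, n_loci=1)


def average_profiles(profiles: Sequence[CorrelationProfile]) -> CorrelationProfile:
    """Per-shift mean of r over loci, ignoring missing values."""
    if not profiles:
        raise ValueError("no profiles to average")
    grid = profiles[0].shifts_px
    for p in profiles[1:]:
        if not np.array_equal(p.shifts_px, grid):
            raise ValueError("profiles have different shift grids")
    stacked = np.vstack([p.r for p in profiles])
    with np.errstate(invalid="ignore"):
        mean_r = np.nanmean(stacked, axis=0)
    return CorrelationProfile(grid, mean_r, n_loci=sum(p.n_loci for p in profiles))


def nucleolin_overlap_mask(
    nucleolin_channel: np.ndarray,
    pixel_size_um: float,
    ball_radius_px: float = 50.0,
    blur_sigma_px: float = 4.0,
    min_area_um2: float = 1.0,
) -> np.ndarray:
    """Nucleolar mask for overlap analysis: rolling-ball background
    subtraction (r=50 px), Gaussian blur (sigma=4 px), Otsu threshold, and
    removal of objects below 1 um^2."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    img = rolling_ball_subtract(np.asarray(nucleolin_channel, dtype=float), ball_radius_px)
    img = gaussian_blur(img, blur_sigma_px)
    mask = img >= otsu_threshold(img)
    labels, n = label_components(mask, connectivity=8)
    if n == 0:
        return mask
    min_px = min_area_um2 / pixel_size_um**2
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def rdna_mask(rdna_channel: np.ndarray) -> np.ndarray:
    """Segment the (projected) rDNA FISH channel by Otsu thresholding."""
    img = np.asarray(rdna_channel, dtype=float)
    return img >= otsu_threshold(img)


def overlap_fraction(a: np.ndarray, b: np.ndarray) -> OverlapResult:
    """|A and B| / |A|.  Asymmetric: the first mask is the reference (e.g.
    the fraction of rDNA area overlapping nucleolin)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have equal dimensions")
    denom = int(a.sum())
    if denom == 0:
        raise ValueError("empty reference mask: overlap fraction undefined")
    return OverlapResult(numerator_px=int((a & b).sum()), denominator_px=denom)
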