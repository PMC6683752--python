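"""High-throughput nuclear and nucleolar segmentation and quantification.

The recipe: the DNA-counterstain channel is blurred, rolling-ball background
subtracted, self-normalized (so neighboring nuclei of unequal brightness
threshold together), thresholded at a fraction of the processed maximum, and
the resulting objects are filtered by border contact, area and circularity.
Nucleoli are then segmented inside each retained nucleus from the nucleolar
marker (nucleolin) channel with a finer version of the same recipe, using a
per-nucleus threshold.  Intensity statistics are always measured on raw
channels; the processed images are used for segmentation only.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from . import imaging
from .imaging import (
    fill_holes,
    gaussian_blur,
    label_components,
    region_stats,
    rolling_ball_subtract,
    self_normalize,
    threshold_fraction_of_max,
)

__all__ = [
    "PipelineParams",
    "segment_nuclei",
    "segment_nucleoli",
    "mean_nuclear_intensity",
    "nucleolar_report",
]


@dataclasses.dataclass
class PipelineParams:
    """Defaults are pixel-count parameters for ~0.1-0.2 um/px fields at 60x
    magnification; all are magnification-bound and therefore configurable."""

    nuclear_blur_sigma_px: float = 12.0
    nuclear_ball_radius_px: float = 200.0
    nuclear_norm_sigma_px: float = 200.0
    nuclear_threshold_fraction: float = 0.15
    nucleus_area_min_px: int = 5_000
    nucleus_area_max_px: int = 18_000
    circularity_min: float = 0.8
    nucleolar_blur_sigma_px: float = 2.0
    nucleolar_ball_radius_px: float = 15.0
    nucleolar_norm_sigma_px: float = 30.0
    nucleolar_threshold_fraction: float = 0.20
    nucleolus_area_min_px: int = 4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        for f in ("nuclear_threshold_fraction", "nucleolar_threshold_fraction"):
            if not 0 < getattr(self, f) <= 1:
                raise ValueError(f"{f} must lie in (0, 1]")
        if self.nucleus_area_min_px >= self.nucleus_area_max_px:
            raise ValueError("nucleus area min must be < max")


def _process_nuclear(dna: np.ndarray, p: PipelineParams) -> np.ndarray:
    img = gaussian_blur(dna, p.nuclear_blur_sigma_px)
    img = rolling_ball_subtract(img, p.nuclear_ball_radius_px)
    return self_normalize(img, p.nuclear_norm_sigma_px, divisor_floor=1.0)


def _process_nucleolar(nucleolin: np.ndarray, p: PipelineParams) -> np.ndarray:
    img = gaussian_blur(nucleolin, p.nucleolar_blur_sigma_px)
    img = rolling_ball_subtract(img, p.nucleolar_ball_radius_px)
    return self_normalize(img, p.nucleolar_norm_sigma_px, divisor_floor=1.0)


def segment_nuclei(
    dna_channel: np.ndarray, params: Optional[PipelineParams] = None
) -> np.ndarray:
    """Segment nuclei from the DNA-counterstain channel.

    Processing order: blur -> rolling-ball subtract -> self-normalize ->
    threshold at ``nuclear_threshold_fraction`` of the processed maximum ->
    label -> drop border-touching objects -> drop objects outside the area
    window -> fill holes per object -> drop circularity below the floor.
    Survivors are relabeled 1..n in raster order.
    """
    p = params or PipelineParams()
    dna = np.asarray(dna_channel, dtype=float)
    if dna.ndim != 2:
        raise ValueError("segment_nuclei expects a 2D image (project stacks first)")
    processed = _process_nuclear(dna, p)
    mask = threshold_fraction_of_max(processed, p.nuclear_threshold_fraction)
    labels, n = label_components(mask, connectivity=8)
    if n == 0:
        return labels

    keep = np.zeros_like(mask)
    from scipy import ndimage as ndi

    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        region = labels[sl] == lab
        if (region & border[sl]).any():
            continue
        filled = fill_holes(region)
        area = int(filled.sum())
        if not p.nucleus_area_min_px <= area <= p.nucleus_area_max_px:
            continue
        perim = imaging.region_perimeter(filled)
        if imaging.circularity(area, perim) < p.circularity_min:
            continue
        keep[sl] |= filled
    relabeled, _ = label_components(keep, connectivity=8)
    return relabeled


def segment_nucleoli(
    nucleolin_channel: np.ndarray,
    nuclei: np.ndarray,
    params: Optional[PipelineParams] = None,
) -> tuple[np.ndarray, dict[int, int]]:
    """Segment nucleoli inside each nucleus of a labeled nucleus map.

    The nucleolin channel is blurred, background subtracted and
    self-normalized once; each nucleus is then thresholded at
    ``nucleolar_threshold_fraction`` of its own processed maximum, so a dim
    nucleus cannot lose its nucleoli to a bright neighbor.  Returns a
    labeled nucleolus map plus ``{nucleolus_label: parent_nucleus_label}``.
    """
    p = params or PipelineParams()
    nuclei = np.asarray(nuclei)
    if nuclei.max() == 0:
        raise ValueError("empty nucleus mask")
    nucleolin = np.asarray(nucleolin_channel, dtype=float)
    if nucleolin.shape != nuclei.shape:
        raise ValueError("channel and nucleus map shapes differ")
    processed = _process_nucleolar(nucleolin, p)

    from scipy import ndimage as ndi

    out = np.zeros(nuclei.shape, dtype=np.int32)
    parents: dict[int, int] = {}
    next_label = 1
    n_nuclei = int(nuclei.max())
    objects = ndi.find_objects(nuclei)
    for nuc in range(1, n_nuclei + 1):
        sl = objects[nuc - 1]
        if sl is None:
            continue
        inside = nuclei[sl] == nuc
        mask = threshold_fraction_of_max(processed[sl], p.nucleolar_threshold_fraction, within=inside)
        labels, n = label_components(mask, connectivity=8)
        for lab in range(1, n + 1):
            region = labels == lab
            if int(region.sum()) < p.nucleolus_area_min_px:
                continue
            out[sl][region] = next_label
            parents[next_label] = nuc
            next_label += 1
    return out, parents


def mean_nuclear_intensity(nuclei: np.ndarray, channel: np.ndarray) -> dict[int, float]:
    """Arithmetic mean of the raw channel over each nucleus's pixels."""
    nuclei = np.asarray(nuclei)
    channel = np.asarray(channel, dtype=float)
    if channel.shape != nuclei.shape:
        raise ValueError("channel and nucleus map shapes differ")
    from scipy import ndimage as ndi

    n = int(nuclei.max())
    if n == 0:
        return {}
    means = ndi.mean(channel, labels=nuclei, index=np.arange(1, n + 1))
    return {lab: float(m) for lab, m in zip(range(1, n + 1), means)}


def nucleolar_report(
    nuclei: np.ndarray,
    nucleoli: np.ndarray,
    parents: dict[int, int],
    pixel_size_um: float,
    intensity_channels: Optional[dict[str, np.ndarray]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-nucleolus table, per-nucleus table and an image-level summary.

    The summary follows the averaging convention of averaging within nuclei
    first and then across nuclei of the image, with the SEM computed across
    nuclei.  Intensities are measured on the supplied raw channels.
    """
    intensity_channels = intensity_channels or {}
    nuc_stats = region_stats(nuclei, pixel_size_um)
    nucleolus_stats = region_stats(nucleoli, pixel_size_um)

    nucleolus_rows = []
    for s in nucleolus_stats:
        nucleolus_rows.append(
            {
                "nucleolus_id": s.label,
                "parent_nucleus_id": parents[s.label],
                "area_px": s.area_px,
                "area_um2": s.area_um2,
            }
        )
    per_nucleolus = pd.DataFrame(
        nucleolus_rows, columns=["nucleolus_id", "parent_nucleus_id", "area_px", "area_um2"]
    )

    channel_means = {
        name: mean_nuclear_intensity(nuclei, channel)
        for name, channel in intensity_channels.items()
    }
    nucleus_rows = []
    for s in nuc_stats:
        mine = per_nucleolus[per_nucleolus.parent_nucleus_id == s.label]
        row = {
            "nucleus_id": s.label,
            "area_px": s.area_px,
            "area_um2": s.area_um2,
            "circularity": s.circularity,
            "nucleolus_count": len(mine),
            "total_nucleolar_area_px": int(mine.area_px.sum()),
            "total_nucleolar_area_um2": float(mine.area_um2.sum()),
        }
        for name in intensity_channels:
            row[f"mean_{name}"] = channel_means[name][s.label]
        nucleus_rows.append(row)
    per_nucleus = pd.DataFrame(nucleus_rows)

    def _sem(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            return float("nan")
        return float(x.std(ddof=1) / np.sqrt(x.size))

    if len(per_nucleus):
        counts = per_nucleus["nucleolus_count"].to_numpy()
        areas = per_nucleus["total_nucleolar_area_um2"].to_numpy()
        summary = pd.DataFrame(
            [
                {
                    "n_nuclei": len(per_nucleus),
                    "mean_nucleolus_count": float(counts.mean()),
                    "sem_nucleolus_count": _sem(counts),
                    "mean_nucleolar_area_um2": float(areas.mean()),
                    "sem_nucleolar_area_um2": _sem(areas),
                }
            ]
        )
    else:
        summary = pd.DataFrame(
            [{"n_nuclei": 0, "mean_nucleolus_count": float("nan"),
              "sem_nucleolus_count": float("nan"),
              "mean_nucleolar_area_um2": float("nan"),
              "sem_nucleolar_area_um2": float("nan")}]
        )
    return per_nucleolus, per_nucleus, summary
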