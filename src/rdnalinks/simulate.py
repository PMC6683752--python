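"""Seeded generators for every input the pipelines consume, with
machine-readable ground truth.

The imaging generators emulate the structure of spinning-disk /
widefield fluorescence data: (a) interphase fields with DAPI-like nuclei
containing bright nucleoli in a nucleolin-like channel, over an additive
background gradient and Gaussian read noise; (b) condensed-chromatin
spreads whose rDNA channel carries bright foci joined by thin dim
filaments that are absent from the DNA counterstain — the defining
appearance of rDNA linkages; (c) dual-label copies of one structure in two
channels with independent noise.  The coverage generator emulates
whole-genome sequencing depth over a collapsed 45S repeat plus a panel of
single-copy exons, with gamma (negative-binomial-like) overdispersion.

All generators are pure functions of (parameters, seed): the same call is
bit-identical, and every rendered object is recorded in the ground truth.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copynumber import COVERAGE_COLUMNS
from .imaging import MultiChannelImage

__all__ = [
    "SceneGroundTruth",
    "CoverageGroundTruth",
    "make_nucleolar_scene",
    "make_spread_scene",
    "make_dual_label_scene",
    "make_filament_field",
    "make_coverage_table",
]

DEFAULT_SHAPE = (1024, 1024)
DEFAULT_PIXEL_SIZE_UM = 0.11  # 60x-like sampling

# nominal object intensities (arbitrary fluorescence units); the noise
# standard deviation of a channel is its object intensity / snr
DNA_INTENSITY = 100.0
NUCLEOLIN_INTENSITY = 200.0
FOCUS_INTENSITY = 200.0


@dataclasses.dataclass
class SceneGroundTruth:
    """Everything rendered into a scene: one row per object with geometry,
    intensity, channel membership and a compliance flag (False for decoys
    deliberately violating the segmentation filters)."""

    objects: pd.DataFrame
    seed: int
    pixel_size_um: float


@dataclasses.dataclass
class CoverageGroundTruth:
    true_copy_number: float
    haploid_depth: float
    dispersion: float
    chrom_dosage_factors: dict[str, float]
    seed: int


# ---------------------------------------------------------------------------
# rendering helpers


def _ellipse_mask(shape, center, radii, angle_rad=0.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius):
    return _ellipse_mask(shape, center, (radius, radius))


def _line_mask(shape, p0, p1, width_px):
    """Pixels within width_px/2 of the segment p0-p1."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    length2 = float(d @ d)
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / length2
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
    return dist <= width_px / 2.0


#: camera read-noise floor as a fraction of the full-signal noise sd
_READ_NOISE_FRACTION = 0.1


def _add_noise(rng, channel, amplitude, snr, gradient_amplitude=0.0):
    """Additive background gradient plus signal-dependent Gaussian noise.

    The noise sd scales with the square root of the local signal (the
    shot-noise law of fluorescence detection), reaching ``amplitude/snr``
    at full signal, with a small constant read-noise floor on background
    pixels.  A signal-independent noise floor as large as amplitude/snr
    would be unphysical for a fluorescence image and would bury any
    fixed-fraction-of-maximum threshold in false positives.
    """
    out = channel.copy()
    h, w = channel.shape
    if gradient_amplitude > 0:
        gr, gc = rng.uniform(-1, 1, 2)
        norm = max(abs(gr), abs(gc), 1e-9)
        rr, cc = np.mgrid[:h, :w]
        plane = (gr * rr / h + gc * cc / w) / norm
        out += gradient_amplitude * (plane - plane.min())
    sd = (amplitude / snr) * np.sqrt(
        np.clip(out, 0.0, None) / amplitude + _READ_NOISE_FRACTION**2
    )
    out += rng.normal(0.0, 1.0, size=channel.shape) * sd
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# nucleolar scenes


def _place_centers(rng, shape, n, radii_list, margin, min_gap, max_tries=2000):
    """Rejection-sample n centers with given per-object bounding radii so
    objects stay margin px from the border and min_gap px apart."""
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii_list:
        for _ in range(max_tries):
            cand = (
                rng.uniform(r + margin, shape[0] - r - margin),
                rng.uniform(r + margin, shape[1] - r - margin),
            )
            ok = all(
                np.hypot(cand[0] - c[0], cand[1] - c[1]) >= r + pr + min_gap
                for c, pr in zip(centers, placed_r)
            )
            if ok:
                centers.append(cand)
                placed_r.append(r)
                break
        else:
            raise RuntimeError(
                f"could not place {n} objects of radius ~{r:.0f} in {shape} "
                "within the retry budget"
            )
    return centers


def make_nucleolar_scene(
    n_nuclei: int = 8,
    nucleoli_per_nucleus: Sequence[int] = (1, 2, 3),
    nucleoli_probs: Sequence[float] = (0.3, 0.45, 0.25),
    snr: float = 10.0,
    background_gradient: float = 5.0,
    seed: int = 0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    nucleus_area_range_px: tuple[float, float] = (6_000.0, 11_000.0),
    nucleolus_radius_range_px: tuple[float, float] = (4.0, 7.0),
    add_small_decoy: bool = False,
    add_border_nucleus: bool = False,
    add_dumbbell: bool = False,
) -> tuple[MultiChannelImage, SceneGroundTruth]:
    """Interphase field: elliptical nuclei in the DNA channel, bright
    nucleolar disks over dim nucleoplasm in the nucleolin channel.

    Compliant nuclei fall inside the default acceptance window: geometric
    areas of 6,000-11,000 px leave room for the systematic outward dilation
    of the 15%-of-max threshold on the blurred image (~10 px radially, about
    +40% in area) while the measured area stays inside the 5,000-18,000
    filter; circularity is near 1; nuclei keep 40 px clearance from the
    border (so the dilated mask cannot touch it) and 50 px from each other
    (so blurred tails cannot bridge above threshold).  Decoy
    flags add objects that the segmentation filters must reject: an
    undersized blob, a border-clipped nucleus, a low-circularity dumbbell.
    """
    if n_nuclei < 0 or snr <= 0:
        raise ValueError("need n_nuclei >= 0 and snr > 0")
    rng = np.random.default_rng(seed)
    dna = np.zeros(shape)
    nucleolin = np.zeros(shape)
    rows = []

    # sample nucleus geometry first so placement knows the bounding radii
    geoms = []
    for _ in range(n_nuclei):
        area = rng.uniform(*nucleus_area_range_px)
        ratio = rng.uniform(1.0, 1.35)
        b = np.sqrt(area / (np.pi * ratio))
        a = ratio * b
        geoms.append((a, b, rng.uniform(0, np.pi)))
    bounding = [g[0] for g in geoms]
    extra = []
    if add_small_decoy:
        # small enough that even the ~10 px threshold dilation keeps the
        # measured area below the 5,000 px floor
        extra.append(("small_decoy", 20.0))
    if add_dumbbell:
        extra.append(("dumbbell", 80.0))
    centers = _place_centers(
        rng, shape, n_nuclei + len(extra), bounding + [e[1] for e in extra],
        margin=40.0, min_gap=50.0,
    )

    nucleolus_id = 0
    for i, ((a, b, angle), center) in enumerate(zip(geoms, centers[:n_nuclei]), start=1):
        nuc_mask = _ellipse_mask(shape, center, (a, b), angle)
        intensity = DNA_INTENSITY * rng.uniform(0.7, 1.0)
        dna[nuc_mask] = np.maximum(dna[nuc_mask], intensity)
        nucleolin[nuc_mask] = np.maximum(
            nucleolin[nuc_mask], 0.08 * NUCLEOLIN_INTENSITY
        )  # dim nucleoplasmic signal
        rows.append(
            dict(object="nucleus", id=i, parent=0, row=center[0], col=center[1],
                 r_major=a, r_minor=b, angle=angle, area_px=int(nuc_mask.sum()),
                 intensity=intensity, channel="dna", compliant=True)
        )
        # nucleoli inside this nucleus
        k = int(rng.choice(nucleoli_per_nucleus, p=nucleoli_probs))
        radii = rng.uniform(*nucleolus_radius_range_px, size=k)
        placed: list[tuple[float, float]] = []
        for r in radii:
            for _ in range(500):
                # stay well inside the nucleus: sample in the inscribed ellipse
                t = rng.uniform(0, 2 * np.pi)
                u = np.sqrt(rng.uniform(0, 1))
                shrink_a = max(a - r - 10.0, 1.0)
                shrink_b = max(b - r - 10.0, 1.0)
                du = u * np.cos(t) * shrink_a
                dv = u * np.sin(t) * shrink_b
                ca, sa = np.cos(angle), np.sin(angle)
                cand = (center[0] + du * ca - dv * sa, center[1] + du * sa + dv * ca)
                if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= r + pr + 8.0
                       for p, pr in zip(placed, radii)):
                    placed.append(cand)
                    break
            else:
                continue
            nucleolus_id += 1
            ncl_mask = _disk_mask(shape, cand, r)
            ncl_int = NUCLEOLIN_INTENSITY * rng.uniform(0.7, 1.0)
            nucleolin[ncl_mask] = np.maximum(nucleolin[ncl_mask], ncl_int)
            rows.append(
                dict(object="nucleolus", id=nucleolus_id, parent=i, row=cand[0],
                     col=cand[1], r_major=r, r_minor=r, angle=0.0,
                     area_px=int(ncl_mask.sum()), intensity=ncl_int,
                     channel="nucleolin", compliant=True)
            )

    decoy_centers = centers[n_nuclei:]
    for (kind, r), center in zip(extra, decoy_centers):
        if kind == "small_decoy":
            mask = _disk_mask(shape, center, r)  # ~1,250 px, under-area decoy
        else:  # dumbbell: two lobes + neck, circularity well below 0.8
            lobe = 36.0
            off = 60.0
            mask = (
                _disk_mask(shape, (center[0], center[1] - off), lobe)
                | _disk_mask(shape, (center[0], center[1] + off), lobe)
                | _line_mask(shape, (center[0], center[1] - off),
                             (center[0], center[1] + off), 18.0)
            )
        dna[mask] = np.maximum(dna[mask], DNA_INTENSITY * 0.9)
        rows.append(
            dict(object=kind, id=0, parent=0, row=center[0], col=center[1],
                 r_major=r, r_minor=r, angle=0.0, area_px=int(mask.sum()),
                 intensity=DNA_INTENSITY * 0.9, channel="dna", compliant=False)
        )
    if add_border_nucleus:
        r = 55.0
        center = (2.0, shape[1] / 2)
        mask = _disk_mask(shape, center, r)
        dna[mask] = np.maximum(dna[mask], DNA_INTENSITY * 0.9)
        rows.append(
            dict(object="border_nucleus", id=0, parent=0, row=center[0],
                 col=center[1], r_major=r, r_minor=r, angle=0.0,
                 area_px=int(mask.sum()), intensity=DNA_INTENSITY * 0.9,
                 channel="dna", compliant=False)
        )

    dna = _add_noise(rng, dna, DNA_INTENSITY, snr, background_gradient)
    nucleolin = _add_noise(rng, nucleolin, NUCLEOLIN_INTENSITY, snr, background_gradient)
    truth = SceneGroundTruth(
        objects=pd.DataFrame(
            rows, columns=["object", "id", "parent", "row", "col", "r_major",
                           "r_minor", "angle", "area_px", "intensity",
                           "channel", "compliant"],
        ),
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    img = MultiChannelImage(
        data={"dna": dna, "nucleolin": nucleolin}, pixel_size_um=pixel_size_um
    )
    return img, truth


# ---------------------------------------------------------------------------
# chromosome-spread scenes


def make_spread_scene(
    n_foci: int = 9,
    linkage_pairs: Sequence[tuple[int, int]] = (),
    bridge_intensity_fraction: float = 0.5,
    snr: float = 10.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    focus_radius_px: float = 5.0,
    min_separation_px: float = 10.0,
    bridge_width_px: float = 2.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[MultiChannelImage, SceneGroundTruth]:
    """Condensed-chromatin spread: bright rDNA foci, one per rDNA-bearing
    chromosome, plus thin dim bridges joining each listed pair of foci.

    Bridges are drawn in the rDNA channel only — linkages are not stained
    by DNA counterstains — at ``bridge_intensity_fraction`` of the focus
    intensity.  ``min_separation_px`` is edge-to-edge clearance between
    foci.
    """
    pairs = [tuple(p) for p in linkage_pairs]
    flat = [i for p in pairs for i in p]
    if any(not 0 <= i < n_foci for i in flat):
        raise ValueError("linkage pair indices out of range")
    if any(a == b for a, b in pairs):
        raise ValueError("linkage pair indices must be distinct")
    rng = np.random.default_rng(seed)
    rdna = np.zeros(shape)
    dna = np.zeros(shape)

    def _segment_clearance(p0, p1, q):
        p0, p1, q = (np.asarray(x, float) for x in (p0, p1, q))
        d = p1 - p0
        t = np.clip(((q - p0) @ d) / (d @ d), 0.0, 1.0)
        return float(np.hypot(*(q - (p0 + t * d))))

    # bridges must not graze a third focus, or the component arithmetic
    # (count = n_foci - n_pairs) would silently break; retry whole layouts
    clearance = focus_radius_px + bridge_width_px / 2 + 6.0
    for _ in range(50):
        centers = _place_centers(
            rng, shape, n_foci, [focus_radius_px] * n_foci,
            margin=20.0, min_gap=min_separation_px + 25.0,
        )
        ok = all(
            _segment_clearance(centers[a], centers[b], centers[c]) >= clearance
            for a, b in pairs
            for c in range(n_foci)
            if c not in (a, b)
        )
        # disjoint bridges must not cross or touch each other either
        def _cross(p0, p1, q0, q1):
            p0, p1, q0, q1 = (np.asarray(x, float) for x in (p0, p1, q0, q1))

            def orient(a, b, c):
                u, v = b - a, c - a
                return np.sign(u[0] * v[1] - u[1] * v[0])

            return (orient(p0, p1, q0) * orient(p0, p1, q1) < 0
                    and orient(q0, q1, p0) * orient(q0, q1, p1) < 0)

        for (a, b), (c, d) in itertools.combinations(pairs, 2):
            if {a, b} & {c, d}:
                continue
            gap = min(
                _segment_clearance(centers[a], centers[b], centers[c]),
                _segment_clearance(centers[a], centers[b], centers[d]),
                _segment_clearance(centers[c], centers[d], centers[a]),
                _segment_clearance(centers[c], centers[d], centers[b]),
            )
            if _cross(centers[a], centers[b], centers[c], centers[d]) or gap < clearance:
                ok = False
        if ok:
            break
    else:
        raise RuntimeError("could not place foci with clear bridge paths")
    rows = []
    for i, center in enumerate(centers):
        focus = _disk_mask(shape, center, focus_radius_px)
        rdna[focus] = np.maximum(rdna[focus], FOCUS_INTENSITY)
        # chromosome body in the counterstain, oriented randomly
        angle = rng.uniform(0, np.pi)
        body = _ellipse_mask(shape, center, (3.5 * focus_radius_px, 1.6 * focus_radius_px), angle)
        dna[body] = np.maximum(dna[body], DNA_INTENSITY)
        rows.append(
            dict(object="rdna_focus", id=i, parent=-1, row=center[0], col=center[1],
                 r_major=focus_radius_px, r_minor=focus_radius_px, angle=angle,
                 area_px=int(focus.sum()), intensity=FOCUS_INTENSITY,
                 channel="rdna", compliant=True)
        )
    for a, b in pairs:
        bridge = _line_mask(shape, centers[a], centers[b], bridge_width_px)
        level = bridge_intensity_fraction * FOCUS_INTENSITY
        rdna[bridge] = np.maximum(rdna[bridge], level)
        rows.append(
            dict(object="linkage_bridge", id=a, parent=b, row=centers[a][0],
                 col=centers[a][1], r_major=0.0, r_minor=0.0, angle=0.0,
                 area_px=int(bridge.sum()), intensity=level,
                 channel="rdna", compliant=True)
        )
    rdna = _add_noise(rng, rdna, FOCUS_INTENSITY, snr)
    dna = _add_noise(rng, dna, DNA_INTENSITY, snr)
    truth = SceneGroundTruth(
        objects=pd.DataFrame(rows), seed=seed, pixel_size_um=pixel_size_um
    )
    img = MultiChannelImage(
        data={"rdna": rdna, "dna": dna}, pixel_size_um=pixel_size_um
    )
    return img, truth


# ---------------------------------------------------------------------------
# dual-label scenes


def make_dual_label_scene(
    base_scene: np.ndarray,
    channel_shift_px: int = 0,
    per_channel_snr: float = 10.0,
    seed: int = 0,
    amplitude: Optional[float] = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[MultiChannelImage, SceneGroundTruth]:
    """Render one noise-free structure in two channels with independent
    noise; the second channel is translated along columns by
    ``channel_shift_px`` (the injected registration error).

    ``per_channel_snr=inf`` gives noiseless channels.
    """
    base = np.asarray(base_scene, dtype=float)
    if base.ndim != 2:
        raise ValueError("base_scene must be 2D")
    if abs(channel_shift_px) >= base.shape[1]:
        raise ValueError("shift larger than the image")
    rng = np.random.default_rng(seed)
    shifted = np.roll(base, channel_shift_px, axis=1)
    # SNR is defined against typical structure brightness (99th percentile)
    amp = amplitude if amplitude is not None else float(np.percentile(base, 99)) or 1.0
    if np.isinf(per_channel_snr):
        ch_a, ch_b = base.copy(), shifted
    else:
        ch_a = _add_noise(rng, base, amp, per_channel_snr)
        ch_b = _add_noise(rng, shifted, amp, per_channel_snr)
    truth = SceneGroundTruth(
        objects=pd.DataFrame(
            [dict(object="dual_label", id=0, parent=0, row=0.0, col=0.0,
                  r_major=0.0, r_minor=0.0, angle=0.0, area_px=int((base > 0).sum()),
                  intensity=float(base.max()), channel="both",
                  compliant=True, shift_px=channel_shift_px)]
        ),
        seed=seed,
        pixel_size_um=pixel_size_um,
    )
    img = MultiChannelImage(
        data={"label_a": ch_a, "label_b": ch_b}, pixel_size_um=pixel_size_um
    )
    return img, truth


def make_filament_field(
    shape: tuple[int, int] = (256, 256),
    density: float = 0.02,
    thickness_sigma_px: float = 2.5,
    amplitude: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Noise-free filamentous structure resembling decondensed rDNA fibers:
    sparse seeds smoothed into overlapping soft threads.

    Normalized so that the 99th intensity percentile equals ``amplitude``:
    the signal-to-noise ratio of a scene built on this field is then
    defined against typical filament brightness, not against the single
    brightest crossing point.  Used as the base structure for dual-label
    scenes."""
    rng = np.random.default_rng(seed)
    seeds = (rng.random(shape) > 1.0 - density).astype(float)
    field = _gaussian(seeds, thickness_sigma_px)
    scale = np.percentile(field, 99.0)
    if scale == 0:
        return field
    return field / scale * amplitude


def _gaussian(img, sigma):
    from scipy import ndimage as ndi

    return ndi.gaussian_filter(img, sigma, mode="reflect")


# ---------------------------------------------------------------------------
# sequencing coverage


def make_coverage_table(
    true_copy_number: float = 400.0,
    n_exons: int = 1000,
    haploid_depth: float = 15.0,
    dispersion: float = 0.02,
    chrom_dosage_factors: Optional[dict[str, float]] = None,
    seed: int = 0,
    n_45s_windows: int = 100,
    locus_length_bp: int = 43_000,
    bins_per_chrom: int = 200,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], CoverageGroundTruth]:
    """Simulate a coverage table over the 45S locus and single-copy exons,
    plus binned per-chromosome depths.

    Depth convention: the background genome is diploid, so the expected
    exon mean depth is ``2 * haploid_depth * dosage`` and the copy number
    is reported per background-normalized (diploid) unit: the expected 45S
    depth is ``2 * haploid_depth * true_copy_number``.  Mean depths are
    drawn from a gamma distribution with unit mean and squared coefficient
    of variation ``dispersion`` (the continuous negative-binomial-like
    limit for a regional mean); ``dispersion=0`` is exactly noiseless, so
    the estimator returns ``true_copy_number`` identically.

    Returns (coverage table, {chrom: binned depths}, ground truth).
    """
    if true_copy_number <= 0 or haploid_depth <= 0 or dispersion < 0:
        raise ValueError("copy number, depth must be positive; dispersion >= 0")
    if n_exons < 10:
        raise ValueError("need n_exons >= 10")
    rng = np.random.default_rng(seed)
    factors = chrom_dosage_factors or {f"chr{i}": 1.0 for i in range(1, 23)}
    chroms = list(factors)

    def draw(mean, size):
        if dispersion == 0:
            return np.full(size, mean, dtype=float)
        shape_p = 1.0 / dispersion
        return rng.gamma(shape_p, scale=np.asarray(mean) / shape_p, size=size)

    background = 2.0 * haploid_depth
    rows = []
    # 45S locus tiled into windows
    edges = np.linspace(0, locus_length_bp, n_45s_windows + 1).astype(int)
    mu_45s = background * true_copy_number
    depths_45s = draw(mu_45s, n_45s_windows)
    for i in range(n_45s_windows):
        rows.append(
            dict(region_id=f"r45S_w{i:03d}", **{"class": "r45S"}, chrom="r45S",
                 start=edges[i], end=edges[i + 1], mean_depth=depths_45s[i])
        )
    # single-copy exons spread over the autosomes
    exon_chroms = rng.choice(chroms, size=n_exons)
    exon_lengths = rng.integers(200, 2_001, size=n_exons)
    exon_starts = rng.integers(0, 100_000_000, size=n_exons)
    exon_mu = background * np.array([factors[c] for c in exon_chroms])
    exon_depths = draw(exon_mu, n_exons)
    for i in range(n_exons):
        rows.append(
            dict(region_id=f"exon_{i:05d}", **{"class": "single_copy_exon"},
                 chrom=str(exon_chroms[i]), start=int(exon_starts[i]),
                 end=int(exon_starts[i] + exon_lengths[i]),
                 mean_depth=exon_depths[i])
        )
    cov = pd.DataFrame(rows, columns=COVERAGE_COLUMNS)

    binned = {
        c: draw(background * factors[c], bins_per_chrom) for c in chroms
    }
    truth = CoverageGroundTruth(
        true_copy_number=true_copy_number,
        haploid_depth=haploid_depth,
        dispersion=dispersion,
        chrom_dosage_factors=dict(factors),
        seed=seed,
    )
    return cov, binned, truth
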