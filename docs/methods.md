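# Methods

This note documents the models and procedures implemented in `rdnalinks`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Scientific setting

Human 45S ribosomal DNA (rDNA) is carried in tandem repeat arrays on the
short arms of the five acrocentric chromosome pairs (13, 14, 15, 21, 22).
The arrays from different chromosomes co-organize the nucleolus in
interphase, and on mitotic spreads the loci of heterologous chromosomes
can be joined by thin, thread-like "linkages" that are visible by rDNA
FISH but not by DNA counterstains. The package implements the
quantitative procedures such a study needs: nucleolar morphometry from
immunofluorescence, colocalization statistics, counting of separated
condensed rDNA loci, contingency statistics on linkage counts between
transcriptionally active (UBF-positive) and silent (UBF-negative) loci,
and rDNA copy-number estimation from whole-genome sequencing coverage.
All pipelines are exercised end-to-end on seeded synthetic fixtures with
machine-readable ground truth; no microscopy or sequencing raw data are
consumed.

## Nuclear and nucleolar segmentation

The DNA-counterstain channel is processed as: Gaussian blur (sigma = 12 px)
→ rolling-ball background subtraction (radius = 200 px) → division by a
Gaussian-blurred copy of itself (sigma = 200 px, divisor clamped to >= 1)
→ threshold at 15% of the processed maximum. Objects touching the image
border, with areas outside [5,000, 18,000] px, or with circularity
4·π·A/P² < 0.8 (computed after per-object hole filling) are discarded.
Nucleoli are segmented from the nucleolar-marker (nucleolin) channel with
the same recipe at finer scales (blur sigma = 2 px, ball radius = 15 px,
normalization sigma = 30 px), thresholded at 20% of the processed maximum
*within each nucleus*, with objects < 4 px removed. All of these constants
are exposed in `PipelineParams`; they are pixel-count parameters
appropriate for ~0.1–0.2 µm/px sampling at 60× magnification and must be
rescaled for other optics.

Conventions worth stating:

- The self-normalization step equalizes nuclei of unequal staining so one
  relative threshold works across the field; the clamp of the divisor at 1
  keeps dark background from being amplified.
- Segmentation runs on processed images; every intensity statistic
  (per-nucleus marker means, etc.) is measured on the raw channel, because
  self-normalization destroys absolute intensity.
- Filters are applied in the order: border contact, area window, hole
  filling, circularity. Circularity is therefore measured on filled
  objects. Hole filling is per-object, so inter-nuclear background is
  never filled.
- A nucleolus is assigned to the nucleus whose mask contains it;
  thresholding within nucleus masks makes a nucleolus spanning two nuclei
  impossible by construction.
- Image-level summaries average within nuclei first and then across the
  nuclei of the image, with the SEM taken across nuclei.

### Known bias: threshold dilation

A fixed-fraction-of-maximum threshold sits where the blurred edge profile
of an object crosses that fraction, which for a sharp-edged object lies
*outside* the true boundary. With the defaults, nuclear masks are dilated
by roughly 10 px radially (about +40% in area for ~10⁴ px nuclei) and
nucleolar masks by 1.5–2 px (which is +40–80% in area for realistic
4–7 px-radius nucleoli). The object *counts* are unaffected, and because
the bias is common to all conditions analyzed with the same constants,
*relative* comparisons of nucleolar size between conditions remain valid;
absolute areas from this recipe are upper bounds. The test suite pins the
bias down as a property: the equivalent-radius error of segmented
nucleoli stays within [0, 3] px of ground truth.

## Colocalization

Two statistics are implemented. The *spatial Pearson shift-correlation
profile* validates dual-label imaging: an intensity profile is sampled
along a user-supplied line in each channel (unit spacing, bilinear
interpolation, averaged over a 3-px perpendicular width to suppress noise
without averaging out structure), the Pearson correlation of the two
profiles is computed, and one profile is then shifted against the other
by integer offsets (default ±20 px). Colocalized signal peaks at shift 0;
a registration error moves the peak to the offset. Profiles from many
loci are averaged per shift; shifts whose overlapping segments have zero
variance yield an undefined r that is recorded as missing and excluded
from averages rather than treated as 0. Shifting is along the profile
axis only.

The *mask-overlap fraction* quantifies how much of a reference structure
lies inside a comparison structure: the nucleolar (nucleolin) mask is
produced by rolling-ball subtraction (radius 50 px), Gaussian blur
(sigma 4 px), Otsu thresholding, and removal of objects < 1 µm²; the rDNA
channel is Otsu-thresholded (the threshold method for this channel is a
configuration choice; Otsu is the default for symmetry). The overlap
fraction |A∧B|/|A| is asymmetric with the rDNA mask as reference.

## Spot counting and linkage statistics

On a condensed-chromatin (premature chromosome condensation) image, a
"separated rDNA spot" is a connected component (8-neighbor) of pixels at
or above 20% of the image maximum, after discarding components < 4 px.
Connectivity is the definition of separation: two loci joined by an
above-threshold bridge are one spot, so with N unlinked rDNA-bearing
chromosomes the expected count is N and each bridge-linked pair removes
exactly one. An RPE1-like karyotype carries rDNA on 9 of its 10
acrocentric chromosomes, so 9 is the reference count.

Linkage occurrence between active and silent loci is tested with Fisher's
exact test on a 2×2 table. The default construction is *event-based*:
each linkage is one event scored against the locus denominator, giving
[[linkages_active, other_active], [linkages_silent, other_silent]]. A
*loci-involved* construction (two loci per pairwise linkage) is available
behind a flag; the published bound holds under either. Sidedness defaults
to one-sided "greater" (the directional claim that active loci carry more
linkages), with two-sided available. Per-spread linkage counts are
compared with the Mann–Whitney U test using midranks; for nA+nB ≤ 12 the
p-value is exact by full enumeration of group assignments (valid under
ties), otherwise the tie-corrected normal approximation is used. qPCR
expression ratios use 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_reference) of
the sample minus the same difference of the control.

## Copy number from sequencing coverage

Reads are assumed to have been aligned to a reference carrying a single
collapsed 45S repeat plus a large panel of pre-selected single-copy exons
(one per gene); only aligner-flagged concordant pairs are kept (the
filter trusts the aligner's call and does not re-evaluate insert sizes).
The pipeline consumes per-region mean depths. Copy number is the
length-weighted mean depth over the 45S records divided by the *median*
mean-depth of the single-copy exons — the median makes the background
robust to the occasional mis-annotated or duplicated exon (perturbing 10%
of exons by 10× moves the denominator by < 5%). Both quantities scale
linearly with sequencing depth, so the ratio is depth-invariant.
Chromosomal dosage is the per-chromosome median depth divided by the
median of all chromosomal medians: disomic chromosomes sit at 1, a
trisomy in a diploid at 1.5. Coordinates are 0-based half-open
throughout. Copy number is reported per background-normalized (diploid)
unit.

## Synthetic data

The generators are pure functions of (parameters, seed) — regeneration is
bit-identical — and every rendered object is recorded in the ground
truth, including decoys built to violate specific filters.

*Nucleolar scenes* render elliptical nuclei (axis ratio ≤ 1.35, geometric
area 6,000–11,000 px so the dilated measured area stays inside the
5,000–18,000 px window) with uniform interiors, nucleolar disks of
4–7 px radius over a dim nucleoplasmic pedestal in the nucleolin channel,
an additive linear background gradient, and noise (below). Compliant
nuclei keep 40 px from the border and 50 px from each other so that
threshold dilation cannot produce border contact or merging. Decoy flags
add an under-area blob, a border-clipped nucleus and a low-circularity
dumbbell. The default canvas is 1024×1024 px at 0.11 µm/px; the recovery
sweeps in the test suite use 512×512 px with three nuclei per scene,
which exercises identical code paths at desk scale.

*Spread scenes* place one bright rDNA focus (5 px radius disk) per
rDNA-bearing chromosome with a minimum edge-to-edge separation (default
10 px), an elongated chromosome body per focus in the DNA counterstain,
and a thin (2 px) bridge at a stated fraction (default 0.5) of the focus
intensity joining each listed pair of foci — in the rDNA channel only,
since linkages are not stained by DNA dyes. Layouts are re-drawn until no
bridge passes near a third focus and no two disjoint bridges touch, so
the component arithmetic (spots = foci − linked pairs) holds by
construction.

*Dual-label scenes* render one structure (by default a filamentous field
emulating decondensed nucleolar rDNA) in two channels with independent
noise, the second channel translated by an integer offset. The field is
normalized so its 99th intensity percentile equals the nominal amplitude:
the signal-to-noise ratio is defined against typical filament brightness,
not against the single brightest crossing point.

*Noise model.* Imaging noise is Gaussian with a signal-dependent standard
deviation sd(I) = (A/snr)·sqrt(I/A + 0.01), where A is the nominal object
amplitude — the shot-noise law of fluorescence detection with a 10% read-
noise floor, reaching A/snr at full signal. A signal-independent floor of
A/snr everywhere would be unphysical for fluorescence data and would bury
any fixed-fraction-of-maximum threshold in false positives at low SNR.
Intensities are clipped at zero after noise addition.

*Coverage tables* draw regional mean depths from a gamma distribution
with unit mean and squared coefficient of variation `dispersion` (the
continuous negative-binomial-like limit appropriate for a regional mean;
`dispersion = 0` is exactly noiseless, making the noiseless estimator
identity testable). Exons center on the diploid background
2·haploid_depth scaled by per-chromosome dosage factors; the 45S locus is
tiled into 100 windows centered on 2·haploid_depth·copy_number. Defaults:
haploid depth 15×, 1,000 exons, dispersion 0.02 (≈14% CV per window).

What the generators do **not** emulate: optical point-spread functions
and diffraction (objects have sharp edges), photobleaching, chromatic
aberration beyond a rigid shift, autofluorescence texture, overlapping
nuclei, GC or mappability bias in coverage, and read-level sampling.
Passing tests therefore demonstrate the correctness of the measurement
logic under controlled conditions, not robustness to every artifact of
real acquisitions.

## Numerical choices

- **Rolling ball.** The background is the grayscale morphological opening
  with a disk structuring element, computed exactly by decomposing the
  disk into horizontal segments and running 1-D moving-minimum/maximum
  filters per row offset. For radii > 32 px the opening is evaluated on a
  block-minimum-shrunk image (bin = radius/16) and bilinearly upsampled —
  the classical large-radius speed-up — and the background is clamped
  below the image, so 0 ≤ output ≤ input holds exactly on every path.
- **Perimeter.** Region perimeters use the 4-direction Crofton estimate
  (boundary intercepts of four line families). A polygonal marching-
  squares contour was rejected because its staircase overestimates smooth
  boundaries by ~6%, pushing the circularity of a perfect rasterized disk
  down to ~0.89; the Crofton estimate keeps it at 0.99. Circularity is
  clamped to [0, 1] (discretization can push 4πA/P² slightly above 1 for
  small squares) and defined as 0 for zero-area structures.
- **Boundary handling** is reflective (edge-inclusive) for all filters,
  avoiding edge darkening that would bias the border-object filter.
- **Connectivity** defaults to 8-neighbor; labels are assigned in
  raster-scan order of first encounter, so labelings are deterministic.
- **Otsu** on a constant image raises a degenerate-input error rather
  than returning an arbitrary cutoff.
- **Fisher's exact and the asymptotic Mann–Whitney** are delegated to
  scipy.stats; the exact small-sample Mann–Whitney path is enumerated
  in-package because a midrank-valid exact method under ties is needed.
  Independent brute-force enumerations (integer-arithmetic
  hypergeometric tails; full permutation scans) serve as oracles in the
  test suite only.
- Images are processed in floating point regardless of on-disk bit depth;
  thresholds are computed on processed intensities. Pixel coordinates are
  (row, col), 0-based, at pixel centers.

## Problem sizes in the shipped analyses and tests

The bundled analyses and the acceptance checks run at desk scale: 100
seeded 512² nucleolar scenes with 3 nuclei each for the recovery sweep,
200 seeded 384² spreads for spot-count recovery, 20 replicates per true
copy number in {50, 200, 400, 800} with 1,000 exons, and exhaustive
Fisher enumeration for all 2×2 tables with row margins ≤ 30. These sizes
were chosen so a complete run finishes in minutes on one CPU while
keeping every estimate's sampling error far below the tolerances being
asserted.

## Limitations

- The rolling-ball background is a disk opening, not a reimplementation
  of any specific legacy plugin; agreement with such tools is at the
  property level (backgrounds below the image, narrow features
  preserved), not bit-exact.
- Absolute areas from fraction-of-maximum thresholds carry the dilation
  bias described above.
- Line placement for shift-correlation profiles is supplied by the user
  or the generator; automatic locus detection for profile placement is
  out of scope.
- The copy-number module consumes coverage summaries; alignment and exon
  preselection are upstream.
- z-stacks are maximum-projected before segmentation; there is no 3-D
  morphometry.
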