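"""Spot counting on condensed-chromatin images and the study's count
statistics.

A "separated spot" is a connected component of above-threshold rDNA signal:
two loci joined by an above-threshold bridge are, by definition, one spot,
which is what makes the count informative — with N unlinked rDNA-bearing
chromosomes the expected count is N, and every bridge-linked pair removes
one.  Linkage occurrence between transcriptionally active (UBF-positive)
and silent (UBF-negative) loci is compared with Fisher's exact test on an
event-based 2x2 table; per-spread linkage counts between conditions are
compared with the Mann-Whitney U test.  A 2^-ddCt helper covers relative
qPCR expression.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .imaging import label_components, threshold_fraction_of_max

__all__ = [
    "LinkageCounts",
    "CtRecord",
    "count_separated_spots",
    "linkage_contingency",
    "fisher_exact",
    "mann_whitney_u",
    "ddct_fold_change",
]

Alternative = Literal["two-sided", "greater"]


@dataclasses.dataclass
class LinkageCounts:
    """Observed loci and linkage events, split by transcriptional status."""

    n_active_loci: int
    n_silent_loci: int
    linkages_active: int
    linkages_silent: int

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.linkages_active > self.n_active_loci:
            raise ValueError("more active linkages than active loci")
        if self.linkages_silent > self.n_silent_loci:
            raise ValueError("more silent linkages than silent loci")

    @property
    def loci_per_linkage_active(self) -> float:
        """Average number of active loci per linkage event."""
        if self.linkages_active == 0:
            return math.inf
        return self.n_active_loci / self.linkages_active


@dataclasses.dataclass
class CtRecord:
    """qPCR cycle thresholds for target and reference gene, sample and
    control condition."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValueError(f"{f.name} must be finite")


def count_separated_spots(
    rdna_channel: np.ndarray,
    min_area_px: int = 4,
    threshold_fraction: float = 0.20,
) -> tuple[int, np.ndarray]:
    """Count separated rDNA spots: threshold at a fraction of the image
    maximum, label with 8-connectivity, drop regions below ``min_area_px``.
    Returns (count, labeled map of retained spots)."""
    img = np.asarray(rdna_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("count_separated_spots expects a 2D image")
    if img.max() == 0:
        return 0, np.zeros(img.shape, dtype=np.int32)
    mask = threshold_fraction_of_max(img, threshold_fraction)
    labels, n = label_components(mask, connectivity=8)
    if n == 0:
        return 0, labels
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(counts >= min_area_px)
    keep = keep[keep > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return len(keep), out


def linkage_contingency(counts: LinkageCounts, construction: str = "event") -> np.ndarray:
    """2x2 table [[linkages_active, other_active], [linkages_silent,
    other_silent]].

    ``construction='event'`` (default) counts each linkage as one event
    against the locus denominator; ``'loci'`` counts loci involved in a
    linkage (two per pairwise linkage, capped at the locus count)."""
    if construction == "event":
        a, s = counts.linkages_active, counts.linkages_silent
    elif construction == "loci":
        a = min(2 * counts.linkages_active, counts.n_active_loci)
        s = min(2 * counts.linkages_silent, counts.n_silent_loci)
    else:
        raise ValueError("construction must be 'event' or 'loci'")
    return np.array(
        [[a, counts.n_active_loci - a], [s, counts.n_silent_loci - s]], dtype=int
    )


def fisher_exact(table: np.ndarray, alternative: Alternative = "greater") -> float:
    """Exact hypergeometric p-value for a 2x2 table of non-negative counts."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table: test undefined")
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return float(sps.fisher_exact(t, alternative=alternative).pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    # midrank-based U for group a
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2)


_EXACT_MWU_MAX_N = 12


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney rank-sum test with midrank tie handling.

    For nA+nB <= 12 the p-value is exact, from full enumeration of all
    group assignments of the pooled observations (valid under ties); larger
    samples use the tie-corrected normal approximation.  Returns (U of
    group A, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("bad alternative")
    u_obs = _u_statistic(a, b)
    n_a, n_b = len(a), len(b)
    if n_a + n_b <= _EXACT_MWU_MAX_N:
        pooled = np.concatenate([a, b])
        mean_u = n_a * n_b / 2
        n_ge = n_le = n_extreme = total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
            if u <= u_obs + 1e-9:
                n_le += 1
            if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
                n_extreme += 1
        if alternative == "greater":
            p = n_ge / total
        elif alternative == "less":
            p = n_le / total
        else:
            p = min(1.0, n_extreme / total)
        return u_obs, float(p)
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return u_obs, float(res.pvalue)


def ddct_fold_change(rec: CtRecord) -> float:
    """Relative expression 2^-ddCt, with ddCt = (target - reference) of the
    sample minus (target - reference) of the control."""
    ddct = (rec.ct_target_sample - rec.ct_ref_sample) - (
        rec.ct_target_control - rec.ct_ref_control
    )
    return float(2.0 ** (-ddct))
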