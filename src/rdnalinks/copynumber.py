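"""rDNA copy-number and per-chromosome dosage from sequencing coverage.

The 45S rDNA array is collapsed onto a single reference repeat during
alignment, so its mean depth scales with the genomic copy number of the
repeat.  Expressing that depth in units of the background genome coverage
-- the median mean-depth of a large panel of single-copy exons -- yields a
copy number per background-normalized unit that is comparable across
libraries of different sequencing depth.  Chromosomal dosage works the same
way one level up: per-chromosome median depth normalized to the median of
all chromosomal medians, so a disomic chromosome sits at 1 and a trisomy in
a diploid at 1.5.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "COVERAGE_COLUMNS",
    "CopyNumberResult",
    "read_coverage_table",
    "validate_coverage_table",
    "rdna_copy_number",
    "chromosomal_dosage",
    "concordant_pair_filter",
]

#: required columns of a coverage table; coordinates are 0-based half-open
COVERAGE_COLUMNS = ["region_id", "class", "chrom", "start", "end", "mean_depth"]

REGION_CLASSES = {"r45S", "single_copy_exon"}


@dataclasses.dataclass
class CopyNumberResult:
    mean_45s_depth: float
    background_depth: float

    @property
    def copy_number(self) -> float:
        return self.mean_45s_depth / self.background_depth


def validate_coverage_table(cov: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVERAGE_COLUMNS if c not in cov.columns]
    if missing:
        raise ValueError(f"coverage table lacks columns: {missing}")
    if cov["region_id"].duplicated().any():
        raise ValueError("region_ids must be unique")
    if (cov["mean_depth"] < 0).any():
        raise ValueError("mean_depth must be non-negative")
    if (cov["start"] >= cov["end"]).any():
        raise ValueError("require start < end (0-based half-open)")
    unknown = set(cov["class"]) - REGION_CLASSES
    if unknown:
        raise ValueError(f"unknown region classes: {sorted(unknown)}")
    return cov


def read_coverage_table(path) -> pd.DataFrame:
    """Read a TSV coverage table with the standard header."""
    return validate_coverage_table(pd.read_csv(path, sep="\t"))


def rdna_copy_number(cov: pd.DataFrame) -> CopyNumberResult:
    """Copy number of the 45S locus: length-weighted mean depth over r45S
    records divided by the median mean-depth of the single-copy exons."""
    validate_coverage_table(cov)
    r45 = cov[cov["class"] == "r45S"]
    exons = cov[cov["class"] == "single_copy_exon"]
    if len(r45) == 0 or len(exons) == 0:
        raise ValueError("need >= 1 r45S record and >= 1 single_copy_exon record")
    lengths = (r45["end"] - r45["start"]).to_numpy(dtype=float)
    mean_45s = float(np.average(r45["mean_depth"].to_numpy(dtype=float), weights=lengths))
    background = float(np.median(exons["mean_depth"].to_numpy(dtype=float)))
    if background == 0:
        raise ValueError("zero exon median depth: normalization undefined")
    return CopyNumberResult(mean_45s_depth=mean_45s, background_depth=background)


def chromosomal_dosage(
    depth_by_chrom: Union[dict[str, np.ndarray], pd.DataFrame]
) -> pd.DataFrame:
    """Per-chromosome median depth normalized to the median of those
    medians.

    Accepts either ``{chrom: per-base-or-binned depth array}`` or a
    DataFrame with columns (chrom, depth).  Returns a DataFrame with
    columns (chrom, median_depth, normalized).
    """
    if isinstance(depth_by_chrom, pd.DataFrame):
        groups = {
            str(c): g["depth"].to_numpy(dtype=float)
            for c, g in depth_by_chrom.groupby("chrom", sort=False)
        }
    else:
        groups = {str(c): np.asarray(v, dtype=float) for c, v in depth_by_chrom.items()}
    if len(groups) < 3:
        raise ValueError("need depths for >= 3 chromosomes")
    medians = {c: float(np.median(v)) for c, v in groups.items()}
    overall = float(np.median(list(medians.values())))
    if overall == 0:
        raise ValueError("all-zero chromosomal depths")
    return pd.DataFrame(
        {
            "chrom": list(medians),
            "median_depth": list(medians.values()),
            "normalized": [m / overall for m in medians.values()],
        }
    )


def concordant_pair_filter(records: Iterable) -> list:
    """Keep only reads flagged properly paired by the upstream aligner.

    ``records`` are pysam-style alignment records exposing ``is_paired``
    and ``is_proper_pair``; unpaired records are dropped with a warning.
    Insert sizes are not re-evaluated — the aligner's concordance call is
    authoritative.
    """
    kept = []
    n_unpaired = 0
    for rec in records:
        if not rec.is_paired:
            n_unpaired += 1
            continue
        if rec.is_proper_pair:
            kept.append(rec)
    if n_unpaired:
        warnings.warn(f"dropped {n_unpaired} unpaired record(s)", stacklevel=2)
    return kept
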