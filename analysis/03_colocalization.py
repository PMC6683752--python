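#!/usr/bin/env python
"""Colocalization analyses on synthetic fixtures.

Two measurements: (1) the dual-label control — one filamentous structure
imaged in two channels with independent noise; the averaged Pearson
shift-correlation profile should peak at the injected registration offset
and approach its noise ceiling at shift 0; (2) the rDNA-vs-nucleolin
mask-overlap fraction on a two-channel interphase-like scene."""

from pathlib import Path

import numpy as np
import pandas as pd

from rdnalinks import io
from rdnalinks.coloc import (
    LineProfileSpec,
    average_profiles,
    line_profile,
    nucleolin_overlap_mask,
    overlap_fraction,
    pearson_shift_profile,
    rdna_mask,
)
from rdnalinks.simulate import make_dual_label_scene, make_filament_field, make_nucleolar_scene

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def shift_profiles() -> None:
    base = make_filament_field(seed=SEED)
    rows = [r for r in np.argsort(base.var(axis=1)) if 3 <= r <= 252][-10:]
    records = []
    for injected in (0, 5):
        img, _ = make_dual_label_scene(base, channel_shift_px=injected,
                                       per_channel_snr=10, seed=SEED + 1)
        profiles = []
        for r0 in rows:
            spec = LineProfileSpec((float(r0), 20), (float(r0), 235))
            pa = line_profile(img.data["label_a"], spec)
            pb = line_profile(img.data["label_b"], spec)
            profiles.append(pearson_shift_profile(pa, pb, 15))
        avg = average_profiles(profiles)
        for s, r in zip(avg.shifts_px, avg.r):
            records.append({"injected_shift": injected, "shift_px": s, "pearson_r": r})
        print(f"injected shift {injected:+d}px -> profile peak at "
              f"{avg.peak_shift:+d}px, r_max={np.nanmax(avg.r):.3f} "
              f"({avg.n_loci} lines)")
    io.write_table(RESULTS / "shift_profiles.csv", pd.DataFrame(records),
                   {"seed": SEED})


def mask_overlap() -> None:
    # nucleolin channel: nucleoli; rDNA stand-in: the same nucleoli dilated
    # vs an offset copy, giving a high- and a low-overlap comparison
    scene, _ = make_nucleolar_scene(n_nuclei=6, seed=SEED + 2)
    nucleolin = scene.data["nucleolin"]
    nucl_mask = nucleolin_overlap_mask(nucleolin, scene.pixel_size_um)
    inside = rdna_mask(nucleolin)  # structure colocalizing with nucleoli
    outside = np.roll(inside, (160, 160), axis=(0, 1))  # displaced copy
    res_in = overlap_fraction(inside, nucl_mask)
    res_out = overlap_fraction(outside, nucl_mask)
    io.write_table(
        RESULTS / "overlap_fractions.csv",
        pd.DataFrame([
            {"comparison": "nucleolar_structure", "fraction": res_in.fraction},
            {"comparison": "displaced_structure", "fraction": res_out.fraction},
        ]),
        {"seed": SEED + 2},
    )
    print(f"overlap with nucleolin: in-place structure {res_in.fraction:.2f}, "
          f"displaced structure {res_out.fraction:.2f}")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    shift_profiles()
    mask_overlap()


if __name__ == "__main__":
    main()
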