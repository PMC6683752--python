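#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes seeded scenes (interphase nucleolar fields, condensed-chromatin
spreads with and without linkage bridges, a dual-label filament pair) and
a sequencing-coverage table, each with its machine-readable ground truth.
Images go to scratch/ (bulky, regenerable); tables and truth to results/.
"""

from pathlib import Path

import pandas as pd

from rdnalinks import io
from rdnalinks.simulate import (
    make_coverage_table,
    make_dual_label_scene,
    make_filament_field,
    make_nucleolar_scene,
    make_spread_scene,
)

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "analysis"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    scene, truth = make_nucleolar_scene(n_nuclei=8, seed=SEED)
    io.write_image(SCRATCH / "nucleolar_scene.tiff", scene)
    io.write_table(RESULTS / "nucleolar_scene.truth.csv", truth.objects,
                   params={"seed": SEED})
    n_nuclei = (truth.objects.object == "nucleus").sum()
    n_nucleoli = (truth.objects.object == "nucleolus").sum()
    print(f"nucleolar scene: {n_nuclei} nuclei, {n_nucleoli} nucleoli (seed {SEED})")

    for label, pairs in [("unlinked", ()), ("linked", ((0, 1), (2, 3)))]:
        spread, s_truth = make_spread_scene(n_foci=9, linkage_pairs=pairs, seed=SEED)
        io.write_image(SCRATCH / f"spread_{label}.tiff", spread)
        io.write_table(RESULTS / f"spread_{label}.truth.csv", s_truth.objects,
                       params={"seed": SEED, "pairs": list(pairs)})
        print(f"spread '{label}': 9 foci, {len(pairs)} bridge(s)")

    base = make_filament_field(seed=SEED)
    dual, _ = make_dual_label_scene(base, channel_shift_px=0,
                                    per_channel_snr=10, seed=SEED + 1)
    io.write_image(SCRATCH / "dual_label.tiff", dual)
    print("dual-label pair: same filament field, independent noise, shift 0")

    cov, binned, cov_truth = make_coverage_table(true_copy_number=400, seed=SEED)
    cov.to_csv(RESULTS / "coverage.tsv", sep="\t", index=False)
    depth = pd.DataFrame(
        [(c, d) for c, arr in binned.items() for d in arr],
        columns=["chrom", "depth"],
    )
    depth.to_csv(RESULTS / "chrom_depth.tsv", sep="\t", index=False)
    print(f"coverage table: {len(cov)} regions, true copy number "
          f"{cov_truth.true_copy_number:g}, haploid depth {cov_truth.haploid_depth:g}")


if __name__ == "__main__":
    main()
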