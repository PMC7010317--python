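#!/usr/bin/env python
"""Recovery benchmarks of every pipeline stage against ground truth.

Freshly generates seeded default scenes and scores: blebbing-classifier
sensitivity/specificity, cell-segmentation counts and IoU, touching-pair
resolution, exact focal-adhesion counting, circle-fixture curvature, and
Fisher-test null calibration.  Writes results/validation.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from blebquant.validation import (
    build_scenes,
    circle_curvature,
    classifier_recovery,
    curvature_scale_law_error,
    fa_count_recovery,
    fisher_null_calibration,
    segmentation_recovery,
    touching_pair_resolution,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-scenes", type=int, default=10)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    master = np.random.default_rng(args.seed)
    scenes = build_scenes(master.integers(0, 2**31 - 1, args.n_scenes))
    summary = {
        "circle_mean_curvature_per_px": round(circle_curvature(), 6),
        "curvature_scale_law_max_abs_err": curvature_scale_law_error(),
        "classifier": classifier_recovery(scenes),
        "segmentation": segmentation_recovery(scenes),
        "touching_pairs": touching_pair_resolution(
            master.integers(0, 2**31 - 1, 3)
        ),
        "fa_counting": fa_count_recovery(scenes[:5]),
        "fisher_null": fisher_null_calibration(
            seed=int(master.integers(0, 2**31 - 1))
        ),
    }
    args.results.mkdir(parents=True, exist_ok=True)
    out = args.results / "validation.json"
    with open(out, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    print(json.dumps(summary, indent=2))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
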