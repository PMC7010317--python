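#!/usr/bin/env python
"""Segment every simulated scene and measure per-cell features.

For each scene TIFF from 01_simulate_experiment.py: PST nuclei segmentation,
background-threshold cell-body segmentation with nuclei-seeded splitting,
boundary-curvature morphometry, the three-feature blebbing call, outlier
filters, and filtered focal-adhesion counts.  Writes the combined per-cell
feature table (excluded cells flagged, not deleted) to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from blebquant import (
    apply_cell_filters,
    count_fas,
    extract_features,
    features_to_frame,
    filter_fas,
    segment_cell_bodies,
    segment_fas,
    segment_nuclei,
)
from blebquant import io as bio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scratch", type=Path, default=Path("scratch/experiment"))
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    frames = []
    tiffs = sorted(args.scratch.glob("*.tif"))
    if not tiffs:
        raise SystemExit(f"no scene TIFFs under {args.scratch}; run 01 first")
    for tiff in tiffs:
        channels = bio.read_channel_stack(tiff)
        nuclei = segment_nuclei(channels["nuclei"])
        cells = segment_cell_bodies(channels["cytoplasm"], nuclei)
        records = extract_features(cells, nuclei, channels["adhesion"])
        apply_cell_filters(records)

        fa_raw = segment_fas(channels["adhesion"])
        _, fa_table = filter_fas(fa_raw, cells, nuclei, channels["adhesion"])
        counts = count_fas(fa_table, cells)
        for rec in records:
            rec.fa_count = int(counts.get(rec.cell_id, 0))

        frame = features_to_frame(records)
        frame.insert(0, "scene", tiff.stem)
        frame.insert(0, "group", tiff.stem.rsplit("_", 1)[0])
        frames.append(frame)
        print(f"{tiff.name}: {cells.max()} cells, {len(fa_table)} adhesions")

    df = pd.concat(frames, ignore_index=True)
    out = args.results / "cell_features.csv"
    args.results.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)
    kept = df["excluded_by"] == ""
    print(f"\nwrote {out}: {len(df)} cells ({kept.sum()} pass the outlier filters)")
    print("blebbing calls by group:")
    print(df[kept].groupby("group")["blebbing"].mean().to_string())


if __name__ == "__main__":
    main()
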