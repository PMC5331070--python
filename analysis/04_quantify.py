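#!/usr/bin/env python
"""Regional, laterality and edge-length statistics of the anchored inputs.

Counts input neurons per toy-atlas region and macro group, measures the
ipsilateral bias relative to each animal's starter population, and
summarizes the distance of every input neuron from the segmented RVLM
epicenter (per-animal medians, pooled tail beyond 2.5 and 5 mm).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from atlasmap import (
    SyntheticSpec,
    count_by_region,
    edge_lengths,
    edge_summary,
    gen_label_volume,
    group_percentages,
    laterality,
    read_points,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    spec = SyntheticSpec(seed=args.seed)
    scratch = ROOT / "scratch" / f"fixture_seed{args.seed}"
    results = ROOT / "results"

    points = read_points(scratch / "anchored_points.csv")
    inputs = points[points["class"] == "input"]
    vol = gen_label_volume(spec)

    table = count_by_region(inputs, vol)
    table.to_csv(results / "region_counts.csv", index=False)
    groups = group_percentages(table)
    groups.to_csv(results / "group_percentages.csv", index=False)

    lat = laterality(points, spec.midline_x)
    lat.to_csv(results / "laterality.csv", index=False)

    epi = json.loads((results / "rvlm_segmentation.json").read_text())["epicenter_left"]
    dists = {
        a: edge_lengths(sub, np.array(epi), spec.voxel_size_um)
        for a, sub in inputs.groupby("animal_id")
    }
    edges = edge_summary(dists, thresholds_mm=(2.5, 5.0))
    summary = {
        "per_animal_median_mm": {a: round(v, 2) for a, v in edges.per_animal_median_mm.items()},
        "median_mean_mm": round(edges.median_mean_mm, 2),
        "median_range_mm": [round(edges.median_min_mm, 2), round(edges.median_max_mm, 2)],
        "beyond_2p5mm_pct": round(100 * edges.frac_beyond[2.5], 1),
        "beyond_5mm_pct": round(100 * edges.frac_beyond[5.0], 1),
        "ipsilateral_pct_mean": round(lat.attrs["mean"], 1),
        "ipsilateral_pct_range": [round(lat.attrs["min"], 1), round(lat.attrs["max"], 1)],
    }
    (results / "edge_lengths.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(groups.round(1).to_string(index=False))
    print(f"ipsilateral bias: {summary['ipsilateral_pct_mean']}% "
          f"({summary['ipsilateral_pct_range'][0]}–{summary['ipsilateral_pct_range'][1]})")
    print(f"median edge length: {summary['median_mean_mm']} mm "
          f"({summary['median_range_mm'][0]}–{summary['median_range_mm'][1]}); "
          f"{summary['beyond_5mm_pct']}% beyond 5 mm")


if __name__ == "__main__":
    main()
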