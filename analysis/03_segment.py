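#!/usr/bin/env python
"""Segment the RVLM from the TH+ bulbospinal reference cloud.

Mirrors the reference neurons across the midline, thresholds per-level
disc-count density (>2 neurons within a 10-voxel radius), stacks the
levels into a bilateral mask, and reports the left-side epicenter and the
fraction of generating neurons the region contains. Also builds the
Bötzinger / pre-Bötzinger cylinder primitives (500 µm diameter, 0–600 µm
and 700–1200 µm caudal of the facial-nucleus caudal pole) and counts
anchored input neurons inside each region.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from atlasmap import (
    SyntheticSpec,
    containment_fraction,
    cylinder_region,
    density_mask,
    half_mask,
    mirror_points,
    point_array,
    read_points,
)
from atlasmap.segmentation import epicenter as mask_epicenter
from atlasmap.synthetic import _FACIAL_CENTER_DZ, _FACIAL_SEMI

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    spec = SyntheticSpec(seed=args.seed)
    scratch = ROOT / "scratch" / f"fixture_seed{args.seed}"

    th = point_array(read_points(scratch / "truth_th.csv"))
    mask = density_mask(mirror_points(th, spec.midline_x), spec.grid,
                        radius=10, threshold=2, name="rvlm")
    left = half_mask(mask, spec.midline_x, "left")
    epi = mask_epicenter(left)
    containment = containment_fraction(mask, th)

    # cylinder primitives hang off the facial nucleus caudal pole
    ex, ey, ez = spec.epicenter
    pole_y = (ey + _FACIAL_CENTER_DZ[1]) - _FACIAL_SEMI[1]
    center_xz = (ex, ez + _FACIAL_CENTER_DZ[2])
    botzinger = cylinder_region(spec.grid, pole_y, (0, 600), center_xz, 500.0,
                                direction=-1, name="botzinger")
    prebotzinger = cylinder_region(spec.grid, pole_y, (700, 1200), center_xz, 500.0,
                                   direction=-1, name="prebotzinger")

    inputs = read_points(scratch / "anchored_points.csv")
    inputs = point_array(inputs[inputs["class"] == "input"])
    report = {
        "mask_voxels": mask.n_voxels,
        "epicenter_left": [round(float(c), 2) for c in epi],
        "epicenter_rounded": [int(round(float(c))) for c in epi],
        "containment_pct": round(100 * containment, 1),
        "botzinger_levels": int(botzinger.mask.any(axis=(0, 2)).sum()),
        "inputs_in_rvlm_pct": round(100 * containment_fraction(mask, inputs), 1),
        "inputs_in_botzinger_pct": round(100 * containment_fraction(botzinger, inputs), 1),
        "inputs_in_prebotzinger_pct": round(
            100 * containment_fraction(prebotzinger, inputs), 1
        ),
    }
    out = ROOT / "results" / "rvlm_segmentation.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"density mask: {mask.n_voxels} voxels; left epicenter at "
          f"{report['epicenter_rounded']} (true {list(map(int, spec.epicenter))})")
    print(f"contains {report['containment_pct']}% of the {len(th)} reference neurons")
    print(f"report -> {out}")


if __name__ == "__main__":
    main()
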