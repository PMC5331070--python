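#!/usr/bin/env python
"""Generate the synthetic tracing experiment and write its fixture files.

Produces the ground-truth cohort (4 mapped animals, 1298 input neurons,
152 starters, plus 273 TH+ bulbospinal reference neurons from 6 reference
animals), the toy label atlas, and the virtual-section annotation tables
that downstream scripts anchor and quantify. Bulky artefacts (full point
tables, NIfTI volume) go to scratch/; a compact per-animal summary goes to
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from atlasmap import (
    SyntheticSpec,
    gen_label_volume,
    generate,
    save_label_volume,
    write_anchors,
    write_label_description,
    write_points,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    spec = SyntheticSpec(seed=args.seed)
    scratch = ROOT / "scratch" / f"fixture_seed{args.seed}"
    scratch.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    vol = gen_label_volume(spec)
    truth = generate(spec)

    save_label_volume(vol, scratch / "atlas.nii.gz")
    write_label_description(vol.labels, scratch / "atlas.label")
    write_points(truth.points, scratch / "truth_points.csv")
    write_points(truth.th_points, scratch / "truth_th.csv")
    write_anchors(truth.anchors, scratch / "anchors.json")
    truth.annotations.to_csv(scratch / "annotations.csv", index=False)

    summary = (
        truth.points.groupby(["animal_id", "class"])
        .size()
        .unstack(fill_value=0)
        .reset_index()
    )
    summary.to_csv(results / "cohort_summary.csv", index=False)

    n_inputs = (truth.points["class"] == "input").sum()
    n_sections = truth.annotations["section_id"].nunique()
    print(f"seed {args.seed}: {n_inputs} input neurons across "
          f"{truth.points['animal_id'].nunique()} animals, "
          f"{n_sections} virtual sections, "
          f"{len(truth.th_points)} TH+ reference neurons")
    print(f"fixtures -> {scratch}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
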