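"""Regional and spatial statistics over atlas-anchored neuron coordinates.

Counts per atlas segment, macro-group percentages, laterality relative to
the starter population, and "edge length" statistics — the Euclidean
distance from each input neuron to the epicenter of the target region,
which summarizes how spatially embedded the presynaptic network is.

Reporting follows the descriptive convention used for small cohorts
(n = 4 animals): pooled percentages plus per-animal mean (min–max). All
percentages use the full annotated-point denominator, including points that
fall outside every atlas segment ("unassigned"), so regional shares are
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_io import DEFAULT_VOXEL_SIZE_UM, LabelVolume, labels_at, point_array
from .errors import ConfigError, GeometryError
from .segmentation import RegionMask

UNASSIGNED = "unassigned"


def _per_animal_counts(df: pd.DataFrame, animals: list[str]) -> dict[str, int]:
    c = df["animal_id"].value_counts()
    return {a: int(c.get(a, 0)) for a in animals}


def count_by_region(
    points: pd.DataFrame,
    vol: LabelVolume,
    extra_masks: tuple[RegionMask, ...] = (),
) -> pd.DataFrame:
    """Tally points per atlas segment, with optional overlay masks.

    Every point is assigned to exactly one atlas label (the label of its
    containing voxel); background or out-of-volume points go to the
    "unassigned" bucket, so per-animal and pooled counts conserve the total.
    ``extra_masks`` (e.g. a density-segmented region) are tested
    independently and reported as overlay rows — they may overlap atlas
    labels and are excluded from the conservation sum.

    Returns a table with columns: region, group, overlay, n_<animal>...,
    n_pooled, pct_pooled, pct_mean, pct_min, pct_max.
    """
    animals = sorted(points["animal_id"].astype(str).unique()) if len(points) else []
    xyz = point_array(points) if len(points) else np.empty((0, 3))
    for m in extra_masks:
        if m.mask.shape != vol.shape:
            raise GeometryError(
                f"mask {m.name!r} shape {m.mask.shape} != volume shape {vol.shape}"
            )
    lab = labels_at(vol, xyz) if len(points) else np.empty(0, dtype=int)
    lab = np.where(lab <= 0, 0, lab)  # background and out-of-volume → unassigned

    n_total = len(points)
    per_animal_total = _per_animal_counts(points, animals) if n_total else {}

    rows = []

    def emit(region: str, group: str, overlay: bool, sel: np.ndarray) -> None:
        sub = points.iloc[np.flatnonzero(sel)] if n_total else points
        pooled = int(sel.sum()) if n_total else 0
        pa = _per_animal_counts(sub, animals)
        pcts = [
            100.0 * pa[a] / per_animal_total[a] for a in animals if per_animal_total.get(a)
        ]
        row = {"region": region, "group": group, "overlay": overlay}
        for a in animals:
            row[f"n_{a}"] = pa[a]
        row["n_pooled"] = pooled
        row["pct_pooled"] = 100.0 * pooled / n_total if n_total else 0.0
        row["pct_mean"] = float(np.mean(pcts)) if pcts else 0.0
        row["pct_min"] = float(np.min(pcts)) if pcts else 0.0
        row["pct_max"] = float(np.max(pcts)) if pcts else 0.0
        rows.append(row)

    for _, lrow in vol.labels.sort_values("label_id").iterrows():
        lid = int(lrow["label_id"])
        emit(str(lrow["name"]), str(lrow["group"]), False, lab == lid)
    emit(UNASSIGNED, UNASSIGNED, False, lab == 0)
    for m in extra_masks:
        if n_total:
            idx = np.floor(xyz).astype(int)
            nx, ny, nz = vol.shape
            inside = (
                (idx[:, 0] >= 0) & (idx[:, 0] < nx)
                & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
                & (idx[:, 2] >= 0) & (idx[:, 2] < nz)
            )
            sel = np.zeros(n_total, dtype=bool)
            ii = idx[inside]
            sel[inside] = m.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        else:
            sel = np.empty(0, dtype=bool)
        emit(m.name or "mask", "overlay", True, sel)

    table = pd.DataFrame(rows)
    return table


def group_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a region-count table into macro-group percentages.

    Overlay rows are excluded (they double-count). Percentages are over the
    total including the unassigned bucket; per-animal values are reported as
    mean (min–max). Regions without a group raise a ConfigError.
    """
    base = table.loc[~table["overlay"]].copy()
    nameless = base.loc[base["group"].isna() | (base["group"] == ""), "region"]
    if len(nameless):
        raise ConfigError(f"region(s) without a group: {list(nameless)}")
    animal_cols = [c for c in base.columns if c.startswith("n_") and c != "n_pooled"]
    totals = base[animal_cols + ["n_pooled"]].sum()
    rows = []
    for group, sub in base.groupby("group"):
        row = {"group": group, "n_pooled": int(sub["n_pooled"].sum())}
        row["pct_pooled"] = (
            100.0 * row["n_pooled"] / totals["n_pooled"] if totals["n_pooled"] else 0.0
        )
        pcts = [
            100.0 * sub[c].sum() / totals[c] for c in animal_cols if totals[c] > 0
        ]
        row["pct_mean"] = float(np.mean(pcts)) if pcts else 0.0
        row["pct_min"] = float(np.min(pcts)) if pcts else 0.0
        row["pct_max"] = float(np.max(pcts)) if pcts else 0.0
        rows.append(row)
    return pd.DataFrame(rows).sort_values("n_pooled", ascending=False).reset_index(drop=True)


def laterality(
    points: pd.DataFrame,
    midline_x: float,
    reference_side: str = "auto_from_starters",
    midline_margin: float = 0.5,
) -> pd.DataFrame:
    """Per-animal ipsilateral percentage of input neurons.

    A point is left/right by the sign of ``x − midline_x``; in
    ``auto_from_starters`` mode the ipsilateral side of each animal is the
    side holding the majority of its starter neurons. Points within
    ``midline_margin`` voxels of the midline are indeterminate and excluded
    from the percentage. Returns one row per animal plus a ``summary`` row
    with the mean (min–max) across animals.
    """
    if reference_side not in ("auto_from_starters", "left", "right"):
        raise ValueError(f"bad reference_side {reference_side!r}")
    inputs = points.loc[points["class"] == "input"]
    starters = points.loc[points["class"].isin(["starter_C1", "starter_nonC1"])]
    rows = []
    for animal, sub in inputs.groupby(inputs["animal_id"].astype(str)):
        if reference_side == "auto_from_starters":
            st = starters.loc[starters["animal_id"].astype(str) == animal]
            if len(st) == 0:
                raise ValueError(f"animal {animal}: no starter neurons for auto laterality")
            ipsi_left = (st["x"] < midline_x).mean() >= 0.5
        else:
            ipsi_left = reference_side == "left"
        dx = sub["x"].to_numpy(dtype=float) - midline_x
        determinate = np.abs(dx) > midline_margin
        on_ipsi = (dx < 0) if ipsi_left else (dx > 0)
        n_det = int(determinate.sum())
        pct = 100.0 * float((on_ipsi & determinate).sum()) / n_det if n_det else np.nan
        rows.append(
            {
                "animal_id": animal,
                "ipsi_side": "left" if ipsi_left else "right",
                "n_inputs": len(sub),
                "n_indeterminate": int((~determinate).sum()),
                "ipsi_pct": pct,
            }
        )
    out = pd.DataFrame(rows)
    vals = out["ipsi_pct"].dropna()
    out.attrs["mean"] = float(vals.mean()) if len(vals) else np.nan
    out.attrs["min"] = float(vals.min()) if len(vals) else np.nan
    out.attrs["max"] = float(vals.max()) if len(vals) else np.nan
    return out


def edge_lengths(
    points: pd.DataFrame | np.ndarray,
    epicenter: np.ndarray,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> np.ndarray:
    """Euclidean distance (mm) from each point to the region epicenter."""
    xyz = point_array(points) if isinstance(points, pd.DataFrame) else np.asarray(points, float)
    epicenter = np.asarray(epicenter, dtype=float).reshape(3)
    d_vox = np.linalg.norm(xyz - epicenter, axis=1)
    return d_vox * voxel_size_um / 1000.0


@dataclass
class EdgeLengthSummary:
    """Distance-to-epicenter summary, per animal and pooled."""

    per_animal_median_mm: dict[str, float]
    median_mean_mm: float
    median_min_mm: float
    median_max_mm: float
    pooled_median_mm: float
    #: threshold (mm) → fraction of pooled distances strictly exceeding it
    frac_beyond: dict[float, float]
    #: pooled empirical CDF: sorted distances and cumulative fractions
    cdf_mm: np.ndarray = field(repr=False)
    cdf_frac: np.ndarray = field(repr=False)


def edge_summary(
    distances_by_animal: dict[str, np.ndarray],
    thresholds_mm: tuple[float, ...] = (2.5, 5.0),
) -> EdgeLengthSummary:
    """Summarize per-animal edge-length distributions.

    Median of an even-sized sample is the midpoint of the central pair.
    Raises ValueError naming any animal with no distances.
    """
    for animal, d in distances_by_animal.items():
        if len(np.asarray(d)) == 0:
            raise ValueError(f"animal {animal}: no distances")
    med = {a: float(np.median(np.asarray(d, float))) for a, d in distances_by_animal.items()}
    pooled = np.concatenate([np.asarray(d, float) for d in distances_by_animal.values()])
    order = np.sort(pooled)
    cdf_frac = np.arange(1, len(order) + 1) / len(order)
    meds = np.array(list(med.values()))
    return EdgeLengthSummary(
        per_animal_median_mm=med,
        median_mean_mm=float(meds.mean()),
        median_min_mm=float(meds.min()),
        median_max_mm=float(meds.max()),
        pooled_median_mm=float(np.median(pooled)),
        frac_beyond={float(t): float((pooled > t).mean()) for t in thresholds_mm},
        cdf_mm=order,
        cdf_frac=cdf_frac,
    )
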