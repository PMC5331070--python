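"""I/O for label atlases and neuron coordinate tables.

The shared coordinate convention, used by every module in this package, is the
Waxholm-style voxel frame: continuous, 0-based coordinates ``(x, y, z)`` in
voxel units where

* ``x`` is lateral,
* ``y`` is rostrocaudal (increasing rostrally),
* ``z`` is dorsoventral,

at an isotropic voxel size of 39 µm by default. A point inside voxel
``(i, j, k)`` has ``floor(coord) == (i, j, k)``, so integer atlas coordinates
from published tables address voxels directly while anchored points keep their
sub-voxel precision. Micrometre distances are always
``voxel_units * voxel_size_um``.

Orientation of an atlas volume on disk is *not* inferred from NIfTI headers:
the caller states an explicit ``axis_map`` (a permutation with optional flips)
once, at load time, and everything downstream sees the fixed
(lateral, rostrocaudal, dorsoventral) layout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, SchemaError

#: Neuron classes used throughout: trans-synaptically labelled inputs, the two
#: starter phenotypes (C1 = catecholaminergic, TH+), and the retrogradely
#: labelled TH+ bulbospinal neurons used to segment the target region.
NEURON_CLASSES = ("input", "starter_C1", "starter_nonC1", "th_bulbospinal")

#: Macro-anatomical groups a labelled region may belong to.
GROUPS = (
    "brainstem",
    "midbrain",
    "forebrain",
    "cerebellum",
    "spinal_cord",
    "white_matter",
    "ventricles",
    "unassigned",
)

DEFAULT_VOXEL_SIZE_UM = 39.0

_POINT_COLUMNS = ["animal_id", "class", "x", "y", "z"]
_ANNOTATION_COLUMNS = [
    "animal_id",
    "section_id",
    "class",
    "px",
    "py",
    "image_w",
    "image_h",
]


@dataclass
class LabelVolume:
    """A 3D integer-labelled atlas grid plus its label table.

    ``voxels`` is indexed ``[x, y, z]`` in the package's fixed
    (lateral, rostrocaudal, dorsoventral) convention. ``labels`` has columns
    ``label_id`` (int), ``name`` (str) and ``group`` (str, one of `GROUPS`).
    Label id 0 is background and never appears in the table.
    """

    voxels: np.ndarray
    labels: pd.DataFrame = field(default_factory=lambda: _empty_label_table())
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"label volume must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError(f"label volume must be integer-valued, got {self.voxels.dtype}")
        if min(self.voxels.shape) < 1:
            raise FormatError(f"degenerate volume shape {self.voxels.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if not {"label_id", "name", "group"} <= set(self.labels.columns):
            raise SchemaError("label table needs columns label_id, name, group")
        present = np.unique(self.voxels)
        known = set(self.labels["label_id"].tolist()) | {0}
        unknown = [int(v) for v in present if int(v) not in known]
        if unknown:
            raise ValueError(f"voxel values not in label table: {unknown}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def name_of(self, label_id: int) -> str:
        if label_id == 0:
            return "background"
        row = self.labels.loc[self.labels["label_id"] == label_id]
        if row.empty:
            raise KeyError(f"unknown label id {label_id}")
        return str(row["name"].iloc[0])

    def group_of(self, label_id: int) -> str:
        if label_id == 0:
            return "unassigned"
        row = self.labels.loc[self.labels["label_id"] == label_id]
        if row.empty:
            raise KeyError(f"unknown label id {label_id}")
        return str(row["group"].iloc[0])


def _empty_label_table() -> pd.DataFrame:
    return pd.DataFrame({"label_id": pd.Series(dtype=int),
                         "name": pd.Series(dtype=str),
                         "group": pd.Series(dtype=str)})


def make_label_table(entries: list[tuple[int, str, str]]) -> pd.DataFrame:
    """Build a label table from ``(label_id, name, group)`` tuples."""
    for _, _, group in entries:
        if group not in GROUPS:
            raise ConfigError(f"unknown group {group!r}; expected one of {GROUPS}")
    return pd.DataFrame(entries, columns=["label_id", "name", "group"])


# --------------------------------------------------------------------------
# axis mapping

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def apply_axis_map(voxels: np.ndarray, axis_map: tuple[str, str, str] | list[str]) -> np.ndarray:
    """Permute/flip a raw volume into the (lateral, rostrocaudal, dorsoventral) frame.

    ``axis_map[i]`` names the *source* axis that becomes output axis ``i``,
    with a leading ``-`` to reverse it, e.g. ``("x", "-z", "y")``.
    """
    if len(axis_map) != 3:
        raise ConfigError(f"axis_map must have 3 entries, got {axis_map!r}")
    src_axes, flips = [], []
    for entry in axis_map:
        m = re.fullmatch(r"(-?)([xyz])", entry.strip())
        if not m:
            raise ConfigError(f"bad axis_map entry {entry!r}")
        flips.append(m.group(1) == "-")
        src_axes.append(_AXIS_INDEX[m.group(2)])
    if sorted(src_axes) != [0, 1, 2]:
        raise ConfigError(f"axis_map must be a permutation of x,y,z: {axis_map!r}")
    out = np.transpose(voxels, src_axes)
    for axis, flip in enumerate(flips):
        if flip:
            out = np.flip(out, axis=axis)
    return out


# --------------------------------------------------------------------------
# label description files (ITK-SNAP dialect)

# id  R  G  B  A  VIS  MSH  "name"
_LABEL_LINE = re.compile(
    r"^\s*(\d+)\s+(\d+)\s+(\d+)\s+(\d+)\s+([\d.]+)\s+(\d+)\s+(\d+)\s+\"(.*)\"\s*$"
)


def parse_label_description(path: str | Path) -> pd.DataFrame:
    """Parse an ITK-SNAP-style label description file into ``(label_id, name)`` rows.

    Lines starting with ``#`` and blank lines are ignored. Each remaining line
    must be ``id R G B A VIS MSH "name"``; anything else raises a
    `FormatError` naming the offending line.
    """
    entries = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _LABEL_LINE.match(raw)
        if not m:
            raise FormatError(f"{path}: unparsable label line {lineno}: {raw!r}")
        entries.append((int(m.group(1)), m.group(8)))
    return pd.DataFrame(entries, columns=["label_id", "name"])


def write_label_description(labels: pd.DataFrame, path: str | Path) -> None:
    """Write a label table in the same ITK-SNAP dialect `parse_label_description` reads."""
    rng = np.random.default_rng(0)
    with open(path, "w") as fh:
        fh.write("# id R G B A VIS MSH \"name\"\n")
        for _, row in labels.iterrows():
            r, g, b = rng.integers(0, 256, size=3)
            fh.write(f'{int(row["label_id"])} {r} {g} {b} 1 1 1 "{row["name"]}"\n')


def load_label_volume(
    path: str | Path,
    label_path: str | Path | None = None,
    axis_map: tuple[str, str, str] | None = None,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    group_map: dict[int, str] | None = None,
) -> LabelVolume:
    """Load an integer NIfTI label volume plus its label description file.

    ``axis_map`` rotates the on-disk array into the package's fixed
    (lateral, rostrocaudal, dorsoventral) convention (default: identity).
    ``group_map`` assigns each label id to a macro group; unmapped ids get
    ``"unassigned"``. Label ids present in the volume but absent from the
    label file are appended with a warning rather than rejected, since atlas
    releases and label files drift out of sync in the wild.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{path}: volume is not integer-valued")
        data = np.round(data).astype(np.int32)
    if axis_map is not None:
        data = apply_axis_map(data, axis_map)

    if label_path is not None:
        labels = parse_label_description(label_path)
    else:
        labels = pd.DataFrame({"label_id": pd.Series(dtype=int), "name": pd.Series(dtype=str)})
    group_map = group_map or {}
    labels["group"] = [
        group_map.get(int(i), "unassigned") for i in labels["label_id"]
    ]
    present = {int(v) for v in np.unique(data)} - {0}
    unknown = sorted(present - set(int(i) for i in labels["label_id"]))
    if unknown:
        warnings.warn(
            f"{path}: {len(unknown)} label id(s) missing from the label table, "
            f"added as unassigned: {unknown[:10]}",
            stacklevel=2,
        )
        extra = pd.DataFrame(
            {"label_id": unknown,
             "name": [f"label_{i}" for i in unknown],
             "group": ["unassigned"] * len(unknown)}
        )
        labels = pd.concat([labels, extra], ignore_index=True)
    return LabelVolume(voxels=data, labels=labels, voxel_size_um=voxel_size_um)


def save_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a LabelVolume's grid as NIfTI (identity affine, voxel size in the header)."""
    affine = np.diag([vol.voxel_size_um / 1000.0] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.int16), affine), str(path))


# --------------------------------------------------------------------------
# point / annotation lookups

def region_of(vol: LabelVolume, point) -> int | None:
    """Label id of the voxel containing ``point`` (x, y, z), or None if outside."""
    x, y, z = (float(point[0]), float(point[1]), float(point[2]))
    i, j, k = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
    nx, ny, nz = vol.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        return None
    return int(vol.voxels[i, j, k])


def labels_at(vol: LabelVolume, xyz: np.ndarray) -> np.ndarray:
    """Vectorized `region_of`: out-of-bounds points get -1."""
    xyz = np.asarray(xyz, dtype=float)
    idx = np.floor(xyz).astype(int)
    nx, ny, nz = vol.shape
    inside = (
        (idx[:, 0] >= 0) & (idx[:, 0] < nx)
        & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
        & (idx[:, 2] >= 0) & (idx[:, 2] < nz)
    )
    out = np.full(len(xyz), -1, dtype=int)
    ii = idx[inside]
    out[inside] = vol.voxels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


# --------------------------------------------------------------------------
# tables

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-section neuron annotation table (CSV/TSV).

    Required columns: animal_id, section_id, class, px, py, image_w, image_h.
    Pixel coordinates are continuous with (0, 0) the image's top-left corner.
    Rows violating the class enum or the 0 ≤ px ≤ image_w / 0 ≤ py ≤ image_h
    bounds raise a ValueError naming the first offending data row (1-based).
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing annotation column(s) {missing}")
    df = df.copy()
    df["animal_id"] = df["animal_id"].astype(str)
    df["section_id"] = df["section_id"].astype(str)
    bad_class = ~df["class"].isin(NEURON_CLASSES)
    if bad_class.any():
        row = int(np.flatnonzero(bad_class.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: row {row}: class {df['class'].iloc[row - 1]!r} not one of {NEURON_CLASSES}"
        )
    for col in ("px", "py", "image_w", "image_h"):
        df[col] = pd.to_numeric(df[col])
    out_of_image = (
        (df["px"] < 0) | (df["px"] > df["image_w"])
        | (df["py"] < 0) | (df["py"] > df["image_h"])
    )
    if out_of_image.any():
        row = int(np.flatnonzero(out_of_image.to_numpy())[0]) + 1
        raise ValueError(f"{path}: row {row}: pixel coordinates outside the image")
    return df


def write_points(points: pd.DataFrame, path: str | Path) -> None:
    """Write an atlas-point table (animal_id, class, x, y, z [+extras]) as CSV.

    Coordinates are written at full float precision so that
    ``read_points(write_points(p)) == p`` bit-for-bit.
    """
    missing = [c for c in _POINT_COLUMNS if c not in points.columns]
    if missing:
        raise SchemaError(f"point table missing column(s) {missing}")
    extras = [c for c in points.columns if c not in _POINT_COLUMNS]
    points[_POINT_COLUMNS + extras].to_csv(path, index=False)


def read_points(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in _POINT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing point column(s) {missing}")
    df["animal_id"] = df["animal_id"].astype(str)
    for col in ("x", "y", "z"):
        df[col] = pd.to_numeric(df[col])
    bad = ~np.isfinite(df[["x", "y", "z"]].to_numpy()).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"{path}: row {row}: non-finite coordinates")
    return df


def point_array(points: pd.DataFrame) -> np.ndarray:
    """(n, 3) float array of the x, y, z columns."""
    return points[["x", "y", "z"]].to_numpy(dtype=float)


def load_config(path: str | Path) -> dict:
    """Load a YAML config (voxel_size_um, axis_map, midline_x, group_map...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if "group_map" in cfg:
        cfg["group_map"] = {int(k): str(v) for k, v in cfg["group_map"].items()}
    return cfg
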