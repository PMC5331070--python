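"""Oriented-plane anchoring of 2D section images in 3D atlas space.

Each histological section is modelled as an oriented plane: an origin ``o``
at the atlas position of the image's top-left corner and two spanning
vectors ``u`` (along the horizontal edge, left→right) and ``v`` (along the
vertical edge, top→bottom), all in voxel units. A pixel ``(px, py)`` on a
``W×H`` image maps to

    o + (px / W) · u + (py / H) · v .

``u`` and ``v`` need not be orthogonal or equal length, so anisotropic
scaling and shear (tissue distortion, oblique cutting planes) are
representable. The inverse map projects a 3D point orthogonally onto the
plane and reports the residual off-plane distance, which is the anchoring
error for points that do not lie exactly in the section.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError


@dataclass
class SectionAnchor:
    """Plane model of one section image in atlas space (voxel units)."""

    section_id: str
    o: np.ndarray
    u: np.ndarray
    v: np.ndarray
    image_w: float
    image_h: float

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float).reshape(3)
        self.u = np.asarray(self.u, dtype=float).reshape(3)
        self.v = np.asarray(self.v, dtype=float).reshape(3)
        if self.image_w < 1 or self.image_h < 1:
            raise GeometryError(
                f"{self.section_id}: image dimensions must be >= 1 pixel"
            )
        if np.linalg.norm(np.cross(self.u, self.v)) == 0.0:
            raise GeometryError(
                f"{self.section_id}: spanning vectors u, v are linearly dependent"
            )

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the section plane."""
        n = np.cross(self.u, self.v)
        return n / np.linalg.norm(n)

    def to_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "o": self.o.tolist(),
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "image_w": self.image_w,
            "image_h": self.image_h,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectionAnchor":
        return cls(
            section_id=str(d["section_id"]),
            o=d["o"], u=d["u"], v=d["v"],
            image_w=float(d["image_w"]), image_h=float(d["image_h"]),
        )


def pixel_to_atlas(a: SectionAnchor, px, py) -> np.ndarray:
    """Map image pixel coordinates to continuous atlas coordinates.

    Accepts scalars or equal-length arrays; returns shape (3,) or (n, 3).
    The result may lie outside the atlas volume — anchoring does not clip.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    alpha = px / a.image_w
    beta = py / a.image_h
    out = (
        a.o
        + alpha[..., np.newaxis] * a.u
        + beta[..., np.newaxis] * a.v
        if px.ndim
        else a.o + alpha * a.u + beta * a.v
    )
    return out


def atlas_to_pixel(a: SectionAnchor, p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project atlas point(s) onto the section plane.

    Returns ``(px, py, off_plane)`` where (px, py) are the pixel coordinates
    of the orthogonal projection (solved via the 2×2 normal equations in the
    (u, v) basis) and ``off_plane`` is the perpendicular residual distance in
    voxel units. Composing with `pixel_to_atlas` reproduces the projection to
    float precision.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    p2 = np.atleast_2d(p)
    d = p2 - a.o
    uu, uv, vv = a.u @ a.u, a.u @ a.v, a.v @ a.v
    det = uu * vv - uv * uv
    if det <= 0.0 or not np.isfinite(det):
        raise GeometryError(f"{a.section_id}: degenerate plane basis")
    bu = d @ a.u
    bv = d @ a.v
    alpha = (vv * bu - uv * bv) / det
    beta = (uu * bv - uv * bu) / det
    proj = a.o + np.outer(alpha, a.u) + np.outer(beta, a.v)
    off = np.linalg.norm(p2 - proj, axis=1)
    px = alpha * a.image_w
    py = beta * a.image_h
    if scalar:
        return px[0], py[0], off[0]
    return px, py, off


def anchor_from_plane(
    section_id: str,
    y_origin: float,
    tilt_lr: float,
    tilt_dv: float,
    scale_x: float,
    scale_z: float,
    image_w: float,
    image_h: float,
) -> SectionAnchor:
    """Build an anchor for a nominally coronal section.

    ``y_origin`` is the rostrocaudal level of the image origin (voxel units).
    ``tilt_lr`` shears the plane about the dorsoventral axis and ``tilt_dv``
    about the lateral axis (degrees): the in-plane extents stay ``scale_x``
    and ``scale_z`` voxels while the rostrocaudal components grow as
    ``scale · tan(tilt)``, so a 1° lateral tilt across a 16 mm section shifts
    its edge ~280 µm rostrocaudally. With both tilts zero the section is
    exactly coronal: u = (scale_x, 0, 0), v = (0, 0, scale_z),
    o = (0, y_origin, 0).
    """
    for name, tilt in (("tilt_lr", tilt_lr), ("tilt_dv", tilt_dv)):
        if abs(tilt) >= 90.0:
            raise ValueError(f"{name} must satisfy |tilt| < 90°, got {tilt}")
    tl = math.tan(math.radians(tilt_lr))
    td = math.tan(math.radians(tilt_dv))
    return SectionAnchor(
        section_id=section_id,
        o=np.array([0.0, float(y_origin), 0.0]),
        u=np.array([scale_x, scale_x * tl, 0.0]),
        v=np.array([0.0, scale_z * td, scale_z]),
        image_w=image_w,
        image_h=image_h,
    )


def tilt_offset_um(width_um: float, tilt_deg: float) -> float:
    """Rostrocaudal offset across a section of given width caused by a cut-angle tilt.

    ``width_um · tan(tilt)``: at the rat brain's widest point (~16 mm) each
    degree of deviation in the lateral plane displaces the far edge by
    ~280 µm rostrocaudally — the systematic error incurred when an oblique
    section is treated as a standard coronal plate.
    """
    if width_um < 0:
        raise ValueError(f"width_um must be >= 0, got {width_um}")
    if abs(tilt_deg) >= 90.0:
        raise ValueError(f"|tilt| must be < 90°, got {tilt_deg}")
    return width_um * math.tan(math.radians(tilt_deg))


def anchor_annotations(
    anchors: dict[str, SectionAnchor],
    records: pd.DataFrame,
    grid_shape: tuple[int, int, int] | None = None,
) -> pd.DataFrame:
    """Translate annotated pixel coordinates into 3D atlas coordinates.

    ``records`` is an annotation table (see `atlas_io.read_annotations`);
    every ``section_id`` must have an anchor. Returns a point table with
    columns animal_id, class, x, y, z, section_id (and ``in_bounds`` when a
    grid shape is supplied — out-of-volume points are kept but flagged).
    """
    missing = sorted(set(records["section_id"].astype(str)) - set(anchors))
    if missing:
        raise KeyError(f"no anchor for section(s): {missing[:5]}")
    if len(records) == 0:
        cols = ["animal_id", "class", "x", "y", "z", "section_id"]
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    xyz = np.empty((len(records), 3), dtype=float)
    sec = records["section_id"].astype(str).to_numpy()
    px = records["px"].to_numpy(dtype=float)
    py = records["py"].to_numpy(dtype=float)
    for sid in np.unique(sec):
        rows = sec == sid
        xyz[rows] = pixel_to_atlas(anchors[sid], px[rows], py[rows])
    out = pd.DataFrame(
        {
            "animal_id": records["animal_id"].astype(str).to_numpy(),
            "class": records["class"].to_numpy(),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "section_id": sec,
        }
    )
    # provenance columns (e.g. ground-truth ids) ride along untouched
    for col in records.columns:
        if col not in ("animal_id", "section_id", "class", "px", "py",
                       "image_w", "image_h") and col not in out.columns:
            out[col] = records[col].to_numpy()
    if grid_shape is not None:
        nx, ny, nz = grid_shape
        out["in_bounds"] = (
            (out["x"] >= 0) & (out["x"] < nx)
            & (out["y"] >= 0) & (out["y"] < ny)
            & (out["z"] >= 0) & (out["z"] < nz)
        )
    return out


def write_anchors(anchors: list[SectionAnchor] | dict[str, SectionAnchor], path: str | Path) -> None:
    """Serialize anchors as a JSON list (hand-editable fixture format)."""
    if isinstance(anchors, dict):
        anchors = list(anchors.values())
    Path(path).write_text(json.dumps([a.to_dict() for a in anchors], indent=1))


def read_anchors(path: str | Path) -> dict[str, SectionAnchor]:
    """Read a JSON anchor list into a section_id → anchor mapping."""
    data = json.loads(Path(path).read_text())
    anchors = [SectionAnchor.from_dict(d) for d in data]
    return {a.section_id: a for a in anchors}
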