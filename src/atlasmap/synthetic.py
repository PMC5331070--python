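"""Synthetic ground truth: toy atlas, neuron clouds, and virtual sections.

Every stage of the mapping pipeline is testable without downloading an
atlas or supplementary coordinate tables: this module generates a small
Waxholm-like label volume, neuron point clouds with the statistical
structure of a monosynaptic rabies tracing experiment targeting the RVLM,
and tilted virtual coronal sections with pixel annotations that feed the
anchoring stage.

The default scene is parameterized to the printed marginals of the study it
emulates: 1298 input neurons over 4 animals (220–561 each), a ~12-component
spatial mixture dominated by medullary sources, a 77% ipsilateral bias
implemented as a per-point contralateral flip, per-animal median distance
to the RVLM epicenter ≈ 2.5 mm with ~10% of inputs beyond 5 mm, compact
starter populations (19–67 per animal, 40% C1), and 273 TH+ bulbospinal
reference neurons whose density segmentation recovers the RVLM. The toy
atlas is a brainstem tube with nested RVLM/facial-nucleus ellipsoids plus
midbrain, forebrain, cerebellum and spinal-cord blocks, so regional counts
have non-trivial ground truth.

All randomness flows from a single integer seed through one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anchoring import SectionAnchor, anchor_from_plane, atlas_to_pixel
from .atlas_io import LabelVolume, make_label_table
from .errors import ConfigError

DEFAULT_VOXEL_SIZE_UM = 39.0


@dataclass(frozen=True)
class ClusterComponent:
    """One component of the input-neuron spatial mixture (ipsilateral side)."""

    name: str
    weight: float
    mean: tuple[float, float, float]
    sd: float


#: Input-neuron mixture. All means are on the ipsilateral (left, x < midline)
#: side or near the midline; contralateral labelling arises from the
#: ipsi-bias flip. Positions are loosely modelled on the known afferents of
#: the RVLM (ventrolateral medullary column, NTS, raphe/RVMM, prepositus,
#: lateral tegmental field, pons, parabrachial region, midbrain and
#: hypothalamic sources), laid out in the toy grid below.
DEFAULT_CLUSTERS: tuple[ClusterComponent, ...] = (
    ClusterComponent("rvlm_peri", 0.14, (66.0, 120.0, 88.0), 7.5),
    ClusterComponent("cvlm", 0.13, (70.0, 78.0, 74.0), 8.8),
    ClusterComponent("botzinger", 0.12, (80.0, 160.0, 100.0), 8.8),
    ClusterComponent("nts", 0.12, (92.0, 100.0, 124.0), 8.8),
    ClusterComponent("raphe_rvmm", 0.12, (90.0, 146.0, 60.0), 8.8),
    ClusterComponent("prepositus", 0.05, (96.0, 156.0, 134.0), 8.8),
    ClusterComponent("caudal_vrg", 0.04, (62.0, 54.0, 98.0), 8.8),
    ClusterComponent("spinal_trigeminal", 0.04, (52.0, 62.0, 128.0), 8.8),
    ClusterComponent("pons_a5", 0.10, (78.0, 208.0, 96.0), 11.2),
    ClusterComponent("parabrachial", 0.08, (86.0, 232.0, 120.0), 11.2),
    ClusterComponent("midbrain_pag", 0.03, (92.0, 272.0, 112.0), 11.2),
    ClusterComponent("hypothalamus_pvn", 0.03, (94.0, 344.0, 104.0), 11.2),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic experiment."""

    grid: tuple[int, int, int] = (224, 448, 176)
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    midline_x: float = 112.0
    n_inputs: tuple[int, ...] = (220, 237, 280, 561)
    n_starters: tuple[int, ...] = (19, 31, 35, 67)
    n_th_reference: int = 273
    clusters: tuple[ClusterComponent, ...] = DEFAULT_CLUSTERS
    ipsi_bias: float = 0.77
    epicenter: tuple[float, float, float] = (66.0, 120.0, 88.0)
    starter_sd: float = 4.0
    starter_c1_fraction: float = 0.40
    #: anisotropic spread of the TH+ reference cloud — a dorsoventrally
    #: flattened ovoid, like the nucleus it stands in for
    th_sd: tuple[float, float, float] = (6.5, 7.5, 4.5)
    #: 50 µm vibratome sections on the 39 µm grid
    section_thickness: float = 50.0 / 39.0
    section_spacing: float | None = None  # defaults to thickness
    tilt_range_deg: float = 3.0
    tilt_jitter_deg: float = 0.0
    image_w: int = 1600
    image_h: int = 1100
    seed: int = 0

    @property
    def n_animals(self) -> int:
        return len(self.n_inputs)

    @property
    def spacing(self) -> float:
        return self.section_thickness if self.section_spacing is None else self.section_spacing

    def validate(self) -> None:
        if min(self.grid) < 32:
            raise ConfigError(f"grid dims must all be >= 32, got {self.grid}")
        w = sum(c.weight for c in self.clusters)
        if abs(w - 1.0) > 1e-9:
            raise ConfigError(f"cluster weights must sum to 1, got {w}")
        if any(c.sd <= 0 for c in self.clusters):
            raise ConfigError("cluster sds must be positive")
        if not 0.5 <= self.ipsi_bias <= 1.0:
            raise ConfigError(f"ipsi_bias must be in [0.5, 1], got {self.ipsi_bias}")
        if len(self.n_starters) != len(self.n_inputs):
            raise ConfigError("n_starters and n_inputs must have one entry per animal")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator."""

    spec: SyntheticSpec
    #: inputs + starters of the mapped animals: animal_id, class, x, y, z,
    #: component (mixture index, 0 for starters), flipped (contralateral flip)
    points: pd.DataFrame
    #: TH+ bulbospinal neurons from the reference (segmentation) animals
    th_points: pd.DataFrame
    anchors: dict[str, SectionAnchor] = field(default_factory=dict)
    annotations: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# toy atlas

LABELS = (
    (1, "brainstem_core", "brainstem"),
    (2, "rvlm", "brainstem"),
    (3, "facial_nucleus", "brainstem"),
    (4, "midbrain_block", "midbrain"),
    (5, "forebrain_block", "forebrain"),
    (6, "cerebellum_block", "cerebellum"),
    (7, "spinal_cord_stub", "spinal_cord"),
)

# geometry of the toy scene (voxel units, 224×448×176 grid)
_BRAINSTEM_Y = (12, 262)
_BRAINSTEM_ELLIPSE = (112.0, 95.0, 90.0, 62.0)  # cx, cz, semi_x, semi_z
_MIDBRAIN_Y = (262, 302)
_FOREBRAIN_Y = (302, 400)
_BLOCK_X = (58, 166)
_BLOCK_Z = (66, 162)
_CEREBELLUM_Y = (30, 110)
_CEREBELLUM_Z = (150, 176)
_SPINAL_Y = (0, 12)
_RVLM_SEMI = (21.0, 20.0, 12.0)
_FACIAL_CENTER_DZ = (0.0, 4.0, -9.0)  # offset of facial-nucleus center from epicenter
_FACIAL_SEMI = (11.0, 7.0, 8.0)


def gen_label_volume(spec: SyntheticSpec) -> LabelVolume:
    """Deterministic toy atlas with nested, bilaterally mirrored regions.

    Later regions overwrite earlier ones, so specific nuclei (RVLM, facial
    nucleus) are carved out of the brainstem core last.
    """
    spec.validate()
    nx, ny, nz = spec.grid
    if ny < _FOREBRAIN_Y[0] + 8 or nx < _BLOCK_X[1] or nz < _CEREBELLUM_Z[0] + 4:
        raise ConfigError(f"grid {spec.grid} too small for the toy scene")
    vox = np.zeros(spec.grid, dtype=np.int16)
    xx = np.arange(nx, dtype=float)[:, None, None]
    yy = np.arange(ny, dtype=float)[None, :, None]
    zz = np.arange(nz, dtype=float)[None, None, :]

    def yband(lo, hi):
        return (yy >= lo) & (yy < hi)

    block_xz = (
        (xx >= _BLOCK_X[0]) & (xx < _BLOCK_X[1])
        & (zz >= _BLOCK_Z[0]) & (zz < _BLOCK_Z[1])
    )
    vox[np.broadcast_to(block_xz & yband(*_MIDBRAIN_Y), spec.grid)] = 4
    vox[np.broadcast_to(block_xz & yband(*_FOREBRAIN_Y), spec.grid)] = 5
    cereb = (
        (xx >= _BLOCK_X[0]) & (xx < _BLOCK_X[1])
        & (zz >= _CEREBELLUM_Z[0]) & (zz < _CEREBELLUM_Z[1])
        & yband(*_CEREBELLUM_Y)
    )
    vox[np.broadcast_to(cereb, spec.grid)] = 6
    cx, cz, sx, sz = _BRAINSTEM_ELLIPSE
    tube = ((xx - cx) / sx) ** 2 + ((zz - cz) / sz) ** 2 <= 1.0
    vox[np.broadcast_to(tube & yband(*_BRAINSTEM_Y), spec.grid)] = 1
    spinal = ((xx - cx) / 40.0) ** 2 + ((zz - 88.0) / 30.0) ** 2 <= 1.0
    vox[np.broadcast_to(spinal & yband(*_SPINAL_Y), spec.grid)] = 7

    ex, ey, ez = spec.epicenter
    for side_x in (ex, 2.0 * spec.midline_x - ex):
        fx, fy, fz = (side_x + _FACIAL_CENTER_DZ[0],
                      ey + _FACIAL_CENTER_DZ[1],
                      ez + _FACIAL_CENTER_DZ[2])
        facial = (
            ((xx - fx) / _FACIAL_SEMI[0]) ** 2
            + ((yy - fy) / _FACIAL_SEMI[1]) ** 2
            + ((zz - fz) / _FACIAL_SEMI[2]) ** 2
            <= 1.0
        )
        vox[np.broadcast_to(facial, spec.grid)] = 3
        rvlm = (
            ((xx - side_x) / _RVLM_SEMI[0]) ** 2
            + ((yy - ey) / _RVLM_SEMI[1]) ** 2
            + ((zz - ez) / _RVLM_SEMI[2]) ** 2
            <= 1.0
        )
        vox[np.broadcast_to(rvlm, spec.grid)] = 2

    labels = make_label_table(list(LABELS))
    return LabelVolume(voxels=vox, labels=labels, voxel_size_um=spec.voxel_size_um)


# --------------------------------------------------------------------------
# point clouds

def gen_points(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw input, starter and TH-reference neurons with ground-truth labels.

    Inputs come from the ipsilateral cluster mixture; each is flipped to the
    contralateral side (x → 2·midline − x) with probability 1 − ipsi_bias.
    Starters are a compact Gaussian cloud at the epicenter, split into C1 /
    non-C1. TH+ bulbospinal reference neurons (separate ref animals) form
    the cloud from which the RVLM is segmented.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.clusters])
    means = np.array([c.mean for c in spec.clusters])
    sds = np.array([c.sd for c in spec.clusters])

    frames = []
    for i, (n_in, n_st) in enumerate(zip(spec.n_inputs, spec.n_starters)):
        animal = f"A{i + 1}"
        comp = rng.choice(len(weights), size=n_in, p=weights)
        xyz = rng.normal(means[comp], sds[comp][:, None])
        flip = rng.random(n_in) < (1.0 - spec.ipsi_bias)
        xyz[flip, 0] = 2.0 * spec.midline_x - xyz[flip, 0]
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "class": "input",
                    "x": xyz[:, 0],
                    "y": xyz[:, 1],
                    "z": xyz[:, 2],
                    "component": comp + 1,
                    "flipped": flip,
                }
            )
        )
        st = rng.normal(spec.epicenter, spec.starter_sd, size=(n_st, 3))
        c1 = rng.random(n_st) < spec.starter_c1_fraction
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "class": np.where(c1, "starter_C1", "starter_nonC1"),
                    "x": st[:, 0],
                    "y": st[:, 1],
                    "z": st[:, 2],
                    "component": 0,
                    "flipped": False,
                }
            )
        )
    points = pd.concat(frames, ignore_index=True)
    points.insert(0, "point_id", np.arange(len(points)))

    n_ref_animals = 6
    per = np.full(n_ref_animals, spec.n_th_reference // n_ref_animals)
    per[: spec.n_th_reference % n_ref_animals] += 1
    th_frames = []
    for i, n in enumerate(per):
        th = rng.normal(spec.epicenter, spec.th_sd, size=(int(n), 3))
        th_frames.append(
            pd.DataFrame(
                {
                    "animal_id": f"ref{i + 1}",
                    "class": "th_bulbospinal",
                    "x": th[:, 0],
                    "y": th[:, 1],
                    "z": th[:, 2],
                }
            )
        )
    th_points = pd.concat(th_frames, ignore_index=True)
    return SyntheticTruth(spec=spec, points=points, th_points=th_points)


# --------------------------------------------------------------------------
# virtual sectioning

def gen_sections(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> tuple[dict[str, SectionAnchor], pd.DataFrame]:
    """Cut each mapped animal into tilted near-coronal virtual sections.

    One cutting angle per animal (the blocked brain is mounted once), drawn
    uniformly from ±tilt_range_deg, with optional per-section jitter.
    Each true point is assigned to the nearest section plane — planes are
    spaced ``spec.spacing`` apart, so the assignment error is at most half
    a section — and converted to pixel coordinates through the anchor's
    orthogonal projection. Returns the anchors and the annotation table;
    both are also stored on ``truth``.
    """
    spec = truth.spec
    if spec.tilt_range_deg > 15.0:
        raise ConfigError(
            f"tilt_range_deg {spec.tilt_range_deg} exceeds ±15° (unrealistic sectioning)"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    nx, ny, nz = spec.grid
    spacing = spec.spacing
    anchors: dict[str, SectionAnchor] = {}
    rows = []
    for animal, sub in truth.points.groupby("animal_id", sort=True):
        tilt_lr = rng.uniform(-spec.tilt_range_deg, spec.tilt_range_deg)
        tilt_dv = rng.uniform(-spec.tilt_range_deg, spec.tilt_range_deg)
        tl = np.tan(np.radians(tilt_lr))
        td = np.tan(np.radians(tilt_dv))
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        # plane coordinate: the section through origin level y0 contains all
        # points with y - x·tan(lr) - z·tan(dv) = y0
        q = xyz[:, 1] - xyz[:, 0] * tl - xyz[:, 2] * td
        k = np.round(q / spacing).astype(int)
        for kk in np.unique(k):
            sid = f"{animal}_s{kk:04d}"
            jl = rng.uniform(-spec.tilt_jitter_deg, spec.tilt_jitter_deg) if spec.tilt_jitter_deg else 0.0
            jd = rng.uniform(-spec.tilt_jitter_deg, spec.tilt_jitter_deg) if spec.tilt_jitter_deg else 0.0
            anchor = anchor_from_plane(
                sid,
                y_origin=kk * spacing,
                tilt_lr=tilt_lr + jl,
                tilt_dv=tilt_dv + jd,
                scale_x=float(nx),
                scale_z=float(nz),
                image_w=spec.image_w,
                image_h=spec.image_h,
            )
            anchors[sid] = anchor
            sel = k == kk
            px, py, _ = atlas_to_pixel(anchor, xyz[sel])
            px = np.clip(px, 0.0, spec.image_w)
            py = np.clip(py, 0.0, spec.image_h)
            ids = sub["point_id"].to_numpy()[sel]
            for (p, q2), cls, pid in zip(
                zip(px, py), sub["class"].to_numpy()[sel], ids
            ):
                rows.append(
                    {
                        "animal_id": animal,
                        "section_id": sid,
                        "class": cls,
                        "px": p,
                        "py": q2,
                        "image_w": spec.image_w,
                        "image_h": spec.image_h,
                        "point_id": pid,
                    }
                )
    annotations = pd.DataFrame(rows)
    truth.anchors = anchors
    truth.annotations = annotations
    return anchors, annotations


def generate(spec: SyntheticSpec | None = None) -> SyntheticTruth:
    """Full synthetic experiment: points + virtual sections, one seed."""
    spec = spec or SyntheticSpec()
    truth = gen_points(spec)
    gen_sections(truth)
    return truth
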