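"""Visual-search stimuli: scene sampling, rendering, tone mapping, trial designs.

A stimulus is one ellipsoid target ("caterpillar") plus 20 or 40 leaf
distractors floating on a fronto-parallel plane in front of a backdrop whose
radiance equals that of a horizontal leaf patch.  Item centres are drawn
i.i.d. uniformly on the plane and the whole scene is rejected until every
pairwise centre distance is at least 1.3 leaf lengths, so accepted scenes
are draws from the uniform distribution conditioned on the separation rule.

Leaf poses are randomised about the horizontal upward-facing default:
roll ~ Normal(0, 50 deg), yaw ~ Normal(0, 10 deg), pitch ~ Uniform(-180,
180] deg (folded into the canonical pitch range), and fold angles ~
Normal(20, 20 deg) truncated to [0, 90).  The target is the reference pose
with a single departure angle applied on one axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .countershade import ReflectanceMap, leaf_reference_radiance, optimal_reflectance
from .geometry import Orientation, TriMesh, make_ellipsoid, make_leaf, rotate_mesh, scene_pose
from .lightfield import SkyModel, irradiance_many

__all__ = [
    "ItemSpec",
    "SceneSpec",
    "ImageRaster",
    "CameraSpec",
    "TrialDesign",
    "sample_scene",
    "render_scene",
    "tone_map",
    "make_design",
]

LEAF_LENGTH = 120.0          # mm, item long axis
SEPARATION_FACTOR = 1.3      # minimum centre separation in leaf lengths
#: Stimulus-plane side (mm).  27.5 leaf lengths: the smallest square in
#: which whole-scene rejection sampling of 41 items at the 1.3-length
#: separation accepts within a 1e4-attempt budget with margin to spare.
PLANE_SIDE = 3300.0
FIELD_DEGREES = 10.58        # angular size the plane subtends (metadata)
LEAF_ALBEDO = 0.5
SEMI_AXES = (60.0, 20.0, 20.0)
FLATTEN_RATIO = 0.1
SET_SIZES = (20, 40)
LEVELS = (0.0, 15.0, 30.0, 45.0, 90.0)


@dataclass
class ItemSpec:
    """One placed item: role, 2D centre on the stimulus plane (mm), pose."""

    role: str                      # "target" | "leaf"
    position: tuple[float, float]  # (horizontal, vertical) on the plane
    orientation: Orientation
    fold_angle: float = 0.0        # leaves only
    condition: str | None = None   # target only: "countershaded" | "uniform"


@dataclass
class SceneSpec:
    """A sampled search scene: items, design condition and provenance."""

    items: list[ItemSpec]
    n_distractors: int
    target_axis: str
    target_angle: float
    condition: str
    seed: int
    plane_side: float = PLANE_SIDE
    separation_factor: float = SEPARATION_FACTOR
    leaf_length: float = LEAF_LENGTH

    def __post_init__(self) -> None:
        targets = [it for it in self.items if it.role == "target"]
        if len(targets) != 1:
            raise ValueError("a scene must contain exactly one target")
        if self.n_distractors not in SET_SIZES:
            raise ValueError(f"n_distractors must be one of {SET_SIZES}")

    @property
    def target(self) -> ItemSpec:
        return next(it for it in self.items if it.role == "target")

    def positions(self) -> np.ndarray:
        return np.asarray([it.position for it in self.items], dtype=float)

    def min_separation(self) -> float:
        """Smallest pairwise centre distance, in leaf lengths."""
        return float(pdist(self.positions()).min() / self.leaf_length)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "SceneSpec":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        items = [
            ItemSpec(
                role=i["role"],
                position=tuple(i["position"]),
                orientation=Orientation(**i["orientation"]),
                fold_angle=i.get("fold_angle", 0.0),
                condition=i.get("condition"),
            )
            for d_i, i in ((None, x) for x in d.pop("items"))
        ]
        return cls(items=items, **d)


@dataclass
class ImageRaster:
    """Scalar image: linear radiance (pre tone-map) or display values in [0, 1]."""

    values: np.ndarray
    kind: str = "linear"           # "linear" | "display"
    mm_per_px: float = 1.0
    degrees_per_px: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("raster values must be non-negative")
        if self.kind == "display" and np.any(self.values > 1.0):
            raise ValueError("display raster values must lie in [0, 1]")

    def save(self, path) -> None:
        """Write linear rasters as 32-bit float TIFF, display rasters as 16-bit PNG."""
        path = str(path)
        if self.kind == "linear":
            import tifffile

            tifffile.imwrite(path, self.values.astype(np.float32))
        else:
            import imageio.v3 as iio

            iio.imwrite(path, (self.values * 65535).round().astype(np.uint16))


@dataclass
class CameraSpec:
    """Orthographic camera looking along +x at the stimulus plane."""

    width_px: int = 256
    orthographic: bool = True
    target_subdivision: int = 3
    leaf_subdivision: int = 2
    quadrature: tuple[int, int] = (32, 16)


@dataclass
class TrialDesign:
    """Balanced, seed-shuffled trial list for one experiment."""

    table: pd.DataFrame
    seed: int
    levels: tuple[float, ...] = LEVELS

    @property
    def n_trials(self) -> int:
        return len(self.table)


def sample_scene(
    seed: int,
    n_distractors: int = 20,
    target_axis: str = "pitch",
    target_angle: float = 0.0,
    condition: str = "countershaded",
    plane_side: float = PLANE_SIDE,
    separation_factor: float = SEPARATION_FACTOR,
    leaf_length: float = LEAF_LENGTH,
    max_attempts: int = 10_000,
) -> SceneSpec:
    """Sample one search scene by whole-scene rejection.

    All item centres are redrawn together until the minimum pairwise
    distance is at least ``separation_factor`` leaf lengths, which keeps the
    accepted positions exchangeable (per-item resampling would bias the
    spatial distribution).  Raises after ``max_attempts`` rejections with
    advice to enlarge the plane or reduce the item count.
    """
    if target_axis not in ("pitch", "roll", "yaw"):
        raise ValueError(f"unknown target axis {target_axis!r}")
    if condition not in ("countershaded", "uniform"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    n_items = n_distractors + 1
    min_dist = separation_factor * leaf_length
    positions = None
    for _ in range(max_attempts):
        cand = rng.uniform(-plane_side / 2.0, plane_side / 2.0, size=(n_items, 2))
        if pdist(cand).min() >= min_dist:
            positions = cand
            break
    if positions is None:
        raise RuntimeError(
            f"no admissible scene in {max_attempts} attempts; "
            "use a larger plane or fewer items"
        )
    pitches, rolls, yaws, folds = sample_leaf_angles(rng, n_distractors)

    items = [
        ItemSpec(
            role="target",
            position=tuple(positions[0]),
            orientation=Orientation(**{target_axis: float(target_angle)}),
            condition=condition,
        )
    ]
    for k in range(n_distractors):
        items.append(
            ItemSpec(
                role="leaf",
                position=tuple(positions[k + 1]),
                orientation=Orientation.wrapped(pitches[k], rolls[k], yaws[k]),
                fold_angle=float(folds[k]),
            )
        )
    return SceneSpec(
        items=items,
        n_distractors=n_distractors,
        target_axis=target_axis,
        target_angle=float(target_angle),
        condition=condition,
        seed=int(seed),
        plane_side=plane_side,
        separation_factor=separation_factor,
        leaf_length=leaf_length,
    )


def sample_leaf_angles(rng: np.random.Generator, n: int):
    """Raw leaf pose draws: pitch ~ U(-180, 180), roll ~ N(0, 50),
    yaw ~ N(0, 10), fold ~ N(20, 20) truncated to [0, 90) (degrees).

    Pitch draws beyond +/-90 are later folded into the canonical
    (pitch, roll, yaw) ranges by :meth:`Orientation.wrapped`; the values
    returned here are the pre-wrap draws.
    """
    rolls = rng.normal(0.0, 50.0, size=n)
    yaws = rng.normal(0.0, 10.0, size=n)
    pitches = rng.uniform(-180.0, 180.0, size=n)
    folds = _truncated_normal(rng, 20.0, 20.0, 0.0, 90.0, n)
    return pitches, rolls, yaws, folds


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Normal draws resampled into [lo, hi) (handles the sub-zero mass of
    the Normal(20, 20) fold-angle distribution)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out >= hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out >= hi)
    return out


# -- rendering ---------------------------------------------------------------


def _rasterize(
    image: np.ndarray,
    depth: np.ndarray,
    verts_px: np.ndarray,
    verts_depth: np.ndarray,
    faces: np.ndarray,
    face_values: np.ndarray,
) -> None:
    """Flat-shaded triangle rasterization with a z-buffer (in place)."""
    h, w = image.shape
    tri = verts_px[faces]            # (F, 3, 2) pixel coords (col, row)
    dep = verts_depth[faces]         # (F, 3)
    lo = np.maximum(np.floor(tri.min(axis=1)).astype(int), 0)
    hi = np.minimum(np.ceil(tri.max(axis=1)).astype(int), [w - 1, h - 1])
    for f in range(len(faces)):
        x0, y0 = lo[f]
        x1, y1 = hi[f]
        if x1 < x0 or y1 < y0:
            continue
        xs = np.arange(x0, x1 + 1) + 0.5
        ys = np.arange(y0, y1 + 1) + 0.5
        px, py = np.meshgrid(xs, ys)
        (ax, ay), (bx, by), (cx, cy) = tri[f]
        det = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
        if abs(det) < 1e-12:
            continue
        w1 = ((px - ax) * (cy - ay) - (cx - ax) * (py - ay)) / det
        w2 = ((bx - ax) * (py - ay) - (px - ax) * (by - ay)) / det
        w0 = 1.0 - w1 - w2
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        d = w0 * dep[f, 0] + w1 * dep[f, 1] + w2 * dep[f, 2]
        sub_d = depth[y0 : y1 + 1, x0 : x1 + 1]
        upd = inside & (d < sub_d)
        sub_d[upd] = d[upd]
        image[y0 : y1 + 1, x0 : x1 + 1][upd] = face_values[f]


def render_scene(
    scene: SceneSpec,
    sky: SkyModel,
    camera: CameraSpec | None = None,
    leaf_albedo: float = LEAF_ALBEDO,
    clamp_target: bool = False,
) -> ImageRaster:
    """Render a scene to a linear-radiance raster.

    Per-face radiance is albedo * irradiance / pi (no cast shadows — the
    lighting arrangement was chosen so shadows carry no cues); the backdrop
    and implied ground plane render at the horizontal-leaf radiance.  The
    camera is orthographic along +x onto the (horizontal, vertical) plane.
    """
    cam = camera or CameraSpec()
    w = cam.width_px
    rad_leaf = leaf_reference_radiance(sky, leaf_albedo, cam.quadrature)
    image = np.full((w, w), rad_leaf)
    depth = np.full((w, w), np.inf)
    scale = w / scene.plane_side     # px per mm

    target_ref = scene_pose(make_ellipsoid(SEMI_AXES, cam.target_subdivision))
    for item in scene.items:
        if item.role == "target":
            base = target_ref
            if item.condition == "countershaded":
                refl = optimal_reflectance(
                    base, sky, rad_leaf, cam.quadrature, clamp=clamp_target
                )
            else:
                refl = ReflectanceMap(np.full(base.n_faces, leaf_albedo))
        else:
            base = scene_pose(
                make_leaf(SEMI_AXES, FLATTEN_RATIO, item.fold_angle,
                          cam.leaf_subdivision)
            )
            refl = ReflectanceMap(np.full(base.n_faces, leaf_albedo))
        posed = rotate_mesh(base, item.orientation)
        irr = irradiance_many(sky, posed.face_normals, cam.quadrature)
        radiance = refl.values * irr / np.pi
        verts = posed.vertices + np.array([0.0, item.position[0], item.position[1]])
        # orthographic projection: world y -> column, world z -> row (up)
        col = (verts[:, 1] + scene.plane_side / 2.0) * scale
        row = (scene.plane_side / 2.0 - verts[:, 2]) * scale
        _rasterize(
            image, depth,
            np.column_stack([col, row]), verts[:, 0],
            posed.faces, radiance,
        )
    return ImageRaster(
        values=image,
        kind="linear",
        mm_per_px=scene.plane_side / w,
        degrees_per_px=FIELD_DEGREES / w,
    )


def tone_map(raster: ImageRaster) -> ImageRaster:
    """Rescale so the 99th-percentile pixel maps to 1, then clip to [0, 1]."""
    if raster.kind != "linear":
        raise ValueError("tone_map expects a linear raster")
    p99 = float(np.percentile(raster.values, 99.0))
    if p99 <= 0.0:
        raise ValueError("cannot tone-map an all-zero raster")
    return ImageRaster(
        values=np.clip(raster.values / p99, 0.0, 1.0),
        kind="display",
        mm_per_px=raster.mm_per_px,
        degrees_per_px=raster.degrees_per_px,
    )


# -- trial designs ------------------------------------------------------------


def make_design(
    seed: int,
    levels: tuple[float, ...] = LEVELS,
    n_trials: int = 200,
    set_sizes: tuple[int, ...] = SET_SIZES,
) -> TrialDesign:
    """Balanced design: equal trials per departure level, set sizes split
    evenly within level, order shuffled by seed.  Per-trial scene seeds are
    drawn from the same generator for downstream reproducibility."""
    n_cells = len(levels) * len(set_sizes)
    if n_trials % n_cells:
        raise ValueError(
            f"n_trials={n_trials} not divisible by levels x set sizes = {n_cells}"
        )
    per_cell = n_trials // n_cells
    rows = [
        {"level": float(lev), "n_distractors": int(n)}
        for lev in levels
        for n in set_sizes
        for _ in range(per_cell)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    table = pd.DataFrame([rows[i] for i in order])
    table.insert(0, "trial", np.arange(n_trials))
    table["scene_seed"] = rng.integers(0, 2**31 - 1, size=n_trials)
    return TrialDesign(table=table, seed=int(seed), levels=tuple(levels))
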