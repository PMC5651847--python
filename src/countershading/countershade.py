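"""Optimal countershading, re-rendering at departures, and apparent shading.

A Lambertian body in the reference orientation receives per-face irradiance
irr(x) from the light field.  Choosing per-face reflectance

    refl(x) = pi * rad_hor_leaf / irr(x)

makes every face leave the constant radiance ``rad_hor_leaf`` — the
radiance of a horizontal, upward-facing leaf patch — so the body appears
flat and matches the foliage around it.  When the body rotates away from
the reference orientation the pattern no longer cancels the illumination
gradient; the *apparent shading* (max - min outgoing radiance over the
viewer-visible faces) grows, and is the physical conspicuousness proxy
behind the behavioural experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import Orientation, TriMesh, rotate_mesh
from .lightfield import (
    DEFAULT_QUADRATURE,
    VIEW_DIRECTION,
    SkyModel,
    irradiance,
    irradiance_many,
)

logger = logging.getLogger(__name__)

DEPARTURE_LEVELS = (0.0, 15.0, 30.0, 45.0, 90.0)
AXES = ("pitch", "roll", "yaw")


@dataclass
class ReflectanceMap:
    """Per-face Lambertian albedo aligned to a mesh's face list.

    Values are dimensionless and non-negative; the inverse-irradiance
    formula can demand albedo > 1 on faces turned away from the light, so
    maps are unclamped by default and carry a ``clamped`` flag when capped
    at 1.
    """

    values: np.ndarray
    clamped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("albedo values must be non-negative")
        if self.clamped and np.any(self.values > 1.0):
            raise ValueError("clamped map contains values > 1")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RenderedView:
    """Per-face outgoing radiance of a posed body, with viewer visibility."""

    radiance: np.ndarray
    visible: np.ndarray
    orientation: Orientation

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.radiance.shape != self.visible.shape:
            raise ValueError("radiance and visibility must align")


@dataclass
class ShadingCurve:
    """Apparent shading against angular departure along one axis."""

    axis: str
    levels: tuple[float, ...]
    raw: np.ndarray
    normalized: np.ndarray


def leaf_reference_radiance(
    sky: SkyModel,
    leaf_albedo: float = 0.5,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
) -> float:
    """Radiance of a horizontal, upward-facing Lambertian leaf patch."""
    if not 0.0 < leaf_albedo <= 1.0:
        raise ValueError("leaf_albedo must be in (0, 1]")
    return leaf_albedo * irradiance(sky, [0.0, 0.0, 1.0], quadrature) / np.pi


def optimal_reflectance(
    mesh: TriMesh,
    sky: SkyModel,
    rad_hor_leaf: float,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
    clamp: bool = False,
    min_irradiance: float = 1e-9,
) -> ReflectanceMap:
    """Countershading map that cancels the irradiance pattern at reference.

    Per-face albedo = pi * rad_hor_leaf / irr(face normal), for the mesh in
    the (world) reference pose it is passed in.  Faces receiving irradiance
    below ``min_irradiance`` would need unbounded albedo and raise.
    """
    if rad_hor_leaf <= 0:
        raise ValueError("rad_hor_leaf must be positive")
    irr = irradiance_many(sky, mesh.face_normals, quadrature)
    dark = np.nonzero(irr <= min_irradiance)[0]
    if dark.size:
        raise ValueError(
            f"faces {dark[:5].tolist()}... receive no light; "
            "optimal reflectance would be unbounded"
        )
    values = np.pi * rad_hor_leaf / irr
    if clamp:
        n_over = int(np.sum(values > 1.0))
        if n_over:
            logger.info("clamping %d faces with albedo > 1", n_over)
        return ReflectanceMap(np.minimum(values, 1.0), clamped=True)
    if np.any(values > 1.0):
        logger.warning(
            "optimal map contains %d faces with albedo > 1 (unclamped)",
            int(np.sum(values > 1.0)),
        )
    return ReflectanceMap(values, clamped=False)


def render(
    mesh: TriMesh,
    refl: ReflectanceMap,
    sky: SkyModel,
    orientation: Orientation = Orientation(),
    view_direction: np.ndarray = VIEW_DIRECTION,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
) -> RenderedView:
    """Re-render a reflectance-carrying body at an arbitrary pose.

    The map rotates with the body; outgoing radiance is albedo * irr / pi
    per face.  Visibility is a back-face test against the viewing direction
    (exact for the convex target).
    """
    if len(refl) != mesh.n_faces:
        raise ValueError(
            f"reflectance map ({len(refl)}) does not align with mesh "
            f"({mesh.n_faces} faces)"
        )
    view = np.asarray(view_direction, dtype=float)
    rotated = rotate_mesh(mesh, orientation)
    irr = irradiance_many(sky, rotated.face_normals, quadrature)
    radiance = refl.values * irr / np.pi
    visible = rotated.face_normals @ view < 0.0
    return RenderedView(radiance=radiance, visible=visible, orientation=orientation)


def apparent_shading(view: RenderedView, visible_only: bool = True) -> float:
    """Max - min outgoing radiance, over viewer-visible faces by default."""
    r = view.radiance[view.visible] if visible_only else view.radiance
    if r.size == 0:
        raise ValueError("no faces selected for apparent shading")
    return float(r.max() - r.min())


def shading_curves(
    mesh: TriMesh,
    refl: ReflectanceMap,
    sky: SkyModel,
    axes: tuple[str, ...] = AXES,
    levels: tuple[float, ...] = DEPARTURE_LEVELS,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
    visible_only: bool = True,
) -> dict[str, ShadingCurve]:
    """Apparent-shading sweeps along pitch, roll and yaw, jointly normalized.

    ``refl`` must be the optimal map for ``mesh`` in the pose it is passed
    in (the reference orientation).  One shared multiplicative factor
    brings the global maximum over all axes and levels to exactly 1.
    """
    raw: dict[str, np.ndarray] = {}
    for axis in axes:
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}")
        vals = []
        for level in levels:
            view = render(
                mesh, refl, sky,
                Orientation(**{axis: float(level)}),
                quadrature=quadrature,
            )
            vals.append(apparent_shading(view, visible_only=visible_only))
        raw[axis] = np.asarray(vals)
    global_max = max(v.max() for v in raw.values())
    if global_max <= 1e-12:
        raise ValueError("degenerate light field: apparent shading is zero everywhere")
    return {
        axis: ShadingCurve(
            axis=axis,
            levels=tuple(float(l) for l in levels),
            raw=raw[axis],
            normalized=raw[axis] / global_max,
        )
        for axis in axes
    }


def curves_to_records(curves: dict[str, ShadingCurve]) -> list[dict]:
    """Flatten shading curves to (axis, angle, raw, normalized) records."""
    out = []
    for axis, c in curves.items():
        for lev, r, n in zip(c.levels, c.raw, c.normalized):
            out.append({"axis": axis, "angle": lev, "raw": float(r), "normalized": float(n)})
    return out
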