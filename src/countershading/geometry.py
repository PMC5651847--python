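"""Triangle-mesh bodies: the ellipsoid target, leaf distractors, and posing.

Meshes are built with the body long axis on +x, in millimetres.  A body's
pose in space is described by pitch (tilting the long axis out of the
horizontal, -90..90 deg), roll (spin about the long axis, -180..180 deg)
and yaw (rotation about the world vertical, -180..180 deg); the reference
orientation is (0, 0, 0).

Each mesh carries the rotation ``frame`` mapping its rest body axes into
the current pose, so repeated rotations compose correctly: roll acts about
the body's current long axis, pitch about its current lateral axis, and yaw
about the world vertical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "TriMesh",
    "make_ellipsoid",
    "make_leaf",
    "rotate_mesh",
    "scene_pose",
    "load_mesh",
]


def _wrap_180(angle: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


@dataclass(frozen=True)
class Orientation:
    """Body pose angles in degrees: pitch in [-90, 90], roll and yaw in (-180, 180]."""

    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.pitch <= 90.0:
            raise ValueError(f"pitch {self.pitch} outside [-90, 90]")
        for name in ("roll", "yaw"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name} {v} outside (-180, 180]")

    @classmethod
    def wrapped(cls, pitch: float, roll: float = 0.0, yaw: float = 0.0) -> "Orientation":
        """Reduce arbitrary angles into the canonical ranges.

        A pitch beyond +/-90 is folded into the equivalent pose with
        |pitch| <= 90 by flipping roll and yaw by 180 deg (the gimbal
        equivalence of Euler angles); used for leaf pitches drawn uniformly
        on (-180, 180].
        """
        p = _wrap_180(pitch)
        if p > 90.0:
            p, roll, yaw = 180.0 - p, roll + 180.0, yaw + 180.0
        elif p < -90.0:
            p, roll, yaw = -180.0 - p, roll + 180.0, yaw + 180.0
        return cls(pitch=p, roll=_wrap_180(roll), yaw=_wrap_180(yaw))

    def is_identity(self) -> bool:
        return self.pitch == 0.0 and self.roll == 0.0 and self.yaw == 0.0


@dataclass
class TriMesh:
    """Triangle mesh with derived per-face normals and areas.

    ``frame`` is the rotation taking rest body axes (long = x, lateral = y,
    dorsal = z) into the current pose.
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        self._normals: np.ndarray | None = None
        self._areas: np.ndarray | None = None

    def _compute_face_data(self) -> None:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        if np.any(norm <= 0):
            raise ValueError("mesh contains degenerate (zero-area) faces")
        self._normals = cross / norm[:, None]
        self._areas = 0.5 * norm

    @property
    def face_normals(self) -> np.ndarray:
        if self._normals is None:
            self._compute_face_data()
        return self._normals

    @property
    def face_areas(self) -> np.ndarray:
        if self._areas is None:
            self._compute_face_data()
        return self._areas

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def long_axis(self) -> np.ndarray:
        """Current direction of the body long axis (unit vector)."""
        return self.frame @ np.array([1.0, 0.0, 0.0])

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def translated(self, offset) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(offset, dtype=float),
                       self.faces.copy(), self.frame.copy())

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.frame.copy())

    # -- interop / I/O ------------------------------------------------------

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def is_outward_convex(self) -> bool:
        """True when every face normal points away from the body centroid."""
        rel = self.face_centroids - self.centroid
        return bool(np.all(np.einsum("ij,ij->i", rel, self.face_normals) > 0))

    def save(self, path) -> None:
        """Export as ASCII OBJ or PLY (by extension); 1 unit = 1 mm, z-up."""
        path = str(path)
        tm = self.to_trimesh()
        if path.endswith(".obj"):
            data = tm.export(file_type="obj", header=None)
            data = "# countershading mesh, units mm, z-up\n" + data
            with open(path, "w") as fh:
                fh.write(data)
        elif path.endswith(".ply"):
            data = tm.export(file_type="ply", encoding="ascii")
            with open(path, "wb") as fh:
                fh.write(data if isinstance(data, bytes) else data.encode())
        else:
            raise ValueError("supported mesh formats: .obj, .ply (ASCII)")


def load_mesh(path) -> TriMesh:
    """Load an OBJ/PLY mesh written by :meth:`TriMesh.save` (mm, z-up)."""
    tm = _trimesh.load_mesh(str(path), process=False)
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def make_ellipsoid(
    semi_axes: tuple[float, float, float] = (60.0, 20.0, 20.0),
    subdivision: int = 3,
) -> TriMesh:
    """Ellipsoid target mesh by icosphere subdivision (20 * 4**k faces).

    Default is the caterpillar body, 120 mm long and 40 mm wide, long axis
    on body x.
    """
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    ico = _trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    return TriMesh(np.asarray(ico.vertices) * semi, np.asarray(ico.faces))


def make_leaf(
    semi_axes: tuple[float, float, float] = (60.0, 20.0, 20.0),
    flatten_ratio: float = 0.1,
    fold_angle: float = 20.0,
    subdivision: int = 3,
    crease: bool = False,
    match_outline: bool = True,
) -> TriMesh:
    """Leaf distractor: the target ellipsoid flattened and folded.

    The vertical short semi-axis is scaled by ``flatten_ratio``; vertices
    are then rotated about the long (x) axis by an angle proportional to
    their signed lateral offset, so the tangent planes at the two lateral
    extremes form a dihedral of ``fold_angle`` (smooth curvature).  With
    ``crease=True`` the two lateral halves are instead rotated rigidly by
    +/- fold_angle / 2 (sharp fold).  Finally (``match_outline``) the
    lateral extent is rescaled so the leaf's outline, projected along its
    flattened axis, matches the unfolded ellipse ("same 2D shape as the
    target"); the rescale slightly re-tilts normals, so geometric checks of
    the fold itself can disable it.
    """
    if not 0.0 < flatten_ratio <= 1.0:
        raise ValueError("flatten_ratio must be in (0, 1]")
    if not 0.0 <= fold_angle < 90.0:
        raise ValueError("fold_angle must be in [0, 90) degrees")
    a, b, c = semi_axes
    mesh = make_ellipsoid((a, b, c * flatten_ratio), subdivision)
    v = mesh.vertices
    if fold_angle > 0.0:
        half = np.deg2rad(fold_angle) / 2.0
        if crease:
            alpha = half * np.sign(v[:, 1])
        else:
            alpha = half * v[:, 1] / b
        y, z = v[:, 1].copy(), v[:, 2].copy()
        v[:, 1] = y * np.cos(alpha) - z * np.sin(alpha)
        v[:, 2] = y * np.sin(alpha) + z * np.cos(alpha)
        if match_outline:
            # restore the projected outline width lost to the fold
            v[:, 1] *= b / np.abs(v[:, 1]).max()
    return TriMesh(v, mesh.faces)


def _rotation_matrix(orientation: Orientation, frame: np.ndarray) -> np.ndarray:
    """World rotation for the given pose change of a body in ``frame``.

    Intrinsic order roll -> pitch -> yaw: roll about the body's current
    long axis, pitch about its current lateral axis, yaw about the world
    vertical.  Only one angle is ever nonzero in the experiments, so the
    composition order matters only for reproducibility.
    """
    long_axis = frame @ np.array([1.0, 0.0, 0.0])
    lateral = frame @ np.array([0.0, 1.0, 0.0])
    r_roll = Rotation.from_rotvec(np.deg2rad(orientation.roll) * long_axis)
    r_pitch = Rotation.from_rotvec(-np.deg2rad(orientation.pitch) * lateral)
    r_yaw = Rotation.from_rotvec(np.deg2rad(orientation.yaw) * np.array([0.0, 0.0, 1.0]))
    return (r_yaw * r_pitch * r_roll).as_matrix()


def rotate_mesh(mesh: TriMesh, orientation: Orientation) -> TriMesh:
    """Rigidly rotate a body about its centroid by the given pose angles.

    Normals and areas are recomputed lazily on the returned mesh; the body
    frame is carried along so subsequent rotations act about the body's
    current axes.
    """
    if orientation.is_identity():
        return mesh.copy()
    R = _rotation_matrix(orientation, mesh.frame)
    center = mesh.centroid
    verts = (mesh.vertices - center) @ R.T + center
    return TriMesh(verts, mesh.faces.copy(), R @ mesh.frame)


def scene_pose(mesh: TriMesh) -> TriMesh:
    """Place a body in the world reference pose used by the search scenes.

    The stimulus plane is fronto-parallel to a viewer looking toward
    azimuth 90 (+x), so at the reference orientation the body lies
    broadside: long axis horizontal along world y, dorsal side up.  The sun
    (azimuth 270) then sits in the vertical plane through the viewing axis,
    above and behind the viewer.
    """
    return rotate_mesh(mesh, Orientation(yaw=90.0))
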