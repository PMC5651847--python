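"""Directional light field: direct sun, CIE general-sky dome and a diffuse ground term.

The world frame is right-handed with z up.  Azimuth is measured clockwise
from +y ("north") so that a direction with azimuth ``az`` and elevation
``el`` (both degrees) is ``(sin az cos el, cos az cos el, sin el)``.  The
virtual viewer of the search stimuli looks toward azimuth 90 (+x); with the
default sun at azimuth 270, altitude 45, the scene is lit from above and
behind the viewer.

The diffuse sky follows the two-factor CIE general-sky form: relative
radiance is a gradation function of the zenith angle of the sky element
times a scattering indicatrix of its angular distance from the sun,
normalized so the zenith radiance equals ``zenith_radiance``.  The direct
sun is a delta beam.  Below the horizon a constant-radiance ground reflects
``ground_albedo`` of the horizontal (sun + sky) irradiance; a single bounce
only, since ground light reaches only downward-facing patches and
second-order terms are smaller than albedo**2 of the diffuse term.

All radiometric quantities are in arbitrary linear units; every quantity
used downstream is a ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from functools import cached_property, lru_cache

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Direction the virtual viewer looks along (toward azimuth 90 = +x).
VIEW_DIRECTION = np.array([1.0, 0.0, 0.0])

#: Default hemispherical quadrature (elevation nodes, azimuth nodes).
DEFAULT_QUADRATURE = (64, 32)
#: Coarsest quadrature accepted by :func:`irradiance`.
MIN_QUADRATURE = (16, 8)


class DomainError(ValueError):
    """Raised when a light-field query is outside its domain."""


def direction_from_angles(azimuth: float, elevation: float) -> np.ndarray:
    """Unit vector for compass azimuth / elevation, both in degrees.

    Azimuth is clockwise from +y ("north"); elevation is above the horizon.
    """
    az = np.deg2rad(azimuth)
    el = np.deg2rad(elevation)
    return np.array(
        [np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)]
    )


def _check_unit(v: np.ndarray, tol: float = 1e-8, name: str = "direction") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > tol:
        raise ValueError(f"{name} must be unit length (|v| = {n:.3g})")
    return v


@dataclass(frozen=True)
class SkyCoefficients:
    """Gradation/indicatrix coefficients of the CIE general sky.

    Gradation: phi(Z) = 1 + a * exp(b / cos Z)   (Z = zenith angle of the
    sky element; phi -> 1 at the horizon for b < 0).
    Indicatrix: f(chi) = 1 + c * (exp(d * chi) - exp(d * pi/2)) + e * cos^2 chi
    (chi = angular distance from the sun).
    """

    a: float
    b: float
    c: float
    d: float
    e: float

    def gradation(self, cos_zenith: np.ndarray) -> np.ndarray:
        cz = np.maximum(np.asarray(cos_zenith, dtype=float), 1e-9)
        return 1.0 + self.a * np.exp(np.minimum(self.b / cz, 50.0))

    def indicatrix(self, chi: np.ndarray) -> np.ndarray:
        chi = np.asarray(chi, dtype=float)
        return (
            1.0
            + self.c * (np.exp(self.d * chi) - np.exp(self.d * np.pi / 2.0))
            + self.e * np.cos(chi) ** 2
        )


#: Standard clear ("sunny") sky, low turbidity — CIE type 12.
CIE_CLEAR = SkyCoefficients(a=-1.0, b=-0.32, c=10.0, d=-3.0, e=0.45)
#: Standard overcast sky — CIE type 1.
CIE_OVERCAST = SkyCoefficients(a=4.0, b=-0.7, c=0.0, d=-1.0, e=0.0)
#: Isotropic dome (constant gradation and indicatrix), for tests/oracles.
ISOTROPIC = SkyCoefficients(a=0.0, b=-1.0, c=0.0, d=-1.0, e=0.0)

SKY_TYPES = {"clear": CIE_CLEAR, "overcast": CIE_OVERCAST, "isotropic": ISOTROPIC}


@dataclass(frozen=True)
class SkyModel:
    """Sun + CIE sky dome + constant-radiance ground.

    Parameters
    ----------
    sun_azimuth, sun_altitude
        Sun position in degrees (azimuth clockwise from north, altitude
        above the horizon; negative altitude is rejected).
    sun_irradiance
        Flux density of the direct beam at normal incidence (>= 0).
    coefficients
        CIE gradation/indicatrix parameter set.
    zenith_radiance
        Radiance of the diffuse sky at the zenith (>= 0); the whole dome
        scales with it.
    ground_albedo
        Diffuse ground reflectance in [0, 1].
    """

    sun_azimuth: float = 270.0
    sun_altitude: float = 45.0
    sun_irradiance: float = 0.0
    coefficients: SkyCoefficients = CIE_CLEAR
    zenith_radiance: float = 1.0
    ground_albedo: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.sun_altitude <= 90.0:
            raise ValueError("sun_altitude must be in [0, 90] degrees")
        if self.sun_irradiance < 0 or self.zenith_radiance < 0:
            raise ValueError("radiometric quantities must be non-negative")
        if not 0.0 <= self.ground_albedo <= 1.0:
            raise ValueError("ground_albedo must be in [0, 1]")

    # -- constructors -----------------------------------------------------

    @classmethod
    def clear_sky(
        cls,
        sun_azimuth: float = 270.0,
        sun_altitude: float = 45.0,
        zenith_radiance: float = 1.0,
        sun_to_diffuse: float = 5.0,
        ground_albedo: float = 0.25,
    ) -> "SkyModel":
        """Clear-sky default: direct-beam strength set so the sun's
        horizontal irradiance is ``sun_to_diffuse`` times the diffuse-sky
        horizontal irradiance (5:1 is typical of a clear day)."""
        if sun_altitude <= 0:
            raise ValueError("clear_sky requires the sun above the horizon")
        diffuse_only = cls(
            sun_azimuth=sun_azimuth,
            sun_altitude=sun_altitude,
            sun_irradiance=0.0,
            coefficients=CIE_CLEAR,
            zenith_radiance=zenith_radiance,
            ground_albedo=ground_albedo,
        )
        d_hor = diffuse_only.sky_horizontal_irradiance()
        sun_irr = sun_to_diffuse * d_hor / np.sin(np.deg2rad(sun_altitude))
        return cls(
            sun_azimuth=sun_azimuth,
            sun_altitude=sun_altitude,
            sun_irradiance=float(sun_irr),
            coefficients=CIE_CLEAR,
            zenith_radiance=zenith_radiance,
            ground_albedo=ground_albedo,
        )

    @classmethod
    def overcast(
        cls, zenith_radiance: float = 1.0, ground_albedo: float = 0.25
    ) -> "SkyModel":
        """Sunless CIE overcast dome."""
        return cls(
            sun_azimuth=0.0,
            sun_altitude=45.0,
            sun_irradiance=0.0,
            coefficients=CIE_OVERCAST,
            zenith_radiance=zenith_radiance,
            ground_albedo=ground_albedo,
        )

    # -- geometry ---------------------------------------------------------

    @property
    def sun_direction(self) -> np.ndarray:
        return direction_from_angles(self.sun_azimuth, self.sun_altitude)

    # -- radiance fields --------------------------------------------------

    def _sky_radiance(self, dirs: np.ndarray) -> np.ndarray:
        """Diffuse sky radiance for unit directions (n, 3); no horizon check."""
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        cos_z = np.clip(dirs[:, 2], 0.0, 1.0)
        cos_chi = np.clip(dirs @ self.sun_direction, -1.0, 1.0)
        chi = np.arccos(cos_chi)
        zs = np.deg2rad(90.0 - self.sun_altitude)  # sun zenith angle
        c = self.coefficients
        norm = c.gradation(np.array(1.0)) * c.indicatrix(np.array(zs))
        return self.zenith_radiance * c.gradation(cos_z) * c.indicatrix(chi) / norm

    def _environment_radiance(self, dirs: np.ndarray) -> np.ndarray:
        """Full-sphere radiance: sky above the horizon, ground below."""
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        out = self._sky_radiance(dirs)
        below = dirs[:, 2] <= 0.0
        if np.any(below):
            out = np.where(below, self.ground_radiance, out)
        return out

    def sky_horizontal_irradiance(
        self, quadrature: tuple[int, int] = DEFAULT_QUADRATURE
    ) -> float:
        """Diffuse-sky irradiance on an upward horizontal patch (no sun)."""
        mu, dirs, w = _hemisphere_quadrature(*quadrature)
        return float(w @ self._sky_radiance(dirs))

    def horizontal_irradiance(
        self, quadrature: tuple[int, int] = DEFAULT_QUADRATURE
    ) -> float:
        """Total (sun + sky) irradiance on an upward horizontal patch."""
        sun = self.sun_irradiance * max(0.0, float(self.sun_direction[2]))
        return sun + self.sky_horizontal_irradiance(quadrature)

    @cached_property
    def ground_radiance(self) -> float:
        """Constant ground radiance: albedo * E_horizontal / pi (one bounce)."""
        return self.ground_albedo * self.horizontal_irradiance() / np.pi

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = asdict(self.coefficients)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SkyModel":
        d = dict(d)
        coeff = d.get("coefficients", CIE_CLEAR)
        if isinstance(coeff, str):
            coeff = SKY_TYPES[coeff]
        elif isinstance(coeff, dict):
            coeff = SkyCoefficients(**coeff)
        d["coefficients"] = coeff
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "SkyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# -- public radiance queries ----------------------------------------------


def sky_radiance(sky: SkyModel, direction) -> float:
    """Diffuse-sky radiance toward ``direction`` (unit vector above horizon).

    Excludes the direct solar beam.  Directions at or below the horizon are
    a domain error; use :func:`environment_radiance` for full-sphere queries.
    """
    d = _check_unit(direction)
    if d[2] <= 0.0:
        raise DomainError("sky_radiance is defined above the horizon only")
    return float(sky._sky_radiance(d)[0])


def environment_radiance(sky: SkyModel, direction) -> float:
    """Radiance of the environment (sky dome above, constant ground below)."""
    d = _check_unit(direction)
    return float(sky._environment_radiance(d)[0])


# -- hemispherical quadrature ----------------------------------------------


@lru_cache(maxsize=8)
def _hemisphere_quadrature(n_elev: int, n_azim: int):
    """Product rule on the upper hemisphere in a local z-up frame.

    Gauss-Legendre in mu = cos(polar angle) on (0, 1] crossed with uniform
    azimuth; returned weights already include the projected-solid-angle
    factor mu, so an irradiance is ``sum(w * L(dirs))``.
    """
    x, w = np.polynomial.legendre.leggauss(n_elev)
    mu = 0.5 * (x + 1.0)          # (0, 1)
    wmu = 0.5 * w
    phi = (np.arange(n_azim) + 0.5) * (2.0 * np.pi / n_azim)
    s = np.sqrt(1.0 - mu**2)
    dirs = np.empty((n_elev * n_azim, 3))
    dirs[:, 0] = np.outer(s, np.cos(phi)).ravel()
    dirs[:, 1] = np.outer(s, np.sin(phi)).ravel()
    dirs[:, 2] = np.repeat(mu, n_azim)
    weights = np.repeat(wmu * mu, n_azim) * (2.0 * np.pi / n_azim)
    return mu, dirs, weights


def _local_bases(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent pairs (t1, t2) for unit normals (n, 3)."""
    n = normals
    helper = np.tile(np.array([1.0, 0.0, 0.0]), (len(n), 1))
    swap = np.abs(n[:, 0]) > 0.9
    helper[swap] = [0.0, 1.0, 0.0]
    t1 = np.cross(helper, n)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    return t1, t2


def _validate_quadrature(quadrature: tuple[int, int]) -> tuple[int, int]:
    ne, na = int(quadrature[0]), int(quadrature[1])
    if ne < MIN_QUADRATURE[0] or na < MIN_QUADRATURE[1]:
        raise ValueError(
            f"quadrature {quadrature} below accepted minimum {MIN_QUADRATURE}"
        )
    return ne, na


@lru_cache(maxsize=32)
def _sky_nodes(sky: SkyModel, n_elev: int, n_azim: int):
    """Sky radiance sampled at the world-frame quadrature nodes.

    Returns node directions (K, 3) and the combined weight * radiance
    vector; weights here exclude the incidence cosine, which depends on the
    receiving normal and is applied in :func:`irradiance_many`.
    """
    x, w = np.polynomial.legendre.leggauss(n_elev)
    mu = 0.5 * (x + 1.0)
    wmu = 0.5 * w
    phi = (np.arange(n_azim) + 0.5) * (2.0 * np.pi / n_azim)
    s = np.sqrt(1.0 - mu**2)
    dirs = np.empty((n_elev * n_azim, 3))
    dirs[:, 0] = np.outer(s, np.cos(phi)).ravel()
    dirs[:, 1] = np.outer(s, np.sin(phi)).ravel()
    dirs[:, 2] = np.repeat(mu, n_azim)
    weights = np.repeat(wmu, n_azim) * (2.0 * np.pi / n_azim)
    return dirs, weights * sky._sky_radiance(dirs)


def irradiance(
    sky: SkyModel, normal, quadrature: tuple[int, int] = DEFAULT_QUADRATURE
) -> float:
    """Irradiance on a Lambertian patch with the given unit normal.

    E = sun_irradiance * max(0, n.s) + integral of environment radiance
    over the hemisphere above the patch, cosine-weighted.  No occlusion:
    the scene arrangement avoids cast shadows, and the bodies are convex so
    a face never shadows its own hemisphere.
    """
    n = _check_unit(normal, name="normal")
    return float(irradiance_many(sky, n[None, :], quadrature)[0])


def irradiance_many(
    sky: SkyModel,
    normals: np.ndarray,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
) -> np.ndarray:
    """Vectorized :func:`irradiance` for an (n, 3) array of unit normals.

    The diffuse-sky integral runs over the world upper hemisphere with the
    incidence cosine clipped at the patch's own horizon (so the sky's
    horizon never cuts through quadrature cells), and the constant-radiance
    ground contributes its exact tilted-patch view factor
    pi * (1 - cos beta) / 2.
    """
    ne, na = _validate_quadrature(quadrature)
    normals = np.asarray(normals, dtype=float)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        raise ValueError("normals must be unit length")
    dirs, wl = _sky_nodes(sky, ne, na)
    e_sky = np.maximum(0.0, normals @ dirs.T) @ wl
    e_ground = sky.ground_radiance * np.pi * 0.5 * (1.0 - normals[:, 2])
    e_sun = sky.sun_irradiance * np.maximum(0.0, normals @ sky.sun_direction)
    return e_sky + e_ground + e_sun
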