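"""Closed-form optical parameters of the lensless point-source (DLHM) geometry.

A digital lensless holographic microscope places the sample at distance
``d - z`` from a point source and ``z`` from the sensor (source-to-sensor
distance ``d``).  The diffracted wavefront reaching the sensor is a
geometrically magnified projection of the object, so magnification, field of
view, numerical aperture and the diffraction-limited resolution all follow
from the axial distances and the sensor dimensions alone:

* magnification          ``M = d / (d - z)``
* field of view          ``FOV = nx * ny * p**2 / M**2``
* numerical aperture     ``NA = sin(atan(N * p / (2 z)))``
* resolution limit       ``rho = k * lambda / NA`` (Rayleigh-type, ``k ~ 1``)

All quantities are SI (meters) internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OpticalGeometry",
    "DerivedOptics",
    "magnification",
    "field_of_view",
    "numerical_aperture",
    "resolution_limit",
    "nyquist_ok",
    "usaf_period",
    "derive_optics",
]


@dataclass(frozen=True)
class OpticalGeometry:
    """Point-source lensless geometry.

    Parameters
    ----------
    d : float
        Source-to-sensor distance in meters.
    z : float
        Sample-to-sensor distance in meters; ``0 < z < d``.
    pitch : float
        Sensor pixel pitch in meters.
    nx, ny : int
        Pixel counts along x (columns) and y (rows).
    """

    d: float
    z: float
    pitch: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"source-to-sensor distance d must be > 0, got {self.d}")
        if not 0 < self.z < self.d:
            raise ValueError(f"z must satisfy 0 < z < d, got z={self.z}, d={self.d}")
        if not self.pitch > 0:
            raise ValueError(f"pixel pitch must be > 0, got {self.pitch}")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("sensor must have at least 2x2 pixels")

    @property
    def sensor_extent(self) -> tuple[float, float]:
        """Physical sensor size (x, y) in meters."""
        return (self.nx * self.pitch, self.ny * self.pitch)


@dataclass(frozen=True)
class DerivedOptics:
    """Derived imaging parameters for a geometry and a set of wavelengths."""

    magnification: float
    fov_x: float
    fov_y: float
    fov_area: float
    na_x: float
    na_y: float
    na: float                     # conservative scalar: the smaller axis NA
    rho: dict[float, float] = field(default_factory=dict)  # wavelength -> limit (m)


def magnification(geom: OpticalGeometry) -> float:
    """Geometric projection magnification ``M = d / (d - z)``.

    Always ``>= 1`` for ``0 < z < d`` and diverges as the sample approaches
    the source (``z -> d``).
    """
    return geom.d / (geom.d - geom.z)


def field_of_view(geom: OpticalGeometry) -> tuple[float, float, float]:
    """Imaged field of view ``(extent_x, extent_y, area)`` in meters / m^2.

    The sensor area demagnified to the object plane:
    per-axis extent ``n_i * p / M``, area ``nx * ny * p^2 / M^2``.
    """
    m = magnification(geom)
    ext_x = geom.nx * geom.pitch / m
    ext_y = geom.ny * geom.pitch / m
    return ext_x, ext_y, ext_x * ext_y


def numerical_aperture(geom: OpticalGeometry, axis: str = "min") -> float:
    """Collection NA ``sin(atan(N p / (2 z)))`` of the sensor half-aperture.

    ``axis`` selects ``'x'``, ``'y'``, or ``'min'`` (the smaller of the two,
    conservative for anisotropic sensors).
    """
    def _na(n: int) -> float:
        return math.sin(math.atan(n * geom.pitch / (2.0 * geom.z)))

    if axis == "x":
        return _na(geom.nx)
    if axis == "y":
        return _na(geom.ny)
    if axis == "min":
        return min(_na(geom.nx), _na(geom.ny))
    raise ValueError(f"axis must be 'x', 'y' or 'min', got {axis!r}")


def resolution_limit(wavelength: float, na: float, k: float = 1.0) -> float:
    """Diffraction-limited resolution ``rho = k * wavelength / NA`` in meters.

    ``k`` defaults to 1, the Rayleigh-criterion constant for coherent
    near-field imaging.
    """
    if not 0 < na <= 1:
        raise ValueError(f"NA must lie in (0, 1], got {na}")
    if not wavelength > 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    return k * wavelength / na


def nyquist_ok(geom: OpticalGeometry, rho: float) -> tuple[bool, float]:
    """Check the digital-sampling bound ``rho > 2 p / M`` (strict).

    Returns ``(ok, margin)`` with ``margin = rho - 2 p / M`` in meters; the
    diffraction limit must exceed two demagnified pixels for the fringes to be
    sampled.
    """
    limit = 2.0 * geom.pitch / magnification(geom)
    return rho > limit, rho - limit


def usaf_period(group: int, element: int) -> float:
    """Line-pair period (m) of a USAF-1951 element.

    Spatial frequency is ``2**(group + (element - 1) / 6)`` line pairs per mm,
    so the period is ``1e-3 / 2**(group + (element - 1) / 6)`` meters.
    """
    if not 1 <= element <= 6:
        raise ValueError(f"USAF element must be 1..6, got {element}")
    if not -2 <= group <= 11:
        raise ValueError(f"USAF group must be -2..11, got {group}")
    return 1.0e-3 / 2.0 ** (group + (element - 1) / 6.0)


def derive_optics(
    geom: OpticalGeometry,
    wavelengths: tuple[float, ...] = (),
    k: float = 1.0,
) -> DerivedOptics:
    """Bundle all derived parameters for a geometry and wavelength list."""
    m = magnification(geom)
    fov_x, fov_y, fov_area = field_of_view(geom)
    na_x = numerical_aperture(geom, "x")
    na_y = numerical_aperture(geom, "y")
    na = min(na_x, na_y)
    rho = {lam: resolution_limit(lam, na, k) for lam in wavelengths}
    return DerivedOptics(
        magnification=m,
        fov_x=fov_x,
        fov_y=fov_y,
        fov_area=fov_area,
        na_x=na_x,
        na_y=na_y,
        na=na,
        rho=rho,
    )
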