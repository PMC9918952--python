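"""Scalar free-space propagation of sampled complex fields.

Two frequency-domain propagators are provided:

* ``angular_spectrum`` (default): multiplication of the field's spatial
  spectrum by ``exp(+j 2 pi z sqrt(1/lambda^2 - fx^2 - fy^2))``.  The transfer
  function has unit modulus over the propagating band, so forward and
  backward propagation are exact inverses there — the property the iterative
  retrieval relies on.
* ``rayleigh_sommerfeld``: FFT convolution with the sampled first
  Rayleigh-Sommerfeld impulse response
  ``h = (1/2pi) (e^{jkr}/r) (z/r) (jk - 1/r)``, ``r = sqrt(x^2+y^2+z^2)``.
  Retained as an independent route; it agrees with the angular spectrum for
  band-limited paraxial fields.

Sign convention: ``exp(+jkr)`` diverging away from the source, so a positive
distance propagates from the object towards the sensor and a negative
distance reconstructs (back-propagates).  Back-propagation by ``-z`` uses the
conjugate kernel of ``+z``.

The point-source recording geometry is handled through the Fresnel scaling
equivalence: a spherical-wave hologram recorded at sample-to-sensor distance
``z`` with magnification ``M`` is treated as a plane-wave hologram of the
``M``-magnified object at the equivalent distance ``M * z``, sampled at the
sensor pitch.  Simulator and retrieval share this convention, so it cancels
in round trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .optics import OpticalGeometry, magnification

__all__ = [
    "ComplexField",
    "PropagationSpec",
    "propagate",
    "extract_phase",
    "equivalent_plane_wave_distance",
    "check_fringe_sampling",
]


@dataclass(frozen=True)
class ComplexField:
    """A sampled 2-D complex amplitude.

    Parameters
    ----------
    values : ndarray, complex, shape (ny, nx)
    pitch : float
        Sampling interval in meters.
    wavelength : float
        Illumination wavelength in meters.
    plane : str
        Free-form label, e.g. ``"hologram"`` or ``"object"``.
    """

    values: np.ndarray
    pitch: float
    wavelength: float
    plane: str = "hologram"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"field must be 2-D, got shape {v.shape}")
        if not np.iscomplexobj(v):
            v = v.astype(np.complex128)
        object.__setattr__(self, "values", v)
        if not self.pitch > 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PropagationSpec:
    """How to propagate: signed distance, kernel, zero-padding factor."""

    distance: float
    method: str = "angular_spectrum"
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if self.pad_factor < 1:
            raise ValueError(f"pad_factor must be >= 1, got {self.pad_factor}")
        if self.method not in ("angular_spectrum", "rayleigh_sommerfeld"):
            raise ValueError(f"unknown propagation method {self.method!r}")


def _padded(values: np.ndarray, pad_factor: int) -> tuple[np.ndarray, tuple[slice, slice]]:
    ny, nx = values.shape
    py, px = ny * pad_factor, nx * pad_factor
    out = np.zeros((py, px), dtype=np.complex128)
    y0, x0 = (py - ny) // 2, (px - nx) // 2
    out[y0 : y0 + ny, x0 : x0 + nx] = values
    return out, (slice(y0, y0 + ny), slice(x0, x0 + nx))


def _as_transfer(shape: tuple[int, int], pitch: float, wavelength: float, z: float) -> np.ndarray:
    """Angular-spectrum transfer function; evanescent components are zeroed."""
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    fsq = fy[:, None] ** 2 + fx[None, :] ** 2
    arg = 1.0 / wavelength**2 - fsq
    prop = arg > 0
    kz = np.zeros_like(fsq)
    kz[prop] = 2.0 * np.pi * np.sqrt(arg[prop])
    h = np.zeros(shape, dtype=np.complex128)
    h[prop] = np.exp(1j * kz[prop] * z)
    return h


def _rs_transfer(shape: tuple[int, int], pitch: float, wavelength: float, z: float) -> np.ndarray:
    """DFT of the sampled Rayleigh-Sommerfeld impulse response for |z|.

    Back-propagation (z < 0) uses the conjugate of the forward kernel so that
    the two directions are mutually inverse in the same sense as the angular
    spectrum.
    """
    az = abs(z)
    k = 2.0 * np.pi / wavelength
    y = (np.arange(shape[0]) - shape[0] // 2) * pitch
    x = (np.arange(shape[1]) - shape[1] // 2) * pitch
    r = np.sqrt(y[:, None] ** 2 + x[None, :] ** 2 + az**2)
    h = (az / (2.0 * np.pi)) * np.exp(1j * k * r) / r**2 * (1.0 / r - 1j * k)
    hk = np.fft.fft2(np.fft.ifftshift(h)) * pitch**2
    if z < 0:
        hk = np.conj(hk)
    return hk


def check_fringe_sampling(
    shape: tuple[int, int], pitch: float, wavelength: float, z: float
) -> bool:
    """Check the sampling of the spatial chirp over an aperture.

    The local fringe frequency of the free-space kernel (and of an in-line
    hologram) at radius r is ~ r/(lambda z); over the given aperture it must
    stay below the grid Nyquist frequency 1/(2 p).  Returns True when safely
    sampled, warns and returns False otherwise.
    """
    if z == 0:
        return True
    r_max = 0.5 * np.hypot(shape[0] * pitch, shape[1] * pitch)
    f_max = r_max / (wavelength * abs(z))
    if f_max > 1.0 / (2.0 * pitch):
        warnings.warn(
            "spatial chirp under-sampled: local fringe frequency "
            f"{f_max:.3g} cyc/m exceeds Nyquist {1.0 / (2 * pitch):.3g} cyc/m "
            f"(pitch={pitch:g} m, z={z:g} m); expect aliasing artifacts",
            stacklevel=3,
        )
        return False
    return True


def _border_mean(v: np.ndarray, width: int = 8) -> complex:
    w = min(width, v.shape[0] // 4, v.shape[1] // 4)
    return complex(
        (v[:w].mean() + v[-w:].mean() + v[:, :w].mean() + v[:, -w:].mean()) / 4.0
    )


def propagate(
    field: ComplexField,
    spec: PropagationSpec | float,
    background: complex | str | None = None,
) -> ComplexField:
    """Propagate a field by a signed distance.

    ``spec`` may be a :class:`PropagationSpec` or a bare distance in meters
    (angular spectrum, pad factor 2).  Wavelength and pitch are preserved;
    the computation zero-pads by ``pad_factor``, multiplies the spectrum by
    the chosen transfer function, and crops back.

    ``background`` treats a uniform plane-wave pedestal analytically: the
    scalar (or, with ``"edge"``, the border-mean estimate) is subtracted
    before the transform and re-added with the on-axis phase advance
    ``exp(+j 2 pi z / lambda)``.  In-line holograms sit on a background of
    order 1 that extends beyond the sensor window; splitting it off keeps the
    zero-padding from turning the window edge into a diffracting aperture.
    """
    if not isinstance(spec, PropagationSpec):
        spec = PropagationSpec(distance=float(spec))
    v = field.values
    if not np.all(np.isfinite(v)):
        raise ValueError("field contains non-finite values")
    if spec.distance == 0.0:
        return replace(field, values=v.copy())

    if background is not None:
        bg = _border_mean(v) if background == "edge" else complex(background)
        inner = propagate(replace(field, values=v - bg), spec, background=None)
        dc = np.exp(1j * 2.0 * np.pi * spec.distance / field.wavelength)
        return replace(inner, values=inner.values + bg * dc)

    padded, crop = _padded(v, spec.pad_factor)
    if spec.method == "angular_spectrum":
        hk = _as_transfer(padded.shape, field.pitch, field.wavelength, spec.distance)
    else:
        # the sampled spatial chirp is the accuracy limit of this route
        check_fringe_sampling(padded.shape, field.pitch, field.wavelength, spec.distance)
        hk = _rs_transfer(padded.shape, field.pitch, field.wavelength, spec.distance)
    out = np.fft.ifft2(np.fft.fft2(padded) * hk)[crop]
    return replace(field, values=out, plane=f"z{spec.distance:+g}")


def extract_phase(field: ComplexField, return_mask: bool = False):
    """Four-quadrant phase ``atan2(Im, Re)`` in (-pi, pi].

    Pixels with exactly zero amplitude have undefined phase; they are reported
    as 0 and flagged in the optional mask.
    """
    v = field.values
    phase = np.angle(v)
    zero = v == 0
    if np.any(zero):
        phase = phase.copy()
        phase[zero] = 0.0
    if return_mask:
        return phase, zero
    return phase


def equivalent_plane_wave_distance(geom: OpticalGeometry) -> float:
    """Plane-wave-equivalent propagation distance ``M * z`` (Fresnel scaling).

    At the sensor pitch, the spherical-reference recording is equivalent to a
    plane-wave recording of the M-magnified object propagated by ``M * z``.
    """
    return magnification(geom) * geom.z
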