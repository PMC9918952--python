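"""Seeded forward model: scenes, per-wavelength Gabor holograms, sensor effects.

The simulator produces everything the rest of the toolkit consumes, in the
order a real instrument would: a weakly diffracting scene (amplitude bars or
phase beads), one in-line hologram per illumination wavelength computed as
the exact nonlinear intensity ``|U|^2`` of the propagated field (the
weak-object linearization is a *checked assumption*, not an approximation
baked into the model), spectral crosstalk mixing through an n x n matrix,
color-filter-array mosaicing, vignetting of the spherical reference, and
shot + read noise.

Scenes live on the magnified (plane-wave-equivalent) grid: object-plane
pitch ``p / M`` over the same pixel counts as the sensor, so no resampling
is needed between object and sensor planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticalGeometry, magnification, usaf_period
from .propagation import (
    ComplexField,
    PropagationSpec,
    check_fringe_sampling,
    equivalent_plane_wave_distance,
    propagate,
)

__all__ = [
    "SceneSpec",
    "CrosstalkMatrix",
    "CfaPattern",
    "MosaicFrame",
    "HologramSet",
    "make_usaf_target",
    "make_bead_phantom",
    "forward_hologram",
    "forward_hologram_set",
    "apply_crosstalk",
    "mosaic",
    "add_noise",
    "apply_vignette",
    "vignette_profile",
    "default_crosstalk",
]


@dataclass(frozen=True)
class SceneSpec:
    """Complex-transmittance scene ``t * exp(i phi)`` on the object grid.

    ``transmittance`` in [0, 1]; ``phase`` in radians; ``pitch`` is the
    object-scale sampling interval (``sensor pitch / M``).  ``axial_offsets``
    maps a wavelength to an extra signed focus offset (meters, in the
    plane-wave-equivalent frame) modelling slide dispersion.  ``layout``
    optionally records where resolution-target elements were drawn.
    """

    transmittance: np.ndarray
    phase: np.ndarray
    pitch: float
    axial_offsets: dict[float, float] = field(default_factory=dict)
    layout: tuple = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.transmittance, dtype=float)
        p = np.asarray(self.phase, dtype=float)
        if t.shape != p.shape or t.ndim != 2:
            raise ValueError("transmittance and phase must be equal-shape 2-D arrays")
        if t.min() < -1e-12 or t.max() > 1 + 1e-12:
            raise ValueError("transmittance must lie in [0, 1]")
        object.__setattr__(self, "transmittance", t)
        object.__setattr__(self, "phase", p)

    @property
    def complex_transmittance(self) -> np.ndarray:
        return self.transmittance * np.exp(1j * self.phase)


@dataclass(frozen=True)
class CrosstalkMatrix:
    """Sensor spectral-response mixing matrix ``L`` (channels x wavelengths).

    ``L[i, j]`` is the fraction of illumination ``j`` detected by channel
    ``i``.  Recorded channel intensities are ``I_c = L @ I_lambda`` pixelwise;
    demixing applies ``L^{-1}``.
    """

    matrix: np.ndarray
    max_condition: float = 1.0e3

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"crosstalk matrix must be square, got shape {m.shape}")
        if np.any(m < 0):
            raise ValueError("crosstalk coefficients must be nonnegative")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def check_invertible(self) -> None:
        """Raise when the channels cannot be demixed reliably."""
        if self.condition_number > self.max_condition:
            raise ValueError(
                f"detectors not separable: condition number "
                f"{self.condition_number:.3g} exceeds bound {self.max_condition:.3g}"
            )

    @property
    def inverse(self) -> np.ndarray:
        self.check_invertible()
        return np.linalg.inv(self.matrix)

    def column_normalized(self) -> "CrosstalkMatrix":
        """Each column scaled to unit sum (removes per-illumination power)."""
        s = self.matrix.sum(axis=0, keepdims=True)
        return CrosstalkMatrix(self.matrix / s, self.max_condition)


def default_crosstalk(n: int, leakage: float = 0.10, seed: int | None = None) -> CrosstalkMatrix:
    """Diagonally dominant mixing matrix with ~``leakage`` off-diagonal spill.

    Mimics the overlap of neighbouring color-filter sensitivity curves:
    adjacent channels leak most, distant channels progressively less.
    """
    rng = np.random.default_rng(seed)
    m = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                base = leakage / 2 ** (abs(i - j) - 1)
                jitter = 1.0 + (0.3 * rng.uniform(-1, 1) if seed is not None else 0.0)
                m[i, j] = base * jitter
    return CrosstalkMatrix(m)


@dataclass(frozen=True)
class CfaPattern:
    """Color-filter-array tiling: a small integer array of channel indices."""

    name: str
    tile: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        t = np.asarray(self.tile, dtype=int)
        object.__setattr__(self, "tile", t)
        present = set(np.unique(t).tolist())
        if present != set(range(self.n_channels)):
            raise ValueError(
                f"every channel 0..{self.n_channels - 1} must appear in the tile; got {sorted(present)}"
            )

    @classmethod
    def named(cls, name: str) -> "CfaPattern":
        """Predefined patterns by channel count / convention.

        ``mono`` (1), ``checker2`` (2), ``rggb`` (3: Bayer, channels R=0 G=1
        B=2), ``rgbw`` (4: Truesense-style 4x4 with white, channels
        R=0 G=1 B=2 W=3).
        """
        name = name.lower()
        if name == "mono":
            return cls("mono", np.array([[0]]), 1)
        if name == "checker2":
            return cls("checker2", np.array([[0, 1], [1, 0]]), 2)
        if name == "rggb":
            return cls("rggb", np.array([[0, 1], [1, 2]]), 3)
        if name == "rgbw":
            tile = np.array(
                [
                    [3, 2, 3, 1],
                    [2, 3, 1, 3],
                    [3, 1, 3, 0],
                    [1, 3, 0, 3],
                ]
            )
            return cls("rgbw", tile, 4)
        raise ValueError(f"unknown CFA pattern {name!r}")

    def channel_mask(self, channel: int, shape: tuple[int, int]) -> np.ndarray:
        """Boolean map of the sites belonging to ``channel``."""
        ty, tx = self.tile.shape
        yy, xx = np.indices(shape)
        return self.tile[yy % ty, xx % tx] == channel


@dataclass(frozen=True)
class MosaicFrame:
    """Single-plane raw sensor raster plus its CFA descriptor."""

    data: np.ndarray
    cfa: CfaPattern
    bit_depth: int | None = None  # None = float frame (no quantization)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError("mosaic frame must be 2-D")
        if np.any(d < 0):
            raise ValueError("mosaic counts must be nonnegative")
        if self.bit_depth is not None and np.any(d > 2**self.bit_depth - 1):
            raise ValueError(f"values exceed {self.bit_depth}-bit range")
        object.__setattr__(self, "data", d)


@dataclass(frozen=True)
class HologramSet:
    """Per-wavelength real intensity holograms on a common grid.

    ``tag`` records provenance: ``"true"`` (per-wavelength, demixed),
    ``"mixed"`` (after crosstalk), or ``"channel"`` (demosaiced sensor
    channels).
    """

    images: np.ndarray  # (n, ny, nx)
    wavelengths: tuple[float, ...]
    pitch: float
    tag: str = "true"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        im = np.asarray(self.images, dtype=float)
        if im.ndim != 3:
            raise ValueError("images must be a (n, ny, nx) stack")
        if im.shape[0] != len(self.wavelengths):
            raise ValueError("one image per wavelength required")
        object.__setattr__(self, "images", im)
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


# ---------------------------------------------------------------------------
# scene generators
# ---------------------------------------------------------------------------

def make_usaf_target(
    elements: list[tuple[int, int]],
    pitch: float,
    shape: tuple[int, int],
    bar_transmittance: float = 0.7,
) -> SceneSpec:
    """Three-bar resolution chart with the standard USAF-1951 periods.

    Each requested ``(group, element)`` is drawn as three dark vertical bars
    (bar width = period / 2, bar length = 5 x bar width), laid out on a grid
    left-to-right, coarsest first.  An empty ``elements`` list yields a
    uniform transmittance-1 scene.  Raises if a requested period falls below
    two samples.
    """
    ny, nx = shape
    t = np.ones(shape, dtype=float)
    layout = []
    if not elements:
        return SceneSpec(t, np.zeros(shape), pitch)

    elements = sorted(elements, key=lambda ge: usaf_period(*ge), reverse=True)
    periods = [usaf_period(g, e) for g, e in elements]
    for per in periods:
        if per < 2.0 * pitch:
            raise ValueError(
                f"USAF period {per:.3g} m under-sampled at pitch {pitch:.3g} m"
            )

    margin = max(6, int(0.02 * min(shape)))
    x0, y0 = margin, margin
    row_h = 0
    for (g, e), per in zip(elements, periods):
        w = max(1, int(round(per / 2.0 / pitch)))        # bar width, px
        length = 5 * w                                    # bar length, px
        block_w, block_h = 5 * w, length
        gap = max(3, 2 * w)                               # clearance around the block
        if x0 + block_w + gap > nx:
            x0 = margin
            y0 += row_h + gap
            row_h = 0
        if y0 + block_h + margin > ny:
            raise ValueError("USAF elements do not fit in the requested extent")
        for b in range(3):
            xs = x0 + b * 2 * w
            t[y0 : y0 + length, xs : xs + w] = bar_transmittance
        layout.append(
            {
                "group": g,
                "element": e,
                "period": per,
                "bar_px": w,
                "bbox": (y0, x0, y0 + block_h, x0 + block_w),
                "orientation": "vertical",
            }
        )
        x0 += block_w + gap
        row_h = max(row_h, block_h)
    return SceneSpec(t, np.zeros(shape), pitch, layout=tuple(layout))


def make_bead_phantom(
    n_beads: int,
    diameter: float,
    phase_height: float,
    pitch: float,
    shape: tuple[int, int],
    seed: int | None = None,
    max_tries: int = 2000,
    transmittance_dip: float = 0.0,
) -> SceneSpec:
    """Non-overlapping phase disks (polystyrene-bead stand-in).

    Each disk adds ``phase_height`` radians of retardation; an optional
    ``transmittance_dip`` darkens the disks (scattering loss of real beads).
    Placement is seeded rejection sampling; raises if ``n_beads`` cannot be
    placed without overlap.
    """
    ny, nx = shape
    rng = np.random.default_rng(seed)
    r_px = diameter / 2.0 / pitch
    if 2 * r_px > min(shape):
        raise ValueError("bead does not fit in extent")
    phase = np.zeros(shape, dtype=float)
    trans = np.ones(shape, dtype=float)
    centers: list[tuple[float, float]] = []
    yy, xx = np.indices(shape)
    tries = 0
    while len(centers) < n_beads:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_beads} non-overlapping beads in {max_tries} tries"
            )
        tries += 1
        cy = rng.uniform(r_px + 1, ny - r_px - 1)
        cx = rng.uniform(r_px + 1, nx - r_px - 1)
        if all((cy - oy) ** 2 + (cx - ox) ** 2 >= (2 * r_px) ** 2 for oy, ox in centers):
            centers.append((cy, cx))
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
            phase[disk] += phase_height
            trans[disk] = 1.0 - transmittance_dip
    return SceneSpec(trans, phase, pitch)


# ---------------------------------------------------------------------------
# hologram formation
# ---------------------------------------------------------------------------

def forward_hologram(
    scene: SceneSpec,
    geom: OpticalGeometry,
    wavelength: float,
    pad_factor: int = 2,
    weak_object_rms: float = 0.3,
) -> np.ndarray:
    """In-line Gabor hologram intensity for one wavelength.

    The scene's complex transmittance (unit plane-wave reference times the
    object) is propagated by the plane-wave-equivalent distance
    ``M z + offset(lambda)`` and squared: the reference, object, and the two
    twin interference terms all emerge from ``|U|^2`` with no linearization.
    Warns when the object wave is too strong for the weak-diffraction
    assumption (RMS of ``t e^{i phi} - 1`` above ``weak_object_rms``).
    """
    m = magnification(geom)
    expected = geom.pitch / m
    if not np.isclose(scene.pitch, expected, rtol=1e-6):
        raise ValueError(
            f"scene pitch {scene.pitch:g} m does not match sensor pitch / M = {expected:g} m"
        )
    u0 = scene.complex_transmittance
    obj_rms = float(np.sqrt(np.mean(np.abs(u0 - 1.0) ** 2)))
    if obj_rms > weak_object_rms:
        warnings.warn(
            f"weak-diffraction assumption violated: object-wave RMS {obj_rms:.3g} "
            f"exceeds {weak_object_rms:g} relative to the reference",
            stacklevel=2,
        )
    z_eq = equivalent_plane_wave_distance(geom) + scene.axial_offsets.get(wavelength, 0.0)
    check_fringe_sampling(u0.shape, geom.pitch, wavelength, z_eq)  # hologram fringes
    f = ComplexField(u0, pitch=geom.pitch, wavelength=wavelength, plane="object")
    # background=1: the unit reference extends beyond the simulated window
    u = propagate(f, PropagationSpec(distance=+z_eq, pad_factor=pad_factor), background=1.0)
    return np.abs(u.values) ** 2


def forward_hologram_set(
    scene: SceneSpec,
    geom: OpticalGeometry,
    wavelengths: tuple[float, ...],
    pad_factor: int = 2,
) -> HologramSet:
    """Stack of true per-wavelength holograms (no sensor effects yet)."""
    imgs = np.stack(
        [forward_hologram(scene, geom, w, pad_factor=pad_factor) for w in wavelengths]
    )
    return HologramSet(imgs, tuple(wavelengths), geom.pitch, tag="true")


# ---------------------------------------------------------------------------
# sensor effects
# ---------------------------------------------------------------------------

def apply_crosstalk(true_set: HologramSet, xtalk: CrosstalkMatrix) -> HologramSet:
    """Mix true holograms into channel intensities: ``I_c = L @ I_lambda``."""
    if xtalk.n != true_set.n:
        raise ValueError(
            f"crosstalk matrix is {xtalk.n}x{xtalk.n} but set has {true_set.n} wavelengths"
        )
    mixed = np.einsum("ij,jyx->iyx", xtalk.matrix, true_set.images)
    return HologramSet(mixed, true_set.wavelengths, true_set.pitch, tag="channel")


def mosaic(
    channels: HologramSet,
    cfa: CfaPattern,
    bit_depth: int | None = 12,
    full_scale: float | None = None,
) -> MosaicFrame:
    """Sample each pixel from its CFA-assigned channel; optionally quantize.

    ``full_scale`` maps intensity units to the top quantization code; by
    default 4x the stack mean (headroom above the reference level).
    """
    if cfa.n_channels != channels.n:
        raise ValueError(
            f"CFA has {cfa.n_channels} channels but set has {channels.n}"
        )
    ny, nx = channels.shape
    ty, tx = cfa.tile.shape
    if ny % ty or nx % tx:
        raise ValueError("image shape must be divisible by the CFA tile")
    yy, xx = np.indices((ny, nx))
    idx = cfa.tile[yy % ty, xx % tx]
    raw = channels.images[idx, yy, xx]
    if bit_depth is not None:
        top = 2**bit_depth - 1
        if full_scale is None:
            full_scale = 4.0 * float(channels.images.mean())
        raw = np.clip(np.round(raw / full_scale * top), 0, top)
    return MosaicFrame(raw, cfa, bit_depth)


def add_noise(
    frame: np.ndarray,
    shot: bool = True,
    read_sigma: float = 0.005,
    seed: int | None = None,
    gain: float = 2500.0,
) -> np.ndarray:
    """Poisson shot noise plus Gaussian read noise, in intensity units.

    ``gain`` is the photoelectron count corresponding to unit intensity (the
    reference level), so a unit-intensity pixel has shot SNR ``sqrt(gain)``.
    ``read_sigma`` is in the same intensity units.  Deterministic per seed.
    """
    out = np.asarray(frame, dtype=float)
    rng = np.random.default_rng(seed)
    if shot:
        if np.any(out < 0):
            raise ValueError("shot noise requires nonnegative intensities")
        out = rng.poisson(out * gain).astype(float) / gain
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return out


def vignette_profile(geom: OpticalGeometry, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Radial intensity falloff of the spherical reference (cos^4 law).

    Normalized to 1 on the optical axis (array center).
    """
    ny, nx = shape if shape is not None else (geom.ny, geom.nx)
    y = (np.arange(ny) - (ny - 1) / 2.0) * geom.pitch
    x = (np.arange(nx) - (nx - 1) / 2.0) * geom.pitch
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    cos_t = geom.d / np.sqrt(geom.d**2 + r2)
    return cos_t**4


def apply_vignette(frame: np.ndarray, geom: OpticalGeometry) -> np.ndarray:
    """Multiply a frame by the spherical-reference falloff profile."""
    return np.asarray(frame, dtype=float) * vignette_profile(geom, frame.shape)
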