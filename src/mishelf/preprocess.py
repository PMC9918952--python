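"""Hologram preparation: demosaic, background equalization, crosstalk
demixing, and inter-channel registration.

The stages run in recording order: the raw single-plane mosaic is split into
full-resolution channel images (bilinear fill within each channel), the
spherical-reference background is equalized against a sample-free flat frame,
the spectral crosstalk matrix measured in a calibration step is inverted
pixelwise, and finally per-channel scale/shift mismatches (sources not
perfectly co-located) are estimated on focused reconstructions and applied to
the true holograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp, warp_polar

from .simulate import CrosstalkMatrix, HologramSet, MosaicFrame

__all__ = [
    "RegistrationParams",
    "CalibrationBundle",
    "demosaic",
    "equalize_background",
    "calibrate_crosstalk",
    "remove_crosstalk",
    "register_channels",
    "apply_registration",
]


@dataclass(frozen=True)
class RegistrationParams:
    """Per-channel similarity correction relative to a reference channel.

    ``scales[i]`` is the magnification of channel ``i`` relative to the
    reference (1 for the reference); ``shifts[i]`` its (row, col) displacement
    in pixels (sub-pixel).  ``apply_registration`` resamples each channel by
    ``1/scale`` about the array center and translates by ``-shift``.
    """

    scales: np.ndarray
    shifts: np.ndarray
    reference_index: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=float)
        sh = np.asarray(self.shifts, dtype=float).reshape(len(s), 2)
        if np.any(s <= 0):
            raise ValueError("scales must be positive")
        object.__setattr__(self, "scales", s)
        object.__setattr__(self, "shifts", sh)

    @classmethod
    def identity(cls, n: int, reference_index: int = 0) -> "RegistrationParams":
        return cls(np.ones(n), np.zeros((n, 2)), reference_index)


@dataclass(frozen=True)
class CalibrationBundle:
    """Everything measured once per instrument: flat frame, crosstalk, registration."""

    flat: np.ndarray | None = None
    crosstalk: CrosstalkMatrix | None = None
    registration: RegistrationParams | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# demosaicing
# ---------------------------------------------------------------------------

def _fill_kernel(radius: int) -> np.ndarray:
    """Separable triangle kernel reproducing bilinear interpolation."""
    t = 1.0 - np.abs(np.arange(-radius, radius + 1)) / (radius + 1.0)
    return np.outer(t, t)


def demosaic(frame: MosaicFrame) -> HologramSet | np.ndarray:
    """Split a mosaic into n full-resolution channel images.

    CFA sample sites keep their raw values exactly; the gaps are filled by
    normalized (mask-weighted) triangular convolution within each channel,
    which reduces to classic bilinear interpolation on Bayer-type patterns
    and reproduces affine intensity ramps exactly away from the borders.

    Returns a plain (n, ny, nx) array; pair it with wavelengths via
    :class:`~mishelf.simulate.HologramSet` when they are known.
    """
    data = np.asarray(frame.data, dtype=float)
    cfa = frame.cfa
    ny, nx = data.shape
    radius = int(max(cfa.tile.shape))  # covers the largest within-channel gap
    kern = _fill_kernel(radius)
    out = np.empty((cfa.n_channels, ny, nx), dtype=float)
    for ch in range(cfa.n_channels):
        mask = cfa.channel_mask(ch, (ny, nx)).astype(float)
        num = ndimage.convolve(data * mask, kern, mode="constant", cval=0.0)
        den = ndimage.convolve(mask, kern, mode="constant", cval=0.0)
        if np.any(den == 0):
            raise ValueError(f"CFA pattern {cfa.name!r} leaves channel {ch} gaps unfillable")
        ch_img = num / den
        ch_img[mask.astype(bool)] = data[mask.astype(bool)]
        out[ch] = ch_img
    return out


# ---------------------------------------------------------------------------
# background equalization
# ---------------------------------------------------------------------------

def equalize_background(
    channel_set: HologramSet,
    flat: np.ndarray,
    mode: str = "subtract",
) -> HologramSet:
    """Remove the spherical-reference background using a sample-free flat.

    ``flat`` is either one 2-D frame shared by all channels or an (n, ny, nx)
    per-channel stack.

    * ``"subtract"`` (default, the measured background term is subtracted):
      ``out = I - flat + mean(flat)``, so an object-free recording becomes a
      uniform background at the flat's mean level.
    * ``"ratio"``: ``out = I * max(flat) / flat`` — exactly inverts a
      multiplicative vignette profile.  Nonpositive flat pixels are masked
      (left unchanged) with a warning.
    """
    imgs = channel_set.images
    flat = np.asarray(flat, dtype=float)
    if flat.ndim == 2:
        flat = np.broadcast_to(flat, imgs.shape)
    if flat.shape != imgs.shape:
        raise ValueError("flat shape does not match hologram set")

    if mode == "subtract":
        ref = flat.mean(axis=(-2, -1), keepdims=True)
        out = imgs - flat + ref
    elif mode == "ratio":
        bad = flat <= 0
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} nonpositive flat pixels masked during ratiometric "
                "equalization",
                stacklevel=2,
            )
        safe = np.where(bad, 1.0, flat)
        ref = flat.max(axis=(-2, -1), keepdims=True)
        out = np.where(bad, imgs, imgs * ref / safe)
    else:
        raise ValueError(f"mode must be 'subtract' or 'ratio', got {mode!r}")
    return replace(channel_set, images=out)


# ---------------------------------------------------------------------------
# crosstalk
# ---------------------------------------------------------------------------

def calibrate_crosstalk(
    single_illum_frames: np.ndarray,
    max_condition: float = 1.0e3,
) -> CrosstalkMatrix:
    """Measure the mixing matrix from sequential single-illumination captures.

    ``single_illum_frames[j]`` holds the n demosaiced channel images recorded
    with only illumination ``j`` switched on (shape (n, n, ny, nx), ordered
    [illumination, channel, y, x]).  ``L[i, j]`` is the mean intensity of
    channel ``i`` under illumination ``j``; columns are normalized to unit
    sum, which removes the per-illumination source power (and makes the
    result invariant to a global exposure rescaling).
    """
    frames = np.asarray(single_illum_frames, dtype=float)
    if frames.ndim != 4 or frames.shape[0] != frames.shape[1]:
        raise ValueError(
            "expected (n_illuminations, n_channels, ny, nx) with matching n, "
            f"got shape {frames.shape}"
        )
    raw = frames.mean(axis=(-2, -1)).T  # [channel, illumination]
    out = CrosstalkMatrix(raw, max_condition=max_condition)
    out.check_invertible()
    return out.column_normalized()


def remove_crosstalk(channel_set: HologramSet, xtalk: CrosstalkMatrix) -> HologramSet:
    """Demix channel intensities into true per-wavelength holograms (L^-1).

    Negative residuals (noise pushed below zero by the inversion) are clipped
    to 0; the clipped-pixel fraction is recorded in ``meta['clipped_fraction']``
    and warned about above 1%.
    """
    if xtalk.n != channel_set.n:
        raise ValueError(
            f"crosstalk matrix is {xtalk.n}x{xtalk.n} but set has {channel_set.n} channels"
        )
    demixed = np.einsum("ij,jyx->iyx", xtalk.inverse, channel_set.images)
    clipped = float(np.mean(demixed < 0))
    if clipped > 0.01:
        warnings.warn(
            f"{clipped:.1%} of pixels fell below zero after crosstalk removal; "
            "check calibration",
            stacklevel=2,
        )
    demixed = np.clip(demixed, 0.0, None)
    meta = dict(channel_set.meta, clipped_fraction=clipped)
    return HologramSet(
        demixed, channel_set.wavelengths, channel_set.pitch, tag="true", meta=meta
    )


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _coarse_scale(ref: np.ndarray, img: np.ndarray) -> float:
    """Relative isotropic scale via log-polar correlation of |FFT| magnitudes.

    A target magnified by ``s`` has its spectrum shrunk by ``s``, which in
    log-polar coordinates is a pure shift along the log-radius axis.
    """
    win = _hann2d(ref.shape)
    fr = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2((ref - ref.mean()) * win))))
    fi = np.log1p(np.abs(np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))))
    radius = min(ref.shape) // 4
    n_rad = 4 * min(ref.shape)
    wr = warp_polar(fr, radius=radius, scaling="log", output_shape=(360, n_rad))
    wi = warp_polar(fi, radius=radius, scaling="log", output_shape=(360, n_rad))
    pw = _hann2d(wr.shape)  # edges of the polar map otherwise dominate
    shift, _, _ = phase_cross_correlation(
        (wr - wr.mean()) * pw, (wi - wi.mean()) * pw,
        upsample_factor=20, normalization=None,
    )
    klog = n_rad / np.log(radius)
    return float(np.exp(shift[1] / klog))


def _estimate_shift(ref: np.ndarray, img: np.ndarray, upsample: int) -> tuple[np.ndarray, float]:
    win = _hann2d(ref.shape)
    shift, error, _ = phase_cross_correlation(
        (ref - ref.mean()) * win, (img - img.mean()) * win,
        upsample_factor=upsample, normalization=None,
    )
    # returned shift registers img onto ref, i.e. minus the displacement
    return -shift, 1.0 - float(error)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = float(np.linalg.norm(a)) * float(np.linalg.norm(b))
    return float(np.sum(a * b)) / denom if denom > 0 else 0.0


def register_channels(
    focused_images: np.ndarray,
    reference_index: int = 0,
    upsample_factor: int = 100,
    min_confidence: float = 0.03,
    estimate_scale: bool = True,
    scale_halfwidth: float = 0.05,
) -> RegistrationParams:
    """Estimate per-channel scale and sub-pixel shift against a reference.

    A coarse scale comes from log-polar correlation of the Fourier
    magnitudes; the sub-pixel shift from windowed phase correlation; both are
    then refined by maximizing the normalized cross-correlation of the
    resampled channel against the reference.  The reference channel (by
    convention the shortest wavelength, which sets the system resolution)
    gets scale 1 and shift (0, 0).  Raises when the correlation peak is too
    weak for a confident estimate.
    """
    from scipy.optimize import minimize_scalar

    imgs = np.asarray(focused_images, dtype=float)
    n = imgs.shape[0]
    scales = np.ones(n)
    shifts = np.zeros((n, 2))
    ref = imgs[reference_index]
    win = _hann2d(ref.shape)
    b = max(8, min(ref.shape) // 16)
    inner = np.s_[b:-b, b:-b]
    for i in range(n):
        if i == reference_index:
            continue
        s = _coarse_scale(ref, imgs[i]) if estimate_scale else 1.0
        shift = np.zeros(2)
        confidence = 1.0
        for _ in range(2):
            corrected = (
                _resample(imgs[i], s, tuple(shift))
                if (abs(s - 1) > 1e-9 or np.any(shift != 0))
                else imgs[i]
            )
            d, confidence = _estimate_shift(ref, corrected, upsample_factor)
            shift = shift + d * s  # displacement measured post-resampling
            if not estimate_scale:
                continue

            def cost(sc: float) -> float:
                return -_ncc(
                    (ref * win)[inner], (_resample(imgs[i], sc, tuple(shift)) * win)[inner]
                )

            res = minimize_scalar(
                cost,
                bounds=(s - scale_halfwidth, s + scale_halfwidth),
                method="bounded",
                options={"xatol": 1e-5},
            )
            s = float(res.x)
        if not np.isfinite(confidence) or confidence < min_confidence:
            raise ValueError(
                f"registration of channel {i} failed: correlation confidence "
                f"{confidence:.3g} below {min_confidence:g}"
            )
        scales[i] = s
        shifts[i] = shift
    return RegistrationParams(scales, shifts, reference_index)


def _resample(img: np.ndarray, scale: float, shift: tuple[float, float]) -> np.ndarray:
    """Undo a similarity (scale about center, then shift) with bicubic warp."""
    cy, cx = (np.asarray(img.shape) - 1) / 2.0
    # map output coords -> input coords: scale about center then translate
    tform = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(scale=(scale, scale))
        + AffineTransform(translation=(cx + shift[1], cy + shift[0]))
    )
    return warp(img, tform, order=3, mode="edge", preserve_range=True)


def apply_registration(channel_set: HologramSet, params: RegistrationParams) -> HologramSet:
    """Resample each hologram with the stored similarity correction.

    Channels with exactly identity parameters are passed through untouched
    (bit-identical); others are bicubically warped.
    """
    imgs = channel_set.images
    if len(params.scales) != channel_set.n:
        raise ValueError("registration parameters do not match channel count")
    out = np.empty_like(imgs)
    for i in range(channel_set.n):
        s, (dy, dx) = params.scales[i], params.shifts[i]
        if s == 1.0 and dy == 0.0 and dx == 0.0:
            out[i] = imgs[i]
            continue
        if abs(s - 1.0) * max(imgs[i].shape) / 2 > min(imgs[i].shape) * 0.1:
            warnings.warn(
                f"channel {i}: scale {s:g} pushes content far off-grid", stacklevel=2
            )
        out[i] = _resample(imgs[i], s, (dy, dx))
    return replace(channel_set, images=out)
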