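"""Iterative multi-wavelength phase retrieval with spectral merging.

The reconstruction takes the n true per-wavelength in-line holograms from a
single exposure and suppresses the twin image by exploiting the wavelength
dependence of defocus:

1. amplitudes ``A0_i = sqrt(I_i)`` at the hologram plane (phase zero);
2. back-propagation of each amplitude by its focus distance ``-z_i``;
3. alignment of the global background phases (so the spectra add rather than
   cancel);
4. frequency-domain merge ``O~ = IFFT( sum_i w_i FFT(O_i) )`` with weight
   masks normalized by passband coverage — frequencies seen by several
   wavelengths are averaged, not summed, so low spatial frequencies are not
   over-weighted;
5. per cycle: split the merged field into n copies, restore each channel's
   background phase, forward-propagate ``+z_i``, replace the amplitude with
   the measured ``A0_i`` while keeping the retrieved phase, back-propagate,
   re-align, re-merge.

The focused object image is reinforced identically by every channel while
each channel's twin is defocused differently, so a couple of cycles
(``m = 2`` by default) are enough for the twins to wash out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticalGeometry, magnification, numerical_aperture
from .propagation import ComplexField, PropagationSpec, equivalent_plane_wave_distance, propagate
from .simulate import HologramSet

__all__ = [
    "RetrievalConfig",
    "ReconstructionResult",
    "amplitudes_from_holograms",
    "autofocus",
    "tamura",
    "align_background_phase",
    "scattered_tamura",
    "background_phase",
    "build_weight_masks",
    "merge_spectra",
    "mishelf_iterate",
    "hologram_residual",
    "effective_na",
    "hologram_plane_field",
]


def effective_na(geom: OpticalGeometry) -> float:
    """Collection NA expressed in the plane-wave-equivalent working frame.

    Fields are handled at sensor pitch over the equivalent distance ``M z``,
    where the magnified aperture cone shrinks by ``M``; the frequency cutoff
    used by the weight masks is therefore ``(NA / M) / lambda``.
    """
    return numerical_aperture(geom) / magnification(geom)


@dataclass(frozen=True)
class RetrievalConfig:
    """Knobs of the iterative reconstruction.

    ``m`` — iteration cycles after the initial merge (default 2, the typical
    number needed for convergence).  ``distances`` — per-wavelength focus
    distances in the working frame (positive, meters); if None they are found
    by autofocus over ``autofocus_range``.  ``na`` — aperture cutoff for the
    weight masks in the working frame (see :func:`effective_na`).
    ``mask_softness`` — raised-cosine edge width as a fraction of each
    cutoff (0 = hard masks).  ``support_mask`` — optional object-plane
    boolean support; outside it the amplitude is reset to the background
    level each cycle.
    """

    m: int = 2
    distances: tuple[float, ...] | None = None
    autofocus_range: tuple[float, float] | None = None
    autofocus_steps: int = 21
    na: float | None = None
    mask_softness: float = 0.0
    support_mask: np.ndarray | None = None
    pad_factor: int = 2
    align_phases: bool = True

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("iteration count m must be >= 0")
        if self.distances is not None and any(d <= 0 for d in self.distances):
            raise ValueError("focus distances must be positive")

    @classmethod
    def for_geometry(cls, geom: OpticalGeometry, scene_offsets: dict | None = None,
                     wavelengths: tuple[float, ...] = (), **kw) -> "RetrievalConfig":
        """Distances and mask NA derived from a known recording geometry."""
        z_eq = equivalent_plane_wave_distance(geom)
        offs = scene_offsets or {}
        distances = tuple(z_eq + offs.get(w, 0.0) for w in wavelengths) or None
        return cls(distances=distances, na=effective_na(geom), **kw)


@dataclass
class ReconstructionResult:
    """Final merged object field plus per-channel diagnostics."""

    merged: ComplexField
    per_wavelength: list[ComplexField]
    distances: tuple[float, ...]
    background_phases: np.ndarray
    residuals: np.ndarray        # (m+1, n) hologram-plane RMS data misfit
    wavelengths: tuple[float, ...]
    converged: bool = True

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.merged.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.merged.values)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def amplitudes_from_holograms(true_set: HologramSet) -> list[ComplexField]:
    """Square-root amplitudes at the hologram plane, zero phase."""
    if np.any(true_set.images < 0):
        raise ValueError("hologram intensities must be nonnegative (clip upstream)")
    return [
        ComplexField(
            np.sqrt(true_set.images[i]).astype(np.complex128),
            pitch=true_set.pitch,
            wavelength=true_set.wavelengths[i],
            plane="hologram",
        )
        for i in range(true_set.n)
    ]


def tamura(amplitude: np.ndarray) -> float:
    """Tamura sharpness coefficient ``sqrt(std / mean)`` of an intensity map."""
    a = np.abs(amplitude) ** 2
    mu = float(a.mean())
    if mu <= 0:
        return 0.0
    return float(np.sqrt(a.std() / mu))


def scattered_tamura(field_values: np.ndarray) -> float:
    """Tamura coefficient of the scattered-field intensity ``|U - bg|^2``.

    The background pedestal (median of the complex field) is removed first,
    so the statistic measures how concentrated the light scattered by the
    object is.  Unitary propagation conserves the scattered energy while
    focusing concentrates it, so this peaks at the focus plane for amplitude
    *and* phase objects — plain amplitude contrast is minimized at focus for
    a pure phase object and would lead autofocus astray.
    """
    v = np.asarray(field_values)
    bg = complex(np.median(v.real) + 1j * np.median(v.imag))
    return tamura(np.abs(v - bg))


def autofocus(
    field: ComplexField,
    z_range: tuple[float, float],
    steps: int = 21,
    metric=scattered_tamura,
    pad_factor: int = 2,
):
    """Scan reconstruction distances and refine the sharpest one.

    Back-propagates the hologram-plane field by each candidate distance,
    scores the result with ``metric`` (Tamura coefficient of the scattered
    intensity by default) and refines the discrete peak with a parabolic
    fit.  Raises when no interior maximum exists (metric monotone over the
    range or flat, e.g. for a pure plane wave).

    Returns ``(z_best, zs, values)``.
    """
    zs = np.linspace(z_range[0], z_range[1], steps)
    vals = np.empty(steps)
    for i, z in enumerate(zs):
        rec = propagate(field, PropagationSpec(distance=-z, pad_factor=pad_factor),
                        background="edge")
        vals[i] = metric(rec.values)
    spread = vals.max() - vals.min()
    if spread <= 1e-9 * max(abs(vals).max(), 1e-30):
        raise ValueError("focus not bracketed: sharpness metric is flat over the scan")
    k = int(np.argmax(vals))
    if k == 0 or k == steps - 1:
        raise ValueError("focus not bracketed: sharpness peaks at the scan boundary")
    # parabolic sub-step refinement on the three points around the peak
    y0, y1, y2 = vals[k - 1 : k + 2]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    z_best = zs[k] + delta * (zs[1] - zs[0])
    return float(z_best), zs, vals


def background_phase(field: ComplexField, low_gradient_quantile: float = 0.5) -> float:
    """Global background phase: circular median over low-gradient pixels.

    The background is where the amplitude is smooth (object-free); pixels
    whose amplitude-gradient magnitude falls below the given quantile form
    the mask (whole field as fallback).
    """
    amp = np.abs(field.values)
    gy, gx = np.gradient(amp)
    g = np.hypot(gy, gx)
    thresh = np.quantile(g, low_gradient_quantile)
    mask = g <= thresh
    if not np.any(mask):
        mask = np.ones_like(g, dtype=bool)
    ph = np.angle(field.values[mask])
    # circular median: recenter around the mean direction, then take the
    # ordinary median of the wrapped residuals
    mean_dir = np.angle(np.mean(np.exp(1j * ph)))
    resid = np.angle(np.exp(1j * (ph - mean_dir)))
    return float(mean_dir + np.median(resid))


def align_background_phase(
    fields: list[ComplexField], mode: str = "lowgrad"
) -> tuple[list[ComplexField], np.ndarray]:
    """Rotate each field by a unit complex constant so its background phase is 0.

    Returns the aligned fields and the removed phases (to be restored before
    forward propagation).  The amplitude is untouched exactly.
    """
    q = 0.5 if mode == "lowgrad" else 1.0
    phases = np.array([background_phase(f, q) for f in fields])
    aligned = [
        ComplexField(f.values * np.exp(-1j * p), f.pitch, f.wavelength, f.plane)
        for f, p in zip(fields, phases)
    ]
    return aligned, phases


def build_weight_masks(
    wavelengths: tuple[float, ...],
    na: float,
    shape: tuple[int, int],
    pitch: float,
    softness: float = 0.0,
) -> np.ndarray:
    """Frequency-domain merge weights, one map per wavelength.

    Each wavelength contributes a passband ``|f| <= na / lambda``; at every
    frequency the weight is the passband indicator divided by the number of
    wavelengths whose passband covers that frequency.  The weights therefore
    sum to 1 over the union of passbands and 0 outside — information present
    in several channels is averaged instead of accumulated, which prevents
    low-spatial-frequency enhancement.  ``softness`` > 0 replaces the hard
    edge with a raised cosine over that fraction of each cutoff.

    Returned in unshifted (fftfreq) layout, shape (n, ny, nx).
    """
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    bands = np.empty((len(wavelengths),) + shape)
    for i, lam in enumerate(wavelengths):
        fc = na / lam
        if softness > 0:
            w = softness * fc
            lo, hi = fc - w / 2, fc + w / 2
            band = np.where(
                fr <= lo,
                1.0,
                np.where(fr >= hi, 0.0, 0.5 * (1 + np.cos(np.pi * (fr - lo) / (hi - lo)))),
            )
        else:
            band = (fr <= fc).astype(float)
        bands[i] = band
    coverage = bands.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        masks = np.where(coverage > 0, bands / np.where(coverage > 0, coverage, 1.0), 0.0)
    return masks


def merge_spectra(fields: list[ComplexField], masks: np.ndarray) -> ComplexField:
    """Weighted spectral fusion: ``IFFT( sum_i mask_i * FFT(O_i) )``."""
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise ValueError("fields must share a common shape")
    if masks.shape[0] != len(fields) or masks.shape[1:] != fields[0].shape:
        raise ValueError("masks do not match the field stack")
    acc = np.zeros(fields[0].shape, dtype=np.complex128)
    for f, m in zip(fields, masks):
        acc += m * np.fft.fft2(f.values)
    ref = min(fields, key=lambda f: f.wavelength)
    return ComplexField(np.fft.ifft2(acc), ref.pitch, ref.wavelength, plane="object")


# ---------------------------------------------------------------------------
# the iteration
# ---------------------------------------------------------------------------

def _data_misfit(hologram_fields: list[ComplexField], amplitudes: list[ComplexField]) -> np.ndarray:
    return np.array(
        [
            float(np.sqrt(np.mean((np.abs(b.values) - np.abs(a.values)) ** 2)))
            for b, a in zip(hologram_fields, amplitudes)
        ]
    )


def mishelf_iterate(true_set: HologramSet, config: RetrievalConfig) -> ReconstructionResult:
    """Run the full merged-spectrum iterative reconstruction.

    See the module docstring for the cycle structure.  The residual log holds
    ``m + 1`` rows of per-wavelength hologram-plane RMS misfits: the entry for
    the initial single-pass merge, then one per cycle.  If the aggregate
    residual grows for two consecutive cycles a divergence warning is raised
    and the best iterate is returned instead of the last.
    """
    n = true_set.n
    a0 = amplitudes_from_holograms(true_set)

    if config.distances is not None:
        if len(config.distances) != n:
            raise ValueError("one focus distance per wavelength required")
        distances = tuple(config.distances)
    else:
        if config.autofocus_range is None:
            raise ValueError("provide focus distances or an autofocus range")
        distances = tuple(
            autofocus(a, config.autofocus_range, config.autofocus_steps,
                      pad_factor=config.pad_factor)[0]
            for a in a0
        )

    def back(fields: list[ComplexField]) -> list[ComplexField]:
        return [
            propagate(f, PropagationSpec(-z, pad_factor=config.pad_factor),
                      background="edge")
            for f, z in zip(fields, distances)
        ]

    def fwd(fields: list[ComplexField]) -> list[ComplexField]:
        return [
            propagate(f, PropagationSpec(+z, pad_factor=config.pad_factor),
                      background="edge")
            for f, z in zip(fields, distances)
        ]

    na = config.na
    if na is None:
        raise ValueError("config.na (working-frame aperture) is required for the masks")
    masks = build_weight_masks(
        true_set.wavelengths, na, true_set.shape, true_set.pitch, config.mask_softness
    )

    def merge_pass(obj_fields: list[ComplexField]):
        if config.align_phases:
            aligned, phases = align_background_phase(obj_fields)
        else:
            aligned, phases = obj_fields, np.zeros(n)
        merged = merge_spectra(aligned, masks)
        if config.support_mask is not None:
            v = merged.values.copy()
            bg = np.median(np.abs(v[~config.support_mask])) if np.any(~config.support_mask) else 1.0
            outside = ~config.support_mask
            v[outside] = bg * np.exp(1j * np.angle(v[outside]))
            merged = ComplexField(v, merged.pitch, merged.wavelength, merged.plane)
        return merged, phases

    # initial pass: sqrt(I) -> back-propagate -> align -> merge
    obj = back(a0)
    merged, phases = merge_pass(obj)

    def residual_of(merged_field: ComplexField, bg_phases: np.ndarray) -> np.ndarray:
        split = [
            ComplexField(merged_field.values * np.exp(1j * p), true_set.pitch, w, "object")
            for p, w in zip(bg_phases, true_set.wavelengths)
        ]
        return _data_misfit(fwd(split), a0)

    residuals = [residual_of(merged, phases)]
    best = (merged, phases, float(residuals[0].mean()))
    grow_streak = 0
    converged = True

    for _ in range(config.m):
        split = [
            ComplexField(merged.values * np.exp(1j * p), true_set.pitch, w, "object")
            for p, w in zip(phases, true_set.wavelengths)
        ]
        holo = fwd(split)
        # amplitude replacement: keep retrieved phase, impose measured modulus
        constrained = [
            ComplexField(
                np.abs(a.values) * np.exp(1j * np.angle(b.values)),
                true_set.pitch,
                b.wavelength,
                "hologram",
            )
            for b, a in zip(holo, a0)
        ]
        obj = back(constrained)
        merged, phases = merge_pass(obj)
        residuals.append(residual_of(merged, phases))

        agg = float(residuals[-1].mean())
        if agg < best[2]:
            best = (merged, phases, agg)
            grow_streak = 0
        else:
            grow_streak += 1
            if grow_streak >= 2:
                warnings.warn(
                    "retrieval residual grew for two consecutive cycles; "
                    "returning the best iterate",
                    stacklevel=2,
                )
                merged, phases, _ = best
                converged = False
                break

    per_wavelength = [
        ComplexField(merged.values * np.exp(1j * p), true_set.pitch, w, "object")
        for p, w in zip(phases, true_set.wavelengths)
    ]
    res = np.vstack(residuals)
    if res.shape[0] < config.m + 1:  # early stop: pad the log with the last row
        res = np.vstack([res] + [res[-1:]] * (config.m + 1 - res.shape[0]))
    return ReconstructionResult(
        merged=merged,
        per_wavelength=per_wavelength,
        distances=distances,
        background_phases=phases,
        residuals=res[: config.m + 1],
        wavelengths=true_set.wavelengths,
        converged=converged,
    )


def hologram_residual(result: ReconstructionResult, true_set: HologramSet,
                      pad_factor: int = 2) -> np.ndarray:
    """Per-wavelength RMS of ``|forward-propagated field| - sqrt(I)``."""
    a0 = amplitudes_from_holograms(true_set)
    holo = [
        propagate(f, PropagationSpec(+z, pad_factor=pad_factor), background="edge")
        for f, z in zip(result.per_wavelength, result.distances)
    ]
    return _data_misfit(holo, a0)


def hologram_plane_field(result: ReconstructionResult, index: int | None = None,
                         pad_factor: int = 2) -> ComplexField:
    """Forward-propagate the reconstruction back to the hologram plane.

    Used e.g. by the twin-plane diagnostics; ``index`` defaults to the
    shortest wavelength (the resolution reference).
    """
    if index is None:
        index = int(np.argmin(result.wavelengths))
    f = result.per_wavelength[index]
    return propagate(f, PropagationSpec(+result.distances[index], pad_factor=pad_factor),
                     background="edge")
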