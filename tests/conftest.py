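"""Shared fixtures: a scaled-down lensless geometry with NA ~ 0.21 and the
matched multi-wavelength hologram sets the retrieval tests reuse.

The study geometry keeps the magnification (20x) and numerical aperture
(~0.2) of a typical point-source lensless microscope while shrinking the
sensor to 512^2 pixels so the whole suite runs in minutes: d = 2.5 mm,
z = 2.375 mm, 2 um pitch.  Wavelengths follow the four-channel instrument:
violet 405, blue 450, green 520, red 630 nm; per-wavelength focus offsets
model the chromatic focal shift of a 1 mm glass slide (Cauchy dispersion),
scaled by the longitudinal magnification M^2.
"""

import pytest

from mishelf.optics import OpticalGeometry
from mishelf.propagation import equivalent_plane_wave_distance
from mishelf.retrieve import RetrievalConfig, effective_na, mishelf_iterate
from mishelf.simulate import HologramSet, SceneSpec, forward_hologram_set, make_usaf_target

WL = {"V": 405e-9, "B": 450e-9, "G": 520e-9, "R": 630e-9}
WL4 = (WL["V"], WL["B"], WL["G"], WL["R"])
WL3 = (WL["V"], WL["G"], WL["R"])  # the three-channel instrument

USAF_ELEMENTS = [(7, 1), (8, 1), (8, 6), (9, 1), (9, 2), (9, 3)]


def slide_dispersion_offsets(geom: OpticalGeometry, slide_thickness: float = 1e-3):
    """Per-wavelength focus offsets of a BK7-like slide, in the working frame."""
    a, b = 1.5046, 4200e-18  # Cauchy n(lambda) = a + b / lambda^2
    m = geom.d / (geom.d - geom.z)
    n = {w: a + b / w**2 for w in WL4}
    n_ref = n[min(WL4)]
    return {w: slide_thickness * (n_ref - n[w]) / 2.3 * m**2 for w in WL4}


@pytest.fixture(scope="session")
def geom512():
    return OpticalGeometry(d=2.5e-3, z=2.375e-3, pitch=2e-6, nx=512, ny=512)


@pytest.fixture(scope="session")
def geom256():
    return OpticalGeometry(d=2.5e-3, z=2.375e-3, pitch=2e-6, nx=256, ny=256)


@pytest.fixture(scope="session")
def usaf512(geom512):
    """USAF chart bracketing the violet diffraction limit, with slide dispersion."""
    obj_pitch = geom512.pitch * (geom512.d - geom512.z) / geom512.d
    scene = make_usaf_target(USAF_ELEMENTS, obj_pitch, (512, 512))
    return SceneSpec(
        scene.transmittance,
        scene.phase,
        scene.pitch,
        axial_offsets=slide_dispersion_offsets(geom512),
        layout=scene.layout,
    )


@pytest.fixture(scope="session")
def holo4_512(usaf512, geom512):
    """Noiseless true holograms for all four wavelengths (matched fixture)."""
    return forward_hologram_set(usaf512, geom512, WL4)


def channel_subset(holo4: HologramSet, wavelengths) -> HologramSet:
    idx = [holo4.wavelengths.index(w) for w in wavelengths]
    return HologramSet(holo4.images[idx], tuple(wavelengths), holo4.pitch)


def reconstruct(holo: HologramSet, geom, offsets, m=2, **kw) -> "mishelf_iterate":
    z_eq = equivalent_plane_wave_distance(geom)
    cfg = RetrievalConfig(
        m=m,
        distances=tuple(z_eq + offsets.get(w, 0.0) for w in holo.wavelengths),
        na=effective_na(geom),
        **kw,
    )
    return mishelf_iterate(holo, cfg)


@pytest.fixture(scope="session")
def recon3_m2(holo4_512, geom512, usaf512):
    """Three-wavelength (V-G-R) reconstruction, two cycles."""
    return reconstruct(
        channel_subset(holo4_512, WL3), geom512, usaf512.axial_offsets, m=2
    )


@pytest.fixture(scope="session")
def recon1_m2(holo4_512, geom512, usaf512):
    """Matched single-wavelength (violet) run, same iteration count."""
    return reconstruct(
        channel_subset(holo4_512, (WL["V"],)), geom512, usaf512.axial_offsets, m=2
    )


@pytest.fixture(scope="session")
def background_mask(usaf512):
    from scipy import ndimage

    object_free = usaf512.transmittance >= 1.0 - 1e-9
    return ndimage.binary_erosion(object_free, iterations=8)
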