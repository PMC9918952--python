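# mishelf

Multi-illumination single-exposure lensless Fresnel holographic microscopy:
a toolkit for simulating, preprocessing and reconstructing wavelength-
multiplexed in-line Gabor holograms recorded on a color sensor.

## The problem

A digital lensless holographic microscope (DLHM) replaces every lens with
geometry: a coherent point source illuminates a weakly diffracting sample at
distance `d − z` and a digital sensor at distance `z` records the magnified
in-line interference pattern.  The optics reduce to four closed forms,

    M   = d / (d − z)                    geometric magnification
    FOV = Nx·Ny·p² / M²                  imaged field of view
    NA  = sin(atan(N·p / 2z))            collection aperture
    ρ   = k·λ / NA,  k ≈ 1               diffraction-limited resolution

but the recorded hologram carries the classic in-line defect: the **twin
image**, a conjugate reconstruction whose defocused copy overlays the
focused one.  Illuminating with n wavelengths simultaneously and recording
them in a single snapshot of a color (Bayer / RGBW) sensor breaks the
degeneracy: each wavelength defocuses its twin differently, so a fast
iterative algorithm — back-propagate the n measured amplitudes `√I_λ`,
align their background phases, fuse their spectra with coverage-normalized
weight masks, and re-impose the measured moduli at the hologram plane for a
couple of cycles — converges to a twin-suppressed complex amplitude without
sacrificing the single-shot acquisition or the resolution of the shortest
wavelength.

The package covers the full chain for synthetic studies: a seeded forward
model (USAF-style bar targets and bead phantoms, exact nonlinear hologram
formation, spectral crosstalk mixing, CFA mosaicing, vignetting, shot/read
noise), the preprocessing block (demosaic, background equalization,
crosstalk calibration and inversion, sub-pixel channel registration), the
iterative retrieval, and quantitative quality metrics (background STD, bar
contrast, finest resolved element, twin-plane ratio).

## Worked example

```python
import numpy as np
from mishelf.optics import OpticalGeometry, derive_optics
from mishelf.propagation import equivalent_plane_wave_distance
from mishelf.simulate import forward_hologram_set, make_usaf_target
from mishelf.retrieve import (RetrievalConfig, effective_na,
                              hologram_plane_field, mishelf_iterate)
from mishelf.metrics import finest_resolved, twin_plane_ratio

geom = OpticalGeometry(d=2.5e-3, z=2.375e-3, pitch=2e-6, nx=512, ny=512)
wavelengths = (405e-9, 520e-9, 630e-9)
opt = derive_optics(geom, wavelengths)
print(f"M = {opt.magnification:.1f}x, NA = {opt.na:.3f}, "
      f"rho(405 nm) = {opt.rho[405e-9]*1e6:.2f} um")

scene = make_usaf_target([(7, 1), (8, 1), (8, 6), (9, 1), (9, 2)],
                         pitch=geom.pitch / opt.magnification,
                         shape=(512, 512))
holos = forward_hologram_set(scene, geom, wavelengths)

z_eq = equivalent_plane_wave_distance(geom)
config = RetrievalConfig(m=2, distances=(z_eq,) * 3, na=effective_na(geom))
result = mishelf_iterate(holos, config)

print(f"data misfit per cycle: {result.residuals.mean(axis=1).round(4)}")
q = finest_resolved(result.amplitude, scene.layout)
print(f"finest resolved element: group {q.finest_element[0]} element "
      f"{q.finest_element[1]} ({q.finest_period*1e6:.2f} um)")
ratio = twin_plane_ratio(hologram_plane_field(result), result.distances[0],
                         template=scene.transmittance)
print(f"twin-plane ratio: {ratio:.2f}")
```

prints

```
M = 20.0x, NA = 0.211, rho(405 nm) = 1.92 um
data misfit per cycle: [0.0252 0.0204 0.0189]
finest resolved element: group 9 element 1 (1.95 um)
twin-plane ratio: 0.23
```

Reading the numbers: the 20x projection geometry collects NA 0.21, so the
violet channel's diffraction limit is 1.92 µm; the hologram-plane data
misfit falls monotonically over the two iteration cycles; the finest chart
element with period above the diffraction limit (group 9 element 1,
1.95 µm) is resolved while finer ones are not; and the structure refocusing
at the conjugate twin plane retains only 23 % of the correlation it would
have without suppression (a raw single-wavelength reconstruction scores
exactly 1.00 by conjugate symmetry).

## Command line

The same workflow runs from a shell, one directory per stage:

```
mishelf simulate    --config run.yaml --scene usaf --out sim/
mishelf preprocess  --config run.yaml --in sim/ --out pre/
mishelf reconstruct --config run.yaml --in pre/ --out rec/
mishelf evaluate    --config run.yaml --recon rec/ --truth sim/ --out report.json
```

`run.yaml` holds the geometry and illumination (`d`, `z`, `pixel_pitch`,
`nx`, `ny`, `wavelengths`, plus optional `cfa`, `seed`, noise and iteration
settings; all distances in meters).  Each stage writes TIFF rasters with
JSON sidecars and a manifest recording parameters, seed and input hashes,
so every run is reproducible from its outputs.

## Layout

| module | contents |
| --- | --- |
| `mishelf.optics` | geometry dataclass, M / FOV / NA / ρ, sampling check, USAF periods |
| `mishelf.propagation` | complex fields, angular-spectrum and Rayleigh–Sommerfeld propagators, phase extraction, plane-wave-equivalent distance |
| `mishelf.simulate` | scene generators, nonlinear hologram formation, crosstalk, CFA mosaic, noise, vignette |
| `mishelf.preprocess` | demosaic, background equalization, crosstalk calibration/inversion, channel registration |
| `mishelf.retrieve` | weight masks, spectral merging, autofocus, the iterative reconstruction |
| `mishelf.metrics` | background STD, profile contrast, finest resolved element, twin-plane ratio |
| `mishelf.io`, `mishelf.cli` | raster/config I/O, manifests, the `mishelf` console command |

See `docs/methods.md` for the model, the numerical choices and their
rationale, and known limitations.
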