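# retisim

Polychromatic virtual retinal imaging of intraocular lenses (IOLs): a
sequential spectral Monte-Carlo ray tracer through a pseudophakic
schematic eye, with parametric monofocal and extended-depth-of-focus
(EDoF) lens models, an aperture-diffraction ray-bending approximation,
and colorimetric rendering of the simulated retinal images to display
colour spaces.

## What it does

* **`retisim.optics_core`** — dispersive materials (two-coefficient
  index model fitted to a centre index and Abbe number), conic-asphere /
  zonal surface geometry, vectorised Snell refraction, sequential
  surface-by-surface ray propagation, and stochastic
  Heisenberg-uncertainty ray bending at the pupil stop.
* **`retisim.eye_iol`** — the phakic Arizona-style schematic eye and its
  pseudophakic variant with an IOL at a configurable anterior chamber
  depth; generators for three packaged 20 D lens emulations
  (`monofocal`, `plateau-edof`, `zonal-sa-edof`); radial in-situ power
  profiles, chromatic refraction differences, through-focus curves and
  depth-of-focus spans.
* **`retisim.scene`** — D65 spectral sampling plans, the Lambertian
  pinhole source (importance-sampled toward the pupil), a three-bar
  USAF-1951-style resolution chart with angular calibration
  (group −2 element 2 anchored at 10 cycles/deg), and photopic/mesopic
  scene polarity.
* **`retisim.retinal_render`** — retinal detector accumulation, CIE XYZ
  integration against the 1931 2° observer, sRGB rendering with absolute
  and perceptual (uniform Oklab chroma desaturation) intents, and
  lightness-only images.
* **`retisim.convolution_imaging`** — per-wavelength Monte-Carlo PSFs
  and fast chart imaging by polychromatic convolution, plus a
  brute-force direct Monte-Carlo cross-check.
* **`retisim.cli`** — end-to-end pipelines with reproducible seeds and
  JSON sidecar metadata.

## CLI

One executable, four subcommands:

```sh
retisim simulate-pinhole --lens plateau-edof --pupil 4.5 --vergence 1.5 \
    --rays 1000000 --seed 1 --out out/pinhole --render all
retisim simulate-chart --lens monofocal --pupil 3.0 --vergence 0.75 \
    --polarity photopic --rays 1000000 --seed 1 --out out/chart
retisim power-profile --lens zonal-sa-edof --out out/profile
retisim through-focus --lens plateau-edof --pupil 3.0 --rays 2000000 \
    --out out/tf
```

Images are written as 8-bit sRGB PNGs (lightness, absolute and
perceptual renderings; `--tiff` adds a 32-bit float linear XYZ TIFF);
profiles and through-focus curves as CSV with commented header metadata.
Every output gets a JSON sidecar with the package version, resolved
configuration and seed — identical seeds give bit-identical outputs.

## Conventions

Lengths in mm, wavelengths in µm, optical axis +z toward the retina,
origin at the anterior corneal vertex. Radius of curvature is positive
when the centre of curvature lies toward the retina. The radial power
profile convention is the labelled lens power plus the object vergence
(D) that focuses a narrow pencil at that lens height onto the retina.
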