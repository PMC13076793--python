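# pamangio

Simulation and analysis pipeline for optical-resolution photoacoustic
microscopy (PAM) of 3D vascular cultures: synthetic absorber phantoms, an
instrument forward model, A-line envelope reconstruction, system
characterization, and skeleton-based angiogenesis quantification with
rank-based group statistics.

## What it does

- **`pamangio.phantom`** — seeded generators for ground-truth absorber
  volumes: branching, self-avoiding vascular tube networks whose segment
  lengths follow per-culture-day log-normal laws (medians 67.1 / 103.2 /
  158.5 µm for days 4/6/8), drug-suppression settings (`control`, `TMZ`,
  `SU`, `combo`) with depth-dependent survival, plus razor-edge, carbon-fiber
  and dispersed-cell calibration targets.
- **`pamangio.forward`** — the instrument model: a Gaussian-spectrum
  bandpass transducer pulse (19 MHz, 69% −6 dB fractional bandwidth),
  per-position PA A-line synthesis at 500 MS/s with one-way time-of-flight
  (1540 m/s), lateral Gaussian PSF (0.51·λ/NA), depth attenuation on the
  1/e² convention, a confocal-stack emulator, and pulse-echo waveforms.
- **`pamangio.recon`** — analytic-signal envelope extraction, time→depth
  mapping (3.08 µm/sample, resampled to the 2×2×3 µm voxel lattice), 3×3×3
  median filtering, MAP / depth-encoded / B-scan projections.
- **`pamangio.characterize`** — theoretical and measured lateral (ESF→LSF
  FWHM) and axial (Gaussian envelope fit) resolution, −6 dB bandwidth
  estimation from waveform spectra, and 1/e² penetration-depth fitting from
  per-depth object-intensity profiles.
- **`pamangio.quantify`** — Otsu vessel segmentation with minimum-component
  filtering, depth-binned vessel density, 2D box-counting fractal dimension,
  3D skeletonization with junction clustering / spur pruning / tip-retraction
  correction, and per-segment arc lengths with distribution statistics.
- **`pamangio.stats`** — Kruskal–Wallis omnibus test (tie-corrected) and
  Dunn's post hoc z-tests with Bonferroni correction, implemented from the
  defining formulas and verified against permutation oracles.
- **`pamangio.config` / `pamangio.cli`** — one YAML run configuration with
  strict key checking, a staged pipeline with checksummed run manifests, and
  the `pam-angio` command-line interface.

## CLI

```sh
# full pipeline (simulate -> recon -> quantify -> stats) into ./demo
pam-angio run --seed 1 --out-dir demo

# individual stages against the same output directory
pam-angio simulate --out-dir demo
pam-angio recon --out-dir demo
pam-angio quantify --out-dir demo

# system characterization report
pam-angio characterize --out report.csv

# group comparison on a (group, value) CSV
pam-angio stats --input lengths.csv --out stats.csv
```

A YAML config can override any module default (`--config run.yaml`); unknown
keys are rejected, and every run writes its resolved config and a manifest
with per-artifact SHA-256 checksums beside the outputs. Volumes are stored
as 32-bit float multi-page TIFF with JSON sidecars; graphs, densities and
test reports as CSV.

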