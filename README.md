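# mtpm — source-localized multifocal two-photon microscopy

Multifocal two-photon microscopy (MTPM) parallelizes excitation with an
array of rastered beamlets imaged onto a camera, trading the descanned
detection of point scanning for speed. In scattering brain tissue the
emitted photons blur across the camera, so signal from one cell leaks
into its neighbors' pixels and contrast collapses with depth. This
package implements the computational side of *source-localized* MTPM
for scientists doing camera-based functional imaging in scattering
samples:

- **Monte Carlo scattering kernels** — photon transport through a
  tissue slab (exponential free paths, scattering coefficient µ;
  Henyey–Greenstein deflections, anisotropy g), with exiting photons
  backprojected to their apparent origin in the focal plane.
- **Streak reconstruction** — the camera runs at m× the scan rate so
  each "streak" sub-frame contains one raster line per beamlet; all
  off-line light is known to be scattered. Richardson–Lucy
  deconvolution (`u ← u · ((d / (u ⊗ p)) ⊗ p̂)`, 100 iterations, flat
  prior, reflective padding) reassigns it, and frames are recovered by
  maximum projection over each group of m deconvolved sub-frames.
- **Synthetic forward model** — generated cell scenes, exact streak
  splitting, scattering blur, and the multiplicative Gaussian camera
  noise model Normal(I₀, I₀/10), enabling depth-penetration and
  crosstalk studies with known ground truth.
- **Analysis** — Michelson contrast C = (I_max − I_min)/(I_max + I_min)
  with percentile intensities from segmented cells and background, 50%
  contrast-cutoff depths from cubic profile fits, correlation-map ROI
  segmentation, ΔF/F₀ traces, the signal localization ratio (SLR), the
  double-exponential calcium transient model
  f(t) = Σ_k A·c_{α,γ}(e^{−α(t−t_k)} − e^{−γ(t−t_k)})·u(t−t_k), and
  PSNR = A²/σ².

See `docs/methods.md` for models, parameter defaults, and the scaling
choices behind the synthetic studies.

## Worked example

Sample a scattering kernel for a cell 100 µm deep in cortex-like
tissue (µ = 20 mm⁻¹, g = 0.9), then render a two-cell scene — one cell
firing a calcium transient, its neighbor silent — through the
scattering forward model and reconstruct it with and without source
localization:

```python
from mtpm.scatter import ScatterConfig, sample_kernel
from mtpm.synthetic import crosstalk_slr

cfg = ScatterConfig(mu=20.0, g=0.9, z_h=100.0, n_photons=1_000_000,
                    kernel_halfwidth=31, seed=7)
kernel = sample_kernel(cfg)
print(f"collected photons: {kernel.n_collected}")
print(f"ballistic center weight: {kernel.values[31, 31]:.3f}")

res = crosstalk_slr(seed=0, kernel=kernel)
print(f"SLR raw-mean:        {res['slr_raw']:.1f}")
print(f"SLR source-localized: {res['slr_sl']:.1f}")
print(f"silent neighbor's spurious raw transient peak: {res['silent_peak_raw']:.3f}")
```

```
collected photons: 922560
ballistic center weight: 0.166
SLR raw-mean:        10.3
SLR source-localized: 234.0
silent neighbor's spurious raw transient peak: 0.029
```

92% of the simulated photons reach the surface, but only 17% of the
kernel weight stays in the central bin — the rest is the scattered
halo the deconvolution inverts. In the raw reconstruction the silent
neighbor inherits a spurious ~3% ΔF/F₀ transient from its active
neighbor's scattered light, and the active cell's signal localization
ratio (peak intracellular over peak extracellular ΔF/F₀) is ~10.
Source localization reassigns the scattered light back to its origin
and the SLR rises by more than an order of magnitude; the exact values
depend on the fixture geometry and seed.

## Command line

`mtpm` exposes the pipeline as subcommands; all stochastic commands
take `--seed` and write it to a YAML sidecar next to each output:

```sh
mtpm simulate-kernel --mu 20 --g 0.9 --depth 190 --photons 1e6 --seed 1 -o kernel.tif
mtpm simulate-data --cells 3 --duration 1.0 -k kernel.tif --seed 1 -o stack.tif
mtpm reconstruct -i stack.tif -k kernel.tif -m 8 --iterations 100 -o out
mtpm analyze-contrast -i depthstack.tif --depths depths.csv -o profile.csv
mtpm analyze-functional -i out_sl.tif --raw out_raw.tif --rate 20 -o traces.csv
mtpm model-depth --seed 1 -o depth_table.csv
```

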