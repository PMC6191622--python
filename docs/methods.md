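# Methods

This note documents the models implemented in `mtpm`, the parameters
that matter, the numerical choices behind them, and what the synthetic
studies do and do not demonstrate.

## Imaging model

Multifocal two-photon microscopy (MTPM) excites fluorescence with a
line array of beamlets rastered across the field and images the
emission onto a camera. Emitted photons scatter on their way out of the
tissue, so light recorded away from the illuminated lines is scattered
signal — crosstalk that degrades contrast and mixes functional signals
between cells. Source localization exploits the structured
illumination: the camera runs at m× the scan rate (m = 8 by default),
so each sub-frame ("streak" image) contains one raster line per
beamlet, and all off-line light in that sub-frame is known to be
scattered. Each sub-frame is deconvolved with a tissue-scattering
kernel to reassign that light, and a full frame is recovered as the
pixelwise maximum over the m deconvolved sub-frames. The pixelwise
mean of the raw sub-frames is the equivalent full-exposure MTPM image
and serves as the comparator throughout.

## Scattering kernel (Monte Carlo)

The deconvolution kernel is the distribution of apparent origins of
photons emitted by a point source at depth `z_h` below the surface of a
homogeneous scattering slab. Photons launch toward the surface with
azimuth uniform on [0, 2π) and elevation uniform on [0, θ_max],
θ_max = arcsin(NA / n), with NA = 1 and n = 1.33 (water immersion) by
default; free paths are exponential with scattering coefficient
µ = 20 mm⁻¹ and deflections follow the Henyey–Greenstein phase function
with anisotropy g = 0.9 (its mean deflection cosine). A photon crossing
the surface is backprojected along its final ray to the focal plane and
binned on a square grid centered on the source; photons crossing the
emitter plane heading away from the objective are discarded, as are
apparent origins outside the grid. Steps that cross a boundary are
truncated at the boundary plane. The resulting kernel is a ballistic
delta (weight ≈ e^(−µ z_h / cos θ)) on a broad scattered pedestal and
is approximately radially symmetric.

Choices worth noting:

- "Uniform elevation" is read as uniform in the polar angle itself,
  not on solid angle; a flag switches to the solid-angle convention.
  The refractive index of the NA cut is configurable (set n = 1 for
  the vacuum convention).
- Absorption, surface refraction, polarization and the microscope's
  diffraction-limited PSF are not modelled.
- An iteration cap of 10⁶ scattering events per photon guards against
  non-termination; reaching it is practically impossible.
- The default kernel pitch equals the reconstruction pixel size in
  sample space (1.5625 µm, one eighth of the 12.5 µm beamlet pitch).
- A fixed seed gives a bit-identical kernel; the vectorized batch
  walker is cross-checked against a scalar per-photon reference in the
  test suite.

## Reconstruction

Richardson–Lucy deconvolution with the update
`u ← u · ((d / (u ⊗ p)) ⊗ p̂)`, run for 100 iterations from a flat
prior (a constant image at the mean of the observed sub-frame, which is
scale-consistent and a fixed point for flat data). `p̂` is the kernel
mirrored along the x = y axis (the transpose); the classical
180°-rotation adjoint is available by configuration, and for the
near-radially-symmetric kernels used the two nearly coincide.
Boundaries are reflectively padded by half the kernel side plus one;
the iteration runs as a circular FFT convolution on the padded domain
(the wrap-around never reaches the retained region) and the padding is
stripped on return. The ratio denominator is floored at 1e-12. Dark
level is subtracted and clipped at zero before deconvolution. An
optional 1-D median filter (3 pixels, along the streak axis) can be
applied to each deconvolved sub-frame before the maximum projection;
it is off by default. Sub-frame series whose length is not a multiple
of m drop the trailing partial group with a warning.

## Synthetic scenes and forward model

No deposited recordings accompany the method, so all quantitative
studies run on generated scenes. `generate_cell_scene` places
non-overlapping somata (discs of 5–8 µm radius with a bright membrane
rim at 1.0 and interior at 0.85 of the cell amplitude) on either a
diffuse neuropil background (~12% of cell amplitude; multi-cell mode)
or a near-zero background (single-cell mode). The first soma is always
placed at the 8 µm top of the size range so at least one cell exceeds
the small-object-removal scale of the contrast segmentation (4 binary
erosions at ~1.6 µm pixels erase features below ~7 µm radius — smaller
somata are intentionally erased by that morphology). The rim/interior
ratio keeps whole somata, not just rims, above the 80%-of-maximum
threshold.

The forward model splits a scene into its m streak images (column k
of the image goes to sub-frame k mod m; the split is an exact
partition), convolves each with a scattering kernel (reflective
boundaries; periodic available for flux-conservation fixtures), and
replaces every clean intensity I₀ > 0 with a draw from
Normal(I₀, I₀/10) clipped at zero (zero pixels stay zero). Dynamic
stacks scale each cell by 1 + ΔF/F₀(t) from the transient model below,
frame by frame. Streaks are one pixel wide — the modelling convention,
not the finite Gaussian width of real beamlets.

What the generator does not emulate: Poisson photon statistics (the
noise is the stated Gaussian model), photobleaching, motion, axial
sectioning, and the texture statistics of real neuropil. Passing the
synthetic studies therefore demonstrates the mechanics and the
direction of the effects, not tissue-calibrated numbers.

## Contrast and depth penetration

Michelson contrast C = (I_max − I_min) / (I_max + I_min) with
I_max the 99.9th percentile of segmented cell pixels and I_min the 10th
percentile of background pixels, which makes the metric robust to hot
pixels and uneven illumination; C is defined as 0 when segmentation is
degenerate (all or no pixels selected) or when both percentiles are 0.
Segmentation thresholds at 80% of the image maximum (the
histogram-mode variant is available but segments everything on images
with an offset background), then applies 4 binary erosions and 4
dilations with a 3×3 cross.

The 50% cutoff depth comes from a least-squares cubic fit of the
relative contrast–depth profile (normalized to the shallowest depth),
scanned at 0.1 µm and refined by bisection; the smallest crossing in
the sampled range is reported, or none if the fit never crosses.

The depth-penetration study sweeps line separations
{6.25, 12.5, 25, 50} µm and µ ∈ {10, 20, 40} mm⁻¹. For each (µ, depth)
a 10⁶-photon kernel is sampled; each separation's streak images are
blurred, noised, and then (a) sum-projected for raw MTPM and (b)
deconvolved with the kernel cropped to 32×32 and max-projected for
source localization. Three scaling choices keep every condition's 50%
crossing measurable:

- Depths are sampled in optical depth τ = µ·z (7 points, evenly to a
  per-µ maximum), because scattering statistics depend on τ alone.
- The kernel grid half-width is ≈ two mean free paths (floored at 63
  and capped at 127 bins) and the field of view twice that, because
  the lateral halo at fixed τ scales like 1/µ; a grid much smaller
  than the halo truncates it and artificially preserves reconstruction
  quality.
- The τ range extends to 11 below µ = 20 mm⁻¹ and 10 otherwise: the
  deconvolution crop, soma sizes and line separations are fixed in
  physical units, so weakly scattering tissue keeps reconstruction
  contrast to larger optical depths.

Cell/background masks are segmented once from the clean reference
scene and reused at every depth, so identical regions are compared
across conditions. (Per-noisy-image segmentation is not viable under
the σ = I₀/10 noise model: the maximum of an image is ≈ 3σ above the
brightest structure's mean, so the 80%-of-max threshold selects a
random sprinkle that four erosions erase.)

The study's pass criteria are ordering properties — the
source-localized cutoff exceeds the raw cutoff in every condition and
the advantage grows with line separation. Absolute cutoff values
depend on the reference scene and are not comparable to tissue
measurements.

## Functional analysis

ROIs are segmented from a local correlation map (mean Pearson
correlation of each pixel's time course with its 8-connected
neighbors; constant time courses contribute 0; edge pixels use their
available neighbors) or, for single-cell labeling, from a temporal
variance map. Maps are thresholded with Otsu's method (the specific
auto-threshold behind the published pipeline is not identified in the
text; Otsu is the ecosystem default and is switchable), closed, opened
twice (3×3 square), and the largest connected component is kept.
Per-trial masks combine by strict majority-of-a-quarter: a pixel is in
the consensus ROI iff it appears in > 25% of trials. The extracellular
region is either the full complement of the intracellular mask
(multi-cell) or the intracellular bounding box extended by 5 pixels
per axis minus the mask (single-cell, which deliberately counts
deconvolution ringing near the cell as unreassigned signal).

ΔF/F₀ divides the dark-subtracted mean time course over a mask by its
baseline mean (default baseline: all frames before the first
stimulus). The signal localization ratio (SLR) is the peak
intracellular ΔF/F₀ over the peak extracellular ΔF/F₀ within a window
after the stimulus (default 0.5 s); a nonpositive extracellular peak
is floored at 1e-6.

The calcium transient is the causal double exponential
`f(t) = Σ_k A c_{α,γ} (e^{−α(t−t_k)} − e^{−γ(t−t_k)}) u(t−t_k)` with
α = 3.18 s⁻¹ (decay) and γ = 34.39 s⁻¹ (rise); c_{α,γ} is computed in
closed form from the pulse peak time ln(γ/α)/(γ−α) so a single pulse
peaks exactly at A. Given spike times, A is fit by linear least
squares against the unit-amplitude waveform (closed form
A = r·y / r·r). Noise σ is the sample standard deviation (n−1) of the
final quiet 0.2 s of the trace (0.3 s for the multi-cell variant), and
PSNR = A²/σ².

## Crosstalk experiment

`crosstalk_slr` renders a two-cell fixture (somata 30 µm apart on
neuropil background; cell 0 fires one spike at 0.5 s, cell 1 silent)
through a 100 µm-depth scattering kernel at 20 Hz for 1.2 s,
reconstructs the stack both ways, and measures the SLR of the active
cell's ground-truth mask against its full surround. Scattering makes
the silent neighbor inherit a spurious transient in the raw
reconstruction; source localization reassigns that light back,
raising the SLR. The test asserts the ordering across 10 seeds; the
magnitudes depend on fixture geometry and are not tissue values.

## Problem sizes

Simulations are sized for a single CPU: 10⁶-photon kernels for the
depth and crosstalk studies, 10⁷ photons for the kernel-symmetry
check, 128–256 px fields, 7-point depth profiles, and 10-seed
replication of the crosstalk ordering. Photon counts, fields and
grids are all configurable upward; the default 10⁸-photon
`ScatterConfig` reproduces the full-fidelity kernel.

## Known limitations

- The Monte Carlo slab is homogeneous and scatter-only; real tissue
  cutoff depths will differ (the published tissue measurements are not
  reproducible without the raw recordings and are out of scope).
- Richardson–Lucy amplifies noise; the 10th-percentile background
  intensity of deconvolved images is sensitive to this speckle, which
  is why fixed masks and profile fitting are used in the depth study.
- The x = y-mirror adjoint is implemented literally; for strongly
  asymmetric kernels it deviates from the classical RL adjoint, which
  is available via `ReconstructionConfig(adjoint="rotate")`.
- The forward model's one-pixel streaks and Gaussian noise are
  idealizations; SNR-versus-frame-rate effects driven by Poisson
  statistics are outside the model.
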