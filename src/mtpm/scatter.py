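"""Monte Carlo photon transport through a scattering slab.

Samples the apparent-origin point spread function used to reassign
scattered fluorescence in source-localized multifocal two-photon
microscopy.  An emitter sits at the origin, a depth ``z_h`` below the
tissue surface; the homogeneous slab occupies 0 <= z <= z_h with the
surface (and objective) on the +z side.  Photons launch toward the
surface within the NA cone, propagate with exponentially distributed
free paths (scattering coefficient ``mu``, mm^-1) and Henyey-Greenstein
angular deflections (anisotropy ``g``), and — once they cross the
surface z = z_h — are backprojected along their final direction to an
apparent (x, y) origin in the focal plane z = 0.  Binning those origins
yields the scattering kernel used by :mod:`mtpm.reconstruct`: a
ballistic delta whose weight decays like exp(-mu z_h / cos(theta)) on a
broad scattered pedestal.  Photons crossing z = 0 downward, away from
the objective, are discarded.

Absorption, refractive-index mismatch at the surface, polarization and
the diffraction-limited excitation PSF are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ScatterConfig",
    "PhotonState",
    "ScatterKernel",
    "sample_initial_direction",
    "sample_free_path",
    "sample_hg_deflection",
    "scatter_direction",
    "propagate_photon",
    "backproject",
    "sample_kernel",
    "crop_kernel",
    "kernel_second_moment",
]

# scattering events per photon before the walk is aborted
_MAX_SCATTER_EVENTS = 10**6


class ConfigurationError(ValueError):
    """Raised for physically invalid scattering configurations."""


class EmptyKernelError(RuntimeError):
    """Raised when no photon was collected into the kernel grid."""


@dataclass(frozen=True)
class ScatterConfig:
    """Parameters of the slab Monte Carlo.

    Parameters
    ----------
    mu : float
        Scattering coefficient in mm^-1 (reciprocal mean free path).
    g : float
        Henyey-Greenstein anisotropy, in [0, 1).  ``g`` equals the mean
        cosine of the single-scattering deflection angle.
    z_h : float
        Slab thickness in µm — the depth of the emitter below the
        tissue surface.  Photons are collected when they cross the
        surface z = z_h; photons that leave through z = 0 (heading away
        from the objective) are lost.
    na : float
        Numerical aperture of the launch cone.
    n_medium : float
        Refractive index used to convert NA to a polar angle,
        ``theta_max = arcsin(na / n_medium)``.  Defaults to 1.33
        (water immersion); set to 1.0 for the vacuum convention.
    n_photons : int
        Number of photon walks to simulate.
    pixel_pitch : float
        Kernel bin size in sample space, µm.
    kernel_halfwidth : int
        Bins from the center to the edge; the kernel is square with
        side ``2 * kernel_halfwidth + 1``.
    seed : int
        Seed for the random stream.
    elevation_uniform_in_angle : bool
        If True (default) the launch elevation is uniform in the polar
        angle itself; if False it is uniform on solid angle within the
        cone.
    """

    mu: float = 20.0
    g: float = 0.9
    z_h: float = 190.0
    na: float = 1.0
    n_medium: float = 1.33
    n_photons: int = 100_000_000
    pixel_pitch: float = 1.5625
    kernel_halfwidth: int = 16
    seed: int = 0
    elevation_uniform_in_angle: bool = True

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ConfigurationError(f"mu must be > 0, got {self.mu}")
        if not (0 <= self.g < 1):
            raise ConfigurationError(f"g must be in [0, 1), got {self.g}")
        if self.z_h < 0:
            raise ConfigurationError(f"z_h must be >= 0, got {self.z_h}")
        if not (0 < self.na <= self.n_medium):
            raise ConfigurationError(
                f"need 0 < na <= n_medium, got na={self.na}, n_medium={self.n_medium}"
            )
        if self.n_photons < 1:
            raise ConfigurationError("n_photons must be >= 1")
        if self.pixel_pitch <= 0:
            raise ConfigurationError("pixel_pitch must be > 0")
        if self.kernel_halfwidth < 0:
            raise ConfigurationError("kernel_halfwidth must be >= 0")

    @property
    def theta_max(self) -> float:
        """Maximum launch polar angle, rad."""
        return float(np.arcsin(self.na / self.n_medium))

    @property
    def mean_free_path_um(self) -> float:
        """Mean free path 1/mu converted to µm."""
        return 1000.0 / self.mu


@dataclass
class PhotonState:
    """Position (µm) and unit direction of a photon."""

    position: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit-norm, |d| = {norm}")


@dataclass
class ScatterKernel:
    """Normalized 2-D scattering PSF.

    ``values`` is nonnegative and sums to 1; ``pixel_pitch`` is the bin
    size in µm; ``meta`` records the configuration that produced it
    (None for synthetic kernels such as deltas or crops).
    """

    values: np.ndarray
    pixel_pitch: float
    meta: Optional[ScatterConfig] = None
    n_collected: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kernel must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("kernel entries must be nonnegative")
        total = self.values.sum()
        if total <= 0:
            raise EmptyKernelError("kernel has zero total weight")
        self.values = self.values / total

    @classmethod
    def delta(cls, halfwidth: int, pixel_pitch: float) -> "ScatterKernel":
        """A no-scattering kernel: all weight in the center bin."""
        side = 2 * halfwidth + 1
        values = np.zeros((side, side))
        values[halfwidth, halfwidth] = 1.0
        return cls(values=values, pixel_pitch=pixel_pitch)


def sample_initial_direction(
    cfg: ScatterConfig, rng: np.random.Generator, n: Optional[int] = None
) -> np.ndarray:
    """Draw launch directions within the NA cone, pointing toward the
    surface (+z).

    Azimuth is uniform on [0, 2π).  Elevation (polar angle from +z) is
    uniform on [0, theta_max] by default, or uniform on solid angle
    within the cone if the configuration requests it.
    """
    size = 1 if n is None else n
    phi = rng.uniform(0.0, 2.0 * np.pi, size)
    if cfg.elevation_uniform_in_angle:
        theta = rng.uniform(0.0, cfg.theta_max, size)
        cos_t = np.cos(theta)
        sin_t = np.sin(theta)
    else:
        # uniform on solid angle: cos(theta) uniform on [cos(theta_max), 1]
        cos_t = rng.uniform(np.cos(cfg.theta_max), 1.0, size)
        sin_t = np.sqrt(1.0 - cos_t**2)
    out = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)
    return out[0] if n is None else out


def sample_free_path(
    mu: float, rng: np.random.Generator, n: Optional[int] = None
) -> np.ndarray | float:
    """Exponential free path with mean 1/mu, returned in mm."""
    if mu <= 0:
        raise ConfigurationError(f"mu must be > 0, got {mu}")
    draw = rng.exponential(1.0 / mu, size=n)
    return draw


def sample_hg_deflection(
    g: float, rng: np.random.Generator, n: Optional[int] = None
) -> np.ndarray | float:
    """Polar deflection angle (rad) from the Henyey-Greenstein phase function.

    Uses the standard inverse CDF
    ``cos(theta) = (1 + g^2 - ((1 - g^2) / (1 - g + 2 g U))^2) / (2 g)``
    for g > 0 and the isotropic limit ``cos(theta) = 2U - 1`` at g = 0.
    """
    if not (0 <= g < 1):
        raise ConfigurationError(f"g must be in [0, 1), got {g}")
    u = rng.random(size=n)
    if g == 0:
        cos_t = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g * g - frac * frac) / (2.0 * g)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    return np.arccos(cos_t)


def scatter_direction(
    direction: np.ndarray, deflection: np.ndarray, azimuth: np.ndarray
) -> np.ndarray:
    """Rotate ``direction`` by a polar deflection with an azimuthal spin.

    Builds an orthonormal frame around each input direction and rotates
    by ``deflection`` about an axis selected by ``azimuth``; preserves
    unit norm.  Accepts a single vector or an (n, 3) batch.
    """
    d = np.asarray(direction, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm direction")
    d = d / norms[:, None]

    defl = np.atleast_1d(np.asarray(deflection, dtype=float))
    az = np.atleast_1d(np.asarray(azimuth, dtype=float))

    # Perpendicular frame (e1, e2): pivot on the smallest component to
    # stay well-conditioned near the poles.
    near_z = np.abs(d[:, 2]) < 0.99999
    e1 = np.empty_like(d)
    # e1 = z_hat x d / |.| when d is not near z_hat, else x_hat x d
    e1[near_z, 0] = -d[near_z, 1]
    e1[near_z, 1] = d[near_z, 0]
    e1[near_z, 2] = 0.0
    e1[~near_z, 0] = 0.0
    e1[~near_z, 1] = -d[~near_z, 2]
    e1[~near_z, 2] = d[~near_z, 1]
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(d, e1)

    sin_t = np.sin(defl)[:, None]
    cos_t = np.cos(defl)[:, None]
    out = cos_t * d + sin_t * (np.cos(az)[:, None] * e1 + np.sin(az)[:, None] * e2)
    out /= np.linalg.norm(out, axis=1)[:, None]
    return out[0] if single else out


def backproject(position: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Apparent (x, y) origin of an exiting photon in the focal plane z = 0.

    Extends the final ray through the exit point (on the surface
    z = z_h) back to its intersection with the emitter plane z = 0; an
    unscattered photon maps exactly onto the source.  A photon already
    at z = 0 maps to its own (x, y).  Directions parallel to the
    surface (d_z = 0 with z != 0) have no intersection and raise.
    """
    p = np.atleast_2d(np.asarray(position, dtype=float))
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    single = np.asarray(position).ndim == 1
    xy = p[:, :2].copy()
    off_surface = np.abs(p[:, 2]) > 1e-12
    if np.any(off_surface):
        dz = d[off_surface, 2]
        if np.any(np.abs(dz) < 1e-15):
            raise ValueError("exit direction parallel to the surface")
        t = -p[off_surface, 2] / dz
        xy[off_surface] = p[off_surface, :2] + t[:, None] * d[off_surface, :2]
    return xy[0] if single else xy


def propagate_photon(cfg: ScatterConfig, rng: np.random.Generator) -> dict:
    """Walk a single photon through the slab (reference implementation).

    Returns a dict with ``position`` (µm, truncated at the crossed
    face), ``direction``, ``collected`` (True if the photon crossed the
    surface z = z_h toward the objective), and ``n_scatter``.
    `sample_kernel` uses a vectorized equivalent; this scalar version is
    the readable reference and is cross-checked against it in tests.
    """
    pos = np.zeros(3)
    direction = sample_initial_direction(cfg, rng)
    if cfg.z_h == 0:
        return {"position": pos, "direction": direction, "collected": True, "n_scatter": 0}

    n_scatter = 0
    mfp = cfg.mean_free_path_um
    for _ in range(_MAX_SCATTER_EVENTS):
        step = rng.exponential(mfp)
        new_pos = pos + step * direction
        if direction[2] > 0 and new_pos[2] >= cfg.z_h:
            t = (cfg.z_h - pos[2]) / direction[2]
            pos = pos + t * direction
            pos[2] = cfg.z_h
            return {
                "position": pos,
                "direction": direction,
                "collected": True,
                "n_scatter": n_scatter,
            }
        if new_pos[2] <= 0:
            t = -pos[2] / direction[2]
            pos = pos + t * direction
            pos[2] = 0.0
            return {
                "position": pos,
                "direction": direction,
                "collected": False,
                "n_scatter": n_scatter,
            }
        pos = new_pos
        deflection = sample_hg_deflection(cfg.g, rng)
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        direction = scatter_direction(direction, deflection, azimuth)
        n_scatter += 1
    raise RuntimeError("photon walk exceeded the scattering-event cap")


def _propagate_batch(
    cfg: ScatterConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized photon walks.

    Returns (exit_xy, exit_direction, collected) for n photons; exit_xy
    is the truncated exit point on the crossed face, in µm.  Collected
    photons exit exactly at z = z_h and must be backprojected to the
    focal plane z = 0 for binning.
    """
    pos = np.zeros((n, 3))
    direction = sample_initial_direction(cfg, rng, n)
    exit_dir = direction.copy()
    collected = np.zeros(n, dtype=bool)
    if cfg.z_h == 0:
        collected[:] = True
        return pos[:, :2], exit_dir, collected

    exit_xy = np.zeros((n, 2))
    active = np.arange(n)
    mfp = cfg.mean_free_path_um
    for _ in range(_MAX_SCATTER_EVENTS):
        if active.size == 0:
            break
        step = rng.exponential(mfp, size=active.size)
        p = pos[active]
        d = direction[active]
        new_z = p[:, 2] + step * d[:, 2]

        up = (d[:, 2] > 0) & (new_z >= cfg.z_h)
        down = ~up & (new_z <= 0)
        keep = ~(up | down)

        if np.any(up):
            idx = active[up]
            t = (cfg.z_h - p[up, 2]) / d[up, 2]
            exit_xy[idx] = p[up, :2] + t[:, None] * d[up, :2]
            exit_dir[idx] = d[up]
            collected[idx] = True
        if np.any(down):
            idx = active[down]
            t = -p[down, 2] / d[down, 2]
            exit_xy[idx] = p[down, :2] + t[:, None] * d[down, :2]
            exit_dir[idx] = d[down]

        active = active[keep]
        if active.size == 0:
            break
        pos[active] = p[keep] + step[keep, None] * d[keep]
        deflection = sample_hg_deflection(cfg.g, rng, active.size)
        azimuth = rng.uniform(0.0, 2.0 * np.pi, active.size)
        direction[active] = scatter_direction(direction[active], deflection, azimuth)
    else:
        raise RuntimeError("photon walks exceeded the scattering-event cap")
    return exit_xy, exit_dir, collected


def sample_kernel(cfg: ScatterConfig, batch_size: int = 2_000_000) -> ScatterKernel:
    """Sample the scattering kernel from ``cfg.n_photons`` photon walks.

    Collected photons (those crossing the tissue surface toward the
    objective) are backprojected to the focal plane z = 0 and binned on
    a square grid centered at the source; photons whose apparent origin
    falls outside the grid, or which leave through the bottom face, are
    discarded.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    side = 2 * cfg.kernel_halfwidth + 1
    counts = np.zeros((side, side), dtype=np.int64)
    collected_total = 0

    remaining = cfg.n_photons
    while remaining > 0:
        n = min(remaining, batch_size)
        remaining -= n
        exit_xy, exit_dir, collected = _propagate_batch(cfg, rng, n)
        collected_total += int(collected.sum())
        if cfg.z_h == 0:
            xy = exit_xy[collected]
        else:
            pos3 = np.column_stack(
                [exit_xy[collected], np.full(int(collected.sum()), cfg.z_h)]
            )
            xy = backproject(pos3, exit_dir[collected])
        # bin index: nearest bin, center bin = source
        ix = np.rint(xy[:, 0] / cfg.pixel_pitch).astype(np.int64) + cfg.kernel_halfwidth
        iy = np.rint(xy[:, 1] / cfg.pixel_pitch).astype(np.int64) + cfg.kernel_halfwidth
        inside = (ix >= 0) & (ix < side) & (iy >= 0) & (iy < side)
        np.add.at(counts, (iy[inside], ix[inside]), 1)

    if counts.sum() == 0:
        raise EmptyKernelError("no photons collected into the kernel grid")
    return ScatterKernel(
        values=counts.astype(float),
        pixel_pitch=cfg.pixel_pitch,
        meta=cfg,
        n_collected=collected_total,
    )


def crop_kernel(kernel: ScatterKernel, size: int) -> ScatterKernel:
    """Center crop of the kernel to ``size`` x ``size`` bins, renormalized.

    The deconvolution uses a 32x32 crop of the sampled kernel; an even
    ``size`` crops symmetrically with the extra row/column dropped on
    the high side.
    """
    values = kernel.values
    if size > min(values.shape):
        raise ValueError(f"crop size {size} exceeds kernel shape {values.shape}")
    cy, cx = values.shape[0] // 2, values.shape[1] // 2
    lo = size // 2
    hi = size - lo
    cropped = values[cy - lo : cy + hi, cx - lo : cx + hi]
    return ScatterKernel(values=cropped.copy(), pixel_pitch=kernel.pixel_pitch, meta=kernel.meta)


def kernel_second_moment(kernel: ScatterKernel) -> float:
    """Mean squared radius of the kernel (µm^2), a width measure."""
    side_y, side_x = kernel.values.shape
    y = (np.arange(side_y) - side_y // 2) * kernel.pixel_pitch
    x = (np.arange(side_x) - side_x // 2) * kernel.pixel_pitch
    xx, yy = np.meshgrid(x, y)
    return float(np.sum(kernel.values * (xx**2 + yy**2)))
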