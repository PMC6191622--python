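"""Michelson contrast and 50%-cutoff depth estimation.

Contrast between labeled cells and their surround,
``C = (I_max - I_min) / (I_max + I_min)``, computed from segmented cell
and background pixel populations, and the depth at which relative
contrast falls to half its shallow value, from a cubic fit of the
contrast-depth profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "ContrastResult",
    "ContrastProfile",
    "segment_for_contrast",
    "michelson_contrast",
    "cutoff_depth",
    "relative_contrast_profile",
]

# 3x3 cross (4-connectivity) structuring element for erosion/dilation
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class ContrastResult:
    """Michelson contrast with the masks and intensities behind it."""

    contrast: float
    i_max: float
    i_min: float
    cell_mask: np.ndarray
    background_mask: np.ndarray
    degenerate: bool = False


@dataclass
class ContrastProfile:
    """Per-depth contrast, normalized to the shallowest depth."""

    depths: np.ndarray
    contrasts: np.ndarray  # relative contrast
    cutoff_depth: Optional[float] = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")


def segment_for_contrast(
    image: np.ndarray,
    threshold_mode: str = "max",
    morph_iterations: int = 4,
    hist_bins: int = 256,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Segment bright cells and their background for the contrast metric.

    Pixels above 80% of the image maximum (``threshold_mode="max"``,
    default) or above 80% of the intensity at the histogram's peak bin
    (``"hist-mode"``) form the candidate cell mask; 4 binary erosions
    followed by 4 dilations (3x3 cross) remove small objects.  The
    background is the complement of the dilated mask.

    Returns (cell_mask, background_mask, degenerate); ``degenerate`` is
    True when the cell mask is empty or covers the whole image.
    """
    image = np.asarray(image, dtype=float)
    if threshold_mode == "max":
        threshold = 0.8 * image.max()
    elif threshold_mode == "hist-mode":
        counts, edges = np.histogram(image, bins=hist_bins)
        threshold = 0.8 * edges[np.argmax(counts) + 1]
    else:
        raise ValueError("threshold_mode must be 'max' or 'hist-mode'")

    raw_mask = image > threshold
    mask = raw_mask
    if mask.any():
        mask = ndimage.binary_erosion(mask, structure=_CROSS, iterations=morph_iterations)
        if mask.any():
            mask = ndimage.binary_dilation(mask, structure=_CROSS, iterations=morph_iterations)
    background = ~mask
    # degenerate when the threshold selects everything or nothing usable
    degenerate = bool(raw_mask.all() or not mask.any() or mask.all())
    return mask, background, degenerate


def michelson_contrast(
    image: np.ndarray,
    cell_mask: Optional[np.ndarray] = None,
    background_mask: Optional[np.ndarray] = None,
    **segment_kwargs,
) -> ContrastResult:
    """Michelson contrast ``(I_max - I_min) / (I_max + I_min)``.

    ``I_max`` is the 99.9th percentile of the cell-mask intensities and
    ``I_min`` the 10th percentile of the background intensities, making
    the metric robust to hot pixels and uneven illumination.  If the
    segmentation is degenerate (all or no pixels segmented) the contrast
    is defined as 0, as is the 0/0 case ``I_max + I_min = 0``.
    """
    image = np.asarray(image, dtype=float)
    if cell_mask is None or background_mask is None:
        cell_mask, background_mask, degenerate = segment_for_contrast(image, **segment_kwargs)
    else:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        background_mask = np.asarray(background_mask, dtype=bool)
        degenerate = bool(not cell_mask.any() or cell_mask.all())

    if degenerate:
        return ContrastResult(0.0, 0.0, 0.0, cell_mask, background_mask, degenerate=True)

    i_max = float(np.percentile(image[cell_mask], 99.9))
    i_min = float(np.percentile(image[background_mask], 10.0))
    denom = i_max + i_min
    contrast = 0.0 if denom == 0 else (i_max - i_min) / denom
    return ContrastResult(contrast, i_max, i_min, cell_mask, background_mask)


def relative_contrast_profile(
    depths: Sequence[float], contrasts: Sequence[float]
) -> ContrastProfile:
    """Normalize a contrast-depth series to its shallowest value and
    attach the 50% cutoff depth."""
    depths = np.asarray(depths, dtype=float)
    contrasts = np.asarray(contrasts, dtype=float)
    ref = contrasts[0]
    rel = contrasts / ref if ref > 0 else np.zeros_like(contrasts)
    profile = ContrastProfile(depths=depths, contrasts=rel)
    profile.cutoff_depth = cutoff_depth(depths, rel)
    return profile


def cutoff_depth(
    depths: Sequence[float],
    relative_contrasts: Sequence[float],
    level: float = 0.5,
    scan_step: float = 0.1,
) -> Optional[float]:
    """Depth (µm) where the cubic fit of relative contrast crosses ``level``.

    Fits a least-squares 3rd-order polynomial to the profile, scans it
    on a dense grid (``scan_step`` µm) over the sampled depth range, and
    refines the smallest crossing by bisection.  Returns None when the
    fitted polynomial never crosses ``level`` in the range.
    """
    depths = np.asarray(depths, dtype=float)
    rel = np.asarray(relative_contrasts, dtype=float)
    if depths.size < 4:
        raise ValueError("need at least 4 depth points for a cubic fit")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")

    coeffs = np.polyfit(depths, rel, 3)
    poly = np.poly1d(coeffs)

    grid = np.arange(depths[0], depths[-1] + scan_step, scan_step)
    grid = grid[grid <= depths[-1]]
    values = poly(grid) - level
    sign_change = np.nonzero(np.diff(np.signbit(values)))[0]
    if sign_change.size == 0:
        exact = np.nonzero(values == 0)[0]
        return float(grid[exact[0]]) if exact.size else None
    i = sign_change[0]
    return float(optimize.brentq(lambda d: poly(d) - level, grid[i], grid[i + 1]))
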