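"""Functional calcium-imaging analysis.

ROI segmentation from local correlation or variance maps, ΔF/F₀ trace
extraction, the signal localization ratio (SLR) quantifying functional
crosstalk between a cell and its surround, the double-exponential
calcium-transient model

    f(t) = sum_k A c_{α,γ} (exp(-α (t - t_k)) - exp(-γ (t - t_k))) u(t - t_k),

and peak signal-to-noise, PSNR = A² / σ².  The normalization c_{α,γ}
is chosen in closed form so a single pulse peaks exactly at A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import filters, measure, morphology

__all__ = [
    "RoiSet",
    "Trace",
    "TransientModel",
    "local_correlation_map",
    "segment_functional_roi",
    "consensus_roi",
    "extracellular_ring",
    "dff",
    "slr",
    "transient_waveform",
    "fit_amplitude",
    "estimate_noise",
    "psnr",
    "psnr_db",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class RoiSet:
    """Disjoint intracellular / extracellular masks for one cell."""

    intracellular_mask: np.ndarray
    extracellular_mask: np.ndarray
    provenance: str = "correlation-map"  # or "variance-map" / "ground-truth"

    def __post_init__(self) -> None:
        self.intracellular_mask = np.asarray(self.intracellular_mask, dtype=bool)
        self.extracellular_mask = np.asarray(self.extracellular_mask, dtype=bool)
        if np.any(self.intracellular_mask & self.extracellular_mask):
            raise ValueError("intracellular and extracellular masks must be disjoint")


@dataclass
class Trace:
    """A ΔF/F₀ time course with frame-rate metadata."""

    values: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate


@dataclass
class TransientModel:
    """Calcium-transient pulse parameters.

    ``alpha`` and ``gamma`` (s⁻¹) set the decay and rise speed of the
    indicator; the defaults are the Cal-520 constants 3.18 and 34.39.
    ``c_norm`` normalizes a single pulse to peak amplitude ``amplitude``.
    """

    amplitude: float = 1.0
    alpha: float = 3.18
    gamma: float = 34.39
    spike_times: tuple = ()
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gamma > self.alpha > 0):
            raise ValueError(
                f"need gamma > alpha > 0, got alpha={self.alpha}, gamma={self.gamma}"
            )

    @property
    def peak_time(self) -> float:
        """Time after a spike at which a single pulse peaks, s."""
        return float(np.log(self.gamma / self.alpha) / (self.gamma - self.alpha))

    @property
    def c_norm(self) -> float:
        """Normalization such that a single pulse's maximum equals the
        amplitude parameter."""
        t = self.peak_time
        return 1.0 / (np.exp(-self.alpha * t) - np.exp(-self.gamma * t))


def local_correlation_map(frames: np.ndarray) -> np.ndarray:
    """Mean Pearson correlation of each pixel with its 8-connected
    neighbors, over time.

    Edge pixels average over their available neighbors; a pixel with a
    constant time course contributes correlation 0 to any pair it is in.
    Requires at least 3 frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 3:
        raise ValueError("need a (t, h, w) movie with >= 3 frames")
    t, h, w = frames.shape
    centered = frames - frames.mean(axis=0)
    norm = np.sqrt((centered**2).sum(axis=0))
    # z-scored time courses; constants become all-zero (correlation 0)
    z = np.where(norm > 0, centered / np.where(norm > 0, norm, 1.0), 0.0)

    corr_sum = np.zeros((h, w))
    count = np.zeros((h, w))
    offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    for dy, dx in offsets:
        ys = slice(max(0, dy), h + min(0, dy))
        xs = slice(max(0, dx), w + min(0, dx))
        ys_n = slice(max(0, -dy), h + min(0, -dy))
        xs_n = slice(max(0, -dx), w + min(0, -dx))
        corr_sum[ys, xs] += (z[:, ys, xs] * z[:, ys_n, xs_n]).sum(axis=0)
        count[ys, xs] += 1
    return corr_sum / count


def segment_functional_roi(
    map_image: np.ndarray, mode: str = "correlation"
) -> tuple[np.ndarray, bool]:
    """Threshold a correlation or variance map into an intracellular ROI.

    Applies Otsu's global threshold, binary closing, two rounds of
    opening (3x3 square), and keeps the largest connected component.
    Returns (mask, empty_flag); the flag is True when nothing survives.
    """
    if mode not in ("correlation", "variance"):
        raise ValueError("mode must be 'correlation' or 'variance'")
    map_image = np.asarray(map_image, dtype=float)
    if not np.all(np.isfinite(map_image)):
        raise ValueError("map contains non-finite values")
    if np.ptp(map_image) == 0:
        return np.zeros(map_image.shape, dtype=bool), True

    mask = map_image > filters.threshold_otsu(map_image)
    mask = morphology.closing(mask, footprint=_SQUARE3)
    for _ in range(2):
        mask = morphology.opening(mask, footprint=_SQUARE3)
    if not mask.any():
        return mask, True
    labels = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest, False


def consensus_roi(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixels included in strictly more than a quarter of the per-trial
    masks."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    fraction = np.mean(masks, axis=0)
    return fraction > 0.25


def extracellular_ring(
    intracellular: np.ndarray, mode: str = "5-pixel-ring", margin: int = 5
) -> np.ndarray:
    """Extracellular mask surrounding an intracellular ROI.

    ``"full-surround"`` returns the complement of the intracellular mask
    over the whole ROI image (multi-cell analysis).  ``"5-pixel-ring"``
    returns the intracellular bounding box extended by ``margin`` pixels
    in x and y (clipped to the image), minus the intracellular mask —
    the conservative surround used for single-cell labeling, where
    deconvolution ringing just outside the cell counts as unreassigned
    signal.
    """
    intracellular = np.asarray(intracellular, dtype=bool)
    if not intracellular.any():
        raise ValueError("intracellular mask is empty")
    if mode == "full-surround":
        return ~intracellular
    if mode != "5-pixel-ring":
        raise ValueError("mode must be 'full-surround' or '5-pixel-ring'")
    ys, xs = np.nonzero(intracellular)
    y0 = max(ys.min() - margin, 0)
    y1 = min(ys.max() + margin + 1, intracellular.shape[0])
    x0 = max(xs.min() - margin, 0)
    x1 = min(xs.max() + margin + 1, intracellular.shape[1])
    box = np.zeros_like(intracellular)
    box[y0:y1, x0:x1] = True
    return box & ~intracellular


def dff(
    movie: np.ndarray,
    mask: np.ndarray,
    dark_level: float = 0.0,
    baseline_window: Optional[tuple[int, int]] = None,
    frame_rate: float = 1.0,
) -> Trace:
    """ΔF/F₀ trace of the mean intensity over a mask.

    The raw trace is the per-frame mean over the mask minus the dark
    level; F₀ is its mean over ``baseline_window`` (frame indices,
    half-open; default the whole trace) and the returned trace is
    (raw − F₀) / F₀.
    """
    movie = np.asarray(movie, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    raw = movie[:, mask].mean(axis=1) - dark_level
    if baseline_window is None:
        baseline_window = (0, raw.size)
    f0 = raw[baseline_window[0] : baseline_window[1]].mean()
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive, got {f0}")
    return Trace(values=(raw - f0) / f0, frame_rate=frame_rate)


def slr(
    intra: Trace,
    extra: Trace,
    stimulus_window: tuple[float, float],
    eps: float = 1e-6,
) -> float:
    """Signal localization ratio: peak intracellular over peak
    extracellular ΔF/F₀ within the stimulus window (seconds).

    A higher SLR means less of the cell's transient leaks into the
    surrounding pixels.  A nonpositive extracellular peak is floored at
    ``eps``.
    """
    if intra.frame_rate != extra.frame_rate or intra.values.size != extra.values.size:
        raise ValueError("traces must share frame rate and length")
    t = intra.times
    window = (t >= stimulus_window[0]) & (t <= stimulus_window[1])
    if not window.any():
        raise ValueError("stimulus window contains no frames")
    peak_intra = float(intra.values[window].max())
    peak_extra = float(extra.values[window].max())
    return peak_intra / max(peak_extra, eps)


def transient_waveform(
    t: np.ndarray | float,
    spike_times: Sequence[float],
    model: Optional[TransientModel] = None,
) -> np.ndarray | float:
    """Evaluate the spike-evoked fluorescence model at times ``t`` (s).

    Sum over spikes of causal double-exponential pulses, each peaking at
    ``model.amplitude`` a time ``peak_time`` after its spike; linear in
    the amplitude and in the spike set.
    """
    if model is None:
        model = TransientModel()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    c = model.amplitude * model.c_norm
    for tk in spike_times:
        dt = t_arr - tk
        active = dt >= 0
        out[active] += c * (
            np.exp(-model.alpha * dt[active]) - np.exp(-model.gamma * dt[active])
        )
    return out if np.ndim(t) else float(out[0])


def fit_amplitude(
    trace: Trace, spike_times: Sequence[float], model: Optional[TransientModel] = None
) -> float:
    """Least-squares amplitude of the transient model given spike times.

    Regresses the trace on the unit-amplitude waveform sampled at frame
    times; the single free scale has the closed form
    ``A = (r . y) / (r . r)``.
    """
    if model is None:
        model = TransientModel()
    unit = TransientModel(
        amplitude=1.0, alpha=model.alpha, gamma=model.gamma
    )
    r = transient_waveform(trace.times, spike_times, unit)
    rr = float(np.dot(r, r))
    if rr == 0:
        raise ValueError("regressor is identically zero (no spike in range)")
    return float(np.dot(r, trace.values) / rr)


def estimate_noise(trace: Trace, window_seconds: float = 0.2) -> float:
    """Noise s.d. from the quiescent tail of a trace.

    Sample standard deviation (n−1 denominator) over the final
    ``window_seconds`` of the trace (0.2 s for single-cell, 0.3 s for
    multi-cell analysis).
    """
    n = int(round(window_seconds * trace.frame_rate))
    if n < 2 or n > trace.values.size:
        raise ValueError(
            f"noise window of {n} samples invalid for a {trace.values.size}-sample trace"
        )
    return float(np.std(trace.values[-n:], ddof=1))


def psnr(amplitude: float, sigma: float) -> float:
    """Peak signal-to-noise ratio A² / σ² (infinite when σ = 0)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return float("inf")
    return (amplitude / sigma) ** 2


def psnr_db(value: float) -> float:
    """PSNR expressed in decibels, 10 log10(PSNR)."""
    return 10.0 * np.log10(value)
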