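"""From frames and masks to analysis-ready channel time series.

The trace path: spatially average masked pixels per frame, linearly
resample onto a uniform grid (23 fps by default), remove slow baseline
wander by subtracting a centered moving average, and z-score normalize.
The green channel — the one carrying the strongest plethysmographic
signal on consumer cameras — is what downstream smoothing and
decomposition consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthio import FrameSequence, RGBTrace

__all__ = [
    "NormalizationParams",
    "spatial_average",
    "resample",
    "detrend",
    "detrend_trace",
    "normalize",
    "normalize_trace",
    "extract_green",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Mean and standard deviation removed by z-scoring."""

    mean: float
    sd: float


def spatial_average(frames: FrameSequence, mask: np.ndarray) -> RGBTrace:
    """Mean of each channel over the masked pixels, per frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frames.frames.shape[1:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {frames.frames.shape[1:3]}"
        )
    if not mask.any():
        raise ValueError("mask selects no pixels")
    sel = frames.frames[:, mask, :]  # (n, n_pixels, 3)
    means = sel.mean(axis=1)
    return RGBTrace(frames.times, means[:, 0], means[:, 1], means[:, 2],
                    frames.fps, "raw")


def resample(trace: RGBTrace, target_fps: float = 23.0) -> RGBTrace:
    """Linear interpolation onto a uniform grid spanning [t0, t_end]."""
    if len(trace) < 2:
        raise ValueError("resampling requires at least 2 samples")
    t0, t1 = trace.times[0], trace.times[-1]
    n = int(np.floor((t1 - t0) * target_fps)) + 1
    t_new = t0 + np.arange(n) / target_fps
    t_new[-1] = min(t_new[-1], t1)  # guard fp overshoot at the endpoint
    chans = [np.interp(t_new, trace.times, c) for c in (trace.r, trace.g, trace.b)]
    return RGBTrace(t_new, *chans, target_fps, "resampled")


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average with mirror-padded ends."""
    if win % 2 == 0:
        win += 1
    half = win // 2
    padded = np.pad(x, half, mode="reflect")
    kernel = np.ones(win) / win
    return np.convolve(padded, kernel, mode="valid")


def detrend(signal: np.ndarray, fps: float, window_s: float = 4.0) -> np.ndarray:
    """Subtract a centered moving average of ``window_s`` seconds.

    Frequencies well below 1/window_s are removed (baseline wander);
    the pulse band passes nearly untouched.  Mirror padding bounds the
    edge effect to about half a window at each end.
    """
    signal = np.asarray(signal, dtype=float)
    win = int(round(window_s * fps))
    if window_s <= 2.0 / fps:
        raise ValueError(f"window_s must exceed 2/fps = {2.0 / fps:.4g} s")
    if win >= len(signal):
        raise ValueError(
            f"detrend window ({win} samples) must be shorter than the record "
            f"({len(signal)} samples)"
        )
    return signal - _moving_average(signal, win)


def detrend_trace(trace: RGBTrace, window_s: float = 4.0) -> RGBTrace:
    chans = [detrend(c, trace.fps_nominal, window_s)
             for c in (trace.r, trace.g, trace.b)]
    return RGBTrace(trace.times, *chans, trace.fps_nominal, "detrended")


def normalize(signal: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Z-score: subtract the mean, divide by the population sd."""
    signal = np.asarray(signal, dtype=float)
    mean = float(signal.mean())
    sd = float(signal.std())
    if sd == 0:
        raise ValueError("cannot normalize a constant signal")
    return (signal - mean) / sd, NormalizationParams(mean, sd)


def normalize_trace(trace: RGBTrace) -> tuple[RGBTrace, dict[str, NormalizationParams]]:
    out, params = {}, {}
    for name, c in (("r", trace.r), ("g", trace.g), ("b", trace.b)):
        out[name], params[name] = normalize(c)
    return (RGBTrace(trace.times, out["r"], out["g"], out["b"],
                     trace.fps_nominal, "normalized"), params)


def extract_green(trace: RGBTrace) -> tuple[np.ndarray, np.ndarray]:
    """Green channel with its timestamps."""
    return trace.times.copy(), trace.g.copy()
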