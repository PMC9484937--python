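"""Seeded generators of synthetic vital-sign data with known ground truth.

Real facial-video corpora for remote photoplethysmography are rarely
shareable, so every quantitative test in this package runs against signals
produced here: RGB traces with a cardiac tone amplitude-modulated by
respiration, plain tone mixtures for the decomposition engines, Gaussian
pixel clouds for the segmentation model, and rendered frame sequences with
a skin-colored elliptical region whose mean color carries the trace.

All generators are deterministic given a root seed.  Independent substreams
are derived per generator with :func:`numpy.random.SeedSequence.spawn`-style
keying (``SeedSequence((seed, stream_id))``) so that, e.g., adding noise to
the trace does not perturb the phases of a tone mixture built from the same
root seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "VitalParams",
    "GroundTruth",
    "FrameGeometry",
    "RGBTrace",
    "FrameSequence",
    "generate_trace",
    "generate_tone_mixture",
    "generate_frames",
    "generate_gaussian_pixels",
    "snr_noise_sd",
    "write_trace_csv",
    "read_trace_csv",
    "write_frames_png",
    "write_ground_truth_json",
]

# stream ids for per-generator RNG substreams
_STREAM_TRACE = 1
_STREAM_TONES = 2
_STREAM_FRAMES = 3
_STREAM_PIXELS = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for (root seed, substream)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


@dataclass(frozen=True)
class VitalParams:
    """Physiological and acquisition parameters of a synthetic RGB trace.

    Defaults describe a resting adult filmed by a consumer camera: heart
    rate 72 bpm (1.2 Hz), respiration 15 breaths/min (0.25 Hz), 60 s of
    video at 23 frames/s.  The green channel carries the largest
    plethysmographic gain, as consistently reported for camera-based pulse
    measurement.

    Respiration enters twice: as an additive baseline oscillation
    (``resp_amp``) and as a fractional amplitude modulation of the cardiac
    tone (``am_depth``) — the two mechanisms by which breathing imprints on
    a photoplethysmographic waveform alongside baseline drift.
    """

    hr_hz: float = 1.2
    rr_hz: float = 0.25
    card_amp: float = 1.0
    resp_amp: float = 0.5
    am_depth: float = 0.2
    drift_amp: float = 0.5
    drift_hz: float = 0.01
    noise_sd: float = 0.0
    fps: float = 23.0
    duration_s: float = 60.0
    seed: int = 0
    channel_gains: tuple[float, float, float] = (0.7, 1.0, 0.5)

    def validate(self) -> None:
        if not (self.hr_hz > self.rr_hz > 0):
            raise ValueError(
                f"require hr_hz > rr_hz > 0, got hr_hz={self.hr_hz}, rr_hz={self.rr_hz}"
            )
        if not self.fps > 2 * self.hr_hz:
            raise ValueError(
                f"fps must exceed twice the cardiac frequency (Nyquist): "
                f"fps={self.fps}, hr_hz={self.hr_hz}"
            )
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not (0 <= self.am_depth < 1):
            raise ValueError(f"am_depth must lie in [0, 1), got {self.am_depth}")
        if any(g < 0 for g in self.channel_gains):
            raise ValueError(f"channel_gains must be >= 0, got {self.channel_gains}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass(frozen=True)
class GroundTruth:
    """Evaluation oracle attached to every generated trace."""

    hr_bpm: float
    rr_bpm: float
    clean_trace: "RGBTrace"


@dataclass
class RGBTrace:
    """Per-frame mean channel values over a region of interest."""

    times: np.ndarray
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fps_nominal: float
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.times)
        if not (len(self.r) == len(self.g) == len(self.b) == n):
            raise ValueError("channel arrays must match times in length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def channels(self) -> np.ndarray:
        """(n, 3) array in r, g, b order."""
        return np.column_stack([self.r, self.g, self.b])


@dataclass
class FrameSequence:
    """Ordered frames with timestamps; frames are (h, w, 3) float arrays."""

    frames: np.ndarray  # (n, h, w, 3)
    times: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.frames)


def _clean_waveform(params: VitalParams, t: np.ndarray) -> np.ndarray:
    """Gain-free physiological waveform shared by all channels."""
    carrier = np.cos(2 * np.pi * params.hr_hz * t)
    am = 1.0 + params.am_depth * np.cos(2 * np.pi * params.rr_hz * t)
    resp = params.resp_amp * np.cos(2 * np.pi * params.rr_hz * t)
    drift = params.drift_amp * np.cos(2 * np.pi * params.drift_hz * t)
    return params.card_amp * am * carrier + resp + drift


def generate_trace(params: VitalParams) -> tuple[RGBTrace, GroundTruth]:
    """Generate a synthetic RGB trace plus its noiseless ground truth.

    Per channel ``c``: ``x_c(t) = gain_c * w(t) + eps(t)`` where ``w`` is the
    cardiac tone (amplitude-modulated by respiration) plus additive
    respiratory baseline and slow drift, and ``eps ~ N(0, noise_sd^2)`` is
    drawn independently per channel.
    """
    params.validate()
    n = params.n_samples
    t = np.arange(n) / params.fps
    base = _clean_waveform(params, t)
    gains = np.asarray(params.channel_gains, dtype=float)
    clean = base[:, None] * gains[None, :]
    rng = _rng(params.seed, _STREAM_TRACE)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)

    trace = RGBTrace(t, noisy[:, 0], noisy[:, 1], noisy[:, 2], params.fps, "raw")
    clean_trace = RGBTrace(t, clean[:, 0], clean[:, 1], clean[:, 2], params.fps, "clean")
    truth = GroundTruth(hr_bpm=60 * params.hr_hz, rr_bpm=60 * params.rr_hz,
                        clean_trace=clean_trace)
    return trace, truth


def snr_noise_sd(params: VitalParams, snr_db: float) -> float:
    """Noise s.d. giving the requested SNR on the green channel.

    SNR is the ratio of the AC power of the noiseless green signal (mean
    removed) to the white-noise power.
    """
    noiseless = dataclasses.replace(params, noise_sd=0.0)
    _, truth = generate_trace(noiseless)
    p_sig = float(np.var(truth.clean_trace.g))
    return float(np.sqrt(p_sig / 10 ** (snr_db / 10)))


def generate_tone_mixture(
    freqs: list[float],
    amps: list[float],
    fps: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sum of cosines with seeded uniform phases plus optional white noise.

    An empty frequency list yields a pure-noise (or zero) signal.
    """
    freqs = list(freqs)
    amps = list(amps)
    if len(freqs) != len(amps):
        raise ValueError("freqs and amps must have equal length")
    for f in freqs:
        if not 0 < f < fps / 2:
            raise ValueError(f"frequency {f} Hz outside (0, Nyquist={fps / 2}) Hz")
    n = int(round(fps * duration_s))
    t = np.arange(n) / fps
    rng = _rng(seed, _STREAM_TONES)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    x = np.zeros(n)
    for f, a, phi in zip(freqs, amps, phases):
        x += a * np.cos(2 * np.pi * f * t + phi)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    return x


@dataclass(frozen=True)
class FrameGeometry:
    """Image size and the skin-region ellipse of rendered frames."""

    height: int = 48
    width: int = 64
    center: tuple[float, float] = (24.0, 32.0)  # (row, col)
    axes: tuple[float, float] = (14.0, 20.0)  # (semi-row, semi-col)
    background: tuple[float, float, float] = (40.0, 40.0, 40.0)
    skin_base: tuple[float, float, float] = (150.0, 110.0, 90.0)
    pixel_noise_sd: float = 0.0

    def validate(self) -> None:
        cy, cx = self.center
        ay, ax = self.axes
        if ay <= 0 or ax <= 0:
            raise ValueError("ellipse axes must be positive")
        if (cy - ay < 0 or cy + ay > self.height - 1
                or cx - ax < 0 or cx + ax > self.width - 1):
            raise ValueError("ellipse extends outside image bounds")

    def mask(self) -> np.ndarray:
        yy, xx = np.mgrid[0:self.height, 0:self.width]
        cy, cx = self.center
        ay, ax = self.axes
        return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_frames(
    params: VitalParams, geometry: FrameGeometry | None = None
) -> tuple[FrameSequence, GroundTruth]:
    """Render frames: static background + ellipse carrying the trace.

    The ellipse's mean color at frame ``i`` equals ``skin_base`` plus the
    generated trace value at index ``i``; optional per-pixel Gaussian noise
    is added on top.
    """
    geometry = geometry or FrameGeometry()
    geometry.validate()
    trace, truth = generate_trace(params)
    mask = geometry.mask()
    n = len(trace)
    h, w = geometry.height, geometry.width
    frames = np.empty((n, h, w, 3), dtype=float)
    frames[:] = np.asarray(geometry.background, dtype=float)
    skin = np.asarray(geometry.skin_base, dtype=float)
    chans = trace.channels()
    for i in range(n):
        frames[i][mask] = skin + chans[i]
    if geometry.pixel_noise_sd > 0:
        rng = _rng(params.seed, _STREAM_FRAMES)
        frames += rng.normal(0.0, geometry.pixel_noise_sd, size=frames.shape)
    return FrameSequence(frames, trace.times.copy(), params.fps), truth


def generate_gaussian_pixels(
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a labeled pixel cloud from a diagonal Gaussian mixture.

    Returns ``(pixels, labels)`` with ``pixels`` of shape (n, d).  Labels
    index the mixture component each pixel was drawn from, retained so that
    segmentation accuracy can be scored against the truth.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    sds = np.atleast_2d(np.asarray(sds, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if means.shape != sds.shape:
        raise ValueError("means and sds must have identical shapes")
    if len(weights) != len(means):
        raise ValueError("one weight per component required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {weights.sum()}")
    if n < 0:
        raise ValueError("n must be non-negative")
    k, d = means.shape
    rng = _rng(seed, _STREAM_PIXELS)
    labels = rng.choice(k, size=n, p=weights)
    pixels = rng.normal(means[labels], sds[labels]) if n else np.empty((0, d))
    return pixels.reshape(n, d), labels


# ---------------------------------------------------------------------------
# plain-text writers / readers

def write_trace_csv(trace: RGBTrace, path: str | Path) -> Path:
    path = Path(path)
    header = "time_s,r,g,b"
    data = np.column_stack([trace.times, trace.r, trace.g, trace.b])
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.10g")
    return path


def read_trace_csv(path: str | Path, fps_nominal: float | None = None) -> RGBTrace:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"time_s", "r", "g", "b"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    t = df["time_s"].to_numpy()
    if fps_nominal is None:
        fps_nominal = float(1.0 / np.median(np.diff(t))) if len(t) > 1 else 1.0
    return RGBTrace(t, df["r"].to_numpy(), df["g"].to_numpy(), df["b"].to_numpy(),
                    fps_nominal)


def write_frames_png(frames: FrameSequence, outdir: str | Path) -> list[Path]:
    """Write frames as zero-padded PNG files (values clipped to uint8)."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(frames) - 1)))
    paths = []
    for i, frame in enumerate(frames.frames):
        p = outdir / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, np.clip(frame, 0, 255).astype(np.uint8))
        paths.append(p)
    return paths


def write_ground_truth_json(truth: GroundTruth, params: VitalParams,
                            path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "hr_bpm": truth.hr_bpm,
        "rr_bpm": truth.rr_bpm,
        "params": dataclasses.asdict(params),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
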