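"""End-to-end orchestration: config parsing, stage chain, fixture generation.

Three input modes share one stage chain:

* ``synthetic`` — generate a trace (and optionally frames) from seeded
  parameters, then analyze it;
* ``frames`` — read a PNG/JPEG directory; without a user-supplied mask the
  key-frame + GMM stages produce the skin mask, then spatial averaging
  yields the trace;
* ``trace`` — read a CSV trace and skip the image stages entirely.

Every run writes its intermediate traces, per-engine mode CSVs, the final
rate table, and a JSON manifest (stage log, config echo, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gmm, keyframes, synthio, traces
from .decompose import ENGINES, AFDConfig, HVDConfig, VMDConfig
from .rates import CARDIAC_BAND, RESPIRATORY_BAND, BandSpec, compare_engines
from .synthio import (FrameGeometry, RGBTrace, VitalParams, generate_frames,
                      generate_tone_mixture, generate_trace,
                      generate_gaussian_pixels, read_trace_csv, snr_noise_sd,
                      write_frames_png, write_ground_truth_json, write_trace_csv)

log = logging.getLogger("rppgkit")

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "load_config"]

_KNOWN_KEYS = {
    "mode", "frames_dir", "trace_csv", "mask_npy", "out_dir", "seed",
    "keyframe", "gmm", "resample_fps", "detrend_window_s", "kalman",
    "engines", "engine_configs", "bands", "synthetic", "log_level",
}


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | frames | trace
    frames_dir: str | None = None
    trace_csv: str | None = None
    mask_npy: str | None = None
    out_dir: str = "rppgkit_out"
    seed: int = 0
    keyframe: dict = field(default_factory=lambda: {"n_bins": 16, "m_bins": 16, "T": 0.8})
    gmm: dict = field(default_factory=lambda: {"G": 2, "tol": 1e-6, "max_iter": 200})
    resample_fps: float = 23.0
    detrend_window_s: float = 4.0
    kalman: dict = field(default_factory=lambda: {"preset": "reconstructed",
                                                  "Q": 1.0, "adapt_q": True,
                                                  "enabled": True})
    engines: list = field(default_factory=lambda: ["mafd", "ehvd", "ivmd"])
    engine_configs: dict = field(default_factory=dict)
    bands: dict = field(default_factory=lambda: {
        "cardiac": {"low": 0.75, "high": 3.0},
        "respiratory": {"low": 0.1, "high": 0.5},
    })
    synthetic: dict = field(default_factory=dict)  # VitalParams overrides
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "frames", "trace"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "frames" and not self.frames_dir:
            raise ValueError("frames mode requires frames_dir")
        if self.mode == "trace" and not self.trace_csv:
            raise ValueError("trace mode requires trace_csv")
        for name in self.engines:
            if name not in ENGINES:
                raise ValueError(f"unknown engine {name!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a hierarchical key/value config file (YAML subset)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _band_specs(cfg: PipelineConfig) -> tuple[BandSpec, BandSpec]:
    c = cfg.bands.get("cardiac", {})
    r = cfg.bands.get("respiratory", {})
    cardiac = BandSpec("cardiac", c.get("low", 0.75), c.get("high", 3.0))
    resp = BandSpec("respiratory", r.get("low", 0.1), r.get("high", 0.5))
    return cardiac, resp


def _engine_configs(cfg: PipelineConfig) -> dict:
    out = {}
    builders = {"mafd": AFDConfig, "ehvd": HVDConfig, "ivmd": VMDConfig}
    for name, kw in (cfg.engine_configs or {}).items():
        out[name] = builders[name](**kw)
    return out


def _read_frames_dir(path: Path) -> synthio.FrameSequence:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not files:
        raise FileNotFoundError(f"no PNG/JPEG frames under {path}")
    imgs = np.stack([np.asarray(iio.imread(p), dtype=float) for p in files])
    if imgs.ndim == 3:
        imgs = imgs[..., None].repeat(3, axis=-1)
    fps = 10.0  # nominal acquisition rate when the directory carries no timing
    return synthio.FrameSequence(imgs[..., :3], np.arange(len(imgs)) / fps, fps)


def _frames_to_trace(seq: synthio.FrameSequence, cfg: PipelineConfig,
                     stage_log: list) -> RGBTrace:
    """Key-frame + GMM mask path used when no mask is supplied."""
    t0 = time.perf_counter()
    kf_cfg = cfg.keyframe
    clusters = keyframes.cluster_frames(
        list(seq.frames), T=kf_cfg.get("T", 0.8),
        n_bins=kf_cfg.get("n_bins", 16), m_bins=kf_cfg.get("m_bins", 16))
    kset = keyframes.select_keyframes(clusters)
    stage_log.append({"stage": "keyframes", "n_clusters": len(clusters),
                      "keyframes": kset.indices,
                      "elapsed_s": time.perf_counter() - t0})

    t0 = time.perf_counter()
    key_frame = seq.frames[kset.indices[0]]
    feats = gmm.extract_pixel_features(key_frame, "rgb")
    model = gmm.fit_gmm(feats, G=cfg.gmm.get("G", 2), seed=cfg.seed,
                        tol=cfg.gmm.get("tol", 1e-6),
                        max_iter=cfg.gmm.get("max_iter", 200))
    _, masks = gmm.segment_frame(key_frame, model)
    mask = masks[gmm.skin_component(model)]
    stage_log.append({"stage": "gmm_segmentation", "G": model.G,
                      "mask_pixels": int(mask.sum()),
                      "elapsed_s": time.perf_counter() - t0})
    return traces.spatial_average(seq, mask)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stage chain for the configured input mode.

    Returns the run manifest (also written to ``out_dir/manifest.json``).
    Raises on stage failure after recording the failing stage in the
    manifest written so far.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []
    manifest = {"config": dataclasses.asdict(config), "seed": config.seed,
                "stages": stage_log, "status": "running"}

    def _fail(stage: str, exc: Exception):
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    # --- acquire trace -----------------------------------------------------
    truth = None
    try:
        t0 = time.perf_counter()
        if config.mode == "synthetic":
            params = VitalParams(**{"seed": config.seed, **config.synthetic})
            trace, truth = generate_trace(params)
            write_ground_truth_json(truth, params, out / "ground_truth.json")
        elif config.mode == "trace":
            trace = read_trace_csv(config.trace_csv)
        else:
            seq = _read_frames_dir(Path(config.frames_dir))
            if config.mask_npy:
                mask = np.loadtxt(config.mask_npy, dtype=bool, delimiter=",")
                trace = traces.spatial_average(seq, mask)
            else:
                trace = _frames_to_trace(seq, config, stage_log)
        write_trace_csv(trace, out / "trace_raw.csv")
        stage_log.append({"stage": "acquire", "n_samples": len(trace),
                          "fps": trace.fps_nominal,
                          "elapsed_s": time.perf_counter() - t0})
    except Exception as exc:
        _fail("acquire", exc)
        raise

    # --- resample / rate table --------------------------------------------
    try:
        t0 = time.perf_counter()
        if abs(trace.fps_nominal - config.resample_fps) > 1e-9 or np.ptp(
                np.diff(trace.times)) > 1e-9:
            trace = traces.resample(trace, config.resample_fps)
            write_trace_csv(trace, out / "trace_resampled.csv")
        stage_log.append({"stage": "resample", "fps": trace.fps_nominal,
                          "n_samples": len(trace),
                          "elapsed_s": time.perf_counter() - t0})

        t0 = time.perf_counter()
        cardiac, resp = _band_specs(config)
        preset = (config.kalman.get("preset", "reconstructed")
                  if config.kalman.get("enabled", True) else None)
        table = compare_engines(
            trace, config.engines, cardiac, resp,
            detrend_window_s=config.detrend_window_s,
            kalman_preset=preset,
            engine_configs=_engine_configs(config),
        )
        table.to_csv(out / "rate_table.csv", index=False)
        table.to_json(out / "rate_table.json", orient="records", indent=2)
        stage_log.append({"stage": "rates", "n_rows": len(table),
                          "elapsed_s": time.perf_counter() - t0})
    except Exception as exc:
        _fail("rates", exc)
        raise

    manifest["status"] = "ok"
    if truth is not None:
        manifest["ground_truth"] = {"hr_bpm": truth.hr_bpm, "rr_bpm": truth.rr_bpm}
    manifest["rate_table"] = table.to_dict(orient="records")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_fixtures(seed: int, outdir: str | Path) -> list[Path]:
    """Regenerate the canonical fixtures, bitwise-reproducibly.

    Standard 60 s trace, two-tone mixture, two-component pixel cloud, and a
    100-frame mini-video (10 fps x 10 s) with its ground-truth sidecars.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    params = VitalParams(seed=seed)
    params = dataclasses.replace(params, noise_sd=snr_noise_sd(params, 10.0))
    trace, truth = generate_trace(params)
    written.append(write_trace_csv(trace, outdir / "trace_standard.csv"))
    written.append(write_ground_truth_json(truth, params,
                                           outdir / "trace_standard_truth.json"))

    tones = generate_tone_mixture([0.25, 1.2], [1.0, 1.0], fps=23.0,
                                  duration_s=60.0, seed=seed)
    p = outdir / "two_tone.csv"
    np.savetxt(p, np.column_stack([np.arange(len(tones)) / 23.0, tones]),
               delimiter=",", header="time_s,x", comments="", fmt="%.10g")
    written.append(p)

    pixels, labels = generate_gaussian_pixels(
        means=[[0.2, 0.2, 0.2], [0.8, 0.7, 0.6]],
        sds=[[0.05, 0.05, 0.05], [0.05, 0.05, 0.05]],
        weights=[0.5, 0.5], n=5000, seed=seed)
    p = outdir / "gmm_cloud.csv"
    np.savetxt(p, np.column_stack([pixels, labels]), delimiter=",",
               header="r,g,b,label", comments="", fmt="%.10g")
    written.append(p)

    video_params = dataclasses.replace(
        VitalParams(seed=seed), fps=10.0, duration_s=10.0, noise_sd=0.5,
        card_amp=8.0, resp_amp=4.0, drift_amp=6.0)
    seq, vtruth = generate_frames(video_params)
    written.extend(write_frames_png(seq, outdir / "mini_video"))
    written.append(write_ground_truth_json(vtruth, video_params,
                                           outdir / "mini_video_truth.json"))
    return written
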