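"""Histogram-based key-frame extraction for single-shot video.

A shot is abstracted by (1) computing a quantized color histogram per
frame, (2) leader-clustering frames by histogram intersection against a
threshold ``T``, (3) electing each cluster's most central member as its key
frame, and (4) refining the key-frame set with region-wise distances built
from a segmentation of each key frame.

Histogram intersection of two unit-mass histograms,
``X(h1, h2) = sum_ab min(h1[a,b], h2[a,b])``, is 1 for identical
histograms and 0 for disjoint supports, so larger values mean more similar
frames.  The refinement distance squares the per-region intersection and
sums over regions; note this quantity *grows* with similarity, so the
retention rule's sense (keep similar vs. keep dissimilar pairs) is
configurable rather than fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorHistogram",
    "Cluster",
    "ClusterSet",
    "KeyFrameSet",
    "build_histogram",
    "similarity",
    "cluster_frames",
    "select_keyframes",
    "refine_keyframes",
]


@dataclass
class ColorHistogram:
    """2-D histogram over quantized color coordinates."""

    bins: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if np.any(self.bins < 0):
            raise ValueError("histogram entries must be non-negative")

    @property
    def mass(self) -> float:
        return float(self.bins.sum())

    @property
    def is_normalized(self) -> bool:
        return abs(self.mass - 1.0) <= 1e-9

    def normalized(self) -> "ColorHistogram":
        m = self.mass
        if m == 0:
            raise ValueError("cannot normalize an empty histogram")
        return ColorHistogram(self.bins / m)


def _chromaticity(frame: np.ndarray) -> np.ndarray:
    """Brightness-free (r, g) chromaticity per pixel; gray maps to (1/3, 1/3)."""
    px = frame.reshape(-1, frame.shape[-1]).astype(float)
    s = px.sum(axis=1)
    s[s == 0] = 1.0  # black pixels -> put at origin-ish corner deterministically
    return np.column_stack([px[:, 0] / s, px[:, 1] / s])


def build_histogram(
    frame: np.ndarray,
    n_bins: int = 16,
    m_bins: int = 16,
    normalize: bool = True,
    mode: str = "chromaticity",
) -> ColorHistogram:
    """Color histogram of one frame.

    ``mode='chromaticity'`` bins (r/(r+g+b), g/(r+g+b)) on an
    ``n_bins x m_bins`` grid — robust to global brightness changes.
    ``mode='per_channel'`` concatenates per-channel 1-D histograms into a
    (3, n_bins) array instead.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if frame.ndim == 2:
        frame = frame[..., None].repeat(3, axis=-1)
    if mode == "chromaticity":
        chroma = _chromaticity(frame)
        h, _, _ = np.histogram2d(
            chroma[:, 0], chroma[:, 1], bins=[n_bins, m_bins], range=[[0, 1], [0, 1]]
        )
    elif mode == "per_channel":
        px = frame.reshape(-1, 3).astype(float)
        hi = max(px.max(), 1.0)
        h = np.stack([
            np.histogram(px[:, c], bins=n_bins, range=(0, hi))[0] for c in range(3)
        ]).astype(float)
    else:
        raise ValueError(f"unknown histogram mode {mode!r}")
    hist = ColorHistogram(h)
    return hist.normalized() if normalize else hist


def similarity(h1: ColorHistogram, h2: ColorHistogram) -> float:
    """Histogram intersection: sum of cell-wise minima, in [0, 1]."""
    if h1.bins.shape != h2.bins.shape:
        raise ValueError(
            f"histogram shapes differ: {h1.bins.shape} vs {h2.bins.shape}"
        )
    if not (h1.is_normalized and h2.is_normalized):
        raise ValueError("similarity requires normalized histograms")
    return float(np.minimum(h1.bins, h2.bins).sum())


@dataclass
class Cluster:
    members: list[int] = field(default_factory=list)
    centroid: ColorHistogram | None = None
    _sum: np.ndarray | None = None

    def add(self, index: int, hist: ColorHistogram) -> None:
        self.members.append(index)
        self._sum = hist.bins.copy() if self._sum is None else self._sum + hist.bins
        # running mean renormalized to unit mass
        self.centroid = ColorHistogram(self._sum / self._sum.sum())


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float
    histograms: list[ColorHistogram]

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_frames(
    frames: list[np.ndarray] | np.ndarray,
    T: float = 0.8,
    n_bins: int = 16,
    m_bins: int = 16,
    mode: str = "chromaticity",
) -> ClusterSet:
    """Sequential leader clustering of frames by histogram intersection.

    Each frame joins the existing cluster whose centroid it resembles most,
    provided that similarity exceeds ``T``; otherwise it opens a new
    cluster.  Deterministic given the input order (temporal order).
    """
    if not 0 < T < 1:
        raise ValueError(f"threshold T must lie in (0, 1), got {T}")
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("no frames to cluster")
    hists = [build_histogram(f, n_bins, m_bins, True, mode) for f in frames]
    clusters: list[Cluster] = []
    for i, h in enumerate(hists):
        best, best_sim = None, -1.0
        for c in clusters:
            s = similarity(h, c.centroid)
            if s > best_sim:
                best, best_sim = c, s
        if best is not None and best_sim > T:
            best.add(i, h)
        else:
            c = Cluster()
            c.add(i, h)
            clusters.append(c)
    return ClusterSet(clusters, T, hists)


@dataclass
class KeyFrameSet:
    """Ordered key-frame indices, one per cluster."""

    indices: list[int]
    cluster_of: list[int]  # cluster id per key frame
    region_histograms: list[list[ColorHistogram]] | None = None

    def __len__(self) -> int:
        return len(self.indices)


def select_keyframes(clusters: ClusterSet) -> KeyFrameSet:
    """Pick each cluster's member most similar to its centroid.

    Ties break toward the smallest frame index; the result is sorted by
    frame index so key frames appear in temporal order.
    """
    if len(clusters) == 0:
        raise ValueError("empty cluster set")
    picks: list[tuple[int, int]] = []
    for ci, c in enumerate(clusters.clusters):
        sims = [similarity(clusters.histograms[i], c.centroid) for i in c.members]
        best = int(np.argmax(sims))  # argmax returns first max -> smallest index
        picks.append((c.members[best], ci))
    picks.sort()
    return KeyFrameSet([p[0] for p in picks], [p[1] for p in picks])


def pair_distance(regions_a: list[ColorHistogram],
                  regions_b: list[ColorHistogram]) -> float:
    """Region-wise distance between two key frames.

    Sum over regions of the *squared* histogram intersection.  Identical
    region partitions give G (the region count); disjoint ones give 0.
    """
    if len(regions_a) != len(regions_b):
        raise ValueError(
            f"region counts differ: {len(regions_a)} vs {len(regions_b)}"
        )
    return float(sum(similarity(a, b) ** 2 for a, b in zip(regions_a, regions_b)))


def refine_keyframes(
    keyframes: KeyFrameSet,
    partitions: list[list[ColorHistogram]],
    threshold: float | None = None,
    keep: str = "dissimilar",
) -> tuple[list[float], list[int]]:
    """Consecutive-pair distances and the retained key-frame indices.

    ``partitions[i]`` holds the G region histograms of key frame ``i``.
    Returns ``(distances, kept_indices)``.  The distance grows with
    similarity (it is a sum of squared intersections), so ``keep``
    selects the retention sense: ``'dissimilar'`` keeps a pair's second
    frame when distance < threshold, ``'similar'`` when distance >=
    threshold.  With ``threshold=None`` all key frames are kept and only
    the distances are informative.
    """
    if len(partitions) != len(keyframes):
        raise ValueError("one region partition per key frame required")
    if keep not in ("dissimilar", "similar"):
        raise ValueError(f"keep must be 'dissimilar' or 'similar', got {keep!r}")
    g_counts = {len(p) for p in partitions}
    if len(g_counts) > 1:
        raise ValueError(f"inconsistent region counts across key frames: {g_counts}")
    distances = [
        pair_distance(partitions[i + 1], partitions[i])
        for i in range(len(partitions) - 1)
    ]
    if threshold is None:
        return distances, list(keyframes.indices)
    kept = [keyframes.indices[0]]
    for i, d in enumerate(distances):
        cond = d < threshold if keep == "dissimilar" else d >= threshold
        if cond:
            kept.append(keyframes.indices[i + 1])
    return distances, kept
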