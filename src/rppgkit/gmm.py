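"""Pixel-wise Gaussian-mixture segmentation via expectation-maximization.

Frames are turned into per-pixel feature vectors (raw RGB or brightness-free
chromaticity) and modeled as a G-component Gaussian mixture fitted by EM
with a seeded k-means++ initialization.  Pixels are then assigned to their
maximum-posterior component, which partitions the frame into regions — the
inputs to key-frame refinement and to mask-based trace extraction.

The EM here is written out explicitly (diagonal covariances by default,
with a variance floor; full covariances behind a flag) so the
log-likelihood trace is available and its monotonicity can be asserted on
every fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PixelFeatures",
    "GMMModel",
    "extract_pixel_features",
    "fit_gmm",
    "segment_frame",
]


@dataclass
class PixelFeatures:
    """Per-pixel feature vectors with image coordinates retained."""

    features: np.ndarray  # (n_pixels, d)
    coords: np.ndarray  # (n_pixels, 2) row, col
    shape: tuple[int, int]
    spec: str


@dataclass
class GMMModel:
    weights: np.ndarray  # (G,)
    means: np.ndarray  # (G, d)
    covariances: np.ndarray  # (G, d) diagonal or (G, d, d) full
    log_likelihood: list[float]
    feature_spec: str
    covariance_type: str = "diag"
    converged: bool = False

    @property
    def G(self) -> int:
        return len(self.weights)


def extract_pixel_features(frame: np.ndarray, feature_spec: str = "rgb") -> PixelFeatures:
    """One feature vector per pixel.

    ``'rgb'`` keeps raw channel values; ``'chromaticity'`` uses
    (r/(r+g+b), g/(r+g+b)), which maps every gray pixel to (1/3, 1/3).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if frame.ndim == 2:
        frame = frame[..., None].repeat(3, axis=-1)
    h, w = frame.shape[:2]
    px = frame.reshape(-1, frame.shape[-1])
    if feature_spec == "rgb":
        feats = px.copy()
    elif feature_spec == "chromaticity":
        s = px.sum(axis=1)
        s[s == 0] = 1.0
        feats = np.column_stack([px[:, 0] / s, px[:, 1] / s])
    else:
        raise ValueError(f"unknown feature_spec {feature_spec!r}")
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([yy.ravel(), xx.ravel()])
    return PixelFeatures(feats, coords, (h, w), feature_spec)


def _kmeanspp_init(x: np.ndarray, G: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++ center selection on (a subsample of) x."""
    n = len(x)
    if n > 10_000:
        x = x[rng.choice(n, 10_000, replace=False)]
        n = len(x)
    centers = [x[rng.integers(n)]]
    for _ in range(1, G):
        d2 = np.min(
            [np.sum((x - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:  # all points coincide with a center
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def _log_gauss_diag(x: np.ndarray, means: np.ndarray, var: np.ndarray) -> np.ndarray:
    """(n, G) log densities for diagonal covariances."""
    d = x.shape[1]
    # (n, G) via broadcasting
    diff2 = (x[:, None, :] - means[None, :, :]) ** 2
    return -0.5 * (
        d * np.log(2 * np.pi)
        + np.sum(np.log(var), axis=1)[None, :]
        + np.sum(diff2 / var[None, :, :], axis=2)
    )


def _log_gauss_full(x: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    from scipy.stats import multivariate_normal

    return np.column_stack([
        multivariate_normal.logpdf(x, mean=m, cov=c, allow_singular=True)
        for m, c in zip(means, cov)
    ])


def _log_prob(x: np.ndarray, model_weights, means, cov, cov_type) -> np.ndarray:
    lg = (_log_gauss_diag(x, means, cov) if cov_type == "diag"
          else _log_gauss_full(x, means, cov))
    return lg + np.log(model_weights)[None, :]


def fit_gmm(
    features: PixelFeatures | np.ndarray,
    G: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    var_floor: float = 1e-6,
    covariance_type: str = "diag",
) -> GMMModel:
    """Fit a G-component Gaussian mixture by EM.

    Initialization is seeded k-means++ on a subsample of at most 10^4
    points, so fits are deterministic given ``seed``.  EM stops when the
    mean log-likelihood gain drops below ``tol`` or after ``max_iter``
    iterations.  A component whose responsibility mass collapses is
    re-seeded once at the point with the lowest likelihood; a second
    collapse raises.
    """
    x = features.features if isinstance(features, PixelFeatures) else np.asarray(features, float)
    spec = features.spec if isinstance(features, PixelFeatures) else "raw"
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if G < 1:
        raise ValueError("G must be >= 1")
    if n < G:
        raise ValueError(f"need at least G={G} points, got {n}")
    if covariance_type not in ("diag", "full"):
        raise ValueError(f"covariance_type must be 'diag' or 'full', got {covariance_type!r}")

    rng = np.random.default_rng(seed)
    means = _kmeanspp_init(x, G, rng)
    gvar = np.maximum(x.var(axis=0), var_floor)
    if covariance_type == "diag":
        cov = np.tile(gvar, (G, 1))
    else:
        cov = np.tile(np.diag(gvar), (G, 1, 1))
    weights = np.full(G, 1.0 / G)

    ll_trace: list[float] = []
    reseeded = set()
    converged = False
    for _ in range(max_iter):
        # E step
        log_wp = _log_prob(x, weights, means, cov, covariance_type)
        log_norm = logsumexp(log_wp, axis=1)
        ll = float(log_norm.mean())
        resp = np.exp(log_wp - log_norm[:, None])

        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            bad = int(np.argmin(nk))
            if bad in reseeded:
                raise RuntimeError(f"component {bad} collapsed twice during EM")
            reseeded.add(bad)
            means[bad] = x[int(np.argmin(log_norm))]
            if covariance_type == "diag":
                cov[bad] = np.maximum(x.var(axis=0), var_floor)
            else:
                cov[bad] = np.diag(np.maximum(x.var(axis=0), var_floor))
            continue
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        if covariance_type == "diag":
            ex2 = (resp.T @ (x ** 2)) / nk[:, None]
            cov = np.maximum(ex2 - means ** 2, var_floor)
        else:
            cov = np.empty((G, d, d))
            for j in range(G):
                diff = x - means[j]
                cov[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
                cov[j][np.diag_indices(d)] = np.maximum(np.diag(cov[j]), var_floor)

        if ll_trace and ll - ll_trace[-1] < tol:
            ll_trace.append(ll)
            converged = True
            break
        ll_trace.append(ll)

    return GMMModel(weights, means, cov, ll_trace, spec, covariance_type, converged)


def posterior(model: GMMModel, x: np.ndarray) -> np.ndarray:
    """(n, G) responsibilities under a fitted model; rows sum to 1."""
    log_wp = _log_prob(x, model.weights, model.means, model.covariances,
                       model.covariance_type)
    return np.exp(log_wp - logsumexp(log_wp, axis=1)[:, None])


def segment_frame(
    frame: np.ndarray, model: GMMModel, feature_spec: str | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Assign each pixel to its maximum-posterior component.

    Returns ``(label_map, masks)`` where ``masks[j]`` is the boolean region
    of component ``j``; the masks partition the frame.  Posterior ties go
    to the lowest component index (argmax's first-hit rule).
    """
    spec = feature_spec or model.feature_spec
    feats = extract_pixel_features(frame, spec if spec != "raw" else "rgb")
    if feats.features.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimension {feats.features.shape[1]} does not match "
            f"model dimension {model.means.shape[1]}"
        )
    log_wp = _log_prob(feats.features, model.weights, model.means,
                       model.covariances, model.covariance_type)
    labels = np.argmax(log_wp, axis=1).reshape(feats.shape)
    masks = [labels == j for j in range(model.G)]
    return labels, masks


def skin_component(model: GMMModel, channel: int = 1) -> int:
    """Heuristic object pick: component with the largest mean green value."""
    if model.means.shape[1] <= channel:
        raise ValueError("model features carry no such channel")
    return int(np.argmax(model.means[:, channel]))
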