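"""Adaptive Kalman smoothing of physiological traces.

A three-lag shift-register state ``A_k = [a_k, a_{k-1}, a_{k-2}]`` is
propagated by a transition matrix ``X`` and observed through a measurement
row ``Y``.  Two presets are shipped:

``reconstructed`` (default)
    ``X = [[2,-1,0],[1,0,0],[0,1,0]]``, ``Y = [1,0,0]``,
    ``R = 0.4 * diag(1,0,0)``.  The top row implements the forward-difference
    extrapolation ``a_{k+1} = a_k + (a_k - a_{k-1})`` — the unique
    shift-register model consistent with a first-order derivative
    approximation on a uniform grid; process noise enters only the newest
    lag.

``literal``
    ``X = [[1,1,0],[-1,0,1],[1,0,0]]``, ``Y = [2,0,-1]`` and an indefinite
    process-noise matrix that is symmetrized and eigenvalue-floored to the
    nearest positive-semidefinite matrix.  Kept for comparison; it is not a
    meaningful tracking model and the default tests do not rely on it.

"Adaptive" is realized as optional innovation-based rescaling of the
measurement-noise variance ``Q`` over a sliding 2 s window.  An alpha-beta
fixed-gain predictor is provided as a cheap fallback tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KalmanModel",
    "KalmanState",
    "AlphaBetaParams",
    "kalman_model",
    "predict",
    "update",
    "smooth_signal",
    "alpha_beta_predict",
]


def _floor_psd(m: np.ndarray) -> np.ndarray:
    """Symmetrize and clamp negative eigenvalues to zero."""
    sym = 0.5 * (m + m.T)
    vals, vecs = np.linalg.eigh(sym)
    return (vecs * np.maximum(vals, 0.0)) @ vecs.T


@dataclass(frozen=True)
class KalmanModel:
    X: np.ndarray  # (3, 3) state transition
    Y: np.ndarray  # (3,) measurement row
    R: np.ndarray  # (3, 3) process-noise covariance
    Q: float = 1.0  # measurement-noise variance
    dt: float = 1.0 / 23.0
    preset: str = "reconstructed"
    adapt_q: bool = False
    adapt_window_s: float = 2.0

    def validate(self) -> None:
        if self.Q <= 0:
            raise ValueError(f"Q must be positive, got {self.Q}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if np.any(np.linalg.eigvalsh(0.5 * (self.R + self.R.T)) < -1e-9):
            raise ValueError("R must be positive semi-definite")


def kalman_model(
    preset: str = "reconstructed",
    Q: float = 1.0,
    dt: float = 1.0 / 23.0,
    adapt_q: bool = False,
    **overrides,
) -> KalmanModel:
    """Build a model from a named preset, optionally overriding X/Y/R."""
    if preset == "reconstructed":
        X = np.array([[2.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        Y = np.array([1.0, 0.0, 0.0])
        R = 0.4 * np.diag([1.0, 0.0, 0.0])
    elif preset == "literal":
        X = np.array([[1.0, 1.0, 0.0], [-1.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        Y = np.array([2.0, 0.0, -1.0])
        R = _floor_psd(np.array([[0.4, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, -1.0]]))
    else:
        raise ValueError(f"unknown preset {preset!r}")
    X = np.asarray(overrides.get("X", X), dtype=float)
    Y = np.asarray(overrides.get("Y", Y), dtype=float)
    R = _floor_psd(np.asarray(overrides.get("R", R), dtype=float))
    model = KalmanModel(X, Y, R, Q, dt, preset, adapt_q)
    model.validate()
    return model


@dataclass
class KalmanState:
    A: np.ndarray  # (3,) signal vector, newest lag first
    P: np.ndarray  # (3, 3) error covariance
    k: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if np.max(np.abs(self.P - self.P.T)) > 1e-9:
            raise ValueError("P must be symmetric")
        if np.any(np.diag(self.P) < 0):
            raise ValueError("P must have non-negative diagonal")


def predict(state: KalmanState, model: KalmanModel) -> KalmanState:
    """Time update: A <- X A, P <- X P X^T + R."""
    if not np.all(np.isfinite(state.A)):
        raise FloatingPointError("non-finite state vector")
    A = model.X @ state.A
    P = model.X @ state.P @ model.X.T + model.R
    P = 0.5 * (P + P.T)
    return KalmanState(A, P, state.k)


def update(state: KalmanState, measurement: float, model: KalmanModel,
           Q: float | None = None) -> KalmanState:
    """Measurement update with gain, innovation correction, Joseph-lite P."""
    if not np.isfinite(measurement):
        raise FloatingPointError("non-finite measurement")
    q = model.Q if Q is None else Q
    Y = model.Y
    s = float(Y @ state.P @ Y) + q
    if s <= 0:
        raise FloatingPointError(f"innovation variance non-positive: {s}")
    gain = (state.P @ Y) / s
    innovation = measurement - float(Y @ state.A)
    A = state.A + gain * innovation
    P = (np.eye(len(Y)) - np.outer(gain, Y)) @ state.P
    P = 0.5 * (P + P.T)
    return KalmanState(A, P, state.k + 1)


def smooth_signal(
    signal: np.ndarray,
    model: KalmanModel | None = None,
    init: KalmanState | None = None,
) -> np.ndarray:
    """Predict/update sweep over a signal; returns the filtered a_k series.

    The state holds three lags, so the first three samples seed it (they
    are passed through unfiltered) and filtering starts at index 3.  With
    ``model.adapt_q`` the measurement-noise variance is re-estimated each
    step as the sample variance of recent innovations (2 s window).
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 3:
        raise ValueError(f"need at least 3 samples, got {len(signal)}")
    model = model or kalman_model()
    state = init or KalmanState(signal[2::-1].copy(), np.eye(3))
    out = signal.copy()
    innovations: list[float] = []
    win = max(5, int(round(model.adapt_window_s / model.dt)))
    for k in range(3, len(signal)):
        state = predict(state, model)
        q = None
        if model.adapt_q and len(innovations) >= 5:
            q = max(float(np.var(innovations[-win:])), 1e-12)
        innovations.append(signal[k] - float(model.Y @ state.A))
        state = update(state, signal[k], model, Q=q)
        out[k] = state.A[0]
    return out


@dataclass(frozen=True)
class AlphaBetaParams:
    """Fixed gains of the one-step-ahead fallback predictor."""

    alpha: float = 0.5
    beta: float = 0.1

    def validate(self) -> None:
        if not 0 <= self.alpha < 2:
            raise ValueError(f"alpha must lie in [0, 2), got {self.alpha}")
        if not 0 <= self.beta < 1:
            raise ValueError(f"beta must lie in [0, 1), got {self.beta}")


def alpha_beta_predict(
    signal: np.ndarray, measurements: np.ndarray, params: AlphaBetaParams | None = None
) -> np.ndarray:
    """One-step-ahead predictions Y_{k+1} = A_k + a(A_k - A_{k-1}) + b(B_k - B_{k-1}).

    ``signal`` holds the state series A and ``measurements`` the aligned
    observation series B; the returned array has one prediction per
    consecutive pair (length n-1).
    """
    params = params or AlphaBetaParams()
    params.validate()
    a = np.asarray(signal, dtype=float)
    b = np.asarray(measurements, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"signal and measurements lengths differ: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    return a[1:] + params.alpha * np.diff(a) + params.beta * np.diff(b)
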