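"""One-step-ahead sample predictors for predictive (DPCM) EEG coding.

Five predictor families share one contract — given the ``p`` most recent
samples (most recent first) produce an estimate of the next sample:

* ``slp``  — single-layer perceptron (linear, p taps + bias), trained with
  Levenberg-Marquardt; for a linear model LM converges to the least-squares
  solution.
* ``mlp``  — multi-layer perceptron, one log-sigmoid hidden layer, linear
  output, Levenberg-Marquardt.
* ``en``   — Elman simple recurrent network: tan-sigmoid hidden layer whose
  previous activation is fed back as context, linear output, trained with
  gradient descent with momentum and adaptive learning rate (GDX) using
  teacher-forced, single-step-truncated gradients.
* ``ar``   — autoregressive coefficients by least squares (covariance
  method).
* ``fir``  — Wiener one-step predictor by the autocorrelation method
  (Toeplitz normal equations).

Integer samples are normalised to [-1, 1] by ``2**(bit_depth-1)`` before
entering a network; predictions are returned de-normalised, in sample units.
Every training path is deterministic given the config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import solve_toeplitz

from .records import EEGRecord

__all__ = [
    "PredictorConfig",
    "PredictorModel",
    "TrainingError",
    "parameter_count",
    "default_config",
    "train_predictor",
    "fit_ar",
    "fit_fir",
    "predict_next",
    "open_loop_residues",
]

logger = logging.getLogger(__name__)

KINDS = ("slp", "mlp", "en", "ar", "fir")


class TrainingError(RuntimeError):
    """Raised when training diverges (NaN loss / singular system)."""


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and training recipe for one predictor.

    Defaults for the neural kinds follow the optimal configurations found
    for EEG prediction: SLP order 5 (LM, ~65 epochs), MLP order 3 with 5
    log-sigmoid hidden units (LM, ~230 epochs), Elman order 5 with 5
    tan-sigmoid hidden units (GDX, ~750 epochs).  Epoch counts are stopping
    defaults, not exact rules — training also stops at ``error_goal``.
    """

    kind: str
    order: int
    hidden_units: int = 0
    activation_hidden: str = "none"
    trainer: str = "least_squares"
    max_epochs: int = 100
    seed: int = 0
    error_goal: float = 1e-5

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind in ("slp", "ar", "fir") and self.hidden_units != 0:
            raise ValueError(f"{self.kind} has no hidden layer")
        if self.kind in ("mlp", "en") and self.hidden_units < 1:
            raise ValueError(f"{self.kind} needs hidden_units >= 1")

    def with_(self, **kw) -> "PredictorConfig":
        return replace(self, **kw)


_DEFAULTS = {
    "slp": dict(order=5, hidden_units=0, activation_hidden="none",
                trainer="levenberg_marquardt", max_epochs=65),
    "mlp": dict(order=3, hidden_units=5, activation_hidden="log_sigmoid",
                trainer="levenberg_marquardt", max_epochs=230),
    "en": dict(order=5, hidden_units=5, activation_hidden="tan_sigmoid",
               trainer="gdx", max_epochs=750),
    "ar": dict(order=5, hidden_units=0, activation_hidden="none",
               trainer="least_squares", max_epochs=1),
    "fir": dict(order=5, hidden_units=0, activation_hidden="none",
                trainer="least_squares", max_epochs=1),
}


def default_config(kind: str, *, seed: int = 0, **overrides) -> PredictorConfig:
    """Standard configuration for a predictor kind."""
    if kind not in _DEFAULTS:
        raise ValueError(f"unknown predictor kind {kind!r}")
    kw = dict(_DEFAULTS[kind])
    kw.update(overrides)
    return PredictorConfig(kind=kind, seed=seed, **kw)


def parameter_count(kind: str, p: int, h: int = 0) -> int:
    """Number of trainable parameters w for an architecture.

    slp/ar/fir: p taps + bias.  mlp: input weights p*h, hidden biases h,
    output weights h, output bias.  en: additionally the h*h context
    (recurrent) weights.
    """
    if kind in ("slp", "ar", "fir"):
        return p + 1
    if kind == "mlp":
        return p * h + h + h + 1
    if kind == "en":
        return p * h + h * h + h + h + 1
    raise ValueError(f"unknown predictor kind {kind!r}")


@dataclass
class PredictorModel:
    """A trained predictor: flat parameter vector + normalisation.

    ``parameters`` layout:
      slp/ar/fir : [taps(p), bias]
      mlp        : [W1(h*p row-major), b1(h), w2(h), b2]
      en         : [Wx(h*p), Wh(h*h), b1(h), w2(h), b2]

    ``scale``/``offset`` map integer samples into the network range:
    ``u = (x - offset) / scale``.  Elman models carry a mutable hidden
    context which must be reset (``reset_context``) at every block start so
    encoder and decoder agree without transmitting state.
    """

    config: PredictorConfig
    parameters: np.ndarray
    scale: float
    offset: float = 0.0
    epochs_run: int = 0
    final_mse: float = math.nan
    _context: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=np.float64).ravel()
        expect = parameter_count(self.config.kind, self.config.order,
                                 self.config.hidden_units)
        if len(self.parameters) != expect:
            raise ValueError(
                f"{self.config.kind}: expected {expect} parameters, "
                f"got {len(self.parameters)}"
            )
        if self.config.kind == "en" and self._context is None:
            self._context = np.zeros(self.config.hidden_units)

    # -- structure ---------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def _unpack(self):
        p, h = self.config.order, self.config.hidden_units
        th = self.parameters
        if self.config.kind in ("slp", "ar", "fir"):
            return th[:p], th[p]
        if self.config.kind == "mlp":
            i = 0
            W1 = th[i:i + h * p].reshape(h, p); i += h * p
            b1 = th[i:i + h]; i += h
            w2 = th[i:i + h]; i += h
            return W1, b1, w2, th[i]
        i = 0
        Wx = th[i:i + h * p].reshape(h, p); i += h * p
        Wh = th[i:i + h * h].reshape(h, h); i += h * h
        b1 = th[i:i + h]; i += h
        w2 = th[i:i + h]; i += h
        return Wx, Wh, b1, w2, th[i]

    def reset_context(self) -> None:
        """Zero the Elman hidden context (no-op for other kinds)."""
        if self.config.kind == "en":
            self._context = np.zeros(self.config.hidden_units)

    def round_to_float32(self) -> "PredictorModel":
        """Model with parameters rounded to IEEE-754 single precision.

        The bitstream stores weights at 32 bits; both codec ends must
        predict with the rounded values.
        """
        return PredictorModel(
            config=self.config,
            parameters=self.parameters.astype(np.float32).astype(np.float64),
            scale=self.scale, offset=self.offset,
            epochs_run=self.epochs_run, final_mse=self.final_mse,
        )

    # -- prediction --------------------------------------------------------
    def predict(self, window: Iterable[float]) -> float:
        """Predict the next sample from the p most recent samples.

        ``window[0]`` is the most recent sample.  Elman models advance their
        context as a side effect.
        """
        u = (np.asarray(window, dtype=np.float64) - self.offset) / self.scale
        if len(u) != self.config.order:
            raise ValueError(
                f"window length {len(u)} != predictor order {self.config.order}"
            )
        kind = self.config.kind
        if kind in ("slp", "ar", "fir"):
            taps, bias = self._unpack()
            y = float(taps @ u + bias)
        elif kind == "mlp":
            W1, b1, w2, b2 = self._unpack()
            a = _logsig(W1 @ u + b1)
            y = float(w2 @ a + b2)
        else:
            Wx, Wh, b1, w2, b2 = self._unpack()
            hid = np.tanh(Wx @ u + Wh @ self._context + b1)
            self._context = hid
            y = float(w2 @ hid + b2)
        return y * self.scale + self.offset

    def predict_batch(self, windows: np.ndarray) -> np.ndarray:
        """Vectorised prediction on an (N, p) window matrix.

        For the Elman network the recurrence is replayed sequentially from a
        zero context; for all other kinds this is a single matrix product.
        """
        U = (np.asarray(windows, dtype=np.float64) - self.offset) / self.scale
        kind = self.config.kind
        if kind in ("slp", "ar", "fir"):
            taps, bias = self._unpack()
            y = U @ taps + bias
        elif kind == "mlp":
            W1, b1, w2, b2 = self._unpack()
            y = _logsig(U @ W1.T + b1) @ w2 + b2
        else:
            Wx, Wh, b1, w2, b2 = self._unpack()
            h = np.zeros(self.config.hidden_units)
            y = np.empty(len(U))
            for i, u in enumerate(U):
                h = np.tanh(Wx @ u + Wh @ h + b1)
                y[i] = w2 @ h + b2
        return y * self.scale + self.offset


def predict_next(model: PredictorModel, window: Iterable[float]) -> float:
    """Functional alias for :meth:`PredictorModel.predict`."""
    return model.predict(window)


# ---------------------------------------------------------------------------
# training data
# ---------------------------------------------------------------------------

def _as_samples(record) -> tuple[np.ndarray, int]:
    """Extract a 1-D sample array + bit depth from a record/array."""
    if isinstance(record, EEGRecord):
        if record.n_channels != 1:
            raise ValueError(
                "predictors operate per channel; pass record.channel(i)"
            )
        return record.channel(0).astype(np.float64), record.bit_depth
    arr = np.asarray(record, dtype=np.float64).ravel()
    return arr, 16


def _windows(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """(N, p) matrix of past windows (most recent first) and targets."""
    W = sliding_window_view(x, p)[:-1][:, ::-1]
    return np.ascontiguousarray(W), x[p:]


def _logsig(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Levenberg-Marquardt (slp / mlp)
# ---------------------------------------------------------------------------

def _forward_jacobian(kind: str, theta: np.ndarray, U: np.ndarray, h: int):
    """Predictions and Jacobian d y_i / d theta_j for slp/mlp."""
    N, p = U.shape
    if kind == "slp":
        J = np.hstack([U, np.ones((N, 1))])
        return J @ theta, J
    i = 0
    W1 = theta[i:i + h * p].reshape(h, p); i += h * p
    b1 = theta[i:i + h]; i += h
    w2 = theta[i:i + h]; i += h
    b2 = theta[i]
    A = _logsig(U @ W1.T + b1)                   # (N, h)
    y = A @ w2 + b2
    G = (w2 * A * (1.0 - A))                     # (N, h): dy/dz
    J = np.hstack([
        (G[:, :, None] * U[:, None, :]).reshape(N, h * p),  # dW1
        G,                                                   # db1
        A,                                                   # dw2
        np.ones((N, 1)),                                     # db2
    ])
    return y, J


def _train_lm(kind: str, theta: np.ndarray, U: np.ndarray, t: np.ndarray,
              h: int, max_epochs: int, error_goal: float):
    """Full-batch Levenberg-Marquardt with standard damping schedule."""
    lam = 1e-3
    y, J = _forward_jacobian(kind, theta, U, h)
    r = t - y
    mse = float(r @ r / len(r))
    best = (theta.copy(), mse)
    epochs = 0
    for epoch in range(max_epochs):
        epochs = epoch + 1
        if mse <= error_goal:
            break
        improved = False
        for _ in range(12):                      # inner damping attempts
            A = J.T @ J + lam * np.eye(len(theta))
            g = J.T @ r
            try:
                step = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(A, g, rcond=None)
            cand = theta + step
            y_c, J_c = _forward_jacobian(kind, cand, U, h)
            r_c = t - y_c
            mse_c = float(r_c @ r_c / len(r_c))
            if not math.isfinite(mse_c):
                raise TrainingError(
                    f"LM diverged (non-finite loss) at epoch {epoch}, lambda={lam:g}"
                )
            if mse_c < mse:
                theta, y, J, r, mse = cand, y_c, J_c, r_c, mse_c
                lam = max(lam / 10.0, 1e-12)
                improved = True
                break
            lam *= 10.0
            if lam > 1e10:
                break
        if mse < best[1]:
            best = (theta.copy(), mse)
        if not improved:
            break
    return best[0], epochs, best[1]


# ---------------------------------------------------------------------------
# GDX (Elman)
# ---------------------------------------------------------------------------

def _en_forward(theta: np.ndarray, U: np.ndarray, p: int, h: int):
    """Teacher-forced Elman forward pass over the whole sequence.

    Returns predictions, hidden activations H (N, h) and the contexts
    C (N, h) seen by each step (C[0] = 0, C[i] = H[i-1]).
    """
    i = 0
    Wx = theta[i:i + h * p].reshape(h, p); i += h * p
    Wh = theta[i:i + h * h].reshape(h, h); i += h * h
    b1 = theta[i:i + h]; i += h
    w2 = theta[i:i + h]; i += h
    b2 = theta[i]
    N = len(U)
    H = np.empty((N, h))
    C = np.empty((N, h))
    ctx = np.zeros(h)
    for n in range(N):
        C[n] = ctx
        ctx = np.tanh(Wx @ U[n] + Wh @ ctx + b1)
        H[n] = ctx
    y = H @ w2 + b2
    return y, H, C, w2


def _en_gradient(theta: np.ndarray, U: np.ndarray, t: np.ndarray,
                 p: int, h: int):
    """MSE and its gradient with one-step-truncated (Elman-style) credit."""
    y, H, C, w2 = _en_forward(theta, U, p, h)
    r = y - t
    N = len(t)
    mse = float(r @ r / N)
    G = (2.0 / N) * r[:, None] * (w2 * (1.0 - H * H))     # (N, h): dE/dz
    gWx = (G[:, :, None] * U[:, None, :]).sum(axis=0).ravel()
    gWh = (G[:, :, None] * C[:, None, :]).sum(axis=0).ravel()
    gb1 = G.sum(axis=0)
    gw2 = (2.0 / N) * (r @ H)
    gb2 = (2.0 / N) * r.sum()
    grad = np.concatenate([gWx, gWh, gb1, gw2, [gb2]])
    return mse, grad


def _train_gdx(theta: np.ndarray, U: np.ndarray, t: np.ndarray,
               p: int, h: int, max_epochs: int, error_goal: float,
               lr: float = 0.01, momentum: float = 0.9,
               lr_up: float = 1.05, lr_down: float = 0.7,
               max_err_ratio: float = 1.04):
    """Gradient descent w/ momentum + adaptive learning rate (GDX).

    A tentative update is rejected (and the learning rate reduced) when the
    error grows by more than ``max_err_ratio``; otherwise it is accepted and
    the learning rate grows whenever the error decreased.
    """
    mse, grad = _en_gradient(theta, U, t, p, h)
    velocity = np.zeros_like(theta)
    best = (theta.copy(), mse)
    epochs = 0
    for epoch in range(max_epochs):
        epochs = epoch + 1
        if mse <= error_goal:
            break
        v_c = momentum * velocity - lr * grad
        cand = theta + v_c
        mse_c, grad_c = _en_gradient(cand, U, t, p, h)
        if not math.isfinite(mse_c):
            raise TrainingError(f"GDX diverged (non-finite loss) at epoch {epoch}")
        if mse_c > mse * max_err_ratio:
            lr *= lr_down
            velocity[:] = 0.0
            continue
        if mse_c < mse:
            lr *= lr_up
        theta, mse, grad, velocity = cand, mse_c, grad_c, v_c
        if mse < best[1]:
            best = (theta.copy(), mse)
    return best[0], epochs, best[1]


# ---------------------------------------------------------------------------
# public training entry points
# ---------------------------------------------------------------------------

def train_predictor(record, config: PredictorConfig) -> PredictorModel:
    """Train a predictor of the configured kind on one channel of data.

    Guarantees that the returned model's open-loop residual MSE on the
    training data does not exceed that of the zero predictor (which predicts
    0 for every normalised sample); if an unlucky training run ends worse,
    the model falls back to zero output and this is logged.
    """
    x, bit_depth = _as_samples(record)
    p = config.order
    if len(x) <= 10 * p:
        raise ValueError(
            f"record too short: need > {10 * p} samples for order {p}, got {len(x)}"
        )
    if config.kind == "ar":
        return fit_ar(x, p)
    if config.kind == "fir":
        return fit_fir(x, p)

    scale = float(1 << (bit_depth - 1))
    u = x / scale
    U, t = _windows(u, p)
    h = config.hidden_units
    rng = np.random.default_rng(config.seed)
    theta0 = rng.uniform(-0.5, 0.5, parameter_count(config.kind, p, h))

    if config.kind in ("slp", "mlp"):
        theta, epochs, mse = _train_lm(config.kind, theta0, U, t, h,
                                       config.max_epochs, config.error_goal)
    else:
        theta, epochs, mse = _train_gdx(theta0, U, t, p, h,
                                        config.max_epochs, config.error_goal)

    zero_mse = float(t @ t / len(t))
    if mse > zero_mse:
        logger.warning(
            "%s training (mse=%.3g) worse than zero predictor (mse=%.3g); "
            "falling back to zero output", config.kind, mse, zero_mse,
        )
        theta = np.zeros_like(theta)
        mse = zero_mse
    model = PredictorModel(config=config, parameters=theta, scale=scale,
                           epochs_run=epochs, final_mse=mse)
    model.reset_context()
    return model


def fit_ar(record, p: int) -> PredictorModel:
    """Least-squares AR(p) one-step predictor (covariance method).

    No intercept: EEG residual coding assumes near-zero-mean signals and a
    zero intercept keeps the model comparable with Yule-Walker estimates.
    Rank-deficient normal equations (e.g. constant signals) fall back to the
    last-value predictor.
    """
    x, bit_depth = _as_samples(record)
    if p < 1:
        raise ValueError("order must be >= 1")
    if len(x) <= 10 * p:
        raise ValueError(f"record too short for order {p}")
    scale = float(1 << (bit_depth - 1))
    U, t = _windows(x / scale, p)
    coeffs, _, rank, _ = np.linalg.lstsq(U, t, rcond=None)
    if rank < p:
        logger.warning("AR(%d) normal equations rank-deficient (rank %d); "
                       "using last-value predictor", p, rank)
        coeffs = np.zeros(p)
        coeffs[0] = 1.0
    cfg = PredictorConfig(kind="ar", order=p, trainer="least_squares",
                          max_epochs=1)
    resid = t - U @ coeffs
    return PredictorModel(config=cfg, parameters=np.append(coeffs, 0.0),
                          scale=scale, epochs_run=1,
                          final_mse=float(resid @ resid / len(resid)))


def fit_fir(record, p: int) -> PredictorModel:
    """Wiener FIR one-step predictor via the autocorrelation method.

    Solves the Toeplitz normal equations built from the biased sample
    autocorrelation — the classic fixed linear predictor design.
    """
    x, bit_depth = _as_samples(record)
    if p < 1:
        raise ValueError("order must be >= 1")
    if len(x) <= 10 * p:
        raise ValueError(f"record too short for order {p}")
    scale = float(1 << (bit_depth - 1))
    u = x / scale
    n = len(u)
    r = np.array([u[: n - k] @ u[k:] / n for k in range(p + 1)])
    if r[0] <= 0:
        logger.warning("FIR design on zero-power signal; last-value predictor")
        coeffs = np.zeros(p)
        coeffs[0] = 1.0
    else:
        try:
            coeffs = solve_toeplitz(r[:p], r[1:p + 1])
        except np.linalg.LinAlgError:
            logger.warning("FIR Toeplitz system singular; last-value predictor")
            coeffs = np.zeros(p)
            coeffs[0] = 1.0
    cfg = PredictorConfig(kind="fir", order=p, trainer="least_squares",
                          max_epochs=1)
    U, t = _windows(u, p)
    resid = t - U @ coeffs
    return PredictorModel(config=cfg, parameters=np.append(coeffs, 0.0),
                          scale=scale, epochs_run=1,
                          final_mse=float(resid @ resid / len(resid)))


def open_loop_residues(model: PredictorModel, record) -> np.ndarray:
    """Prediction residues e_n = X_n - X^_n on the *original* samples.

    Length is ``v - p``.  Used to fix the threshold scale before the
    closed-loop encoding pass; the Elman context is reset first so the
    residues are reproducible.
    """
    x, _ = _as_samples(record)
    p = model.config.order
    if len(x) <= p:
        raise ValueError("record shorter than predictor order")
    W, targets = _windows(x, p)
    model.reset_context()
    preds = model.predict_batch(W)
    model.reset_context()
    return targets - preds
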