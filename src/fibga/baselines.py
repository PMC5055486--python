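"""Gradient-based comparison trainers: back-propagation (BP) and
modification-of-weights (MW).

Both minimize the full-batch squared error through the tansig hidden layer
and linear output.  The default optimizer is Levenberg-Marquardt, which on
the XOR task converges in a handful of epochs; plain gradient descent is
selectable.  The reported/termination metric is always the mean absolute
error, matching the rest of the package.

MW is BP plus a hard magnitude constraint: after every accepted update each
parameter is clamped to [-theta, +theta], which spreads representation over
more weights instead of letting a few grow dominant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ga import TrainResult
from .network import FeedforwardNet, NetworkConfig, random_parameters, tansig
from .problems import Dataset, mean_abs_error

__all__ = [
    "BPConfig",
    "MWConfig",
    "loss_and_gradient",
    "residual_jacobian",
    "train_bp",
    "train_mw",
]


@dataclass(frozen=True)
class BPConfig:
    algorithm: str = "levenberg_marquardt"  # or "gradient_descent"
    learning_rate: float = 0.1  # gradient_descent only
    max_epochs: int = 1000
    error_tolerance: float = 0.001
    damping_initial: float = 1e-3  # LM only
    damping_factor: float = 10.0  # LM only
    init_bounds: tuple = (-1.0, 1.0)

    def __post_init__(self):
        if self.algorithm not in ("levenberg_marquardt", "gradient_descent"):
            raise ValueError("unknown algorithm")
        if self.learning_rate <= 0 or self.error_tolerance <= 0:
            raise ValueError("rates and tolerances must be positive")


@dataclass(frozen=True)
class MWConfig:
    base: BPConfig = field(default_factory=BPConfig)
    weight_threshold: float = 2.0

    def __post_init__(self):
        if self.weight_threshold <= 0:
            raise ValueError("weight_threshold must be positive")


def _unpack(params: np.ndarray, H: int):
    W = params[: 2 * H].reshape(2, H)
    b = params[2 * H : 3 * H]
    v = params[3 * H : 4 * H]
    b_out = params[4 * H]
    return W, b, v, b_out


def residual_jacobian(params: np.ndarray, inputs: np.ndarray, targets: np.ndarray, n_hidden: int):
    """Residuals r_p = c_p − y_p and their Jacobian wrt the canonical vector.

    Analytic backprop through one tansig layer: with h = tanh(x) the output
    derivatives are dc/dv_j = h_j, dc/db_out = 1, dc/dw_ij = a_i v_j (1−h_j²),
    dc/db_j = v_j (1−h_j²).  Shapes: r (N,), J (N, 4H+1).
    """
    H = n_hidden
    W, b, v, b_out = _unpack(np.asarray(params, dtype=float), H)
    X = np.asarray(inputs, dtype=float)
    h = tansig(X @ W + b)  # (N, H)
    r = h @ v + b_out - np.asarray(targets, dtype=float)
    sech2 = 1.0 - h * h
    J = np.empty((X.shape[0], 4 * H + 1))
    back = sech2 * v  # (N, H)
    J[:, :H] = X[:, [0]] * back
    J[:, H : 2 * H] = X[:, [1]] * back
    J[:, 2 * H : 3 * H] = back
    J[:, 3 * H : 4 * H] = h
    J[:, 4 * H] = 1.0
    return r, J


def loss_and_gradient(params: np.ndarray, inputs: np.ndarray, targets: np.ndarray, n_hidden: int):
    """Half sum-of-squares loss and its gradient (J^T r)."""
    r, J = residual_jacobian(params, inputs, targets, n_hidden)
    return 0.5 * float(r @ r), J.T @ r


def _train_gradient(
    problem: Dataset,
    config: BPConfig,
    net_config: NetworkConfig,
    rng: Optional[np.random.Generator],
    seed: Optional[int],
    clamp: Optional[float],
) -> TrainResult:
    if rng is None:
        rng = np.random.default_rng(seed)
    X, y = problem.inputs, problem.targets
    H = net_config.n_hidden
    params = random_parameters(net_config, rng, config.init_bounds)
    if clamp is not None:
        np.clip(params, -clamp, clamp, out=params)

    lam = config.damping_initial
    trace = []
    reason = "max_iterations"
    terminated_at = None
    for epoch in range(1, config.max_epochs + 1):
        r, J = residual_jacobian(params, X, y, H)
        if not np.all(np.isfinite(r)):
            reason = "diverged"
            terminated_at = epoch - 1
            break
        if config.algorithm == "gradient_descent":
            params = params - config.learning_rate * (J.T @ r)
        else:
            loss = 0.5 * float(r @ r)
            A = J.T @ J
            g = J.T @ r
            accepted = False
            while lam < 1e12:
                try:
                    delta = np.linalg.solve(A + lam * np.eye(A.shape[0]), -g)
                except np.linalg.LinAlgError:
                    lam *= config.damping_factor
                    continue
                trial = params + delta
                if clamp is not None:
                    np.clip(trial, -clamp, clamp, out=trial)
                r_trial, _ = residual_jacobian(trial, X, y, H)
                if np.all(np.isfinite(r_trial)) and 0.5 * float(r_trial @ r_trial) < loss:
                    params = trial
                    lam = max(lam / config.damping_factor, 1e-12)
                    accepted = True
                    break
                lam *= config.damping_factor
            # no improving step found: keep params, continue (next epoch retries)
        if clamp is not None:
            np.clip(params, -clamp, clamp, out=params)
        err = mean_abs_error(
            FeedforwardNet.from_vector(net_config, params).forward(X), y
        )
        trace.append(err)
        if err < config.error_tolerance:
            reason = "tolerance"
            terminated_at = epoch
            break

    net = FeedforwardNet.from_vector(net_config, params)
    final = mean_abs_error(net.forward(X), y)
    return TrainResult(
        best_net=net,
        best_error_trace=np.array(trace),
        terminated_at=len(trace),
        termination_reason=reason,
        final_error=final,
        seed=seed,
    )


def train_bp(
    problem: Dataset,
    config: BPConfig = BPConfig(),
    net_config: NetworkConfig = NetworkConfig(n_hidden=6),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> TrainResult:
    """Back-propagation training from a random init (symmetric zero init is a
    saddle, so initialization matters)."""
    return _train_gradient(problem, config, net_config, rng, seed, clamp=None)


def train_mw(
    problem: Dataset,
    config: MWConfig = MWConfig(),
    net_config: NetworkConfig = NetworkConfig(n_hidden=6),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> TrainResult:
    """Weight-magnitude-limited BP: every update is clamped to ±threshold."""
    return _train_gradient(
        problem, config.base, net_config, rng, seed, clamp=config.weight_threshold
    )
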