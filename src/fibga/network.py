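"""Three-layer feedforward network, flat parameter encoding, stuck-at-zero faults.

The network is fixed-topology 2 -> H -> 1: two input units, H hidden units
with a tansig (hyperbolic tangent) activation, and a single *linear* output
unit.  The linear output is deliberate — the output is the raw weighted sum
of hidden activations plus the output bias, with no squashing — and every
error metric in this package assumes it.

All parameters live in a canonical flat vector of length 4H + 1::

    [w_11 .. w_1H,  w_21 .. w_2H,  b_1 .. b_H,  v_1 .. v_H,  b_out]

i.e. hidden-layer weights row-major by (input, hidden), then hidden biases,
then hidden->output weights, then the output bias.  This ordering is frozen:
the genetic algorithm's genome, the fault-injection fitness and the
exhaustive fault enumeration all index into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkConfig",
    "FeedforwardNet",
    "FaultMask",
    "tansig",
    "forward_batch",
    "apply_faults",
    "neuron_parameter_indices",
    "random_parameters",
    "random_network",
]


def tansig(x):
    """Hyperbolic-tangent sigmoid (1 - e^(-2x)) / (1 + e^(-2x)).

    Identical to tanh; evaluated through :func:`numpy.tanh` so it saturates
    cleanly for large ``|x|`` instead of overflowing the exponentials.
    """
    return np.tanh(x)


@dataclass(frozen=True)
class NetworkConfig:
    """Topology of the 2 -> n_hidden -> 1 network.

    ``n_input`` and ``n_output`` are fixed by the architecture; ``n_hidden``
    is free (the benchmark experiments use 3, 6 or 9).
    """

    n_hidden: int
    n_input: int = 2
    n_output: int = 1

    def __post_init__(self):
        if self.n_input != 2 or self.n_output != 1:
            raise ValueError("topology is fixed to 2 inputs and 1 output")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")

    @property
    def n_params(self) -> int:
        """Total parameter count: 2H hidden weights + H biases + H output weights + 1."""
        return 4 * self.n_hidden + 1


@dataclass
class FeedforwardNet:
    """Weights and biases of one network.

    hidden_weights: shape (2, H), entry [i, j] connects input i to hidden j.
    hidden_biases:  shape (H,)
    output_weights: shape (H,), hidden j to the output unit.
    output_bias:    scalar.
    """

    config: NetworkConfig
    hidden_weights: np.ndarray
    hidden_biases: np.ndarray
    output_weights: np.ndarray
    output_bias: float

    def __post_init__(self):
        H = self.config.n_hidden
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.output_bias = float(self.output_bias)
        if self.hidden_weights.shape != (2, H):
            raise ValueError(f"hidden_weights must have shape (2, {H})")
        if self.hidden_biases.shape != (H,):
            raise ValueError(f"hidden_biases must have shape ({H},)")
        if self.output_weights.shape != (H,):
            raise ValueError(f"output_weights must have shape ({H},)")
        for a in (self.hidden_weights, self.hidden_biases, self.output_weights):
            if not np.all(np.isfinite(a)):
                raise ValueError("network parameters must be finite")
        if not np.isfinite(self.output_bias):
            raise ValueError("network parameters must be finite")

    # -- flat-vector encoding -------------------------------------------------

    def to_vector(self) -> np.ndarray:
        """Canonical flat parameter vector of length 4H + 1 (lossless)."""
        return np.concatenate(
            [
                self.hidden_weights.reshape(-1),
                self.hidden_biases,
                self.output_weights,
                [self.output_bias],
            ]
        )

    @classmethod
    def from_vector(cls, config: NetworkConfig, vec: np.ndarray) -> "FeedforwardNet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (config.n_params,):
            raise ValueError(
                f"parameter vector must have length {config.n_params}, got {vec.shape}"
            )
        H = config.n_hidden
        return cls(
            config=config,
            hidden_weights=vec[: 2 * H].reshape(2, H).copy(),
            hidden_biases=vec[2 * H : 3 * H].copy(),
            output_weights=vec[3 * H : 4 * H].copy(),
            output_bias=float(vec[4 * H]),
        )

    # -- evaluation -----------------------------------------------------------

    def forward(self, inputs: np.ndarray) -> np.ndarray:
        """Outputs c_p for an (N, 2) input matrix: linear readout of tansig units."""
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        if inputs.shape[1] != 2:
            raise ValueError("inputs must have shape (N, 2)")
        hidden = tansig(inputs @ self.hidden_weights + self.hidden_biases)
        return hidden @ self.output_weights + self.output_bias


def forward_batch(params: np.ndarray, inputs: np.ndarray, n_hidden: int) -> np.ndarray:
    """Evaluate many parameter vectors at once.

    params: (B, 4H+1) stack of canonical vectors; inputs: (N, 2).
    Returns (B, N) outputs.  Used heavily by the GA fitness functions and the
    exhaustive fault sweeps, where B runs into the thousands.
    """
    params = np.asarray(params, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    H = n_hidden
    if params.ndim != 2 or params.shape[1] != 4 * H + 1:
        raise ValueError(f"params must have shape (B, {4 * H + 1})")
    W = params[:, : 2 * H].reshape(-1, 2, H)
    b = params[:, 2 * H : 3 * H]
    v = params[:, 3 * H : 4 * H]
    b_out = params[:, 4 * H]
    hidden = tansig(np.einsum("ni,bih->bnh", inputs, W) + b[:, None, :])
    return np.einsum("bnh,bh->bn", hidden, v) + b_out[:, None]


@dataclass(frozen=True)
class FaultMask:
    """A set of stuck-at-zero faults.

    mode "parameter": indices are positions in the canonical parameter vector
    (0 .. 4H).  mode "neuron": indices are hidden-unit positions (0 .. H-1);
    voiding a unit zeroes its two incoming weights, its bias and its outgoing
    weight, so the unit contributes nothing for any input.
    An empty index set is the fault-free network.
    """

    mode: str
    indices: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.mode not in ("parameter", "neuron"):
            raise ValueError("mode must be 'parameter' or 'neuron'")
        object.__setattr__(self, "indices", frozenset(int(i) for i in self.indices))

    def validate(self, config: NetworkConfig) -> None:
        limit = config.n_params if self.mode == "parameter" else config.n_hidden
        for i in self.indices:
            if not 0 <= i < limit:
                raise ValueError(f"fault index {i} out of range for mode {self.mode}")

    def parameter_indices(self, config: NetworkConfig) -> np.ndarray:
        """Expand to positions in the canonical parameter vector."""
        if self.mode == "parameter":
            return np.array(sorted(self.indices), dtype=int)
        idx = []
        for j in self.indices:
            idx.extend(neuron_parameter_indices(j, config.n_hidden))
        return np.array(sorted(idx), dtype=int)


def neuron_parameter_indices(j: int, n_hidden: int) -> tuple:
    """Canonical-vector positions of hidden unit j: w_1j, w_2j, b_j, v_j."""
    H = n_hidden
    if not 0 <= j < H:
        raise ValueError(f"hidden index {j} out of range")
    return (j, H + j, 2 * H + j, 3 * H + j)


def apply_faults(net: FeedforwardNet, mask: FaultMask) -> FeedforwardNet:
    """Return a copy of ``net`` with the masked positions forced to zero.

    Pure: the input network is never modified.  Idempotent by construction.
    """
    mask.validate(net.config)
    vec = net.to_vector()
    idx = mask.parameter_indices(net.config)
    if idx.size:
        vec[idx] = 0.0
    return FeedforwardNet.from_vector(net.config, vec)


def random_parameters(
    config: NetworkConfig,
    rng: np.random.Generator,
    bounds: tuple = (-1.0, 1.0),
) -> np.ndarray:
    """Draw a parameter vector i.i.d. uniform on ``bounds`` (default [-1, 1])."""
    lo, hi = bounds
    return rng.uniform(lo, hi, size=config.n_params)


def random_network(
    config: NetworkConfig,
    rng: np.random.Generator,
    bounds: tuple = (-1.0, 1.0),
) -> FeedforwardNet:
    """Random network with every parameter uniform on ``bounds``."""
    return FeedforwardNet.from_vector(config, random_parameters(config, rng, bounds))
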