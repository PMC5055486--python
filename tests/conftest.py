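import numpy as np
import pytest

from fibga import FeedforwardNet, NetworkConfig, xor_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def xor():
    return xor_dataset()


@pytest.fixture
def net6(rng):
    from fibga import random_network

    return random_network(NetworkConfig(n_hidden=6), rng)


def exact_xor_net(n_hidden: int = 6, gain: float = 20.0) -> FeedforwardNet:
    """Hand-built near-exact XOR solver: two saturated threshold units at
    a1+a2 = 0.5 and 1.5, read out as (h1 - h2)/2; spare units inert."""
    config = NetworkConfig(n_hidden=n_hidden)
    W = np.zeros((2, n_hidden))
    b = np.zeros(n_hidden)
    v = np.zeros(n_hidden)
    W[:, 0] = gain
    b[0] = -0.5 * gain
    W[:, 1] = gain
    b[1] = -1.5 * gain
    v[0], v[1] = 0.5, -0.5
    return FeedforwardNet(
        config=config,
        hidden_weights=W,
        hidden_biases=b,
        output_weights=v,
        output_bias=0.0,
    )


def scalar_loop_forward(net: FeedforwardNet, inputs: np.ndarray) -> np.ndarray:
    """Naive per-neuron loop oracle for the forward pass."""
    out = []
    for row in np.atleast_2d(inputs):
        total = net.output_bias
        for j in range(net.config.n_hidden):
            xj = net.hidden_biases[j]
            for i in range(2):
                xj += row[i] * net.hidden_weights[i, j]
            total += np.tanh(xj) * net.output_weights[j]
        out.append(total)
    return np.array(out)
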