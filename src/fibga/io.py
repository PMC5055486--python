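"""Flat-text serialization: networks and training results as JSON, traces
and datasets as CSV.  Parameter values are stored at full double precision
(repr round-trip) in the canonical vector order."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ga import TrainResult
from .network import FeedforwardNet, NetworkConfig

__all__ = [
    "network_record",
    "network_from_record",
    "save_network",
    "load_network",
    "save_train_result",
    "save_trace_csv",
]


def network_record(net: FeedforwardNet) -> dict:
    return {
        "n_input": net.config.n_input,
        "n_hidden": net.config.n_hidden,
        "n_output": net.config.n_output,
        "parameter_order": "hidden_weights_row_major, hidden_biases, output_weights, output_bias",
        "parameters": net.to_vector().tolist(),
    }


def network_from_record(record: dict) -> FeedforwardNet:
    config = NetworkConfig(n_hidden=int(record["n_hidden"]))
    return FeedforwardNet.from_vector(config, np.asarray(record["parameters"]))


def save_network(net: FeedforwardNet, path) -> None:
    Path(path).write_text(json.dumps(network_record(net), indent=1))


def load_network(path) -> FeedforwardNet:
    return network_from_record(json.loads(Path(path).read_text()))


def save_train_result(result: TrainResult, path, config_echo: dict | None = None) -> None:
    record = {
        "seed": result.seed,
        "terminated_at": result.terminated_at,
        "termination_reason": result.termination_reason,
        "final_error": result.final_error,
        "best_error_trace": result.best_error_trace.tolist(),
        "network": network_record(result.best_net),
    }
    if config_echo:
        record["config"] = config_echo
    Path(path).write_text(json.dumps(record, indent=1))


def save_trace_csv(result: TrainResult, path) -> None:
    pd.DataFrame(
        {
            "generation": np.arange(1, len(result.best_error_trace) + 1),
            "best_error": result.best_error_trace,
        }
    ).to_csv(path, index=False)
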