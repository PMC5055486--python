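"""Exhaustive stuck-at-zero fault evaluation and replicate aggregation.

Given a trained network, every k-subset of parameters (or of hidden
neurons) is forced to zero and the resulting degradation measured: on XOR
the mean absolute error per fault set plus the fraction of sets at or above
an error threshold (default 0.4); on the overlapping-classification task
the per-class relative correct rates.  Enumeration is always exhaustive —
the largest case used anywhere, C(37,4), is small.

Also here: the 20-replicate experiment driver, the parameter-category /
error correlation analysis, and the exponential learning-curve fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .baselines import BPConfig, MWConfig, train_bp, train_mw
from .ga import GAConfig, TrainResult, train_ga
from .network import (
    FeedforwardNet,
    NetworkConfig,
    forward_batch,
    neuron_parameter_indices,
)
from .problems import (
    CIRCLE,
    SQUARE,
    Dataset,
    OverlapSpec,
    generate_overlap,
    xor_dataset,
)

__all__ = [
    "FaultReport",
    "RCRFaultReport",
    "ReplicateSummary",
    "ReplicateResults",
    "ExponentialFit",
    "enumerate_fault_sets",
    "error_rate",
    "fault_error_profile",
    "fault_rcr_profile",
    "run_replicates",
    "category_correlation",
    "fit_exponential",
]

DEFAULT_THRESHOLD = 0.4
TRAINERS = ("bp", "mw", "ge_ga", "fib_ga")


def enumerate_fault_sets(n_items: int, k: int) -> List[Tuple[int, ...]]:
    """All k-subsets of range(n_items) in lexicographic order."""
    if not 0 <= k <= n_items:
        raise ValueError("k must satisfy 0 <= k <= n_items")
    return list(itertools.combinations(range(n_items), k))


def error_rate(errors: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of errors at or above the threshold (inclusive boundary)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("errors must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(np.mean(errors >= threshold))


def _faulted_param_stack(net: FeedforwardNet, mode: str, k: int):
    """Stack of parameter vectors, one per fault set, plus the set list."""
    cfg = net.config
    vec = net.to_vector()
    if mode == "parameter":
        n_items = cfg.n_params
        expand = lambda s: np.array(s, dtype=int)
    elif mode == "neuron":
        n_items = cfg.n_hidden
        expand = lambda s: np.array(
            [p for j in s for p in neuron_parameter_indices(j, cfg.n_hidden)], dtype=int
        )
    else:
        raise ValueError("mode must be 'parameter' or 'neuron'")
    sets = enumerate_fault_sets(n_items, k)
    stack = np.repeat(vec[None, :], len(sets), axis=0)
    for row, s in enumerate(sets):
        idx = expand(s)
        if idx.size:
            stack[row, idx] = 0.0
    return stack, sets


@dataclass
class FaultReport:
    """Error profile of one network over every fault set of one (mode, k)."""

    mode: str
    k: int
    fault_sets: List[Tuple[int, ...]]
    per_set_errors: np.ndarray
    mean_error: float
    error_rate: float
    threshold: float = DEFAULT_THRESHOLD


@dataclass
class RCRFaultReport:
    """Per-class relative correct rates over every fault set of one (mode, k)."""

    mode: str
    k: int
    fault_sets: List[Tuple[int, ...]]
    rcr_square: np.ndarray
    rcr_circle: np.ndarray
    mean_square: float
    mean_circle: float


def fault_error_profile(
    net: FeedforwardNet,
    dataset: Dataset,
    mode: str = "parameter",
    k: int = 1,
    threshold: float = DEFAULT_THRESHOLD,
) -> FaultReport:
    """Mean-absolute-error under every k-fault set, with threshold error rate."""
    stack, sets = _faulted_param_stack(net, mode, k)
    outputs = forward_batch(stack, dataset.inputs, net.config.n_hidden)
    errors = np.mean(np.abs(outputs - dataset.targets), axis=1)
    return FaultReport(
        mode=mode,
        k=k,
        fault_sets=sets,
        per_set_errors=errors,
        mean_error=float(errors.mean()),
        error_rate=error_rate(errors, threshold),
        threshold=threshold,
    )


def fault_rcr_profile(
    net: FeedforwardNet, dataset: Dataset, mode: str = "parameter", k: int = 1
) -> RCRFaultReport:
    """Square/circle relative correct rates under every k-fault set."""
    if dataset.labels is None:
        raise ValueError("dataset must carry class labels")
    stack, sets = _faulted_param_stack(net, mode, k)
    outputs = forward_batch(stack, dataset.inputs, net.config.n_hidden)
    sq = dataset.labels == SQUARE
    ci = dataset.labels == CIRCLE
    if not sq.any() or not ci.any():
        raise ValueError("both classes must be present")
    rcr_sq = np.mean(outputs[:, sq] < 0, axis=1) - 0.5
    rcr_ci = np.mean(outputs[:, ci] > 0, axis=1) - 0.5
    return RCRFaultReport(
        mode=mode,
        k=k,
        fault_sets=sets,
        rcr_square=rcr_sq,
        rcr_circle=rcr_ci,
        mean_square=float(rcr_sq.mean()),
        mean_circle=float(rcr_ci.mean()),
    )


# -- replicate experiments ----------------------------------------------------


@dataclass
class ReplicateSummary:
    """Per-replicate values of one metric with mean and sample (n-1) SD."""

    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(np.mean(self.values))
        self.sd = float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def n_replicates(self) -> int:
        return len(self.values)


def _train_one(
    trainer: str,
    dataset: Dataset,
    net_config: NetworkConfig,
    seed: int,
    ga_config: GAConfig,
    bp_config: BPConfig,
    mw_config: MWConfig,
) -> TrainResult:
    rng = np.random.default_rng(seed)
    if trainer == "bp":
        return train_bp(dataset, bp_config, net_config, rng=rng, seed=seed)
    if trainer == "mw":
        return train_mw(dataset, mw_config, net_config, rng=rng, seed=seed)
    if trainer == "ge_ga":
        return train_ga(dataset, ga_config, net_config, "GE", rng=rng, seed=seed)
    if trainer == "fib_ga":
        return train_ga(dataset, ga_config, net_config, "FIB", rng=rng, seed=seed)
    raise ValueError(f"unknown trainer {trainer!r}; expected one of {TRAINERS}")


@dataclass
class ReplicateResults:
    """Trained replicates plus a tidy table of all fault metrics.

    ``records`` has columns (trainer, problem, n_hidden, mode, k, metric,
    replicate, value); metrics are mean_error / error_rate on XOR and
    rcr_square / rcr_circle on the overlap task, each already aggregated
    over the exhaustive fault enumeration within the replicate.
    """

    trainer: str
    problem: str
    net_config: NetworkConfig
    results: List[TrainResult]
    records: pd.DataFrame
    base_seed: int

    def summary(self, mode: str, k: int, metric: str) -> ReplicateSummary:
        df = self.records
        sel = df[(df["mode"] == mode) & (df["k"] == k) & (df["metric"] == metric)]
        if sel.empty:
            raise KeyError(f"no records for ({mode}, {k}, {metric})")
        return ReplicateSummary(sel.sort_values("replicate")["value"].to_numpy())

    def terminating_iterations(self) -> ReplicateSummary:
        return ReplicateSummary([r.terminated_at for r in self.results])

    def final_errors(self) -> ReplicateSummary:
        return ReplicateSummary([r.final_error for r in self.results])


def run_replicates(
    trainer: str,
    problem,
    n_replicates: int,
    eval_plan: Sequence[Tuple[str, int]],
    base_seed: int,
    n_hidden: int = 6,
    threshold: float = DEFAULT_THRESHOLD,
    ga_config: Optional[GAConfig] = None,
    bp_config: Optional[BPConfig] = None,
    mw_config: Optional[MWConfig] = None,
    overlap_spec: Optional[OverlapSpec] = None,
) -> ReplicateResults:
    """Train ``n_replicates`` networks and run the fault plan on each.

    ``problem`` is "xor", "overlap", or a ready :class:`Dataset` (with
    labels for RCR metrics).  Replicate r trains with seed base_seed + r, so
    any replicate can be reproduced in isolation.  The overlap dataset is
    generated once from base_seed and shared by all replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ga_config = ga_config or GAConfig()
    bp_config = bp_config or BPConfig()
    mw_config = mw_config or MWConfig()
    net_config = NetworkConfig(n_hidden=n_hidden)

    if isinstance(problem, Dataset):
        dataset, problem_name = problem, "custom"
    elif problem == "xor":
        dataset, problem_name = xor_dataset(), "xor"
    elif problem == "overlap":
        spec = overlap_spec or OverlapSpec()
        dataset = generate_overlap(spec, np.random.default_rng(base_seed))
        problem_name = "overlap"
    else:
        raise ValueError(f"unknown problem {problem!r}")
    classified = dataset.labels is not None

    results = []
    rows = []
    for rep in range(n_replicates):
        res = _train_one(
            trainer, dataset, net_config, base_seed + rep, ga_config, bp_config, mw_config
        )
        results.append(res)
        for mode, k in eval_plan:
            common = dict(
                trainer=trainer,
                problem=problem_name,
                n_hidden=n_hidden,
                mode=mode,
                k=k,
                replicate=rep,
            )
            if classified:
                rep_rcr = fault_rcr_profile(res.best_net, dataset, mode, k)
                rows.append(dict(common, metric="rcr_square", value=rep_rcr.mean_square))
                rows.append(dict(common, metric="rcr_circle", value=rep_rcr.mean_circle))
            else:
                rep_err = fault_error_profile(res.best_net, dataset, mode, k, threshold)
                rows.append(dict(common, metric="mean_error", value=rep_err.mean_error))
                rows.append(dict(common, metric="error_rate", value=rep_err.error_rate))

    columns = [
        "trainer", "problem", "n_hidden", "mode", "k", "metric", "replicate", "value",
    ]
    records = pd.DataFrame(rows, columns=columns)
    return ReplicateResults(
        trainer=trainer,
        problem=problem_name,
        net_config=net_config,
        results=results,
        records=records,
        base_seed=base_seed,
    )


# -- analysis helpers ---------------------------------------------------------

CATEGORIES = ("hidden_weights", "hidden_biases", "output_weights", "output_bias")


def _category_stat(net: FeedforwardNet, category: str) -> float:
    """Mean absolute parameter value of one category."""
    if category == "hidden_weights":
        return float(np.mean(np.abs(net.hidden_weights)))
    if category == "hidden_biases":
        return float(np.mean(np.abs(net.hidden_biases)))
    if category == "output_weights":
        return float(np.mean(np.abs(net.output_weights)))
    if category == "output_bias":
        return float(abs(net.output_bias))
    raise ValueError(f"unknown category {category!r}")


def category_correlation(
    nets: Sequence[FeedforwardNet], errors: Sequence[float]
) -> Dict[str, Tuple[float, float]]:
    """Pearson r (and two-tailed p) between per-replicate category statistics
    and final training errors.

    The statistic per network is the mean absolute parameter value within
    the category.  A category with zero variance across replicates has an
    undefined correlation and is reported as (nan, nan).
    """
    errors = np.asarray(errors, dtype=float)
    if len(nets) != len(errors) or len(nets) < 3:
        raise ValueError("need >= 3 aligned networks and errors")
    out = {}
    for cat in CATEGORIES:
        x = np.array([_category_stat(net, cat) for net in nets])
        if np.ptp(x) == 0 or np.ptp(errors) == 0:
            out[cat] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(x, errors)
        out[cat] = (float(r), float(p))
    return out


@dataclass
class ExponentialFit:
    a: float
    tau: float
    r_squared: float
    converged: bool


def fit_exponential(trace: np.ndarray) -> ExponentialFit:
    """Least-squares fit of a·e^(−τx) to a learning curve, x = 1..len(trace).

    Returns the fitted amplitude and rate with the coefficient of
    determination; non-convergence is flagged rather than raised.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise ValueError("trace must have length >= 3")
    x = np.arange(1, trace.size + 1, dtype=float)
    model = lambda x, a, tau: a * np.exp(-tau * x)
    a0 = max(trace[0], 1e-12)
    try:
        (a, tau), _ = optimize.curve_fit(
            model, x, trace, p0=[a0, 0.01], maxfev=20000
        )
        converged = True
    except RuntimeError:
        a, tau, converged = a0, 0.0, False
    resid = trace - model(x, a, tau)
    ss_tot = float(np.sum((trace - trace.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ExponentialFit(a=float(a), tau=float(tau), r_squared=r2, converged=converged)
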