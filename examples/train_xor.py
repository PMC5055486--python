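"""Train one XOR network with each of the four trainers and compare speeds.

The gradient trainers (BP, and BP with the +/-2 weight clamp, MW) converge
in a handful of epochs; the genetic algorithms take hundreds of
generations, and the fault-injection variant (FIB-GA) is the slowest
because its objective averages the error over all 25 single-parameter
stuck-at-zero faults instead of just the clean error.
"""

import numpy as np

from fibga import (
    BPConfig,
    GAConfig,
    MWConfig,
    NetworkConfig,
    train_bp,
    train_ga,
    train_mw,
    xor_dataset,
)

xor = xor_dataset()
net_config = NetworkConfig(n_hidden=6)
seed = 0

runs = {
    "BP": train_bp(xor, BPConfig(), net_config, seed=seed),
    "MW": train_mw(xor, MWConfig(), net_config, seed=seed),
    "GE-GA": train_ga(xor, GAConfig(), net_config, "GE", seed=seed),
    "FIB-GA": train_ga(xor, GAConfig(), net_config, "FIB", seed=seed),
}

print(f"{'trainer':8} {'iterations':>10} {'reason':>15} {'final error':>12}")
for name, res in runs.items():
    print(f"{name:8} {res.terminated_at:>10} {res.termination_reason:>15} "
          f"{res.final_error:>12.6f}")
print("\nfinal error = mean |output - target| over the 4 XOR rows;")
print("'tolerance' means it dropped below 0.001 before the 1000-iteration cap.")
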