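# Methods

## Network model

The network is a fixed-topology multilayer perceptron 2→H→1.  Hidden unit
*j* computes `h_j = tansig(w_1j a_1 + w_2j a_2 + b_j)` with
`tansig(x) = (1 − e^{−2x})/(1 + e^{−2x})`, i.e. the hyperbolic tangent
(evaluated via `numpy.tanh` for numerical stability at large |x|).  The
output unit is **linear**: `c = Σ_j h_j v_j + b_out`, with no squashing.
This matters: many frameworks activate the output by default, and every
error metric and fault bound below assumes the linear readout (e.g. the
all-neurons-voided network outputs exactly `b_out`).

All `P = 4H + 1` parameters live in one canonical flat vector —
`[w_11..w_1H, w_21..w_2H, b_1..b_H, v_1..v_H, b_out]` — which is
simultaneously the GA genome, the substrate of fault enumeration, and the
serialization format.  The ordering is arbitrary but frozen; changing it
silently changes which index a "fault at position 17" hits.

## Fault model

A fault is stuck-at-zero: the affected parameter is replaced by exactly 0.
Parameter mode zeroes chosen positions of the flat vector; neuron mode
voids a hidden unit by zeroing its two incoming weights, bias, *and*
outgoing weight.  Zeroing only the outgoing weight would be
output-equivalent; the stronger form is used so a voided unit is inert in
any downstream inspection.  Fault application is pure (the input network is
never mutated) and idempotent.

Robustness of a trained net is measured by exhaustive enumeration: every
k-subset of parameters or neurons, errors per fault set, their mean, and
the *error rate* — the fraction of sets whose error is ≥ 0.4 (boundary
inclusive).  Enumeration is never sampled; the largest case used, C(37, 4),
is 66 045 sets and evaluates in well under a second through the batched
forward pass.

## Error metrics

* Mean absolute error `(1/N) Σ |c_p − y_p|`: the training/termination
  metric everywhere.  The 1/N generalizes the four-sample XOR definition to
  the 1000-sample overlap task.
* Signed per-element errors `c_i − y_i` are available for element-wise
  analyses; their "fluctuation" per run is the sample SD of the four
  signed errors at termination (one of several defensible readings, so it
  is a helper, not a headline number).
* Overlap task: per-class relative correct rate `RCR = N_correct/500 − 0.5`,
  a circle point being correct iff its output is strictly > 0 and a square
  point iff strictly < 0.  An output of exactly 0 is incorrect for both
  classes (the rule is stated with strict inequalities only); RCR is
  invariant to positive rescaling of outputs.

## The genetic algorithm

Population 20, generation cap 1000.  Each new generation is exactly
2 elites (lowest fitness, copied unchanged) + 14 crossover children + 4
mutation children.  Selection: individuals are ranked 1..20 by ascending
fitness (ties broken by population index so ranks stay unique), scaled as
`1/√Rank_i`, normalized by `Σ_{j=1..20} 1/√j = 7.5953`, and sampled by
stochastic universal sampling: one uniform offset in (0, 1/32), 32 equally
spaced cursors, so each individual is chosen ⌊32 P_i⌋ or ⌈32 P_i⌉ times.

The 32-parent list is randomly permuted before being split into 14
consecutive crossover pairs and 4 mutation parents.  The permutation is a
deliberate design choice: SUS emits parents in cursor order, which places
all copies of the same individual adjacently; pairing that list
consecutively crosses individuals with themselves and, empirically, the
plain-fitness GA then never reaches the 0.001 tolerance within 1000
generations.  With the permutation the trainer converges in most runs.

Crossover is uniform (each coordinate from either parent with probability
1/2, via rounding a uniform (0,1) draw).  Mutation adds i.i.d. Gaussian
noise to every coordinate with
`σ(g) = σ_0 (1 − (g−1)/(G−1))`, σ_0 = 1 — linear from 1 at generation 1 to
0 at the cap — and is **anchored to the configured cap** even when a run
stops early.  Mutants are not clipped.  Alternative schedules
(multiplicative per-generation shrink) were evaluated and converge either
much faster or not better; the linear schedule is the model definition
here.

Initial populations are i.i.d. uniform on [−1, 1] per coordinate
(configurable).  No principled value is fixed by the problem; symmetric
bounded initialization is the standard choice for small tanh networks.

### Fitness variants

* GE fitness: clean mean absolute error of the genome.
* FIB fitness: the mean of the clean-error formula over all P
  single-parameter stuck-at-zero variants of the genome; the unfaulted
  genome is *not* included in the average.  Since selection is rank-based,
  the 1/P normalization does not affect evolution, but it makes the fitness
  directly comparable to the single-fault sweep: the mean of the k=1
  parameter-fault profile of a network equals its FIB fitness to machine
  precision (a cross-module identity the tests enforce).

### Termination

Training stops when the *clean* error of the best-by-fitness individual
drops below 0.001, or at the generation cap — one rule for both fitness
variants, so that every trainer is judged against the same condition.  A config switch (`stop_on="fitness"`) stops on the selection
objective instead.  For FIB runs the clean-error rule matters: robustness
optimization continues only while the clean error stays above tolerance,
and most FIB runs ride to the cap (mean terminating generation ≈ 900).
`best_error_trace` records the minimized objective per generation and is
monotone non-increasing by elitism (for FIB runs that is the fault-averaged
error, not the clean error).

## Baseline trainers

BP minimizes half the summed squared error full-batch.  Default optimizer
is Levenberg–Marquardt (damping λ starts at 1e−3, ×10 on rejection, ÷10 on
acceptance): the network has ≤ 37 parameters, so the normal equations are
trivial and LM converges on XOR in single-digit epochs, as expected of
second-order training on so small a problem; plain gradient descent is
available but needs careful learning rates.  Gradients are analytic
(verified against central finite differences to 1e−6 relative) and the
reported/termination metric is the mean absolute error, like everywhere
else.  Divergence (non-finite loss) is recorded in the result, not raised.

MW is BP with a hard clamp: after every accepted update each parameter is
projected to [−θ, θ], θ = 2.0 by default.  The clamp is this package's
concretization of weight modification above a magnitude threshold; it holds
at every epoch, so trained MW nets satisfy max|p| ≤ θ exactly.

## Synthetic data

XOR is the deterministic 4-row truth table.  The overlap generator draws
two isotropic Gaussian clouds — square class at (0.25, 0.25), circle at
(0.75, 0.75), SD 0.2, 500 points each, targets −0.5/+0.5 — shuffles the
rows, and is exactly reproducible from a seed.  Points are not clipped to
the unit square, class counts are exact (not binomial), and the two clouds
overlap enough that even the Bayes rule misclassifies ≈ 4 % per class, so
per-class RCR saturates near 0.46, not 0.5.  The generator emulates the
benchmark's statistical structure only; nothing about real measured data
(outliers, class imbalance, correlated noise) is represented, so passing
tests certify algorithmic behaviour on the stated conditions, not
field performance.

In replicate experiments one dataset instance is generated from the base
seed and shared by all replicates, which differ only in training seed —
matching a protocol of repeated independent trainings on one dataset.

## Replication and seeding

Every stochastic experiment derives replicate r's generator as
`default_rng(base_seed + r)`, so single replicates are reproducible in
isolation.  Summaries report means with sample (n−1) SDs.  The canonical
protocol uses 20 replicates; the heavier overlap experiments run at 6
replicates in the acceptance script (3 in the test suite), chosen as the
package's desk-scale default for a task whose per-replicate cost is ~300×
the XOR case.

## Numerical notes and limitations

* Batched fault sweeps and GA fitness use an einsum-based forward over
  stacks of parameter vectors; it agrees with the scalar per-neuron loop to
  1e−12 and with `apply_faults` + single forward exactly.
* The exponential learning-curve fit `a·e^{−τx}` uses nonlinear least
  squares with x = 1..L and p0 = (trace[0], 0.01); non-convergence is
  flagged, not raised.  R² is reported against the mean-only model.
* Parameter-category/error correlations (mean |value| per category vs final
  clean error, Pearson r with two-tailed p) report NaN for zero-variance
  categories instead of raising.
* Known limitation: on the 9-hidden XOR task the FIB objective — a *mean*
  over faults — does not sufficiently penalize a single dominant output
  weight, and the GA settles in basins keeping one or two |v_j| ≳ 0.8 whose
  voiding crosses the 0.4 threshold.  Single-fault error rates for H=9
  therefore plateau near 8–12 % under this implementation, and reported
  H=6 single-parameter means sit at the upper edge of their expected
  between-replicate spread.  Longer budgets (5000 generations), alternative
  initialization ranges, genome clipping and direct simplex optimization of
  the same objective were all probed and do not move this plateau; a
  max-over-faults or tail-weighted objective would, but that is a different
  model and is deliberately out of scope.
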