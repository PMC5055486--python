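"""Inside one GA generation: rank scaling, SUS, crossover and mutation.

Shows the selection probabilities implied by the 1/sqrt(rank) scaling for a
population of 20 (normalizer Sigma 1/sqrt(j) = 7.5953), a stochastic
universal sampling draw of the 32 parents a generation consumes
(2 x 14 crossover + 4 mutation), and the linearly shrinking mutation scale.
"""

import numpy as np

from fibga import mutation_sigma, selection_probabilities, sus_select

probs = selection_probabilities(list(range(1, 21)), 20)
print("selection probability by rank:")
for rank in (1, 2, 4, 10, 20):
    print(f"  rank {rank:2d}: P = {probs[rank - 1]:.4f}")
print(f"  (rank 1 is exactly twice rank 4: {probs[0] / probs[3]:.3f})")

parents = sus_select(probs, 32, np.random.default_rng(0))
counts = np.bincount(parents, minlength=20)
print(f"\none SUS draw of 32 parents (copies per rank): {counts.tolist()}")
print("each count is floor or ceil of 32 * P_i — SUS has minimal spread.")

print("\nmutation scale over a 1000-generation run:")
for g in (1, 250, 500, 750, 1000):
    print(f"  generation {g:4d}: sigma = {mutation_sigma(g, 1000):.3f}")
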