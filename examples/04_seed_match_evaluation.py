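"""Evaluate seed-match quality on a simulated error-prone pair.

Mutates a 5 kb sequence at a 10% error rate (substitution / insertion /
deletion with probability r/3 each), seeds both copies, collects matches,
and classifies each match against the recorded ground-truth alignment
(true = more than half of its aligned character pairs are correct).
Prints match precision, segment sensitivity (fraction of 200 bp read
segments touched by a true match) and true/false coverage.
"""

import numpy as np

from subseqseed import (collect_matches, coverage, make_random_tables,
                        match_precision, mutate_rate, seed_sequence,
                        segment_sensitivity)
from subseqseed.simulate import _random_dna

L, r = 5000, 0.1
n, k, d, t = 20, 16, 15, 5

tables = make_random_tables(k, d, rng_seed=1)
x = _random_dna(np.random.default_rng(2), L)
pair = mutate_rate(x, r, rng_seed=3)

seeds_a = seed_sequence(pair.seq_a, n, k, t, tables, seq_id="a")
seeds_b = seed_sequence(pair.seq_b, n, k, t, tables, seq_id="b")
matches = collect_matches(seeds_a, seeds_b)

prec = match_precision(matches, pair.truth)
seg = segment_sensitivity(matches, pair.truth, read_length=L)
tc, fc = coverage(matches, pair.truth, len(pair.seq_a), len(pair.seq_b))

print(f"pair: L={L}, error rate {r:.0%} -> {len(pair.seq_b)} bp mutated copy")
print(f"seeds: {len(seeds_a)} + {len(seeds_b)} (n={n}, k={k}, d={d}, t={t})")
print(f"seed-matches:        {len(matches)}")
print(f"match precision:     {prec:.3f}   (fraction of matches that are true)")
print(f"segment sensitivity: {seg:.3f}   (200 bp segments with a true match)")
print(f"true coverage:       {tc:.3f}   (characters under true match spans)")
print(f"false coverage:      {fc:.3f}   (characters under false match spans)")
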