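"""Extract subsequence seeds from every window of a short sequence.

Builds the packaged k=6, d=5 example tables, seeds a 40 bp sequence with
windows of n=12 and t=2 seeds per window, and prints the seed table.
Each row is one seed: the window it came from, which of the k orders
selected it, the seed string, and the in-window positions of its
characters — note the positions are generally non-contiguous: seeds are
subsequences, which is what lets them survive indels.
"""

import numpy as np

from subseqseed import example_tables, seed_sequence

rng = np.random.default_rng(7)
seq = "".join(rng.choice(list("ACGT"), size=40))
tables = example_tables()

seeds = seed_sequence(seq, n=12, k=6, t=2, tables=tables, seq_id="demo")

print(f"sequence: {seq}")
print(f"{len(seeds)} seeds from {len(seq) - 12 + 1} windows "
      f"(t=2 orders per window)\n")
print("window  order  seed    positions        psi  omega")
for s in seeds[:14]:
    print(f"{s.window_start:6d}  {s.order_index:5d}  {s.seed}  "
          f"{','.join(map(str, s.positions)):15s}  {s.score.psi:3d}  {s.score.omega:5d}")
print("...")
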