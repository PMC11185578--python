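"""Overlap detection on a simulated read set.

Samples 40 error-prone reads (1 kb, 10% error) from a 15 kb genome, seeds
every read, and reports read pairs sharing at least one seed as overlap
candidates.  Ground truth: sampled intervals overlapping by >= 15 bp.
Sweeping the required number of shared seeds trades sensitivity for
precision.
"""

from subseqseed import (make_random_tables, overlap_candidates,
                        overlap_metrics, sample_overlapping_reads,
                        seed_sequence)

n, k, d, t = 24, 20, 15, 4
tables = make_random_tables(k, d, rng_seed=5)
reads, intervals, true_pairs = sample_overlapping_reads(
    genome_length=15_000, n_reads=40, read_length=1000,
    error_rate=0.1, rng_seed=6, min_overlap=15)

seeds = {rid: seed_sequence(seq, n, k, t, tables, seq_id=rid)
         for rid, seq in reads.items()}
print(f"{len(reads)} reads, {len(true_pairs)} truly overlapping pairs")
print("min_shared  candidates  sensitivity  precision")
for m in (1, 2, 5, 10):
    cands = overlap_candidates(seeds, min_shared=m)
    sens, prec = overlap_metrics(cands, true_pairs)
    print(f"{m:10d}  {len(cands):10d}  {sens:11.3f}  {prec:9.3f}")
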