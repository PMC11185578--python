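"""Seeding variants: substring+subsequence seeds and strand-neutral match keys.

The windowed variant prepends a verbatim length-k0 substring to each
subsequence seed extracted from the following length-n window, giving seeds
of length k0+k (the substring anchors an exact match, the subsequence part
tolerates edits).  The match-key canonicalization makes seeds from opposite
strands hash to the same key when the tables are reverse-complement
symmetric.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .dp import orders_for_t, seed_sequence
from .reference import Seed, revcomp
from .tables import ABCkTables

__all__ = ["MatchKey", "seed_sequence_w", "match_key"]


@dataclasses.dataclass(frozen=True)
class MatchKey:
    """Hashable identity of a seed for matching.

    ``order_slot`` is the (possibly strand-folded) order index; ``kernel``
    the (possibly strand-canonical) seed string.  Two seeds match iff their
    keys are equal.
    """
    order_slot: int
    kernel: str


def seed_sequence_w(X: str, n: int, k: int, k0: int, t: int, tables: ABCkTables,
                    seq_id: str = "", engine: str = "numba",
                    order_indices: Sequence[int] | None = None) -> list[Seed]:
    """Windowed-variant seeds: for every start p, concatenate the substring
    X[p, p+k0) with each of the t subsequence seeds of the following
    length-n window, yielding seeds of length k0+k anchored at p.

    ``k0 = 0`` degenerates to :func:`subseqseed.dp.seed_sequence`.  The
    reported positions cover both parts (0..k0-1, then the k subsequence
    offsets shifted by k0); the score is the subsequence part's score.
    """
    if k0 < 0:
        raise ValueError(f"k0 must be >= 0, got {k0}")
    if len(X) < k0 + n:
        return []
    X = X.upper()
    inner = seed_sequence(X[k0:], n, k, t, tables, seq_id=seq_id, engine=engine,
                          order_indices=order_indices)
    if k0 == 0:
        return inner
    out = []
    for s in inner:
        p = s.window_start  # start of the whole (substring + window) seed span
        lead = X[p:p + k0]
        out.append(dataclasses.replace(
            s,
            seed=lead + s.seed,
            positions=tuple(range(k0)) + tuple(q + k0 for q in s.positions)))
    return out


def match_key(seed: Seed, k: int, rc_mode: bool = False) -> MatchKey:
    """Match key of a seed.

    Plain mode pairs the order index with the seed string.  In rc mode the
    order index is folded with its mirror (min(i, k+1-i)) and the kernel is
    the lexicographic minimum of the seed and its reverse complement, so
    that with rc-symmetric tables the i-th seed of x and the (k+1-i)-th seed
    of revcomp(x) share a key.
    """
    if not rc_mode:
        return MatchKey(seed.order_index, seed.seed)
    i = seed.order_index
    return MatchKey(min(i, k + 1 - i), min(seed.seed, revcomp(seed.seed)))
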