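"""Seed-match collection and evaluation metrics.

A *seed-match* (anchor) is a pair of seeds with identical match keys; it
implies one aligned character pair per seed position.  A match is *true*
when strictly more than half of those aligned pairs coincide with the
ground-truth alignment, where "coincide" means the exact (position-in-a,
position-in-b) pair appears in the truth (substituted positions still count
as aligned; inserted/deleted characters have no partner).

Metrics:

* match precision — true matches / all matches (undefined without matches),
* segment sensitivity — fraction of consecutive read segments (default
  200 bp) touched by at least one true match on the read side,
* true/false coverage — proportion of characters encompassed by the full
  span of at least one true (resp. false) match, pooled over both sequences,
* overlap detection — read pairs sharing at least ``min_shared`` seed keys,
  scored against ground-truth overlapping pairs.

No high-frequency-seed filtering, chaining or alignment verification is
applied: these metrics evaluate the raw seeds.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .reference import Seed, revcomp
from .variants import MatchKey, match_key

__all__ = ["GroundTruthAlignment", "SeedMatch", "collect_matches",
           "is_true_match", "match_precision", "segment_sensitivity",
           "coverage", "overlap_candidates", "overlap_metrics"]


@dataclasses.dataclass(frozen=True)
class GroundTruthAlignment:
    """Aligned coordinate pairs (pos_a, pos_b), strictly increasing in both."""
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev = (-1, -1)
        for p in self.pairs:
            if not (p[0] > prev[0] and p[1] > prev[1]):
                raise ValueError(f"truth pairs not strictly increasing at {p}")
            prev = p

    def pair_set(self) -> frozenset[tuple[int, int]]:
        # cached: metrics call this once per match
        cached = getattr(self, "_pair_set", None)
        if cached is None:
            cached = frozenset(self.pairs)
            object.__setattr__(self, "_pair_set", cached)
        return cached


@dataclasses.dataclass(frozen=True)
class SeedMatch:
    """A pair of seeds with equal match keys from two sequences."""
    seed_a: Seed
    seed_b: Seed
    key: MatchKey

    def aligned_pairs(self) -> list[tuple[int, int]]:
        """Absolute (pos_in_a, pos_in_b) character pairs implied by the match.

        If the seed strings agree directly, position i pairs with position i;
        if they agree through the reverse complement (rc-mode matching),
        position i pairs with the mirrored position from the other end.
        """
        a, b = self.seed_a, self.seed_b
        pa = [a.window_start + p for p in a.positions]
        pb = [b.window_start + p for p in b.positions]
        if a.seed == b.seed:
            return list(zip(pa, pb))
        if a.seed == revcomp(b.seed):
            return list(zip(pa, reversed(pb)))
        raise ValueError("matched seeds agree neither directly nor via reverse complement")


def collect_matches(seeds_a: Sequence[Seed], seeds_b: Sequence[Seed],
                    rc_mode: bool = False, k: int | None = None) -> list[SeedMatch]:
    """All seed pairs across the two sets with equal match keys, via a hash
    index on the second set.  Seeds from all order indices are pooled.

    ``k`` is the number of orders, needed to fold i with k+1-i in rc mode;
    when omitted it is inferred as the largest order index present (exact
    whenever order k was used, e.g. for t = k)."""
    lens = {len(s.seed) for s in seeds_a} | {len(s.seed) for s in seeds_b}
    if len(lens) > 1:
        raise ValueError(f"mixed seed lengths {sorted(lens)}: "
                         "seeds must come from identical parameters")
    korder = k if k is not None else \
        max((s.order_index for s in list(seeds_a) + list(seeds_b)), default=1)
    index: dict[MatchKey, list[Seed]] = defaultdict(list)
    for s in seeds_b:
        index[match_key(s, korder, rc_mode)].append(s)
    out = []
    for s in seeds_a:
        key = match_key(s, korder, rc_mode)
        for sb in index.get(key, ()):
            out.append(SeedMatch(seed_a=s, seed_b=sb, key=key))
    return out


def is_true_match(m: SeedMatch, truth: GroundTruthAlignment) -> bool:
    """Strictly more than 50% of the aligned character pairs are in truth."""
    pairs = m.aligned_pairs()
    tset = truth.pair_set()
    hits = sum(1 for p in pairs if p in tset)
    return hits * 2 > len(pairs)


def match_precision(matches: Sequence[SeedMatch], truth: GroundTruthAlignment) -> float:
    """True matches / all matches; NaN (undefined) for an empty match list."""
    if not matches:
        return math.nan
    true = sum(1 for m in matches if is_true_match(m, truth))
    return true / len(matches)


def segment_sensitivity(matches: Sequence[SeedMatch], truth: GroundTruthAlignment,
                        read_length: int, segment_length: int = 200) -> float:
    """Fraction of consecutive read segments (the first sequence's axis,
    [0, read_length) split into segment_length chunks, last may be short)
    containing at least one true seed-match character."""
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    n_seg = max(1, math.ceil(read_length / segment_length))
    hit = [False] * n_seg
    for m in matches:
        if not is_true_match(m, truth):
            continue
        for pa, _ in m.aligned_pairs():
            if 0 <= pa < read_length:
                hit[pa // segment_length] = True
    return sum(hit) / n_seg


def coverage(matches: Sequence[SeedMatch], truth: GroundTruthAlignment,
             len_a: int, len_b: int) -> tuple[float, float]:
    """(true_coverage, false_coverage): proportion of characters lying inside
    the full span (first..last matched position, closed, on either sequence)
    of at least one true (resp. false) seed-match, pooled over both
    sequences."""
    cov = {True: [set(), set()], False: [set(), set()]}
    for m in matches:
        truth_flag = is_true_match(m, truth)
        pairs = m.aligned_pairs()
        pa = [p for p, _ in pairs]
        pb = [q for _, q in pairs]
        cov[truth_flag][0].update(range(min(pa), max(pa) + 1))
        cov[truth_flag][1].update(range(min(pb), max(pb) + 1))
    total = len_a + len_b
    tcov = (len(cov[True][0]) + len(cov[True][1])) / total
    fcov = (len(cov[False][0]) + len(cov[False][1])) / total
    return tcov, fcov


def overlap_candidates(read_seeds: Mapping[str, Sequence[Seed]],
                       rc_mode: bool = False,
                       min_shared: int = 1,
                       k: int | None = None) -> list[tuple[str, str]]:
    """Read pairs sharing at least ``min_shared`` distinct seed keys.

    Returns sorted unordered pairs (id_a < id_b).  This is the candidate
    filter of overlap detection; no verification is applied.  ``k`` as in
    :func:`collect_matches`.
    """
    korder = k if k is not None else \
        max((s.order_index for seeds in read_seeds.values() for s in seeds), default=1)
    key_index: dict[MatchKey, set[str]] = defaultdict(set)
    for rid, seeds in read_seeds.items():
        for s in seeds:
            key_index[match_key(s, korder, rc_mode)].add(rid)
    shared: dict[tuple[str, str], set[MatchKey]] = defaultdict(set)
    for key, rids in key_index.items():
        rids = sorted(rids)
        for x in range(len(rids)):
            for y in range(x + 1, len(rids)):
                shared[(rids[x], rids[y])].add(key)
    return sorted(p for p, keys in shared.items() if len(keys) >= min_shared)


def overlap_metrics(candidates: Iterable[tuple[str, str]],
                    true_pairs: Iterable[tuple[str, str]]) -> tuple[float, float]:
    """(sensitivity, precision) of candidate pairs against ground truth:
    correct candidates over all true pairs, and over all candidates.
    Undefined denominators yield NaN."""
    cand = {tuple(sorted(p)) for p in candidates}
    truth = {tuple(sorted(p)) for p in true_pairs}
    correct = len(cand & truth)
    sens = correct / len(truth) if truth else math.nan
    prec = correct / len(cand) if cand else math.nan
    return sens, prec
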