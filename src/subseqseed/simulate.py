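"""Synthetic data generation and hash-collision estimation.

Two mutation models are provided:

* exact edit-distance categories: a uniform random string receives exactly
  ``e`` edits and is kept only if its true edit distance (exact alignment,
  via edlib) equals ``e`` — this is the categorization used for
  collision-probability curves;
* per-position rate model: each position independently receives a
  substitution, insertion or deletion with probability r/3 each, emulating
  long-read error processes at rate r.

Both record the edit transcript, from which the ground-truth alignment
(matched and substituted positions) is derived.  All randomness flows from
one master seed through named substreams, so every simulation is exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.stats import beta

from .dp import SingleWindowSeeder, orders_for_t
from .matching import GroundTruthAlignment
from .tables import ABCkTables, make_random_tables

__all__ = ["MutatedPair", "pair_with_edit_distance", "mutate_rate",
           "estimate_collision_probability", "collision_curve", "lcs_length",
           "sample_overlapping_reads"]

_BASES = np.array(list("ACGT"))
_RETRY_CAP = 1000


@dataclasses.dataclass(frozen=True)
class MutatedPair:
    """A sequence pair related by a recorded edit transcript.

    ``transcript`` is a list of (op, pos_a, pos_b) steps with op in
    {match, sub, ins, del}; ``pos_a``/``pos_b`` are the coordinates consumed
    on each side (-1 when the op consumes nothing on that side).  ``truth``
    holds the aligned (match or substitution) coordinate pairs.
    """
    seq_a: str
    seq_b: str
    transcript: tuple[tuple[str, int, int], ...]
    truth: GroundTruthAlignment
    edit_distance_category: int | None = None


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def edit_distance(a: str, b: str) -> int:
    """Exact (unit-cost) edit distance."""
    return edlib.align(a, b)["editDistance"]


def _apply_edit_plan(x: str, ops: dict[int, str], rng: np.random.Generator):
    """Apply a per-position edit plan (pos -> sub|ins|del) left to right,
    recording the transcript.  Insertions place a base before the position."""
    out: list[str] = []
    transcript: list[tuple[str, int, int]] = []
    truth: list[tuple[int, int]] = []
    for pa, ch in enumerate(x):
        op = ops.get(pa)
        if op == "ins":
            out.append(str(rng.choice(_BASES)))
            transcript.append(("ins", -1, len(out) - 1))
            op = None  # the original character is kept after the insertion
        if op == "del":
            transcript.append(("del", pa, -1))
            continue
        if op == "sub":
            choices = [c for c in "ACGT" if c != ch]
            out.append(str(rng.choice(np.array(choices))))
            transcript.append(("sub", pa, len(out) - 1))
            truth.append((pa, len(out) - 1))
        else:
            out.append(ch)
            transcript.append(("match", pa, len(out) - 1))
            truth.append((pa, len(out) - 1))
    return "".join(out), tuple(transcript), GroundTruthAlignment(tuple(truth))


def pair_with_edit_distance(n: int, e: int, rng_seed: int) -> MutatedPair:
    """A pair of strings at exact edit distance ``e`` (category ``e``).

    A random length-n string receives exactly ``e`` edits at distinct
    positions; the result is accepted only if the true edit distance equals
    ``e`` (random edits can cancel), retrying with fresh randomness up to a
    cap.  Deterministic given ``rng_seed``.
    """
    if not 0 <= e <= n:
        raise ValueError(f"need 0 <= e <= n, got e={e}, n={n}")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, n, e)))
    for _ in range(_RETRY_CAP):
        x = _random_dna(rng, n)
        pos = rng.choice(n, size=e, replace=False)
        ops = {int(p): str(rng.choice(np.array(["sub", "ins", "del"]))) for p in pos}
        y, transcript, truth = _apply_edit_plan(x, ops, rng)
        if edit_distance(x, y) == e:
            return MutatedPair(x, y, transcript, truth, edit_distance_category=e)
    raise RuntimeError(f"could not hit exact edit distance {e} after {_RETRY_CAP} tries")


def mutate_rate(x: str, r: float, rng_seed: int) -> MutatedPair:
    """Per-position mutation at rate ``r``: each position independently is
    substituted, preceded by an insertion, or deleted with probability r/3
    each.  Expected edit count is r * |x|."""
    if not 0 <= r < 1:
        raise ValueError(f"rate must be in [0, 1), got {r}")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, len(x))))
    u = rng.random(len(x))
    ops: dict[int, str] = {}
    for p in range(len(x)):
        if u[p] < r / 3:
            ops[p] = "sub"
        elif u[p] < 2 * r / 3:
            ops[p] = "ins"
        elif u[p] < r:
            ops[p] = "del"
    y, transcript, truth = _apply_edit_plan(x, ops, rng)
    return MutatedPair(x, y, transcript, truth, edit_distance_category=None)


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence (exact quadratic DP)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = cur[j - 1] if cur[j - 1] >= prev[j] else prev[j]
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# collision probability
# ---------------------------------------------------------------------------

def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def _order_collisions(pair: MutatedPair, seeder_a: SingleWindowSeeder,
                      tables: ABCkTables, rc: bool) -> np.ndarray:
    """Boolean vector over the seeder's order indices: seed strings equal."""
    ca = tables.encode(pair.seq_a).astype(np.int64)
    cb = tables.encode(pair.seq_b).astype(np.int64)
    out = np.zeros(len(seeder_a.order_indices), dtype=bool)
    k = tables.k
    if len(ca) < k or len(cb) < k:  # a heavily deleted partner has no seed
        return out
    _, _, pos_a = seeder_a.seed_codes(ca)
    _, _, pos_b = seeder_a.seed_codes(cb)
    for ti in range(len(out)):
        sa = ca[pos_a[ti]]
        sb = cb[pos_b[ti]]
        if np.array_equal(sa, sb):
            out[ti] = True
        elif rc:
            # strand-folded key: compare against the mirrored order's seed
            i = seeder_a.order_indices[ti]
            tj = seeder_a.order_indices.index(k + 1 - i) if (k + 1 - i) in seeder_a.order_indices else None
            if tj is not None and np.array_equal(sa, _revcomp_codes(cb[pos_b[tj]])):
                out[ti] = True
    return out


def collision_curve(n: int, k: int, d: int, t_values: Sequence[int],
                    categories: Sequence[int], pairs_per_category: int,
                    rng_seed: int = 0, tables: ABCkTables | None = None,
                    rc: bool = False) -> pd.DataFrame:
    """Estimated hash-collision probability per edit-distance category, for
    several repeat counts t at once (evaluated on the same simulated pairs).

    A pair collides under repeat count t if at least one of the t selected
    orders yields identical seed strings for the two members (each member
    seeded as a single length-n window).  Returns a tidy frame with columns
    (t, category, n_pairs, collisions, probability, ci_low, ci_high); the CI
    is the 95% Clopper-Pearson interval.
    """
    if pairs_per_category < 1:
        raise ValueError("pairs_per_category must be >= 1")
    if tables is None:
        tables = make_random_tables(k, d, rng_seed)
    if (tables.k, tables.d) != (k, d):
        raise ValueError("tables do not match requested (k, d)")
    # indels can lengthen a partner string beyond n; size the buffers once
    seeder = SingleWindowSeeder(tables, n + max(categories, default=0),
                                order_indices=range(1, k + 1))
    t_orders = {t: [seeder.order_indices.index(i)
                    for i in orders_for_t(k, t, tables.rc_symmetric)]
                for t in t_values}
    rows = []
    for e in categories:
        hits = {t: 0 for t in t_values}
        for p in range(pairs_per_category):
            pair = pair_with_edit_distance(n, e, rng_seed=hash((rng_seed, e, p)) % 2 ** 31)
            coll = _order_collisions(pair, seeder, tables, rc)
            for t, idxs in t_orders.items():
                if coll[idxs].any():
                    hits[t] += 1
        for t in t_values:
            c, m = hits[t], pairs_per_category
            lo = beta.ppf(0.025, c, m - c + 1) if c > 0 else 0.0
            hi = beta.ppf(0.975, c + 1, m - c) if c < m else 1.0
            rows.append({"t": t, "category": e, "n_pairs": m, "collisions": c,
                         "probability": c / m, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def estimate_collision_probability(n: int, k: int, d: int, t: int,
                                   categories: Sequence[int],
                                   pairs_per_category: int,
                                   tables_or_seed: ABCkTables | int = 0,
                                   rc: bool = False) -> pd.DataFrame:
    """Single-t convenience wrapper around :func:`collision_curve`."""
    if isinstance(tables_or_seed, ABCkTables):
        tables, seed = tables_or_seed, tables_or_seed.rng_seed
    else:
        tables, seed = None, int(tables_or_seed)
    return collision_curve(n, k, d, [t], categories, pairs_per_category,
                           rng_seed=seed, tables=tables, rc=rc)


# ---------------------------------------------------------------------------
# overlap-detection fixtures
# ---------------------------------------------------------------------------

def sample_overlapping_reads(genome_length: int, n_reads: int, read_length: int,
                             error_rate: float, rng_seed: int,
                             min_overlap: int = 15,
                             both_strands: bool = False):
    """Sample error-prone reads from a random genome with known placement.

    Returns (reads, intervals, true_pairs): ``reads`` maps read id to its
    (mutated) sequence, ``intervals`` to the half-open genomic interval it
    was sampled from, and ``true_pairs`` lists unordered id pairs whose
    intervals overlap by at least ``min_overlap`` bases — the ground truth
    for overlap detection.  With ``both_strands`` each read is
    reverse-complemented with probability 1/2.
    """
    from .reference import revcomp

    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, genome_length)))
    genome = _random_dna(rng, genome_length)
    reads: dict[str, str] = {}
    intervals: dict[str, tuple[int, int]] = {}
    for ri in range(n_reads):
        start = int(rng.integers(0, genome_length - read_length + 1))
        rid = f"read{ri:04d}"
        frag = genome[start:start + read_length]
        mutated = mutate_rate(frag, error_rate, int(rng.integers(2 ** 31))).seq_b
        if both_strands and rng.random() < 0.5:
            mutated = revcomp(mutated)
        reads[rid] = mutated
        intervals[rid] = (start, start + read_length)
    ids = sorted(reads)
    true_pairs = []
    for x in range(len(ids)):
        ax, bx = intervals[ids[x]]
        for y in range(x + 1, len(ids)):
            ay, by = intervals[ids[y]]
            if min(bx, by) - max(ax, ay) >= min_overlap:
                true_pairs.append((ids[x], ids[y]))
    return reads, intervals, true_pairs
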