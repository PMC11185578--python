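"""Direct (non-DP) score functions, the order comparison rule, and a
brute-force seeder that enumerates every length-k subsequence of a window.

These are the reference semantics: the production DP in :mod:`subseqseed.dp`
must agree with them exactly, including tie-breaking.  The brute-force seeder
is deliberately simple (literal enumeration, per-candidate recursive scoring)
so it can serve as an independent correctness oracle at small problem sizes.

Scores
------
Each order ``i`` (0-based here; 1-based in user-facing output) maps a
length-k string ``z`` to a pair ``(psi, omega)``:

* ``psi`` in [0, d): a modular residue accumulated from the C tables,
* ``omega``: an integer accumulated from the A tables with signs from the
  B tables, where the sign/magnitude used at each step depends on the
  residue of the *current* prefix.

``z`` is split at its pivot character ``z[i]``: the prefix ``z[:i]`` is scored
right-to-left with the reverse tables, the suffix ``z[i+1:]`` left-to-right
with the forward tables, and the pivot tables stitch the three parts together.

Comparison is asymmetric: ``psi`` ascending, then ``omega`` DESCENDING
(a larger omega ranks earlier).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

from .tables import ABCkTables

__all__ = [
    "ScorePair", "Seed", "revcomp",
    "psi_forward", "psi_reverse", "omega_forward", "omega_reverse",
    "pi_score", "compare", "brute_force_seeds", "candidate_sort_key",
    "window_orientation_flipped",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

BRUTE_FORCE_GUARD = 10 ** 7


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True, order=False)
class ScorePair:
    """Score of a subsequence under one order.

    ``psi`` is in [0, d); comparison is total but asymmetric: ``a`` ranks
    before ``b`` iff ``a.psi < b.psi``, or ``a.psi == b.psi`` and
    ``a.omega > b.omega``.
    """
    psi: int
    omega: int

    def sort_key(self) -> tuple[int, int]:
        return (self.psi, -self.omega)

    def __lt__(self, other: "ScorePair") -> bool:
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "ScorePair") -> bool:
        return self.sort_key() <= other.sort_key()


def compare(a: ScorePair, b: ScorePair) -> int:
    """-1 if ``a`` ranks before ``b``, 1 if after, 0 if equal."""
    ka, kb = a.sort_key(), b.sort_key()
    return -1 if ka < kb else (1 if ka > kb else 0)


@dataclasses.dataclass(frozen=True)
class Seed:
    """One extracted seed: a subsequence of a window plus its provenance.

    ``window_start`` is 0-based in the parent sequence; ``positions`` are
    0-based offsets within the window (strictly increasing, one per seed
    character); ``order_index`` is 1-based in [1, k] as printed in output.
    """
    seq_id: str
    window_start: int
    order_index: int
    seed: str
    positions: tuple[int, ...]
    score: ScorePair


def _codes(s: str, tables: ABCkTables) -> list[int]:
    idx = tables.symbol_index()
    try:
        return [idx[c] for c in s.upper()]
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not in alphabet {tables.alphabet}") from None


def _check_len(s: Sequence, tables: ABCkTables) -> None:
    if len(s) > tables.k:
        raise ValueError(f"string of length {len(s)} exceeds k={tables.k} (no table row)")


def psi_forward(s: str, tables: ABCkTables) -> int:
    """Forward residue: psi(s[:l]) = (psi(s[:l-1]) + CF[l][s_l]) mod d,
    psi(empty) = 0.  Table row l is the position within ``s`` (0-based)."""
    _check_len(s, tables)
    psi = 0
    for l, c in enumerate(_codes(s, tables)):
        psi = (psi + int(tables.CF[l, c])) % tables.d
    return psi


def psi_reverse(s_rev: str, tables: ABCkTables) -> int:
    """Reverse residue, evaluated on the already-reversed string, with CR."""
    _check_len(s_rev, tables)
    psi = 0
    for l, c in enumerate(_codes(s_rev, tables)):
        psi = (psi + int(tables.CR[l, c])) % tables.d
    return psi


def omega_forward(s: str, tables: ABCkTables) -> int:
    """Forward integer score.

    omega(s[:l]) = omega(s[:l-1]) * BF[l][psi][s_l]_1
                 + AF[l][psi][s_l] * BF[l][psi][s_l]_2,
    where psi is the residue of the *full current* prefix s[:l];
    omega(empty) = 0.
    """
    _check_len(s, tables)
    psi, omega = 0, 0
    for l, c in enumerate(_codes(s, tables)):
        psi = (psi + int(tables.CF[l, c])) % tables.d
        omega = (omega * int(tables.BF1[l, psi, c])
                 + int(tables.AF[l, psi, c]) * int(tables.BF2[l, psi, c]))
    return omega


def omega_reverse(s_rev: str, tables: ABCkTables) -> int:
    """Mirror of :func:`omega_forward` with the reverse tables; the argument
    is the already-reversed string."""
    _check_len(s_rev, tables)
    psi, omega = 0, 0
    for l, c in enumerate(_codes(s_rev, tables)):
        psi = (psi + int(tables.CR[l, c])) % tables.d
        omega = (omega * int(tables.BR1[l, psi, c])
                 + int(tables.AR[l, psi, c]) * int(tables.BR2[l, psi, c]))
    return omega


def pi_score(z: str, i: int, tables: ABCkTables) -> ScorePair:
    """Score of the length-k string ``z`` under order ``i`` (1-based).

    The prefix ``z[:i-1]`` is reversed and fed to the reverse recurrences,
    the suffix ``z[i:]`` to the forward recurrences (positions re-indexed
    from the start of each part); the pivot tables combine the halves.
    """
    k, d = tables.k, tables.d
    if len(z) != k:
        raise ValueError(f"pi_score needs |z| = k = {k}, got {len(z)}")
    if not 1 <= i <= k:
        raise ValueError(f"order index {i} outside [1, {k}]")
    io = i - 1
    pivot = _codes(z, tables)[io]
    prefix_rev = z[:io][::-1]
    suffix = z[io + 1:]
    psi = (psi_reverse(prefix_rev, tables) + int(tables.CP[io, pivot])
           + psi_forward(suffix, tables)) % d
    omega = (omega_reverse(prefix_rev, tables) * int(tables.BP1[io, pivot])
             + int(tables.AP[io, pivot])
             + omega_forward(suffix, tables) * int(tables.BP2[io, pivot]))
    return ScorePair(psi, omega)


def window_orientation_flipped(window: str, tables: ABCkTables) -> bool:
    """Canonical orientation of a window for tie-breaking.

    With reverse-complement-symmetric tables, score ties must be broken in a
    way that commutes with the reverse-complement map, otherwise a tied
    window and its reverse complement can resolve to non-corresponding
    seeds.  The convention: a window whose reverse complement is strictly
    lexicographically smaller than itself uses the mirrored tie rule.
    Plain (asymmetric) tables always use the forward rule.
    """
    return tables.rc_symmetric and revcomp(window.upper()) < window.upper()


def candidate_sort_key(window: str, positions: tuple[int, ...], i: int,
                       tables: ABCkTables, flipped: bool | None = None) -> tuple:
    """Deterministic total-order key for one candidate subsequence of a
    window under order ``i`` (1-based).

    Forward-orientation key components, in order: (psi, -omega) of the
    score; the pivot position; the prefix residue class j1; the prefix
    position vector (lexicographic); the reversed suffix position vector
    (lexicographic).  This is the repository tie rule: the production DP
    traceback realizes exactly this ordering, and for ties among candidates
    spelling the same string it selects the leftmost embedding of that
    string.

    In the mirrored orientation (see :func:`window_orientation_flipped`)
    every component is replaced by its image under sequence reversal:
    largest pivot position, smallest *suffix* residue class j2, right-packed
    positions on both sides.
    """
    io = i - 1
    z = "".join(window[p] for p in positions)
    sp = pi_score(z, i, tables)
    if flipped is None:
        flipped = window_orientation_flipped(window, tables)
    if not flipped:
        j1 = psi_reverse(z[:io][::-1], tables)
        return (sp.psi, -sp.omega, positions[io], j1,
                positions[:io], tuple(reversed(positions[io + 1:])))
    j2 = psi_forward(z[io + 1:], tables)
    return (sp.psi, -sp.omega, -positions[io], j2,
            tuple(-p for p in reversed(positions[io + 1:])),
            tuple(-p for p in positions[:io]))


def brute_force_seeds(window: str, tables: ABCkTables, t: int | None = None,
                      order_indices: Iterable[int] | None = None,
                      seq_id: str = "", window_start: int = 0) -> list[Seed]:
    """Enumerate every length-k subsequence of ``window`` (as a position set)
    and return, per selected order, the minimum under the order comparison
    with the repository tie rule.

    Guarded: refuses windows with more than ``BRUTE_FORCE_GUARD`` candidate
    position sets.
    """
    from .dp import orders_for_t  # local import to avoid a cycle

    n, k = len(window), tables.k
    if n < k:
        raise ValueError(f"window length {n} < k = {k}")
    if comb(n, k) > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"C({n},{k}) = {comb(n, k)} candidates exceed the enumeration "
            f"guard ({BRUTE_FORCE_GUARD}); use a smaller window")
    if order_indices is None:
        order_indices = orders_for_t(k, k if t is None else t, tables.rc_symmetric)
    window = window.upper()
    _codes(window, tables)  # alphabet check
    all_pos = [tuple(p) for p in combinations(range(n), k)]
    flipped = window_orientation_flipped(window, tables)
    seeds = []
    for i in sorted(order_indices):
        best = min(all_pos,
                   key=lambda pos: candidate_sort_key(window, pos, i, tables, flipped))
        z = "".join(window[p] for p in best)
        seeds.append(Seed(seq_id=seq_id, window_start=window_start, order_index=i,
                          seed=z, positions=best, score=pi_score(z, i, tables)))
    return seeds
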