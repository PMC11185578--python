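"""Production seeding algorithm: sliding-window dynamic programming.

For a sequence X of length N and window length n, the algorithm finds, for
every length-n window and every selected order i, the minimum-ranked length-k
subsequence of the window, in O(N n k d) scalar work.  It has two steps:

* *iterating*: fill four subproblem families over all spans of X up to
  length n.  ``Fmin/Fmax[s][b][l][j]`` are the extreme forward omega values
  over length-l subsequences of the span [s, s+b) whose forward residue is j;
  ``Rmin/Rmax`` are the reverse-function equivalents (the reversed subsequence
  is scored).  Windows share spans, which is where the speedup over seeding
  each window independently comes from.

* *optimizing*: for window w and order i, enumerate the pivot position b;
  the candidate splits into a length-(i-1) prefix from [w, w+b-1) (a reverse
  subproblem) and a length-(k-i) suffix from [w+b, w+n) (a forward
  subproblem).  The optimal residue is found by scanning the feasible residue
  classes of the two sides, the optimal omega by a d-term scan, and the
  winning subsequence is recovered by traceback.

Three interchangeable engines fill the tables: ``"numba"`` (compiled,
default), ``"elementwise"`` (pure Python, the readable reference) and
``"vectorized"`` (numpy operations over the whole residue axis).  All three
produce bit-identical DP tables.

Determinism: ties are broken by smallest (psi, -omega), then smallest pivot
position, then smallest prefix residue class, then leftmost-packed positions
on both sides — exactly the rule of
:func:`subseqseed.reference.candidate_sort_key`.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .reference import ScorePair, Seed, pi_score
from .tables import ABCkTables

__all__ = ["DPState", "iterate", "psi_opt", "omega_opt", "best_in_window",
           "seed_sequence", "orders_for_t", "window_is_clean"]

logger = logging.getLogger(__name__)

_ENGINES = ("numba", "elementwise", "vectorized")

#: upper bound on |omega|: each recurrence step adds at most max|A|, the pivot
#: combination adds three such terms.  Used to assert no int64 overflow risk
#: and (amply) satisfied for k <= 64 with the default magnitude range.
def _omega_bound(tables: ABCkTables) -> int:
    amax = int(max(tables.AF.max(), tables.AR.max(), np.abs(tables.AP).max()))
    return (2 * tables.k + 1) * amax


@dataclasses.dataclass
class DPState:
    """Filled subproblem tables for one sequence (or chunk).

    Value arrays are int64 of shape (N+1, n+1, k+1, d) indexed
    [span start][span length][subsequence length][residue class]; the boolean
    masks ``ffeas``/``rfeas`` flag feasibility (a feasible entry means a
    length-l subsequence of the span with that residue exists).  Infeasible
    entries hold a canonical 0; arithmetic never consumes them.
    """
    seq: str
    codes: np.ndarray
    n: int
    tables: ABCkTables
    fmin: np.ndarray
    fmax: np.ndarray
    rmin: np.ndarray
    rmax: np.ndarray
    ffeas: np.ndarray
    rfeas: np.ndarray

    @property
    def N(self) -> int:
        return len(self.codes)

    @property
    def num_windows(self) -> int:
        return self.N - self.n + 1


def _alloc(N: int, n: int, k: int, d: int):
    shape = (N + 1, n + 1, k + 1, d)
    vals = [np.zeros(shape, dtype=np.int64) for _ in range(4)]
    masks = [np.zeros(shape, dtype=bool) for _ in range(2)]
    return vals, masks


def _table_args(t: ABCkTables):
    return (t.CF, t.CR, t.AF, t.AR, t.BF1, t.BF2, t.BR1, t.BR2)


# ---------------------------------------------------------------------------
# iterating step
# ---------------------------------------------------------------------------

def _fill_elementwise(codes, n, k, d, t: ABCkTables, fmin, fmax, rmin, rmax, ffeas, rfeas):
    """Pure-Python transcription of the recurrences; scalar in every axis."""
    N = len(codes)
    CF, CR, AF, AR, BF1, BF2, BR1, BR2 = _table_args(t)
    for s in range(N + 1):
        ffeas[s, 0, 0, 0] = True
        rfeas[s, 0, 0, 0] = True
    for s in range(N + 1):
        for b in range(1, min(n, N - s) + 1):
            sigma = codes[s + b - 1]
            for l in range(k + 1):
                for j in range(d):
                    opts = []
                    if ffeas[s, b - 1, l, j]:
                        opts.append((fmin[s, b - 1, l, j], fmax[s, b - 1, l, j]))
                    if l > 0 and sigma >= 0:
                        jp = (j - CF[l - 1, sigma]) % d
                        if ffeas[s, b - 1, l - 1, jp]:
                            a2 = AF[l - 1, j, sigma] * BF2[l - 1, j, sigma]
                            if BF1[l - 1, j, sigma] == 1:
                                opts.append((a2 + fmin[s, b - 1, l - 1, jp],
                                             a2 + fmax[s, b - 1, l - 1, jp]))
                            else:
                                opts.append((a2 - fmax[s, b - 1, l - 1, jp],
                                             a2 - fmin[s, b - 1, l - 1, jp]))
                    if opts:
                        ffeas[s, b, l, j] = True
                        fmin[s, b, l, j] = min(o[0] for o in opts)
                        fmax[s, b, l, j] = max(o[1] for o in opts)
    for b in range(1, n + 1):
        for s in range(N - b + 1):
            sigma = codes[s]
            for l in range(k + 1):
                for j in range(d):
                    opts = []
                    if rfeas[s + 1, b - 1, l, j]:
                        opts.append((rmin[s + 1, b - 1, l, j], rmax[s + 1, b - 1, l, j]))
                    if l > 0 and sigma >= 0:
                        jp = (j - CR[l - 1, sigma]) % d
                        if rfeas[s + 1, b - 1, l - 1, jp]:
                            a2 = AR[l - 1, j, sigma] * BR2[l - 1, j, sigma]
                            if BR1[l - 1, j, sigma] == 1:
                                opts.append((a2 + rmin[s + 1, b - 1, l - 1, jp],
                                             a2 + rmax[s + 1, b - 1, l - 1, jp]))
                            else:
                                opts.append((a2 - rmax[s + 1, b - 1, l - 1, jp],
                                             a2 - rmin[s + 1, b - 1, l - 1, jp]))
                    if opts:
                        rfeas[s, b, l, j] = True
                        rmin[s, b, l, j] = min(o[0] for o in opts)
                        rmax[s, b, l, j] = max(o[1] for o in opts)


def _combine_axis(sk_ok, sk_min, sk_max, tk_ok, tk_min, tk_max):
    """Feasibility-aware min/max over two whole-residue-axis option vectors."""
    big = np.int64(np.iinfo(np.int64).max // 4)
    feas = sk_ok | tk_ok
    lo = np.minimum(np.where(sk_ok, sk_min, big), np.where(tk_ok, tk_min, big))
    hi = np.maximum(np.where(sk_ok, sk_max, -big), np.where(tk_ok, tk_max, -big))
    return feas, np.where(feas, lo, 0), np.where(feas, hi, 0)


def _fill_vectorized(codes, n, k, d, t: ABCkTables, fmin, fmax, rmin, rmax, ffeas, rfeas):
    """Numpy engine: the residue axis j is processed as whole arrays."""
    N = len(codes)
    CF, CR, AF, AR, BF1, BF2, BR1, BR2 = _table_args(t)
    ffeas[:, 0, 0, 0] = True
    rfeas[:, 0, 0, 0] = True
    for s in range(N + 1):
        for b in range(1, min(n, N - s) + 1):
            sigma = codes[s + b - 1]
            for l in range(k + 1):
                sk_ok = ffeas[s, b - 1, l]
                sk_min = fmin[s, b - 1, l]
                sk_max = fmax[s, b - 1, l]
                if l > 0 and sigma >= 0:
                    c = int(CF[l - 1, sigma])
                    ch_ok = np.roll(ffeas[s, b - 1, l - 1], c)
                    ch_min = np.roll(fmin[s, b - 1, l - 1], c)
                    ch_max = np.roll(fmax[s, b - 1, l - 1], c)
                    a2 = AF[l - 1, :, sigma] * BF2[l - 1, :, sigma]
                    plus = BF1[l - 1, :, sigma] == 1
                    tk_min = np.where(plus, a2 + ch_min, a2 - ch_max)
                    tk_max = np.where(plus, a2 + ch_max, a2 - ch_min)
                    feas, lo, hi = _combine_axis(sk_ok, sk_min, sk_max, ch_ok, tk_min, tk_max)
                else:
                    feas, lo, hi = _combine_axis(sk_ok, sk_min, sk_max,
                                                 np.zeros(d, dtype=bool), sk_min, sk_max)
                ffeas[s, b, l] = feas
                fmin[s, b, l] = lo
                fmax[s, b, l] = hi
    for b in range(1, n + 1):
        for s in range(N - b + 1):
            sigma = codes[s]
            for l in range(k + 1):
                sk_ok = rfeas[s + 1, b - 1, l]
                sk_min = rmin[s + 1, b - 1, l]
                sk_max = rmax[s + 1, b - 1, l]
                if l > 0 and sigma >= 0:
                    c = int(CR[l - 1, sigma])
                    ch_ok = np.roll(rfeas[s + 1, b - 1, l - 1], c)
                    ch_min = np.roll(rmin[s + 1, b - 1, l - 1], c)
                    ch_max = np.roll(rmax[s + 1, b - 1, l - 1], c)
                    a2 = AR[l - 1, :, sigma] * BR2[l - 1, :, sigma]
                    plus = BR1[l - 1, :, sigma] == 1
                    tk_min = np.where(plus, a2 + ch_min, a2 - ch_max)
                    tk_max = np.where(plus, a2 + ch_max, a2 - ch_min)
                    feas, lo, hi = _combine_axis(sk_ok, sk_min, sk_max, ch_ok, tk_min, tk_max)
                else:
                    feas, lo, hi = _combine_axis(sk_ok, sk_min, sk_max,
                                                 np.zeros(d, dtype=bool), sk_min, sk_max)
                rfeas[s, b, l] = feas
                rmin[s, b, l] = lo
                rmax[s, b, l] = hi


def iterate(X: str, n: int, tables: ABCkTables, engine: str = "numba") -> DPState:
    """Solve all subproblems for every span of ``X`` up to length ``n``."""
    k, d = tables.k, tables.d
    if not 1 <= k <= n <= len(X):
        raise ValueError(f"need 1 <= k <= n <= |X| (k={k}, n={n}, |X|={len(X)})")
    if engine not in _ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {_ENGINES}")
    assert _omega_bound(tables) < 2 ** 62, "omega range would overflow int64"
    X = X.upper()
    codes = tables.encode(X).astype(np.int64)
    (fmin, fmax, rmin, rmax), (ffeas, rfeas) = _alloc(len(X), n, k, d)
    args = (codes, n, k, d)
    if engine == "numba":
        _kernels.fill_tables(*args, *_table_args(tables),
                             fmin, fmax, rmin, rmax, ffeas, rfeas)
    elif engine == "elementwise":
        _fill_elementwise(*args, tables, fmin, fmax, rmin, rmax, ffeas, rfeas)
    else:
        _fill_vectorized(*args, tables, fmin, fmax, rmin, rmax, ffeas, rfeas)
    return DPState(seq=X, codes=codes, n=n, tables=tables,
                   fmin=fmin, fmax=fmax, rmin=rmin, rmax=rmax,
                   ffeas=ffeas, rfeas=rfeas)


# ---------------------------------------------------------------------------
# optimizing step (per window, per order)
# ---------------------------------------------------------------------------

def psi_opt(w: int, b: int, i: int, state: DPState) -> int | None:
    """Optimal residue for window ``w`` (0-based) with pivot position ``b``
    (1-based within the window) under order ``i`` (1-based): the minimum of
    (j1 + CP[i][pivot] + j2) mod d over the feasible residue classes j1 of
    the prefix side and j2 of the suffix side.  None if either side is
    infeasible.  Direct O(d^2) scan."""
    t, n, d = state.tables, state.n, state.tables.d
    io, lpre, lsuf = i - 1, i - 1, t.k - i
    if lpre > b - 1 or lsuf > n - b:
        return None
    pivot = state.codes[w + b - 1]
    if pivot < 0:
        return None
    c = int(t.CP[io, pivot])
    v1 = np.flatnonzero(state.rfeas[w, b - 1, lpre])
    v2 = np.flatnonzero(state.ffeas[w + b, n - b, lsuf])
    if len(v1) == 0 or len(v2) == 0:
        return None
    return min((int(j1) + c + int(j2)) % d for j1 in v1 for j2 in v2)


def omega_opt(w: int, b: int, i: int, psi_value: int, state: DPState) -> int:
    """Best omega achieving ``psi_value`` at (w, b, i): max over the prefix
    class j1 of R_i(j1) + AP[i][pivot] + F_i(j2), with j2 determined by
    psi_value and the signs in BP selecting min vs max subproblems."""
    if psi_value is None:
        raise ValueError("omega_opt called on an infeasible psi value")
    t, n, d = state.tables, state.n, state.tables.d
    io, lpre, lsuf = i - 1, i - 1, t.k - i
    pivot = state.codes[w + b - 1]
    c = int(t.CP[io, pivot])
    bp1, bp2 = int(t.BP1[io, pivot]), int(t.BP2[io, pivot])
    best = None
    for j1 in range(d):
        if not state.rfeas[w, b - 1, lpre, j1]:
            continue
        j2 = (psi_value - c - j1) % d
        if not state.ffeas[w + b, n - b, lsuf, j2]:
            continue
        rv = int(state.rmax[w, b - 1, lpre, j1]) if bp1 == 1 \
            else -int(state.rmin[w, b - 1, lpre, j1])
        fv = int(state.fmax[w + b, n - b, lsuf, j2]) if bp2 == 1 \
            else -int(state.fmin[w + b, n - b, lsuf, j2])
        tot = rv + int(t.AP[io, pivot]) + fv
        if best is None or tot > best:
            best = tot
    if best is None:
        raise ValueError(f"psi value {psi_value} not achievable at (w={w}, b={b}, i={i})")
    return best


def _trace_prefix(state: DPState, w: int, b: int, io: int, j1: int, bp1: int,
                  prefer_take: bool) -> list[int]:
    """Recover the prefix positions (window-relative, ascending).

    ``prefer_take`` (forward orientation) packs the positions leftmost;
    otherwise skipping is preferred and they pack rightmost."""
    t = state.tables
    d = t.d
    s, B, l, j = w, b - 1, io, j1
    fam = 1 if bp1 == 1 else 0
    v = int(state.rmax[w, b - 1, io, j1]) if fam else int(state.rmin[w, b - 1, io, j1])
    out: list[int] = []
    while l > 0:
        sigma = state.codes[s]
        take_ok = False
        skip_ok = False
        if sigma >= 0:
            jp = (j - int(t.CR[l - 1, sigma])) % d
            if state.rfeas[s + 1, B - 1, l - 1, jp]:
                a2 = int(t.AR[l - 1, j, sigma]) * int(t.BR2[l - 1, j, sigma])
                b1 = int(t.BR1[l - 1, j, sigma])
                cv = b1 * (v - a2)
                cf = fam if b1 == 1 else 1 - fam
                stored = int(state.rmax[s + 1, B - 1, l - 1, jp]) if cf \
                    else int(state.rmin[s + 1, B - 1, l - 1, jp])
                take_ok = stored == cv
        if not (take_ok and prefer_take):
            if B - 1 >= l and state.rfeas[s + 1, B - 1, l, j]:
                stored = int(state.rmax[s + 1, B - 1, l, j]) if fam \
                    else int(state.rmin[s + 1, B - 1, l, j])
                skip_ok = stored == v
        assert take_ok or skip_ok, "broken traceback"
        if take_ok and (prefer_take or not skip_ok):
            out.append(s - w)
            l, j, fam, v = l - 1, jp, cf, cv
        s, B = s + 1, B - 1
    return out


def _trace_suffix(state: DPState, w: int, b: int, io: int, j2: int, bp2: int,
                  prefer_skip: bool) -> list[int]:
    """Recover the suffix positions (window-relative, ascending).

    ``prefer_skip`` (forward orientation) packs the positions leftmost;
    otherwise taking is preferred and they pack rightmost."""
    t = state.tables
    n, k, d = state.n, t.k, t.d
    s0, B, l, j = w + b, n - b, k - 1 - io, j2
    fam = 1 if bp2 == 1 else 0
    v = int(state.fmax[s0, B, l, j]) if fam else int(state.fmin[s0, B, l, j])
    out: list[int] = []
    while l > 0:
        skip_ok = False
        take_ok = False
        cv = cf = jp = 0
        if B - 1 >= l and state.ffeas[s0, B - 1, l, j]:
            stored = int(state.fmax[s0, B - 1, l, j]) if fam else int(state.fmin[s0, B - 1, l, j])
            skip_ok = stored == v
        sigma = state.codes[s0 + B - 1]
        if sigma >= 0 and not (skip_ok and prefer_skip):
            jp = (j - int(t.CF[l - 1, sigma])) % d
            if state.ffeas[s0, B - 1, l - 1, jp]:
                a2 = int(t.AF[l - 1, j, sigma]) * int(t.BF2[l - 1, j, sigma])
                b1 = int(t.BF1[l - 1, j, sigma])
                cv = b1 * (v - a2)
                cf = fam if b1 == 1 else 1 - fam
                stored = int(state.fmax[s0, B - 1, l - 1, jp]) if cf \
                    else int(state.fmin[s0, B - 1, l - 1, jp])
                take_ok = stored == cv
        assert skip_ok or take_ok, "broken traceback"
        if skip_ok and (prefer_skip or not take_ok):
            B -= 1
        else:
            out.append(s0 + B - 1 - w)
            v, fam, j = cv, cf, jp
            l, B = l - 1, B - 1
    return out[::-1]


def best_in_window(w: int, state: DPState, order_indices: Iterable[int] | None = None,
                   seq_id: str = "") -> list[Seed]:
    """Optimal seed of window ``w`` for each selected order (1-based), with
    deterministic tie-breaking; every emitted seed is re-scored through the
    direct recurrences as an internal consistency check."""
    t, n = state.tables, state.n
    k, d = t.k, t.d
    if order_indices is None:
        order_indices = range(1, k + 1)
    if not window_is_clean(state.codes, w, n):
        return []
    from .reference import window_orientation_flipped
    flipped = window_orientation_flipped(state.seq[w:w + n], t)
    seeds = []
    for i in sorted(order_indices):
        if not 1 <= i <= k:
            raise ValueError(f"order index {i} outside [1, {k}]")
        io = i - 1
        best: tuple[int, int, int] | None = None  # (psi, -omega, +-b)
        for b in range(1, n + 1):
            psi_b = psi_opt(w, b, i, state)
            if psi_b is None:
                continue
            om_b = omega_opt(w, b, i, psi_b, state)
            cand = (psi_b, -om_b, -b if flipped else b)
            if best is None or cand < best:
                best = cand
        assert best is not None, "window with n >= k must be feasible"
        psi, omega, b = best[0], -best[1], abs(best[2])
        pivot = state.codes[w + b - 1]
        c = int(t.CP[io, pivot])
        bp1, bp2 = int(t.BP1[io, pivot]), int(t.BP2[io, pivot])
        j1s = None
        for jq in range(d):
            # forward orientation scans the prefix class j1 ascending,
            # mirrored orientation the suffix class j2 ascending
            j1 = jq if not flipped else (psi - c - jq) % d
            j2 = (psi - c - j1) % d
            if not state.rfeas[w, b - 1, io, j1]:
                continue
            if not state.ffeas[w + b, n - b, k - i, j2]:
                continue
            rv = int(state.rmax[w, b - 1, io, j1]) if bp1 == 1 \
                else -int(state.rmin[w, b - 1, io, j1])
            fv = int(state.fmax[w + b, n - b, k - i, j2]) if bp2 == 1 \
                else -int(state.fmin[w + b, n - b, k - i, j2])
            if rv + int(t.AP[io, pivot]) + fv == omega:
                j1s = j1
                break
        assert j1s is not None
        j2s = (psi - c - j1s) % d
        pos = (_trace_prefix(state, w, b, io, j1s, bp1, prefer_take=not flipped)
               + [b - 1]
               + _trace_suffix(state, w, b, io, j2s, bp2, prefer_skip=not flipped))
        z = "".join(state.seq[w + p] for p in pos)
        score = ScorePair(psi, omega)
        assert pi_score(z, i, t) == score, "traceback produced an inconsistent seed"
        seeds.append(Seed(seq_id=seq_id, window_start=w, order_index=i,
                          seed=z, positions=tuple(pos), score=score))
    return seeds


# ---------------------------------------------------------------------------
# whole-sequence driver
# ---------------------------------------------------------------------------

def orders_for_t(k: int, t: int, rc_symmetric: bool = False) -> list[int]:
    """The 1-based order indices used for ``t`` repeats: evenly spaced over
    [1, k] (just the middle order for t=1).  For reverse-complement-symmetric
    tables the set is closed under i -> k+1-i, which may grow it beyond t."""
    if not 1 <= t <= k:
        raise ValueError(f"t must be in [1, {k}], got {t}")
    if t == 1:
        base = {math.ceil(k / 2)}
    elif t == k:
        base = set(range(1, k + 1))
    else:
        base = {int(math.floor(1 + (k - 1) * (j - 1) / (t - 1) + 0.5)) for j in range(1, t + 1)}
    if rc_symmetric:
        base |= {k + 1 - i for i in base}
    return sorted(base)


def window_is_clean(codes: np.ndarray, w: int, n: int) -> bool:
    """True iff window [w, w+n) contains only alphabet symbols."""
    return bool((codes[w:w + n] >= 0).all())


def _clean_window_mask(codes: np.ndarray, n: int) -> np.ndarray:
    bad = codes < 0
    if not bad.any():
        return np.ones(len(codes) - n + 1, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(bad)))
    return (csum[n:] - csum[:-n]) == 0


def seed_sequence(X: str, n: int, k: int, t: int, tables: ABCkTables,
                  seq_id: str = "", engine: str = "numba",
                  order_indices: Sequence[int] | None = None,
                  block_windows: int = 64) -> list[Seed]:
    """Extract ``t`` seeds from every length-``n`` window of ``X``.

    Windows containing non-alphabet symbols emit no seeds (counted and
    logged).  Long sequences are processed in overlapping chunks of
    ``block_windows`` windows, which bounds live DP memory at
    O(block * n * k * d) without changing any result.  Output is sorted by
    (window_start, order_index).
    """
    if k != tables.k:
        raise ValueError(f"k={k} does not match tables.k={tables.k}")
    if order_indices is None:
        order_indices = orders_for_t(k, t, tables.rc_symmetric)
    else:
        order_indices = sorted(order_indices)
    if len(X) < n:
        return []
    X = X.upper()
    if engine != "numba":
        state = iterate(X, n, tables, engine=engine)
        out = []
        for w in range(state.num_windows):
            out.extend(best_in_window(w, state, order_indices, seq_id=seq_id))
        _log_skips(X, tables, n, seq_id)
        return out

    codes_all = tables.encode(X).astype(np.int64)
    d = tables.d
    order_idx0 = np.array([i - 1 for i in order_indices], dtype=np.int64)
    T = len(order_idx0)
    seeds: list[Seed] = []
    W_total = len(X) - n + 1
    start = 0
    while start < W_total:
        stop = min(W_total, start + block_windows)  # windows [start, stop)
        chunk = X[start:stop - 1 + n]
        codes = codes_all[start:stop - 1 + n]
        Nc = len(codes)
        (fmin, fmax, rmin, rmax), (ffeas, rfeas) = _alloc(Nc, n, k, d)
        _kernels.fill_tables(codes, n, k, d, *_table_args(tables),
                             fmin, fmax, rmin, rmax, ffeas, rfeas)
        window_ok = _clean_window_mask(codes, n)
        Wc = Nc - n + 1
        out_psi = np.empty((Wc, T), dtype=np.int64)
        out_omega = np.empty((Wc, T), dtype=np.int64)
        out_pos = np.empty((Wc, T, k), dtype=np.int64)
        use_rc = tables.rc_symmetric and tables.alphabet == ("A", "C", "G", "T")
        _kernels.optimize_windows(codes, n, k, d, *_table_args(tables),
                                  tables.AP, tables.BP1, tables.BP2, tables.CP,
                                  fmin, fmax, rmin, rmax, ffeas, rfeas,
                                  order_idx0, window_ok, use_rc,
                                  out_psi, out_omega, out_pos)
        for w in range(Wc):
            if out_psi[w, 0] < 0:
                continue
            for ti in range(T):
                pos = tuple(int(p) for p in out_pos[w, ti])
                z = "".join(chunk[p + w] for p in pos)
                seeds.append(Seed(seq_id=seq_id, window_start=start + w,
                                  order_index=int(order_idx0[ti]) + 1, seed=z,
                                  positions=pos,
                                  score=ScorePair(int(out_psi[w, ti]), int(out_omega[w, ti]))))
        start = stop
    _log_skips(X, tables, n, seq_id)
    return seeds


class SingleWindowSeeder:
    """Repeated seeding of single length-n windows with reused DP buffers.

    For simulation workloads (many independent short strings) the dominant
    cost is the DP fill; this helper allocates the subproblem arrays once
    and returns raw (psi, omega, positions) arrays without building Seed
    objects.
    """

    def __init__(self, tables: ABCkTables, n: int,
                 order_indices: Sequence[int] | None = None, t: int | None = None):
        self.tables = tables
        self.n = n  # maximum window length the buffers accommodate
        k, d = tables.k, tables.d
        if order_indices is None:
            order_indices = orders_for_t(k, t if t is not None else k, tables.rc_symmetric)
        self.order_indices = sorted(order_indices)
        self._oidx = np.array([i - 1 for i in self.order_indices], dtype=np.int64)
        (self._fmin, self._fmax, self._rmin, self._rmax), (self._ffeas, self._rfeas) = \
            _alloc(n, n, k, d)
        T = len(self._oidx)
        self._psi = np.empty((1, T), dtype=np.int64)
        self._omega = np.empty((1, T), dtype=np.int64)
        self._pos = np.empty((1, T, k), dtype=np.int64)
        self._ok = np.ones(1, dtype=bool)
        self._use_rc = tables.rc_symmetric and tables.alphabet == ("A", "C", "G", "T")

    def seed_codes(self, codes: np.ndarray):
        """Seed one window given its symbol codes (length in [k, n], all
        valid; the whole string is the window).

        Returns (psi, omega, positions) arrays of shapes (T,), (T,), (T, k);
        the seed of order ``order_indices[ti]`` spells ``codes[positions[ti]]``.
        """
        t = self.tables
        nw = len(codes)
        assert t.k <= nw <= self.n, "window length outside [k, n_max]"
        _kernels.fill_tables(codes, nw, t.k, t.d, *_table_args(t),
                             self._fmin, self._fmax, self._rmin, self._rmax,
                             self._ffeas, self._rfeas)
        _kernels.optimize_windows(codes, nw, t.k, t.d, *_table_args(t),
                                  t.AP, t.BP1, t.BP2, t.CP,
                                  self._fmin, self._fmax, self._rmin, self._rmax,
                                  self._ffeas, self._rfeas,
                                  self._oidx, self._ok, self._use_rc,
                                  self._psi, self._omega, self._pos)
        return self._psi[0].copy(), self._omega[0].copy(), self._pos[0].copy()


def _log_skips(X: str, tables: ABCkTables, n: int, seq_id: str) -> None:
    codes = tables.encode(X)
    n_skip = int((~_clean_window_mask(codes.astype(np.int64), n)).sum())
    total = len(X) - n + 1
    if n_skip:
        logger.warning("%s: skipped %d of %d windows containing non-alphabet symbols",
                       seq_id or "<seq>", n_skip, total)
    else:
        logger.debug("%s: seeded %d windows", seq_id or "<seq>", total)
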