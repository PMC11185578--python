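"""Sliding-window DP: subproblem tables, optimizer, traceback, driver."""

import itertools

import numpy as np
import pytest

from subseqseed.dp import (best_in_window, iterate, omega_opt, orders_for_t,
                           psi_opt, seed_sequence)
from subseqseed.reference import (brute_force_seeds, omega_forward,
                                  omega_reverse, pi_score, psi_forward,
                                  psi_reverse, revcomp)
from subseqseed.tables import make_random_tables, make_rc_symmetric_tables

from conftest import random_dna


def _span_oracle_forward(span: str, l: int, j: int, tables):
    """Enumerated (min, max) forward omega over length-l subsequences of the
    span with forward residue j; None if none exists."""
    vals = [omega_forward("".join(c), tables)
            for c in itertools.combinations(span, l)
            if psi_forward("".join(c), tables) == j]
    return (min(vals), max(vals)) if vals else None


def _span_oracle_reverse(span: str, l: int, j: int, tables):
    vals = [omega_reverse("".join(c)[::-1], tables)
            for c in itertools.combinations(span, l)
            if psi_reverse("".join(c)[::-1], tables) == j]
    return (min(vals), max(vals)) if vals else None


class TestIterate:
    def test_initialization_rows(self, small_tables, rng):
        X = random_dna(rng, 12)
        st = iterate(X, 8, small_tables, engine="elementwise")
        d = small_tables.d
        for s in range(len(X) + 1):
            for b in range(0, min(8, len(X) - s) + 1):
                assert st.ffeas[s, b, 0, 0] and st.fmin[s, b, 0, 0] == 0
                assert st.rfeas[s, b, 0, 0] and st.rmax[s, b, 0, 0] == 0
                for j in range(1, d):
                    assert not st.ffeas[s, b, 0, j]
                    assert not st.rfeas[s, b, 0, j]

    def test_single_step_entries(self, small_tables, rng):
        t = small_tables
        X = random_dna(rng, 10)
        st = iterate(X, 6, t, engine="elementwise")
        codes = t.encode(X)
        for s in range(len(X)):
            sigma = int(codes[s])
            for j in range(t.d):
                if j == int(t.CF[0, sigma]):
                    assert st.ffeas[s, 1, 1, j]
                    expect = int(t.AF[0, j, sigma]) * int(t.BF2[0, j, sigma])
                    assert st.fmin[s, 1, 1, j] == st.fmax[s, 1, 1, j] == expect
                else:
                    assert not st.ffeas[s, 1, 1, j]

    def test_entries_match_enumeration(self, rng):
        t = make_random_tables(4, 5, 17)
        X = random_dna(rng, 14)
        st = iterate(X, 9, t, engine="elementwise")
        for s in range(len(X) + 1):
            for b in range(min(9, len(X) - s) + 1):
                span = X[s:s + b]
                for l in range(min(4, b) + 1):
                    for j in range(5):
                        fo = _span_oracle_forward(span, l, j, t)
                        if fo is None:
                            assert not st.ffeas[s, b, l, j]
                        else:
                            assert st.ffeas[s, b, l, j]
                            assert (st.fmin[s, b, l, j], st.fmax[s, b, l, j]) == fo
                        ro = _span_oracle_reverse(span, l, j, t)
                        if ro is None:
                            assert not st.rfeas[s, b, l, j]
                        else:
                            assert st.rfeas[s, b, l, j]
                            assert (st.rmin[s, b, l, j], st.rmax[s, b, l, j]) == ro

    def test_feasible_implies_min_le_max(self, small_tables, rng):
        X = random_dna(rng, 20)
        st = iterate(X, 8, small_tables, engine="numba")
        assert (st.fmin[st.ffeas] <= st.fmax[st.ffeas]).all()
        assert (st.rmin[st.rfeas] <= st.rmax[st.rfeas]).all()

    def test_bad_parameters(self, small_tables):
        with pytest.raises(ValueError):
            iterate("ACG", 8, small_tables)
        with pytest.raises(ValueError):
            iterate("ACGTACGT", 8, small_tables, engine="turbo")


class TestEngines:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_three_engines_bit_identical(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        d = int(rng.integers(2, 9))
        n = int(rng.integers(k + 1, 11))
        t = make_random_tables(k, d, seed)
        X = random_dna(rng, 18)
        states = {e: iterate(X, n, t, engine=e)
                  for e in ("elementwise", "vectorized", "numba")}
        ref = states["elementwise"]
        for e in ("vectorized", "numba"):
            for f in ("fmin", "fmax", "rmin", "rmax", "ffeas", "rfeas"):
                assert np.array_equal(getattr(ref, f), getattr(states[e], f)), (e, f)


class TestOptimizer:
    def test_psi_opt_matches_enumeration(self, rng):
        t = make_random_tables(4, 6, 3)
        X = random_dna(rng, 12)
        n = 9
        st = iterate(X, n, t, engine="vectorized")
        for w in range(st.num_windows):
            win = X[w:w + n]
            for i in range(1, 5):
                for b in range(1, n + 1):
                    got = psi_opt(w, b, i, st)
                    cands = [(pi_score("".join(s1) + win[b - 1] + "".join(s2), i, t))
                             for s1 in itertools.combinations(win[:b - 1], i - 1)
                             for s2 in itertools.combinations(win[b:], 4 - i)]
                    if not cands:
                        assert got is None
                    else:
                        assert got == min(c.psi for c in cands)

    def test_omega_opt_matches_enumeration(self, rng):
        t = make_random_tables(4, 4, 9)
        X = random_dna(rng, 11)
        n = 8
        st = iterate(X, n, t, engine="vectorized")
        checked = 0
        for w in range(st.num_windows):
            win = X[w:w + n]
            for i in range(1, 5):
                for b in range(1, n + 1):
                    psi = psi_opt(w, b, i, st)
                    if psi is None:
                        continue
                    scores = [pi_score("".join(s1) + win[b - 1] + "".join(s2), i, t)
                              for s1 in itertools.combinations(win[:b - 1], i - 1)
                              for s2 in itertools.combinations(win[b:], 4 - i)]
                    best = max(s.omega for s in scores if s.psi == psi)
                    assert omega_opt(w, b, i, psi, st) == best
                    checked += 1
        assert checked > 50

    def test_omega_opt_rejects_infeasible(self, small_tables, rng):
        X = random_dna(rng, 10)
        st = iterate(X, 8, small_tables, engine="vectorized")
        with pytest.raises(ValueError):
            omega_opt(0, 1, 1, None, st)


class TestBestInWindow:
    def test_window_equals_k(self, rng):
        t = make_random_tables(5, 4, 21)
        X = random_dna(rng, 5)
        st = iterate(X, 5, t, engine="elementwise")
        for s in best_in_window(0, st):
            assert s.seed == X
            assert s.positions == (0, 1, 2, 3, 4)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        d = int(rng.integers(2, 9))
        n = int(rng.integers(k + 2, 12))
        t = make_random_tables(k, d, 1000 + seed)
        X = random_dna(rng, n + 5)
        st = iterate(X, n, t, engine="numba")
        for w in range(st.num_windows):
            dp = best_in_window(w, st)
            br = brute_force_seeds(X[w:w + n], t, order_indices=range(1, k + 1),
                                   window_start=w)
            assert [(s.order_index, s.score, s.seed, s.positions) for s in dp] == \
                   [(s.order_index, s.score, s.seed, s.positions) for s in br]

    def test_repetitive_windows_match_brute_force(self, fixture_tables):
        for X in ("A" * 12, "ACACACACACAC", "ACGTACGTACGT"):
            st = iterate(X, 10, fixture_tables, engine="numba")
            for w in range(st.num_windows):
                dp = best_in_window(w, st)
                br = brute_force_seeds(X[w:w + 10], fixture_tables,
                                       order_indices=range(1, 7), window_start=w)
                assert [(s.seed, s.positions) for s in dp] == \
                       [(s.seed, s.positions) for s in br]


class TestSeedSequence:
    def test_sequence_equals_window_gives_t_seeds(self, small_tables):
        X = "ACGTACGT"
        seeds = seed_sequence(X, 8, 4, 2, small_tables)
        assert len(seeds) == 2
        assert all(s.window_start == 0 for s in seeds)

    def test_matches_per_window_recomputation(self, rng):
        t = make_random_tables(6, 5, 31)
        X = random_dna(rng, 12)
        got = seed_sequence(X, 10, 6, 6, t, engine="numba")
        st = iterate(X, 10, t, engine="vectorized")
        want = []
        for w in range(st.num_windows):
            want.extend(best_in_window(w, st))
        assert [(s.window_start, s.order_index, s.seed, s.positions, s.score)
                for s in got] == \
               [(s.window_start, s.order_index, s.seed, s.positions, s.score)
                for s in want]

    def test_periodic_translation_invariance(self, small_tables):
        X = "ACGT" * 6
        seeds = seed_sequence(X, 8, 4, 4, small_tables)
        by_window = {}
        for s in seeds:
            by_window.setdefault(s.window_start, []).append((s.order_index, s.seed, s.score))
        # windows 0, 4, 8, ... have identical content
        assert by_window[0] == by_window[4] == by_window[8]

    def test_chunking_is_exact(self, rng):
        t = make_random_tables(4, 5, 51)
        X = random_dna(rng, 60)
        a = seed_sequence(X, 9, 4, 4, t, block_windows=5)
        b = seed_sequence(X, 9, 4, 4, t, block_windows=1000)
        assert a == b

    def test_non_acgt_windows_skipped_and_lowercase_ok(self, small_tables):
        X = "acgtACGTNacgtacgt"
        seeds = seed_sequence(X, 6, 4, 1, small_tables)
        skipped = {w for w in range(len(X) - 5)
                   if 8 in range(w, w + 6)}
        assert {s.window_start for s in seeds} == set(range(len(X) - 5)) - skipped
        assert all(set(s.seed) <= set("ACGT") for s in seeds)

    def test_t_out_of_range(self, small_tables):
        with pytest.raises(ValueError):
            seed_sequence("ACGTACGT", 8, 4, 0, small_tables)
        with pytest.raises(ValueError):
            seed_sequence("ACGTACGT", 8, 4, 5, small_tables)

    def test_sorted_output(self, rng):
        t = make_random_tables(4, 3, 5)
        X = random_dna(rng, 30)
        seeds = seed_sequence(X, 8, 4, 4, t)
        keys = [(s.window_start, s.order_index) for s in seeds]
        assert keys == sorted(keys)


class TestOrdersForT:
    def test_t1_is_middle(self):
        assert orders_for_t(6, 1) == [3]
        assert orders_for_t(5, 1) == [3]

    def test_tk_is_all(self):
        assert orders_for_t(4, 4) == [1, 2, 3, 4]

    def test_evenly_spaced(self):
        assert orders_for_t(24, 2) == [1, 24]
        sel = orders_for_t(24, 10)
        assert len(sel) == 10 and sel[0] == 1 and sel[-1] == 24

    def test_rc_closure(self):
        for k, t in [(6, 3), (6, 1), (24, 10), (5, 2)]:
            sel = orders_for_t(k, t, rc_symmetric=True)
            assert sorted(k + 1 - i for i in sel) == sel

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            orders_for_t(6, 0)
        with pytest.raises(ValueError):
            orders_for_t(6, 7)


class TestRcEndToEnd:
    def test_seed_sets_correspond(self, rng):
        t = make_rc_symmetric_tables(6, 5, 13)
        X = random_dna(rng, 50)
        n = 12
        W = len(X) - n
        fwd = seed_sequence(X, n, 6, 6, t)
        bwd = seed_sequence(revcomp(X), n, 6, 6, t)
        bidx = {(s.window_start, s.order_index): s for s in bwd}
        for s in fwd:
            m = bidx[(W - s.window_start, 7 - s.order_index)]
            assert m.score == s.score
            assert m.seed == revcomp(s.seed)
            assert m.positions == tuple(sorted(n - 1 - p for p in s.positions))

    def test_homopolymer_rc_correspondence(self):
        t = make_rc_symmetric_tables(4, 3, 2)
        a = seed_sequence("A" * 10, 10, 4, 4, t)
        b = seed_sequence("T" * 10, 10, 4, 4, t)
        for s, m in zip(a, sorted(b, key=lambda x: 5 - x.order_index)):
            assert m.order_index == 5 - s.order_index
            assert m.seed == revcomp(s.seed)
            assert m.positions == tuple(sorted(9 - p for p in s.positions))
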