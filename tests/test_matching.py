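"""Seed-match collection, truth classification and evaluation metrics."""

import math

import pytest

from subseqseed.dp import seed_sequence
from subseqseed.matching import (GroundTruthAlignment, SeedMatch,
                                 collect_matches, coverage, is_true_match,
                                 match_precision, overlap_candidates,
                                 overlap_metrics, segment_sensitivity)
from subseqseed.reference import ScorePair, Seed, revcomp
from subseqseed.tables import make_random_tables, make_rc_symmetric_tables

from conftest import random_dna


def _seed(seq_id, start, positions, seed_str, order=1):
    return Seed(seq_id=seq_id, window_start=start, order_index=order,
                seed=seed_str, positions=tuple(positions), score=ScorePair(0, 0))


def _match(start_a, start_b, k=4, seed_str="ACGT"):
    sa = _seed("a", start_a, range(k), seed_str)
    sb = _seed("b", start_b, range(k), seed_str)
    from subseqseed.variants import match_key
    return SeedMatch(sa, sb, match_key(sa, k))


def _identity_truth(n):
    return GroundTruthAlignment(tuple((i, i) for i in range(n)))


class TestCollectMatches:
    def test_identical_sequences_match_everywhere(self, rng):
        t = make_random_tables(5, 5, 1)
        X = random_dna(rng, 30)
        seeds = seed_sequence(X, 10, 5, 1, t, seq_id="a")
        matches = collect_matches(seeds, seeds)
        per_window = {s.window_start for m in matches
                      for s in (m.seed_a,) if m.seed_b.window_start == s.window_start}
        assert per_window == {s.window_start for s in seeds}

    def test_disjoint_random_sequences_rarely_match_long_k(self):
        t = make_random_tables(24, 11, 2)
        total = 0
        import numpy as np
        for trial in range(10):
            r = np.random.default_rng(trial)
            a = seed_sequence(random_dna(r, 30), 30, 24, 1, t, seq_id="a")
            b = seed_sequence(random_dna(r, 30), 30, 24, 1, t, seq_id="b")
            total += len(collect_matches(a, b))
        assert total <= 1  # sharing a specific 24-mer by chance is vanishing

    def test_rc_mode_matches_reverse_complement(self, rng):
        t = make_rc_symmetric_tables(6, 5, 3)
        X = random_dna(rng, 40)
        a = seed_sequence(X, 12, 6, 6, t, seq_id="a")
        b = seed_sequence(revcomp(X), 12, 6, 6, t, seq_id="b")
        matches = collect_matches(a, b, rc_mode=True, k=6)
        matched_windows = {m.seed_a.window_start for m in matches}
        assert matched_windows == {s.window_start for s in a}

    def test_mixed_seed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            collect_matches([_seed("a", 0, range(4), "ACGT")],
                            [_seed("b", 0, range(5), "ACGTA")])


class TestIsTrueMatch:
    def test_unmutated_region_is_true(self):
        m = _match(10, 10)
        assert is_true_match(m, _identity_truth(100))

    def test_chance_match_between_unrelated_regions_is_false(self):
        m = _match(10, 50)
        assert not is_true_match(m, _identity_truth(100))

    def test_exactly_half_is_false(self):
        # 2 of 4 aligned pairs coincide: not strictly more than 50%
        sa = _seed("a", 0, (0, 1, 2, 3), "ACGT")
        sb = _seed("b", 0, (0, 1, 4, 5), "ACGT")
        from subseqseed.variants import match_key
        m = SeedMatch(sa, sb, match_key(sa, 4))
        assert not is_true_match(m, _identity_truth(100))
        # 3 of 4: true
        sb2 = _seed("b", 0, (0, 1, 2, 5), "ACGT")
        assert is_true_match(SeedMatch(sa, sb2, match_key(sa, 4)), _identity_truth(100))


class TestMetrics:
    def test_precision_mixed(self):
        matches = [_match(0, 0), _match(8, 8), _match(16, 16), _match(30, 70)]
        assert match_precision(matches, _identity_truth(100)) == 0.75

    def test_precision_all_true(self):
        assert match_precision([_match(0, 0)], _identity_truth(10)) == 1.0

    def test_precision_empty_is_nan(self):
        assert math.isnan(match_precision([], _identity_truth(10)))

    def test_segment_sensitivity_one_of_five(self):
        # read of 1000 -> five 200 bp segments; one true match inside segment 2
        m = _match(250, 250)
        assert segment_sensitivity([m], _identity_truth(1000), 1000) == 0.2

    def test_segment_sensitivity_extremes(self):
        truth = _identity_truth(400)
        assert segment_sensitivity([], truth, 400) == 0.0
        ms = [_match(i, i) for i in range(0, 400, 50)]
        assert segment_sensitivity(ms, truth, 400) == 1.0

    def test_coverage_single_span(self):
        # one true match spanning 30 characters on each of two length-1000
        # sequences -> 60/2000 pooled
        sa = _seed("a", 100, (0, 10, 20, 29), "ACGT")
        sb = _seed("b", 100, (0, 10, 20, 29), "ACGT")
        from subseqseed.variants import match_key
        truth = _identity_truth(1000)
        tc, fc = coverage([SeedMatch(sa, sb, match_key(sa, 4))], truth, 1000, 1000)
        assert tc == pytest.approx(60 / 2000)
        assert fc == 0.0

    def test_coverage_no_matches(self):
        assert coverage([], _identity_truth(10), 100, 100) == (0.0, 0.0)

    def test_counts_conserved(self):
        matches = [_match(0, 0), _match(30, 70), _match(8, 8)]
        truth = _identity_truth(100)
        n_true = sum(is_true_match(m, truth) for m in matches)
        n_false = sum(not is_true_match(m, truth) for m in matches)
        assert n_true + n_false == len(matches)


class TestOverlap:
    def test_duplicated_read_set_full_sensitivity(self, rng):
        t = make_random_tables(6, 5, 4)
        reads = {f"r{i}": random_dna(rng, 40) for i in range(4)}
        seeds = {rid: seed_sequence(seq, 12, 6, 2, t, seq_id=rid)
                 for rid, seq in reads.items()}
        dup = {**seeds, **{rid + "_copy": [
            Seed(rid + "_copy", s.window_start, s.order_index, s.seed,
                 s.positions, s.score) for s in ss] for rid, ss in seeds.items()}}
        cands = overlap_candidates(dup)
        truth = [(rid, rid + "_copy") for rid in reads]
        sens, prec = overlap_metrics(cands, truth)
        assert sens == 1.0

    def test_min_shared_filters(self):
        s1 = [_seed("a", 0, range(4), "ACGT"), _seed("a", 9, range(4), "GGGG", order=2)]
        s2 = [_seed("b", 3, range(4), "ACGT"), _seed("b", 5, range(4), "GGGG", order=2)]
        s3 = [_seed("c", 1, range(4), "ACGT")]
        reads = {"a": s1, "b": s2, "c": s3}
        assert overlap_candidates(reads, min_shared=1) == [("a", "b"), ("a", "c"), ("b", "c")]
        assert overlap_candidates(reads, min_shared=2) == [("a", "b")]

    def test_metrics_arithmetic(self):
        sens, prec = overlap_metrics([("a", "b"), ("a", "c")], [("a", "b"), ("b", "c")])
        assert sens == 0.5 and prec == 0.5
        sens, prec = overlap_metrics([], [("a", "b")])
        assert sens == 0.0 and math.isnan(prec)


class TestGroundTruth:
    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthAlignment(((0, 0), (1, 0)))
        with pytest.raises(ValueError):
            GroundTruthAlignment(((2, 0), (1, 1)))
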