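"""Unit and property tests for the tract tokenizer and window scorer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cathi.reference import reference_score, reference_tracts
from cathi.scoring import (ScoringParams, WindowScore, cluster_windows,
                           count_ggtgg, scan_sequence, score_window,
                           tokenize_window)
from conftest import random_seq

PENALIZED = ScoringParams(ggtgg_penalty=1.5)


class TestTokenize:
    @pytest.mark.parametrize("seq,expected", [
        ("GTGT", [(0, 4)]),                    # minimal 4-mer tract
        ("GGGGG", []),                         # all-G truncates to nothing
        ("AAGTGTTGTGGAA", [(2, 6), (7, 11)]),  # TT truncation then rescan
        ("TGTG", []),                          # leading T excluded, remainder < 4
        ("", []),
        ("ACACACAC", []),
        ("GTGGGGT", [(0, 5)]),                 # 4-G run truncates after 3rd G
        ("GGGTGGG", [(0, 7)]),                 # G runs of 3 are fine
        ("gtgt", [(0, 4)]),                    # lowercase normalised
        ("GTNTGT", []),                        # N breaks the run
    ])
    def test_examples(self, seq, expected):
        assert [(t.start, t.end) for t in tokenize_window(seq)] == expected

    def test_non_string_input_rejected(self):
        with pytest.raises(TypeError):
            tokenize_window(b"GTGT")

    def test_tract_invariants_on_random_sequences(self, rng):
        """Every emitted tract obeys the tract rules, on GT-rich input."""
        for _ in range(200):
            s = random_seq(rng, 75, "GGTTA")
            for t in tokenize_window(s):
                frag = s[t.start:t.end]
                assert len(frag) >= 4
                assert frag[0] == "G"
                assert set(frag) <= {"G", "T"}
                assert "TT" not in frag and "GGGG" not in frag
                assert "T" in frag


class TestScoreWindow:
    @pytest.mark.parametrize("seq,params,expected", [
        ("TG" * 31, PENALIZED, 61.0),          # strongest non-subtelomeric site
        ("GTGTGGGTGTG" + "A" * 20, PENALIZED, 11.0),
        ("AAAGGTGGAAA", PENALIZED, 3.5),       # 5-nt tract minus one penalty
        ("ACACACAC", ScoringParams(), 0.0),
        ("GGTGGTGG", PENALIZED, 8.0 - 3.0),    # overlapping GGTGG counted twice
    ])
    def test_examples(self, seq, params, expected):
        assert score_window(seq, params) == pytest.approx(expected)

    def test_overlapping_ggtgg_count(self):
        assert count_ggtgg("GGTGGTGG") == 2
        assert count_ggtgg("AGGTGGA") == 1
        assert count_ggtgg("GGTG") == 0

    def test_tt_penalty_counts_flanking_ts(self):
        # tract GTGT at [2,6) is flanked by T on both sides
        params = ScoringParams(tt_penalty=1.0)
        assert score_window("ATGTGTTA", params) == pytest.approx(4.0 - 2.0)
        assert score_window("AGTGTA", params) == pytest.approx(4.0)

    def test_scores_can_go_negative(self):
        params = ScoringParams(ggtgg_penalty=10.0)
        assert score_window("AGGTGGA", params) == pytest.approx(5.0 - 10.0)

    def test_oracle_equivalence_uniform_and_gt_enriched(self, rng):
        """Scanner equals the independent reference on 1,200 random 75-mers."""
        params = ScoringParams(ggtgg_penalty=1.5, tt_penalty=0.25)
        for i in range(1200):
            alphabet = "ACGT" if i % 2 else "GGTTAC"
            s = random_seq(rng, 75, alphabet)
            assert score_window(s, params) == reference_score(s, params), s

    def test_reference_tracts_match_tokenizer(self, rng):
        for _ in range(300):
            s = random_seq(rng, 75, "GGTTA")
            assert [(t.start, t.end) for t in tokenize_window(s)] == \
                reference_tracts(s)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    def test_score_mode_is_max_of_signal_mode(self, seq):
        params = ScoringParams(window_size=20, ggtgg_penalty=1.5)
        windows = scan_sequence(seq, params, "signal")
        assert scan_sequence(seq, params, "score") == max(w.score for w in windows)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.text(alphabet="GTAC", min_size=4, max_size=80))
    def test_scorer_agrees_with_reference_on_arbitrary_text(self, seq):
        params = ScoringParams(ggtgg_penalty=1.5, tt_penalty=0.5)
        assert score_window(seq, params) == reference_score(seq, params)

    def test_score_additivity_disjoint_windows(self, rng):
        """Concatenating windows with an A-spacer adds their scores."""
        params = ScoringParams(ggtgg_penalty=1.5)
        for _ in range(50):
            a = random_seq(rng, 40, "GGTTA")
            b = random_seq(rng, 40, "GGTTA")
            combined = a + "AA" + b
            big = ScoringParams(window_size=len(combined), ggtgg_penalty=1.5)
            assert score_window(combined, big) == pytest.approx(
                score_window(a, params) + score_window(b, params))

    def test_determinism(self):
        s = "TG" * 40
        assert score_window(s, PENALIZED) == score_window(s, PENALIZED)


class TestScanSequence:
    def test_signal_window_count(self):
        windows = scan_sequence("A" * 300, ScoringParams(), "signal")
        assert len(windows) == 300 - 75 + 1

    def test_all_a_max_score_zero(self):
        assert scan_sequence("A" * 200, ScoringParams(), "score") == 0.0

    def test_planted_tg10_argmax(self):
        """A (TG)10 at offset 50 scores 19 and the argmax window covers it."""
        seq = "A" * 50 + "TG" * 10 + "A" * 130
        params = ScoringParams()
        assert scan_sequence(seq, params, "score") == 19.0
        windows = scan_sequence(seq, params, "signal")
        best = max(windows, key=lambda w: w.score)
        assert best.score == 19.0
        assert best.start <= 50 and best.end >= 70
        # brute-force verification of every window
        for w in windows:
            assert w.score == reference_score(seq[w.start:w.end], params)

    def test_short_sequence_scored_whole(self):
        assert scan_sequence("TG" * 10, ScoringParams(), "score") == 19.0
        windows = scan_sequence("TG" * 10, ScoringParams(), "signal")
        assert len(windows) == 1 and windows[0].end == 20

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_sequence("", ScoringParams())

    def test_step_size(self):
        windows = scan_sequence("A" * 300, ScoringParams(step=25), "signal")
        assert [w.start for w in windows] == list(range(0, 226, 25))


class TestClusterWindows:
    def make(self, start, score, width=75):
        return WindowScore(start, start + width, score)

    def test_merge_rule(self):
        windows = [self.make(10, 25), self.make(11, 22), self.make(300, 21)]
        regions = cluster_windows(windows, 20.0)
        assert [(r.start, r.end, r.score, r.n_windows) for r in regions] == \
            [(10, 86, 25, 2), (300, 375, 21, 1)]

    def test_all_below_threshold(self):
        assert cluster_windows([self.make(0, 19.9)], 20.0) == []

    def test_threshold_is_inclusive(self):
        regions = cluster_windows([self.make(5, 20.0)], 20.0)
        assert len(regions) == 1 and regions[0].score == 20.0

    def test_abutting_windows_merge(self):
        regions = cluster_windows([self.make(0, 21, 10), self.make(10, 22, 10)],
                                  20.0)
        assert len(regions) == 1 and (regions[0].start, regions[0].end) == (0, 20)

    def test_unsorted_input_sorted_internally(self):
        regions = cluster_windows([self.make(11, 22), self.make(10, 25)], 20.0)
        assert len(regions) == 1 and regions[0].start == 10

    def test_monotone_threshold_containment(self, rng):
        """Raising the threshold never widens regions nor grows coverage.

        Every surviving region is contained in a region from the lower
        threshold (one parent region may split when a bridging window
        drops out, but coverage only shrinks).
        """
        windows = [self.make(int(s), float(sc))
                   for s, sc in zip(rng.integers(0, 2000, 60),
                                    rng.uniform(0, 40, 60))]
        prev = cluster_windows(windows, 10.0)
        prev_cov = sum(r.end - r.start for r in prev)
        for thr in (15.0, 20.0, 25.0, 30.0):
            cur = cluster_windows(windows, thr)
            for reg in cur:
                parents = [p for p in prev
                           if p.start <= reg.start and p.end >= reg.end]
                assert parents, "region widened when threshold was raised"
            cov = sum(r.end - r.start for r in cur)
            assert cov <= prev_cov
            prev, prev_cov = cur, cov


class TestScoringParams:
    @pytest.mark.parametrize("kwargs", [
        {"window_size": 2}, {"step": 0}, {"ggtgg_penalty": -1},
        {"tt_penalty": -0.5}, {"cluster_threshold": -1},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringParams(**kwargs)
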