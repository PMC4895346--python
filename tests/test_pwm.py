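"""PWM construction, P-value thresholds, scanning and site filtering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfocc.pwm import (HUMAN_BACKGROUND, InvalidMatrixError,
                       PositionFrequencyMatrix, SiteList,
                       best_match_in_window,
                       filter_sites_by_tag_support,
                       log_odds_from_probabilities, motif_center_offset,
                       scan_sequence, score_distribution,
                       score_threshold_from_pvalue)
from tfocc.tracks import TagTrack

from conftest import random_pfm

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def brute_force_scan(seq, pwm, threshold):
    """Independent all-windows scorer: explicit per-window sums, both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = len(pwm)
    hits = []
    for start in range(len(seq) - n + 1):
        window = seq[start:start + n].upper()
        if any(b not in idx for b in window):
            continue
        fwd = sum(pwm.weights[j, idx[b]] for j, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(pwm.weights[j, idx[b]] for j, b in enumerate(rc))
        if fwd >= threshold:
            hits.append((start + motif_center_offset(n, "+"), "+",
                         round(fwd, 9)))
        if rev >= threshold:
            hits.append((start + motif_center_offset(n, "-"), "-",
                         round(rev, 9)))
    return sorted(hits)


def exact_score_tail(pwm):
    """All (score, probability) pairs by exhaustive k-mer enumeration."""
    pairs = []
    for kmer in itertools.product(range(4), repeat=len(pwm)):
        score = sum(pwm.weights[j, b] for j, b in enumerate(kmer))
        prob = float(np.prod([pwm.background[b] for b in kmer]))
        pairs.append((score, prob))
    return pairs


class TestLogOdds:
    def test_background_rows_give_zero_weights(self):
        pfm = PositionFrequencyMatrix(
            np.tile(HUMAN_BACKGROUND, (3, 1)), "bg")
        pwm = log_odds_from_probabilities(pfm, pseudocount=0.0)
        assert np.allclose(pwm.weights, 0.0)

    def test_hand_computed_single_position(self):
        pfm = PositionFrequencyMatrix(np.array([[1.0, 0, 0, 0]]), "one")
        pwm = log_odds_from_probabilities(pfm, UNIFORM, pseudocount=0.01)
        # w[A] = log2((1 + 0.01*0.25) / (1.01 * 0.25))
        assert pwm.weights[0, 0] == pytest.approx(
            np.log2((1 + 0.01 * 0.25) / (1.01 * 0.25)))
        # w[C] = log2((0 + 0.01*0.25) / (1.01 * 0.25))
        assert pwm.weights[0, 1] == pytest.approx(
            np.log2(0.01 * 0.25 / (1.01 * 0.25)))

    def test_roundtrip_recovers_adjusted_probabilities(self, rng):
        pfm = random_pfm(rng, 6)
        pc = 0.05
        pwm = log_odds_from_probabilities(pfm, HUMAN_BACKGROUND, pc)
        bg = np.asarray(HUMAN_BACKGROUND)
        recovered = (2.0 ** pwm.weights) * bg
        recovered /= recovered.sum(axis=1, keepdims=True)
        expected = (pfm.probabilities + pc * bg) / (1 + pc)
        assert np.allclose(recovered, expected)

    def test_zero_row_rejected(self):
        pfm = PositionFrequencyMatrix(np.array([[0.0, 0, 0, 0]]), "zero")
        with pytest.raises(InvalidMatrixError):
            log_odds_from_probabilities(pfm)


class TestScoreThreshold:
    def test_pvalue_one_gives_minimum_score(self, toy_pwm):
        t = score_threshold_from_pvalue(toy_pwm, 1.0)
        assert t <= toy_pwm.min_score + len(toy_pwm) * 0.01 / 2 + 1e-9

    @pytest.mark.parametrize("pvalue", [1e-2, 1e-3, 1e-4])
    @pytest.mark.parametrize("length", [3, 5, 8])
    def test_matches_exhaustive_enumeration(self, pvalue, length):
        """The accepted k-mer set at the convolution threshold equals the
        set accepted by exhaustive enumeration at the same P-value."""
        pwm = log_odds_from_probabilities(
            random_pfm(np.random.default_rng(length * 97), length))
        grid = 1e-3
        t = score_threshold_from_pvalue(pwm, pvalue, grid=grid)
        pairs = exact_score_tail(pwm)
        # exact threshold over achievable scores
        uniq = sorted({s for s, _ in pairs}, reverse=True)
        t_exact = None
        for s in uniq:
            tail = sum(p for sc, p in pairs if sc >= s - 1e-12)
            if tail <= pvalue:
                t_exact = s
            else:
                break
        if t_exact is None:
            # even the best k-mer exceeds the P-value: nothing is accepted
            assert t > max(s for s, _ in pairs)
            return
        # outside the grid-rounding band the accepted k-mer sets agree;
        # inside it the discretized decision may legitimately differ
        rounding = len(pwm) * grid / 2 + grid
        accepted_conv = {i for i, (s, _) in enumerate(pairs) if s >= t}
        accepted_exact = {i for i, (s, _) in enumerate(pairs)
                          if s >= t_exact - 1e-12}
        for i in accepted_conv.symmetric_difference(accepted_exact):
            assert abs(pairs[i][0] - t_exact) <= rounding
        # t brackets the exact threshold at grid resolution
        rejected = [s for s, _ in pairs if s < t_exact - 1e-12]
        if rejected:
            assert t > max(rejected) - rounding
        assert t <= t_exact + rounding

    def test_monotone_in_pvalue(self, toy_pwm):
        thresholds = [score_threshold_from_pvalue(toy_pwm, p)
                      for p in (0.5, 0.1, 0.01, 0.001)]
        assert all(b >= a for a, b in zip(thresholds, thresholds[1:]))

    def test_distribution_sums_to_one(self, toy_pwm):
        _, probs = score_distribution(toy_pwm)
        assert probs.sum() == pytest.approx(1.0)

    def test_invalid_pvalue(self, toy_pwm):
        for bad in (0.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                score_threshold_from_pvalue(toy_pwm, bad)


class TestScan:
    def test_consensus_self_match(self, toy_pwm):
        hits = scan_sequence(toy_pwm.consensus, toy_pwm,
                             toy_pwm.max_score - 1e-9)
        plus = hits.frame[hits.frame.strand == "+"]
        assert len(plus) == 1
        assert plus.iloc[0]["score"] == pytest.approx(toy_pwm.max_score)
        assert plus.iloc[0]["center"] == motif_center_offset(len(toy_pwm))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pwm = log_odds_from_probabilities(random_pfm(rng, 5))
        seq = "".join(rng.choice(list("ACGTN"), size=10_000,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        threshold = score_threshold_from_pvalue(pwm, 0.01)
        hits = scan_sequence(seq, pwm, threshold)
        got = sorted((int(r.center), r.strand, round(r.score, 9))
                     for r in hits)
        assert got == brute_force_scan(seq, pwm, threshold)

    def test_reverse_complement_mirror(self, rng):
        pwm = log_odds_from_probabilities(random_pfm(rng, 6))
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        threshold = score_threshold_from_pvalue(pwm, 0.01)
        fwd = scan_sequence(seq, pwm, threshold)
        rev = scan_sequence(rc, pwm, threshold)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted((len(seq) - 1 - r.center, flip[r.strand],
                           round(r.score, 9)) for r in rev)
        direct = sorted((r.center, r.strand, round(r.score, 9))
                        for r in fwd)
        assert mirrored == direct

    def test_even_length_center_upstream_of_midpoint(self):
        pfm = PositionFrequencyMatrix(np.eye(4)[:, [0, 1, 2, 3]] * 0.97
                                      + 0.01, "even4")
        pwm = log_odds_from_probabilities(pfm)
        hits = scan_sequence(pwm.consensus, pwm, pwm.max_score - 1e-9)
        plus = hits.frame[hits.frame.strand == "+"]
        assert plus.iloc[0]["center"] == 1

    def test_short_sequence_empty(self, toy_pwm):
        assert len(scan_sequence("ACG", toy_pwm, -100)) == 0


class TestBestMatch:
    def test_consensus_at_center(self, toy_pwm, rng):
        flank = "".join(rng.choice(list("ACGT"), size=300))
        center = 150
        n = len(toy_pwm)
        start = center - motif_center_offset(n)
        seq = flank[:start] + toy_pwm.consensus + flank[start + n:]
        score, offset, strand = best_match_in_window(seq, toy_pwm, center)
        assert score == pytest.approx(toy_pwm.max_score)
        assert (offset, strand) == (0, "+")

    def test_planted_on_minus_strand_recovered(self, rng):
        pwm = log_odds_from_probabilities(random_pfm(rng, 7, "strong"))
        rc = pwm.consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "".join(rng.choice(list("ACGT"), size=600))
        center, delta = 300, 37
        n = len(pwm)
        start = center + delta - motif_center_offset(n, "-")
        seq = seq[:start] + rc + seq[start + n:]
        score, offset, strand = best_match_in_window(seq, pwm, center)
        # brute-force over every window and strand
        best = max(brute_force_scan(seq, pwm, -np.inf),
                   key=lambda h: (h[2], -abs(h[0] - center),
                                  h[1] == "+"))
        assert score == pytest.approx(best[2])
        if score == pytest.approx(pwm.max_score):
            assert (offset, strand) == (delta, "-")

    def test_no_window_gives_sentinel(self, toy_pwm):
        score, offset, strand = best_match_in_window("AC", toy_pwm, 1)
        assert np.isnan(score) and strand == "."


class TestTagSupportFilter:
    def test_graded_counts(self):
        sites = SiteList.from_records(
            [("chr1", 1000 * (i + 1), "+", 0.0, f"s{i}") for i in range(10)])
        records = []
        for i in range(10):            # plant i tags at site i
            records.extend(("chr1", 1000 * (i + 1) + j, "+")
                           for j in range(i))
        track = TagTrack.from_positions(records)
        kept = filter_sites_by_tag_support(sites, [track], min_count=3)
        assert list(kept.frame["id"]) == [f"s{i}" for i in range(3, 10)]

    def test_zero_tags_removed_and_any_track_suffices(self, site_list):
        empty = TagTrack()
        hit = TagTrack.from_positions(
            [("chr1", site_list.centers[0] + d, "+") for d in (-5, 0, 5)])
        kept = filter_sites_by_tag_support(site_list, [empty, hit])
        assert list(kept.frame["id"]) == ["s0"]
        with pytest.raises(ValueError):
            filter_sites_by_tag_support(site_list, [])


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_scan_equals_brute_force_property(seed):
    """Property: the vectorized scanner equals the naive scorer."""
    rng = np.random.default_rng(seed)
    pwm = log_odds_from_probabilities(random_pfm(rng, int(rng.integers(3, 9))))
    seq = "".join(rng.choice(list("ACGTN"), size=800,
                             p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    threshold = float(rng.uniform(pwm.min_score, pwm.max_score))
    hits = scan_sequence(seq, pwm, threshold)
    got = sorted((int(r.center), r.strand, round(r.score, 9)) for r in hits)
    assert got == brute_force_scan(seq, pwm, threshold)
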