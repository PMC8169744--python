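"""Scoring pipeline: thresholds, components, attribution, weights, buckets."""

import numpy as np
import pytest

import cacscore as c
from cacscore.scoring import (ScoringConfig, agatston_weight, assign_vessel,
                              binarize_calcium, bucket, binary_at_cutoff,
                              extract_lesions, score_volume)

from conftest import random_prob_volume
from helpers_oracle import naive_score_volume, naive_weight


def _prob(calc, vessel=None):
    calc = np.asarray(calc, dtype=float)
    if vessel is None:
        vessel = np.full(calc.shape[:1] + (4,) + calc.shape[1:], 0.25)
    return c.ProbabilityVolume(calc, vessel)


class TestBinarize:
    def test_strict_threshold_at_half(self):
        pv = _prob(np.full((1, 4, 4), 0.5))
        assert not binarize_calcium(pv).any()

    def test_single_pixel(self):
        calc = np.full((1, 4, 4), 0.2)
        calc[0, 2, 3] = 0.99
        mask = binarize_calcium(_prob(calc))
        assert mask.sum() == 1 and mask[0, 2, 3]


class TestExtractLesions:
    def test_diagonal_pixels_join_with_8_connectivity(self):
        calc = np.zeros((1, 5, 5))
        calc[0, 1, 1] = calc[0, 2, 2] = 0.9
        hu = np.full((1, 5, 5), 300.0)
        lesions = extract_lesions(binarize_calcium(_prob(calc)), hu, 1.0)
        assert len(lesions) == 1
        assert lesions[0].area_mm2 == 2.0

    def test_adjacent_slices_stay_separate(self):
        calc = np.zeros((2, 5, 5))
        calc[:, 2, 2] = 0.9
        hu = np.full((2, 5, 5), 300.0)
        lesions = extract_lesions(binarize_calcium(_prob(calc)), hu, 1.0)
        assert len(lesions) == 2
        assert {l.slice_index for l in lesions} == {0, 1}

    def test_area_counts_only_pixels_above_130(self):
        calc = np.zeros((1, 5, 5))
        calc[0, 2, 2:4] = 0.9
        hu = np.full((1, 5, 5), 100.0)
        hu[0, 2, 2] = 250.0
        (lesion,) = extract_lesions(binarize_calcium(_prob(calc)), hu, 0.25)
        assert lesion.area_mm2 == 0.25
        assert lesion.max_hu == 250.0

    def test_min_area_filter_drops_small_components(self):
        calc = np.zeros((1, 8, 8))
        calc[0, 1, 1] = 0.9          # 0.25 mm^2
        calc[0, 5, 4:8] = 0.9        # 1.0 mm^2
        hu = np.full((1, 8, 8), 300.0)
        cfg = ScoringConfig(min_lesion_area_mm2=1.0)
        lesions = extract_lesions(binarize_calcium(_prob(calc)), hu, 0.25,
                                  cfg)
        assert len(lesions) == 1 and lesions[0].area_mm2 == 1.0


class TestAssignVessel:
    def test_plurality_vote(self):
        calc = np.zeros((1, 5, 5))
        calc[0, 0, 0:5] = 0.9
        vessel = np.full((1, 4, 5, 5), 0.1)
        vessel[0, 1, 0, 0:3] = 0.7    # 3 pixels LAD
        vessel[0, 2, 0, 3:5] = 0.7    # 2 pixels LCX
        vessel /= vessel.sum(axis=1, keepdims=True)
        pv = c.ProbabilityVolume(calc, vessel)
        hu = np.full((1, 5, 5), 300.0)
        (lesion,) = extract_lesions(binarize_calcium(pv), hu, 1.0)
        assert assign_vessel(lesion, pv).vessel == "LAD"

    def test_tie_broken_by_probability_mass(self):
        calc = np.zeros((1, 4, 4))
        calc[0, 0, 0:2] = 0.9
        vessel = np.full((1, 4, 4, 4), 0.05)
        vessel[0, 0, 0, 0] = 0.80     # one pixel votes LCA weakly-ish
        vessel[0, 3, 0, 1] = 0.95     # one pixel votes RCA with more mass
        vessel /= vessel.sum(axis=1, keepdims=True)
        pv = c.ProbabilityVolume(calc, vessel)
        hu = np.full((1, 4, 4), 300.0)
        (lesion,) = extract_lesions(binarize_calcium(pv), hu, 1.0)
        assert assign_vessel(lesion, pv).vessel == "RCA"


class TestAgatstonWeight:
    @pytest.mark.parametrize("hu,expected", [
        (150, 1), (199.9, 1), (200, 2), (299.9, 2), (300, 3), (399.9, 3),
        (400, 4), (1000, 4),
    ])
    def test_bin_boundaries(self, hu, expected):
        assert agatston_weight(hu) == expected

    def test_sweep_matches_lookup_oracle(self):
        for hu in range(131, 1001):
            assert agatston_weight(float(hu)) == naive_weight(float(hu))


class TestBuckets:
    @pytest.mark.parametrize("score,expected", [
        (0, "I"), (0.5, "II"), (10, "II"), (10.5, "III"), (100, "III"),
        (101, "IV"), (400, "IV"), (400.5, "V"),
    ])
    def test_boundaries(self, score, expected):
        assert bucket(score) == expected

    def test_monotone_over_dense_grid(self):
        grid = np.linspace(0, 600, 6001)
        idx = [c.scoring.bucket_index(bucket(s)) for s in grid]
        assert all(a <= b for a, b in zip(idx, idx[1:]))

    def test_cutoff_positive_iff_score_reaches_cutoff(self):
        assert binary_at_cutoff(100, 100)
        assert not binary_at_cutoff(99.9, 100)
        assert not any(binary_at_cutoff(0, cut) for cut in c.CUTOFFS)

    def test_cutoff_100_equivalent_to_bucket_iv_or_v(self):
        # The bucket boundary is 100 inclusive on the III side while the
        # cutoff is >= 100, so the two conventions agree everywhere except
        # at a score of exactly 100 (and fractional scores below 1, where
        # "any calcium" and "score >= 1" genuinely differ).
        for s in np.linspace(0, 600, 1201):
            if s == 100.0 or 0 < s < 1:
                continue
            assert binary_at_cutoff(s, 100) == (bucket(s) in ("IV", "V"))


class TestScoreVolume:
    def test_empty_volume_scores_zero_bucket_i(self):
        pv = _prob(np.full((2, 6, 6), 0.1))
        scores, lesions = score_volume(pv, np.full((2, 6, 6), 40.0), 0.25)
        assert scores.total == 0 and scores.bucket == "I" and not lesions

    def test_total_is_sum_of_vessels_and_lesions(self, small_phantom):
        vol, gt = small_phantom
        mask = (gt.label_volume >= 1) & (gt.label_volume <= 4)
        scores, lesions = c.score_masks(mask, gt.label_volume,
                                        gt.clean_volume,
                                        gt.spec.pixel_area_mm2)
        assert scores.total == pytest.approx(
            sum(scores.per_vessel.values()))
        assert scores.total == pytest.approx(
            sum(l.agatston() for l in lesions))

    def test_slice_permutation_leaves_scores_unchanged(self):
        rng = np.random.default_rng(4)
        pv = random_prob_volume(rng, n_slices=4, size=16)
        hu = rng.uniform(-100, 500, (4, 16, 16))
        ref = score_volume(pv, hu, 0.25)[0]
        perm = [2, 0, 3, 1]
        pv2 = c.ProbabilityVolume(pv.calc[perm], pv.vessel[perm])
        out = score_volume(pv2, hu[perm], 0.25)[0]
        assert out.per_vessel == ref.per_vessel

    def test_scores_ignore_probability_magnitudes_beyond_threshold(self):
        rng = np.random.default_rng(9)
        pv = random_prob_volume(rng, n_slices=2, size=12)
        hu = rng.uniform(-100, 500, (2, 12, 12))
        ref = score_volume(pv, hu, 0.25)[0]
        calc = np.where(pv.calc > 0.5, 0.93, 0.07)  # same mask, new values
        out = score_volume(c.ProbabilityVolume(calc, pv.vessel), hu, 0.25)[0]
        assert out.per_vessel == ref.per_vessel

    def test_matches_naive_oracle_on_random_volumes(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            pv = random_prob_volume(rng, n_slices=2, size=14)
            hu = rng.uniform(-200, 600, (2, 14, 14))
            scores, lesions = score_volume(pv, hu, 0.25)
            naive, naive_lesions = naive_score_volume(
                pv.calc, pv.vessel, hu, 0.25)
            assert scores.per_vessel == naive
            assert len(lesions) == len(naive_lesions)

    def test_literal_weight_variant(self):
        calc = np.zeros((1, 5, 5))
        calc[0, 2, 2] = 0.9
        hu = np.full((1, 5, 5), 40.0)
        hu[0, 2, 2] = 250.0
        pv = _prob(calc)
        cfg = ScoringConfig(literal_hu_weight=True)
        scores, _ = score_volume(pv, hu, 0.5 ** 2, cfg)
        assert scores.total == pytest.approx(0.25 * 250.0)
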