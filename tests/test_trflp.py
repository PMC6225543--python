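"""T-RFLP processing and alignment: merging, noise, DP, multiple alignment."""

import copy
import itertools
import math

import numpy as np
import pytest

from denitflux.trflp import (
    AlignParams,
    Peak,
    Profile,
    align_pair,
    build_alignment,
    classify_noise,
    combine_enzymes,
    denoise,
    peak_dissimilarity,
    refine_alignment,
    relativize,
    smooth_and_merge,
)
from denitflux.synthetic import default_trflp_truth, gen_trflp_profiles

from conftest import make_profile


def brute_force_cost(pp, qq, params):
    """Independent oracle: exhaustive search over monotone matchings."""
    best = math.inf

    def rec(i, j, cost):
        nonlocal best
        if i == len(pp) or j == len(qq):
            total = cost + (len(pp) - i + len(qq) - j) * params.gap_cost
            best = min(best, total)
            return
        d = peak_dissimilarity(pp[i], qq[j], params)
        if not math.isinf(d):
            rec(i + 1, j + 1, cost + d)
        rec(i + 1, j, cost + params.gap_cost)
        rec(i, j + 1, cost + params.gap_cost)

    rec(0, 0, 0.0)
    return best


def random_toy_profile(rng, sample_id, max_peaks=6):
    n = rng.integers(1, max_peaks + 1)
    sizes = np.sort(rng.uniform(100, 110, n))
    while np.any(np.diff(sizes) <= 0):
        sizes = np.sort(rng.uniform(100, 110, n))
    areas = rng.dirichlet(np.ones(n))
    heights = rng.dirichlet(np.ones(n))
    peaks = [Peak(float(s), float(a), float(h)) for s, a, h in zip(sizes, areas, heights)]
    return Profile(sample_id, "nirK", "HaeIII", peaks, normalized=True)


class TestSmoothAndMerge:
    def test_shoulder_pair_merges_by_rule(self, params):
        prof = make_profile("s", [100.0, 100.3], areas=[10.0, 2.0], heights=[8.0, 1.0])
        out = smooth_and_merge(prof, params)
        assert len(out.peaks) == 1
        p = out.peaks[0]
        assert p.size == pytest.approx(100.05)
        assert p.area == pytest.approx(12.0)
        assert p.height == pytest.approx(8.0)

    def test_separated_peaks_unchanged(self, params):
        prof = make_profile("s", [100.0, 100.6, 102.0])
        out = smooth_and_merge(prof, params)
        assert np.allclose(out.sizes, [100.0, 100.6, 102.0])

    def test_chain_merges_closest_pair_first(self, params):
        # left gap 0.4 < right gap 0.5: left pair merges, then the
        # 0.7 gap to the last peak stops the process
        prof = make_profile("s", [100.0, 100.4, 100.9], areas=[1.0, 1.0, 1.0])
        out = smooth_and_merge(prof, params)
        assert np.allclose(out.sizes, [100.2, 100.9])
        assert np.allclose(out.areas, [2.0, 1.0])
        # right gap smaller: merging order changes the outcome
        prof = make_profile("s", [100.0, 100.45, 100.75], areas=[1.0, 1.0, 1.0])
        out = smooth_and_merge(prof, params)
        assert np.allclose(out.sizes, [100.0, 100.6])
        assert np.allclose(out.areas, [1.0, 2.0])

    def test_merged_label_follows_larger_area(self, params):
        prof = Profile(
            "s", "nirK", "HaeIII",
            [Peak(100.0, 10.0, 8.0, "frag:0"), Peak(100.3, 2.0, 1.0, "shoulder:0")],
        )
        out = smooth_and_merge(prof, params)
        assert out.peaks[0].label == "frag:0"

    def test_empty_profile_passes_through(self, params):
        prof = Profile("s", "nirK", "HaeIII", [])
        assert smooth_and_merge(prof, params).peaks == []


class TestRelativize:
    def test_areas_and_heights_sum_to_one(self):
        prof = make_profile("s", [100, 150, 200], areas=[2.0, 3.0, 5.0], heights=[1.0, 1.0, 2.0])
        out = relativize(prof)
        assert np.allclose(out.areas, [0.2, 0.3, 0.5])
        assert out.heights.sum() == pytest.approx(1.0)
        assert out.normalized

    def test_single_peak_becomes_unit(self):
        out = relativize(make_profile("s", [100.0], areas=[7.0], heights=[3.0]))
        assert out.peaks[0].area == 1.0 and out.peaks[0].height == 1.0

    def test_idempotent(self):
        prof = make_profile("s", [100, 150], areas=[2.0, 2.0])
        once = relativize(prof)
        assert relativize(once) is once

    def test_zero_profile_rejected(self):
        prof = make_profile("s", [100.0], areas=[0.0], heights=[0.0])
        with pytest.raises(ValueError):
            relativize(prof)


class TestClassifyNoise:
    def test_hand_iterated_three_sigma_rule(self, params):
        # 2 large peaks among 200 tiny ones: first pass sigma ~0.0289,
        # 3 sigma ~0.0868 flags both; second pass sigma = 0.002 flags none
        sizes = 100.0 + np.arange(202) * 1.0
        areas = np.array([0.30, 0.28] + [0.002] * 200)
        prof = Profile(
            "s", "nirK", "HaeIII",
            [Peak(s, a, a) for s, a in zip(sizes, areas)],
            normalized=True,
        )
        flags = classify_noise([prof], params)["s"]
        assert flags[:2].all()
        assert not flags[2:].any()

    def test_all_identical_peaks_are_noise(self, params):
        prof = Profile(
            "s", "nirK", "HaeIII",
            [Peak(100.0 + i, 0.1, 0.1) for i in range(10)],
            normalized=True,
        )
        assert not classify_noise([prof], params)["s"].any()

    def test_invariant_to_sample_ordering(self, params):
        rng = np.random.default_rng(0)
        profs = [random_toy_profile(rng, f"s{i}") for i in range(5)]
        a = classify_noise(profs, params)
        b = classify_noise(profs[::-1], params)
        for sid in a:
            assert np.array_equal(a[sid], b[sid])

    def test_requires_normalized_profiles(self, params):
        prof = make_profile("s", [100.0], areas=[5.0])
        with pytest.raises(ValueError):
            classify_noise([prof], params)

    def test_or_rule_flag(self):
        # with OR semantics a peak large in area only still counts as signal
        params_or = AlignParams(noise_require_both=False)
        sizes = 100.0 + np.arange(102) * 1.0
        areas = np.array([0.5] + [0.002] * 101)
        heights = np.array([0.001] * 102)
        prof = Profile(
            "s", "nirK", "HaeIII",
            [Peak(s, a, h) for s, a, h in zip(sizes, areas, heights)],
            normalized=True,
        )
        flags = classify_noise([prof], params_or)["s"]
        assert flags[0]


class TestPeakDissimilarity:
    def test_identical_peaks_zero(self, params):
        p = Peak(100.0, 0.2, 0.1)
        assert peak_dissimilarity(p, p, params) == 0.0

    def test_beyond_max_drift_infeasible(self, params):
        p, q = Peak(100.0, 0.2, 0.1), Peak(101.01, 0.2, 0.1)
        assert math.isinf(peak_dissimilarity(p, q, params))

    def test_weighted_sum_example(self, params):
        p, q = Peak(100.0, 0.2, 0.1), Peak(100.4, 0.25, 0.12)
        assert peak_dissimilarity(p, q, params) == pytest.approx(0.47)


class TestAlignPair:
    def test_self_alignment_costs_zero(self, params, toy_profile):
        res = align_pair(toy_profile, toy_profile, params)
        assert res.cost == 0.0
        assert len(res.matches) == len(toy_profile.peaks)
        assert not res.unmatched_p and not res.unmatched_q

    def test_disjoint_ranges_all_gaps(self, params):
        p = make_profile("a", [100, 101, 102], normalized=True)
        q = make_profile("b", [200, 201], normalized=True)
        res = align_pair(p, q, params)
        assert not res.matches
        assert res.cost == pytest.approx(params.gap_cost * 5)

    def test_matches_brute_force_on_random_toys(self, params):
        rng = np.random.default_rng(123)
        for _ in range(50):
            p = random_toy_profile(rng, "a")
            q = random_toy_profile(rng, "b")
            res = align_pair(p, q, params)
            assert res.cost == pytest.approx(brute_force_cost(p.peaks, q.peaks, params))

    def test_unsorted_input_rejected(self, params):
        with pytest.raises(ValueError):
            align_pair([Peak(101.0, 0.1, 0.1), Peak(100.0, 0.1, 0.1)], [Peak(100.0, 0.1, 0.1)], params)

    def test_matches_are_non_crossing(self, params):
        rng = np.random.default_rng(7)
        p = random_toy_profile(rng, "a")
        q = random_toy_profile(rng, "b")
        res = align_pair(p, q, params)
        for (i1, j1), (i2, j2) in itertools.combinations(res.matches, 2):
            assert (i1 - i2) * (j1 - j2) > 0


class TestBuildAlignment:
    def test_identical_profiles_give_zero_score(self, params, toy_profile):
        profs = [
            Profile(f"s{i}", "nirK", "HaeIII", copy.deepcopy(toy_profile.peaks), normalized=True)
            for i in range(4)
        ]
        aln = build_alignment(profs, params)
        assert len(aln.bins) == len(toy_profile.peaks)
        assert aln.score == pytest.approx(0.0, abs=1e-12)
        assert all(b.occupancy == 4 for b in aln.bins)

    def test_deterministic_under_seed(self, params):
        rng = np.random.default_rng(5)
        profs = [random_toy_profile(rng, f"s{i}") for i in range(6)]
        a = build_alignment(profs, params)
        b = build_alignment(profs, params)
        assert a.score == b.score
        assert a.bin_summary().equals(b.bin_summary())

    def test_invariants_hold(self, params):
        rng = np.random.default_rng(9)
        profs = [random_toy_profile(rng, f"s{i}") for i in range(8)]
        aln = build_alignment(profs, params)
        aln.validate()  # strictly increasing consensus sizes, score recomputable
        for b in aln.bins:
            assert len(b.members) == len(set(b.members))  # one peak per sample

    def test_needs_two_profiles(self, params, toy_profile):
        with pytest.raises(ValueError):
            build_alignment([toy_profile], params)


class TestRefineAlignment:
    def test_identical_profiles_unchanged(self, params, toy_profile):
        profs = [
            Profile(f"s{i}", "nirK", "HaeIII", copy.deepcopy(toy_profile.peaks), normalized=True)
            for i in range(4)
        ]
        aln = build_alignment(profs, params)
        ref = refine_alignment(aln, profs, params)
        assert ref.score == pytest.approx(0.0, abs=1e-12)
        assert len(ref.bins) == len(aln.bins)

    def test_score_history_strictly_decreasing(self, params):
        rng = np.random.default_rng(21)
        profs = [random_toy_profile(rng, f"s{i}") for i in range(10)]
        aln = build_alignment(profs, params)
        ref = refine_alignment(aln, profs, params)
        hist = ref.score_history
        assert all(b < a for a, b in zip(hist, hist[1:]))
        assert ref.score <= aln.score
        ref.validate()

    def test_refined_score_never_worse_over_seeds(self):
        truth = default_trflp_truth(n_fragments=8, seed=17)
        raw, _ = gen_trflp_profiles(truth, 8)
        for seed in range(10):
            params = AlignParams(seed=seed)
            prep = [relativize(smooth_and_merge(p, params)) for p in raw]
            sig = denoise(prep, params)
            aln = build_alignment(sig, params)
            ref = refine_alignment(aln, sig, params)
            assert ref.score <= aln.score + 1e-12


class TestCombineEnzymes:
    def _aligned(self, params, enzyme, n_bins, n_samples=4):
        rng = np.random.default_rng(hash(enzyme) % 2**31)
        profs = []
        for i in range(n_samples):
            sizes = np.sort(rng.uniform(100, 400, n_bins)) + rng.normal(0, 0.05, n_bins)
            sizes.sort()
            areas = rng.dirichlet(np.ones(n_bins))
            peaks = [Peak(float(s), float(a), float(a)) for s, a in zip(sizes, areas)]
            profs.append(Profile(f"s{i}", "nirK", enzyme, peaks, normalized=True))
        return build_alignment(profs, params)

    def test_column_concatenation(self, params):
        a = self._aligned(params, "HaeIII", 5)
        b = self._aligned(params, "HpyCH4IV", 3)
        combined = combine_enzymes(a, b)
        assert combined.shape[1] == len(a.bins) + len(b.bins)
        assert list(combined.index) == a.sample_ids

    def test_row_sums_add(self, params):
        a = self._aligned(params, "HaeIII", 5)
        b = self._aligned(params, "HpyCH4IV", 3)
        combined = combine_enzymes(a, b)
        expect = a.to_frame().sum(axis=1) + b.to_frame().sum(axis=1)
        assert np.allclose(combined.sum(axis=1), expect)

    def test_sample_mismatch_rejected(self, params):
        a = self._aligned(params, "HaeIII", 4, n_samples=4)
        b = self._aligned(params, "HpyCH4IV", 4, n_samples=3)
        with pytest.raises(ValueError):
            combine_enzymes(a, b)
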