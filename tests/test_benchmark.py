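import numpy as np
import pytest

from specweight import (
    BenchmarkPair,
    GeneratorConfig,
    Spectrum,
    auc_roc,
    build_frequency_table,
    contingency,
    count_no_match_queries,
    dominant_peak_profile,
    kl_to_reference,
    label_pairs,
    library_search,
    make_search_benchmark,
    optimal_cutoff,
    precision_at_k,
    tanimoto,
)
from specweight.benchmark import SearchHit


def brute_force_cutoff(scores, labels, beta=1.0):
    """Independent exhaustive scan over every candidate threshold."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    candidates = sorted(set(scores) | {round(0.01 * g, 2) for g in range(101)})
    best = (None, -1.0)
    for c in candidates:
        pred = scores >= c
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        b2 = beta * beta
        denom = (1 + b2) * tp + b2 * fn + fp
        f = (1 + b2) * tp / denom if denom else 0.0
        if f > best[1]:
            best = (c, f)
    return best


def brute_force_auc(scores, labels):
    """Fraction of concordant pos/neg pairs, ties counted half (O(n^2))."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestTanimoto:
    def test_identical_nonzero(self):
        v = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert tanimoto(v, v) == 1.0

    def test_disjoint(self):
        assert tanimoto([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_inclusion_exclusion(self):
        # |a|=3, |b|=3, |a&b|=2 -> 2 / 4
        a = [1, 1, 1, 0]
        b = [1, 1, 0, 1]
        assert tanimoto(a, b) == 0.5

    def test_all_zero_defined_as_one(self):
        assert tanimoto([0, 0], [0, 0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto([1, 0], [1, 0, 1])


class TestLabelPairs:
    def pairs(self, *coeffs):
        s = Spectrum(500.0, [100.0], [1.0])
        return [BenchmarkPair(s, s, c) for c in coeffs]

    def test_strictly_greater_is_positive(self):
        labels = label_pairs(self.pairs(0.71, 0.70, 0.69), 0.7)
        assert list(labels) == [1, 0, 0]

    def test_boundary_positive_variant(self):
        labels = label_pairs(self.pairs(0.70), 0.7, boundary_positive=True)
        assert list(labels) == [1]

    def test_higher_threshold_relabels(self):
        pairs = self.pairs(0.75, 0.85)
        assert list(label_pairs(pairs, 0.7)) == [1, 1]
        assert list(label_pairs(pairs, 0.8)) == [0, 1]

    def test_threshold_bounds_checked(self):
        with pytest.raises(ValueError):
            label_pairs(self.pairs(0.5), 1.0)


class TestOptimalCutoff:
    def test_separable_classes_give_perfect_f1(self):
        scores = [0.9, 0.85, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        cutoff, f1 = optimal_cutoff(scores, labels)
        assert f1 == 1.0
        assert 0.2 < cutoff <= 0.85

    def test_three_point_enumeration(self):
        cutoff, f1 = optimal_cutoff([0.9, 0.8, 0.3], [1, 0, 0])
        assert f1 == 1.0
        assert 0.8 < cutoff <= 0.9

    def test_ties_resolve_to_lowest_cutoff(self):
        # every cutoff in (0.2, 0.9] gives F1 = 1; the 0.21 grid point
        # is the lowest maximizer among candidates
        cutoff, _ = optimal_cutoff([0.9, 0.2], [1, 0])
        assert cutoff == pytest.approx(0.21)

    @pytest.mark.parametrize("beta", [1.0, 2.0])
    def test_matches_brute_force_on_random_sets(self, beta):
        rng = np.random.default_rng(31)
        for n in (200, 1000):
            scores = np.round(rng.uniform(0, 1, n), 3)
            labels = (rng.uniform(0, 1, n) < 0.3).astype(int)
            got_c, got_f = optimal_cutoff(scores, labels, beta)
            exp_c, exp_f = brute_force_cutoff(scores, labels, beta)
            assert got_f == pytest.approx(exp_f, abs=1e-12)
            assert got_c == pytest.approx(exp_c, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff([0.5, 0.6], [1, 1])


class TestContingency:
    def test_perfect_classifier(self):
        c = contingency([0.9, 0.8, 0.2], [1, 1, 0], 0.5)
        assert c == {"tp": 2, "fp": 0, "fn": 0, "tn": 1}

    def test_cutoff_zero_predicts_all_positive(self):
        c = contingency([0.9, 0.1], [1, 0], 0.0)
        assert c["tn"] == 0 and c["fn"] == 0

    def test_three_point_example(self):
        c = contingency([0.9, 0.8, 0.3], [1, 0, 0], 0.85)
        assert c == {"tp": 1, "fp": 0, "fn": 0, "tn": 2}

    def test_cells_sum_to_n(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 1, 500)
        labels = (rng.uniform(0, 1, 500) < 0.4).astype(int)
        c = contingency(scores, labels, 0.37)
        assert sum(c.values()) == 500

    def test_boundary_counted_positive(self):
        c = contingency([0.5], [1], 0.5)
        assert c["tp"] == 1


class TestKlDivergence:
    def test_identical_samples_zero(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 400)
        assert kl_to_reference(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_two_bin_closed_form(self):
        # P entirely in the first bin, Q uniform over both: KL = ln 2
        p = np.full(100, 0.25)
        q = np.concatenate([np.full(50, 0.25), np.full(50, 0.75)])
        assert kl_to_reference(p, q, n_bins=2) == pytest.approx(np.log(2), abs=1e-6)

    def test_asymmetric_direction(self):
        p = np.concatenate([np.full(90, 0.1), np.full(10, 0.9)])
        q = np.full(100, 0.1)
        assert kl_to_reference(p, q) != pytest.approx(kl_to_reference(q, p))

    def test_nonnegative(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            p = rng.uniform(0, 1, 100)
            q = rng.beta(2, 5, 100)
            assert kl_to_reference(p, q) >= 0.0

    def test_min_bins_checked(self):
        with pytest.raises(ValueError):
            kl_to_reference([0.5], [0.5], n_bins=1)


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_six_point_fixture_matches_pair_counting(self):
        scores = [0.9, 0.7, 0.7, 0.5, 0.4, 0.2]
        labels = [1, 1, 0, 0, 1, 0]
        assert auc_roc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    def test_matches_brute_force_and_sklearn_on_random(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        scores = np.round(rng.uniform(0, 1, 1000), 2)  # rounding forces ties
        labels = (rng.uniform(0, 1, 1000) < 0.3).astype(int)
        got = auc_roc(scores, labels)
        assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.5, 0.6], [0, 0])


def hits(qid, *tp_flags, scores=None):
    scores = scores or [1.0 - 0.05 * i for i in range(len(tp_flags))]
    return [SearchHit(qid, f"lib{i}", s, 0.0, bool(t))
            for i, (t, s) in enumerate(zip(tp_flags, scores))]


class TestPrecisionAtK:
    def test_all_top1_true(self):
        results = {"q1": hits("q1", 1, 0), "q2": hits("q2", 1)}
        assert precision_at_k(results, 1) == 1.0

    def test_top5_fraction(self):
        results = {"q": hits("q", 1, 0, 1, 0, 0)}
        assert precision_at_k(results, 5) == pytest.approx(0.4)

    def test_k_beyond_list_uses_full_list(self):
        results = {"q": hits("q", 1, 0)}
        assert precision_at_k(results, 10) == pytest.approx(0.5)

    def test_empty_query_counts_as_zero(self):
        results = {"q1": hits("q1", 1), "q2": []}
        assert precision_at_k(results, 1) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_results(self):
        rng = np.random.default_rng(2)
        results = {}
        for q in range(200):
            n = int(rng.integers(0, 8))
            results[f"q{q}"] = hits(f"q{q}", *(rng.uniform(0, 1, n) < 0.4))
        for k in (1, 5, 10):
            expected = np.mean([
                (sum(h.is_true_positive for h in hs[:k]) / min(k, len(hs)))
                if hs else 0.0
                for hs in results.values()
            ])
            assert precision_at_k(results, k) == pytest.approx(expected)


class TestNoMatchCounts:
    def test_all_matched(self):
        results = {"q": hits("q", 1, scores=[0.9])}
        assert count_no_match_queries(results, 0.5) == (0, 0)

    def test_low_best_score_counted_in_both(self):
        results = {"q": hits("q", 1, scores=[0.4])}
        assert count_no_match_queries(results, 0.5) == (1, 1)

    def test_matched_but_no_true_positive(self):
        results = {"q": hits("q", 0, scores=[0.9])}
        assert count_no_match_queries(results, 0.5) == (0, 1)

    def test_zero_threshold_counts_empty_queries(self):
        results = {"q1": hits("q1", 1, scores=[0.9]), "q2": []}
        assert count_no_match_queries(results, 0.0) == (1, 1)


class TestDominantPeakProfile:
    def test_dominant_share(self, make_spectrum):
        n, share = dominant_peak_profile(make_spectrum([1, 2, 3], [8.0, 1.0, 1.0]))
        assert n == 3 and share == pytest.approx(0.8)

    def test_uniform_not_flagged(self, make_spectrum):
        _, share = dominant_peak_profile(
            make_spectrum(list(100.0 + np.arange(10)), [1.0] * 10))
        assert share == pytest.approx(0.1)

    def test_single_peak(self, make_spectrum):
        n, share = dominant_peak_profile(make_spectrum([100.0], [3.0]))
        assert n == 1 and share == 1.0


@pytest.fixture(scope="module")
def small_search():
    cfg = GeneratorConfig(seed=3)
    return make_search_benchmark(cfg, n_reference=40, n_queries=60)


class TestLibrarySearch:
    def test_window_width_scales_with_ppm(self, small_search):
        # a 10 ppm window at 500 Th is +/- 0.005 Th
        ref = small_search.reference
        q = Spectrum(ref[0].precursor_mz + 0.004, [100.0], [1.0], identifier="q")
        near = library_search(
            type(small_search.queries)([q]), ref, ppm=10)["q"]
        assert any(h.library_id == ref[0].identifier for h in near)
        q_far = Spectrum(ref[0].precursor_mz + 0.01, [100.0], [1.0], identifier="q")
        far = library_search(type(small_search.queries)([q_far]), ref, ppm=10)["q"]
        assert all(h.library_id != ref[0].identifier for h in far)

    def test_exact_copy_ranks_first_with_unit_score(self, small_search):
        results = library_search(small_search.queries, small_search.reference,
                                 ppm=10)
        exact = list(small_search.queries)[0]  # noiseless replicate
        top = results[exact.identifier][0]
        assert top.is_true_positive
        assert top.score == pytest.approx(1.0, abs=1e-9)

    def test_wider_window_is_superset(self, small_search):
        narrow = library_search(small_search.queries, small_search.reference, ppm=10)
        wide = library_search(small_search.queries, small_search.reference, ppm=5000)
        for qid in narrow:
            assert {h.library_id for h in narrow[qid]} <= \
                {h.library_id for h in wide[qid]}

    def test_weighted_search_runs_with_table(self, small_search):
        table = build_frequency_table(small_search.reference)
        results = library_search(small_search.queries, small_search.reference,
                                 ppm=10, scheme="proposed", table=table)
        assert precision_at_k(results, 1) > 0.5

    def test_missing_precursor_rejected(self, small_search):
        from specweight import SpectrumLibrary
        bad = SpectrumLibrary([Spectrum(None, [100.0], [1.0], identifier="b")])
        with pytest.raises(ValueError):
            library_search(bad, small_search.reference, ppm=10)
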