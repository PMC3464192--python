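import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disomut import (
    FeatureAnnotation,
    MutationRecord,
    bonferroni,
    compare_strata,
    composition_profile,
    fisher_exact_2x2,
    fold_difference,
    ft_enrichment,
    interval_overlap,
    normalize_ft,
    stratified_calls,
)
from disomut.stats import fold_se_bootstrap, normalize_description

counts = st.integers(0, 60)
tables = st.tuples(counts, counts, counts, counts).filter(lambda t: sum(t) > 0)


def exact_fisher_oracle(a, b, c, d):
    """Integer-exact two-sided Fisher P via hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, col1 - (c + d)), min(row1, col1)
    numerators = {
        k: math.comb(col1, k) * math.comb(n - col1, row1 - k)
        for k in range(lo, hi + 1)
    }
    total = sum(num for num in numerators.values() if num <= numerators[a])
    return total / math.comb(n, row1)


class TestFisherExact:
    def test_equal_proportions_give_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_small_table_exact_value(self):
        # oracle: full hypergeometric enumeration over k = 0..10
        assert fisher_exact_2x2([[1, 9], [9, 1]]) == pytest.approx(202 / 184756)

    @given(t=tables)
    @settings(max_examples=150, deadline=None)
    def test_matches_integer_exact_enumeration(self, t):
        a, b, c, d = t
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            exact_fisher_oracle(a, b, c, d), rel=1e-6
        )

    @given(t=tables)
    @settings(max_examples=80, deadline=None)
    def test_invariant_under_row_and_column_swaps(self, t):
        a, b, c, d = t
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, rel=1e-9)

    def test_agrees_with_scipy_on_large_tables(self):
        from scipy.stats import fisher_exact

        for table in ([[670, 2686], [1125, 8665]], [[590, 11513], [710, 13720]]):
            ours = fisher_exact_2x2(table)
            reference = fisher_exact(table)[1]
            assert ours == pytest.approx(reference, rel=1e-6)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestBonferroni:
    @pytest.mark.parametrize(
        "raw,expected",
        [([0.01], [0.01]), ([0.01, 0.02], [0.02, 0.04]), ([0.9, 0.9], [1.0, 1.0])],
    )
    def test_examples(self, raw, expected):
        assert bonferroni(raw) == pytest.approx(expected)

    @given(ps=st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_never_decreases_and_preserves_order(self, ps):
        adjusted = bonferroni(ps)
        assert all(q >= p for p, q in zip(ps, adjusted))
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] < ps[j]:
                    assert adjusted[i] <= adjusted[j]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni([0.0])


class TestFoldDifference:
    def test_equal_proportions_fold_one(self):
        fold, _ = fold_difference([[10, 90], [20, 180]])
        assert fold == pytest.approx(1.0)

    def test_delta_method_se_formula(self):
        a, b, c, d = 670, 2686, 1125, 8665
        fold, se = fold_difference([[a, b], [c, d]])
        expected = fold * np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        assert se == pytest.approx(expected)

    @given(t=tables.filter(lambda t: t[0] > 0 and t[2] > 0))
    @settings(max_examples=60, deadline=None)
    def test_group_transpose_reciprocal(self, t):
        a, b, c, d = t
        fold, _ = fold_difference([[a, b], [c, d]])
        inverse, _ = fold_difference([[c, d], [a, b]])
        assert fold == pytest.approx(1.0 / inverse)

    def test_zero_proportion_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            fold_difference([[0, 10], [5, 5]])

    def test_bootstrap_se_close_to_delta_method(self):
        table = [[120, 880], [100, 900]]
        _, se_delta = fold_difference(table)
        se_boot = fold_se_bootstrap(table, reps=20_000, seed=3)
        assert se_boot == pytest.approx(se_delta, rel=0.15)


class TestCompositionProfile:
    def test_identical_compositions_zero_difference(self):
        counts = np.full(20, 50)
        profile = composition_profile(counts, counts, reps=200, seed=1)
        assert np.allclose(profile.difference, 0.0)

    def test_pure_sample_against_uniform_background(self):
        sample = np.zeros(20)
        sample[1] = 100  # all arginine-like mass on one residue
        background = np.full(20, 5)
        profile = composition_profile(sample, background, reps=200, seed=1)
        assert profile.difference[1] == pytest.approx((1.0 - 0.05) / 0.05)
        others = np.delete(profile.difference, 1)
        assert np.allclose(others, -1.0)

    def test_se_shrinks_as_root_n(self):
        # oracle: repeated resampling at two sample sizes
        rng = np.random.default_rng(0)
        base = rng.integers(20, 80, size=20)
        background = np.full(20, 50)
        se_small = composition_profile(base, background, reps=3000, seed=5).se
        se_large = composition_profile(base * 4, background, reps=3000, seed=5).se
        ratio = np.median(se_small / se_large)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_bit_reproducible_with_fixed_seed(self):
        sample = np.arange(1, 21)
        background = np.full(20, 10)
        one = composition_profile(sample, background, reps=500, seed=9)
        two = composition_profile(sample, background, reps=500, seed=9)
        assert np.array_equal(one.se, two.se)

    def test_zero_background_with_sample_mass_rejected(self):
        sample = np.ones(20)
        background = np.ones(20)
        background[0] = 0
        with pytest.raises(ValueError, match="background"):
            composition_profile(sample, background, reps=200)


class TestNormalizeFt:
    def test_prefix_stripping(self):
        assert normalize_description("Required for DNA binding") == "DNA binding"
        assert normalize_description("  Involved in   signal transduction ") == (
            "signal transduction"
        )
        assert normalize_description("Mediates interaction with SMAD3") == (
            "interaction with SMAD3"
        )

    def test_longest_prefix_wins(self):
        # "Essential to" must not be clipped by the bare "For" rule
        assert normalize_description("Essential to DNA repair") == "DNA repair"

    def test_qualifier_marked_features_dropped(self):
        annotations = [
            FeatureAnnotation("p", 1, 5, "DOMAIN", "kinase", "By similarity"),
            FeatureAnnotation("p", 6, 9, "DOMAIN", "kinase"),
        ]
        result = normalize_ft(annotations)
        assert len(result.annotations) == 1
        assert result.n_dropped_qualifier == 1

    def test_rare_features_removed_by_dm_count(self):
        annotations = [FeatureAnnotation("p", 1, 10, "DOMAIN", "kinase")]
        dm = [MutationRecord("p", i, "A", "C", "DM") for i in range(1, 5)]  # 4 hits
        result = normalize_ft(annotations, dm, min_dm_count=5)
        assert result.annotations == []
        assert result.n_dropped_rare == 1
        kept = normalize_ft(
            annotations, dm + [MutationRecord("p", 5, "A", "C", "DM")]
        )
        assert len(kept.annotations) == 1

    def test_disease_keywords_removed(self):
        annotations = [FeatureAnnotation("p", 1, 5, "DISEASE", "EEC syndrome")]
        result = normalize_ft(annotations)
        assert result.annotations == [] and result.n_dropped_disease == 1

    def test_level2_label_combines_key_and_description(self):
        annotations = [FeatureAnnotation("p", 1, 5, "REGION", "Required for DNA binding")]
        result = normalize_ft(annotations)
        assert result.level2 == ["REGION: DNA binding"]


class TestFtEnrichment:
    def build(self, n=400, enriched=True):
        annotations = [FeatureAnnotation("p", 1, 100, "DNA_BIND", "")]
        feats = normalize_ft(annotations)
        idr = [
            MutationRecord("p", (i % 100) + 1 if (enriched and i % 2 == 0) else 150 + (i % 100),
                           "A", "C", "DM")
            for i in range(n)
        ]
        orm = [
            MutationRecord("p", (i % 100) + 1 if i % 10 == 0 else 150 + (i % 100),
                           "A", "C", "DM")
            for i in range(n)
        ]
        return feats, idr, orm

    def test_unhit_features_excluded(self):
        annotations = [FeatureAnnotation("p", 900, 950, "ZN_FING", "")]
        feats = normalize_ft(annotations)
        results = ft_enrichment(feats, [MutationRecord("p", 1, "A", "C")], [])
        assert results == []

    def test_test_count_bookkeeping(self):
        feats, idr, orm = self.build()
        results = ft_enrichment(feats, idr, orm)
        assert all(r.test_count == len(results) for r in results)
        assert all(r.p_adjusted == min(1.0, r.p_raw * r.test_count) for r in results)

    def test_enriched_feature_detected(self):
        feats, idr, orm = self.build()
        results = ft_enrichment(feats, idr, orm)
        assert results[0].label == "DNA_BIND"
        assert results[0].fold > 1.0
        assert results[0].p_adjusted < 0.05


class TestIntervalOverlap:
    INTERVALS = [FeatureAnnotation("p", 3, 7, "ELM", "motif")]

    @pytest.mark.parametrize(
        "position,expected", [(5, 1), (8, 0), (3, 1), (7, 1), (2, 0)]
    )
    def test_inclusive_boundaries(self, position, expected):
        mutations = [MutationRecord("p", position, "A", "C", "DM")]
        table = interval_overlap(mutations, self.INTERVALS)
        assert table.loc[0, "overlap"] == expected

    def test_stratified_by_class(self):
        mutations = [
            MutationRecord("p", 5, "A", "C", "DM"),
            MutationRecord("p", 9, "A", "G", "DM"),
        ]
        klass_of = {mutations[0].key(): "D->O", mutations[1].key(): "D->D"}
        table = interval_overlap(mutations, self.INTERVALS, klass_of)
        table = table.set_index("klass")
        assert table.loc["D->O", "overlap"] == 1
        assert table.loc["D->D", "no_overlap"] == 1


class TestStratifiedCalls:
    def test_uniform_calls_fraction_one_p_one(self):
        calls = [("IDR", "damaging")] * 10 + [("OR", "damaging")] * 10
        table = stratified_calls(calls)
        assert np.allclose(table["frac_damaging"], 1.0)
        result = compare_strata(calls, "IDR", "OR", "damaging")
        assert result.p_raw == 1.0

    def test_fractions_sum_to_one_over_known_categories(self, rng):
        categories = ["damaging", "tolerated", "unknown"]
        calls = [
            (("IDR", "OR")[rng.integers(2)], categories[rng.integers(3)])
            for _ in range(300)
        ]
        table = stratified_calls(calls)
        frac_cols = [c for c in table.columns if str(c).startswith("frac_")]
        assert np.allclose(table[frac_cols].sum(axis=1), 1.0)

    def test_planted_difference_detected(self, rng):
        calls = [("IDR", "damaging" if rng.random() < 0.6 else "tolerated")
                 for _ in range(800)]
        calls += [("OR", "damaging" if rng.random() < 0.75 else "tolerated")
                  for _ in range(800)]
        result = compare_strata(calls, "IDR", "OR", "damaging")
        assert result.p_raw < 0.001
        assert result.fold < 1.0
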