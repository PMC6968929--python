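"""Summary statistics: frozen examples, oracle equivalence, invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pyrclone.lineage import LayerCounts, classify_laminar
from pyrclone.stats import (
    DegenerateSpreadError,
    class_fractions,
    compare_datasets,
    config_frequencies,
    laminar_fractions,
    size_histogram,
    subtype_diversity,
    summarize,
    superficial_deep_correlation,
    zscore,
    zscore_report,
)

from conftest import make_lineage


class TestLaminarFractions:
    def test_uniform_and_concentrated(self):
        assert np.allclose(
            laminar_fractions([make_lineage(1, 1, 1, 1)]), [0.25] * 4
        )
        assert np.allclose(laminar_fractions([make_lineage(l6=5)]), [0, 0, 0, 1])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            laminar_fractions([])


class TestSizeHistogram:
    def test_counts_and_out_of_range(self):
        dataset = [make_lineage(l6=s) for s in (4, 4, 8, 2, 13)]
        hist, out = size_histogram(dataset)
        assert hist[4] == 2 and hist[8] == 1 and hist[5] == 0
        assert out == 2

    def test_empty_dataset(self):
        hist, out = size_histogram([])
        assert all(v == 0 for v in hist.values()) and out == 0


class TestClassFractions:
    def test_one_per_class(self):
        dataset = [
            make_lineage(1, 0, 1, 0),
            make_lineage(0, 0, 1, 1),
            make_lineage(1, 1, 0, 0),
        ]
        assert np.allclose(class_fractions(dataset), [1 / 3] * 3)

    def test_all_translaminar(self):
        dataset = [make_lineage(1, 0, 0, 1)] * 4
        assert np.allclose(class_fractions(dataset), [1, 0, 0])

    def test_agrees_with_per_lineage_reclassification(self, rng):
        from pyrclone.stats import CLASS_ORDER

        dataset = [
            make_lineage(*rng.integers(0, 4, size=4))
            for _ in range(1000)
        ]
        dataset = [lin for lin in dataset if lin.total() > 0]
        fracs = class_fractions(dataset)
        counts = {cls: 0 for cls in CLASS_ORDER}
        for lin in dataset:
            counts[classify_laminar(lin.counts)] += 1
        assert np.allclose(
            fracs, [counts[c] / len(dataset) for c in CLASS_ORDER]
        )


class TestConfigFrequencies:
    def test_single_full_code(self):
        freqs = config_frequencies([make_lineage(1, 1, 1, 1)] * 3)
        assert freqs[(1, 1, 1, 1)] == 1.0
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_restricted_codes_sum_matches_class_fractions(self, small_dataset):
        freqs = config_frequencies(small_dataset)
        cls = class_fractions(small_dataset)
        deep_codes = sum(
            v for code, v in freqs.items() if code[0] == 0 and code[1] == 0
        )
        sup_codes = sum(
            v for code, v in freqs.items() if code[2] == 0 and code[3] == 0
        )
        assert deep_codes == pytest.approx(cls[1])
        assert sup_codes == pytest.approx(cls[2])

    def test_uniform_over_supports(self, rng):
        codes = [bits for bits in itertools.product((0, 1), repeat=4) if any(bits)]
        dataset = [
            make_lineage(*codes[rng.integers(0, 15)]) for _ in range(15000)
        ]
        freqs = config_frequencies(dataset)
        assert np.allclose(list(freqs.values()), 1 / 15, atol=0.012)


class TestSpearman:
    def test_perfect_monotone(self):
        dec = [make_lineage(l23=s, l6=4 - s) for s in (4, 3, 2, 1)]
        assert superficial_deep_correlation(dec) == pytest.approx(-1.0)
        inc = [make_lineage(l23=s, l6=s) for s in (1, 2, 3)]
        assert superficial_deep_correlation(inc) == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(50):
            dataset = [
                make_lineage(*rng.integers(0, 5, size=4)) for _ in range(20)
            ]
            sup = [lin.counts.superficial() for lin in dataset]
            deep = [lin.counts.deep() for lin in dataset]
            if len(set(sup)) < 2 or len(set(deep)) < 2:
                continue
            oracle = sps.pearsonr(sps.rankdata(sup), sps.rankdata(deep)).statistic
            assert superficial_deep_correlation(dataset) == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        dataset = [make_lineage(l23=1, l6=k) for k in (1, 2, 3)]
        with pytest.raises(DegenerateSpreadError):
            superficial_deep_correlation(dataset)


class TestSubtypeDiversity:
    def test_bins(self):
        dataset = [
            make_lineage(1, 1, 1, 1, id="a", subtype_counts={"CCPN": 4}),
            make_lineage(
                1, 1, 1, 1, id="b",
                subtype_counts={"CCPN": 1, "SCPN": 1, "CThPN": 1, "HPN": 1},
            ),
            # not all-layer: excluded
            make_lineage(0, 1, 1, 1, id="c", subtype_counts={"CCPN": 3}),
            # unclassified cell present (counts do not cover total): excluded
            make_lineage(1, 1, 1, 1, id="d", subtype_counts={"CCPN": 3}),
        ]
        bins = subtype_diversity(dataset)
        assert np.allclose(bins, [0.5, 0, 0, 0.5])
        assert bins.sum() == pytest.approx(1.0)


class TestZScore:
    def test_frozen_examples(self):
        assert zscore(2, [1, 2, 3]) == 0.0
        assert zscore(4, [1, 2, 3]) == pytest.approx(2.0)

    @given(
        st.floats(-50, 50),
        st.lists(st.floats(-50, 50), min_size=3, max_size=10),
        st.floats(-20, 20),
        st.floats(0.1, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_translation_and_scale_invariance(self, exp, sims, shift, scale):
        sims = np.asarray(sims)
        if sims.std(ddof=1) < 1e-6:
            return
        base = zscore(exp, sims)
        assert zscore(exp + shift, sims + shift) == pytest.approx(base, rel=1e-6)
        assert zscore(exp * scale, sims * scale) == pytest.approx(base, rel=1e-6)

    def test_degenerate_spread(self):
        with pytest.raises(DegenerateSpreadError):
            zscore(1.0, [2.0, 2.0, 2.0])
        assert zscore(2.0, [2.0, 2.0, 2.0]) == 0.0


class TestCompareDatasets:
    def test_identical_counts_give_zero_chi_square(self):
        res = compare_datasets([10, 10, 10], [10, 10, 10])
        assert res["test"] == "chi-square"
        assert res["statistic"] == pytest.approx(0.0)

    def test_fisher_2x2_matches_hypergeometric_enumeration(self):
        table = np.array([[1, 9], [9, 1]])
        res = compare_datasets(table[0], table[1])
        assert res["test"] == "fisher-exact"
        # oracle: enumerate all tables with the same margins
        n1, n2 = table.sum(axis=1)
        c1 = table.sum(axis=0)[0]
        probs = {
            a: sps.hypergeom.pmf(a, n1 + n2, n1, c1)
            for a in range(max(0, c1 - n2), min(n1, c1) + 1)
        }
        p_obs = probs[table[0, 0]]
        p_two_sided = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert res["p_value"] == pytest.approx(p_two_sided, rel=1e-6)

    def test_mann_whitney_identical_samples_at_null_mean(self):
        sizes = [3, 4, 5, 6, 7, 8]
        res = compare_datasets(sizes_a=sizes, sizes_b=sizes)
        assert res["test"] == "mann-whitney"
        assert res["statistic"] == pytest.approx(len(sizes) ** 2 / 2)

    def test_goodness_of_fit_validates_fractions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compare_datasets([5, 5], expected_fractions=[0.3, 0.3])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compare_datasets([0, 0], [0, 0])


class TestSummaryInvariances:
    def test_fraction_outputs_sum_to_one(self, small_dataset):
        stats = summarize(small_dataset, size_range=(1, 12))
        assert stats.laminar_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert stats.class_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert sum(stats.config_frequencies.values()) == pytest.approx(1.0, abs=1e-12)

    def test_order_invariance(self, small_dataset, rng):
        stats_a = summarize(small_dataset, size_range=(1, 12))
        shuffled = list(small_dataset)
        rng.shuffle(shuffled)
        stats_b = summarize(shuffled, size_range=(1, 12))
        assert np.allclose(stats_a.laminar_fractions, stats_b.laminar_fractions)
        assert stats_a.size_histogram == stats_b.size_histogram
        assert stats_a.spearman_r == pytest.approx(stats_b.spearman_r)

    def test_zscore_report_against_permutation_ensemble(self, small_dataset, rng):
        """Statistics conserved by permutation score exactly zero; the rest
        are finite."""
        from pyrclone.permutation import permute_dataset

        obs = summarize(small_dataset, size_range=(1, 12))
        sims = [
            summarize(permute_dataset(small_dataset, rng), size_range=(1, 12))
            for _ in range(10)
        ]
        report = zscore_report(obs, sims)
        for key, value in report.items():
            assert not np.isnan(value)
            if key.startswith(("laminar_fraction", "size_fraction")):
                assert value == pytest.approx(0.0)
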