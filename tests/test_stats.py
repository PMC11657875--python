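import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import chi2_contingency

from spinemorph import stats as st
from spinemorph import synth
from tests.conftest import make_dataset


def labelled(dataset):
    return synth.ground_truth_classes(dataset)


class TestClassCountTable:
    def test_all_one_class(self):
        ds = make_dataset(seed=1, n_per_dendrite=10, n_dendrites=2,
                          mixtures=[(1, 0, 0, 0)] * 2)
        table = st.class_count_table(ds, labelled(ds))
        np.testing.assert_array_equal(table.counts, [[10], [10]])

    def test_fractions_per_dendrite_sum_to_one(self):
        ds = make_dataset(seed=2, n_per_dendrite=30, n_dendrites=3)
        table = st.class_count_table(ds, labelled(ds))
        np.testing.assert_allclose(table.fractions_per_dendrite().sum(axis=1), 1.0)

    def test_fractions_per_class_sum_to_one(self):
        ds = make_dataset(seed=2, n_per_dendrite=30, n_dendrites=3)
        table = st.class_count_table(ds, labelled(ds))
        np.testing.assert_allclose(table.fractions_per_class().sum(axis=0), 1.0)

    def test_unlabelled_spine_errors(self):
        ds = make_dataset(seed=3, n_per_dendrite=5, n_dendrites=1)
        labels = labelled(ds)
        missing = ds.spine_ids()[0]
        del labels[missing]
        with pytest.raises(st.StatsError, match=missing):
            st.class_count_table(ds, labels)

    def test_scope_restricts_to_neuron(self):
        ds = make_dataset(seed=4, n_per_dendrite=5, n_dendrites=2)
        table = st.class_count_table(ds, labelled(ds), scope="n1")
        assert len(table.dendrite_ids) == 2
        with pytest.raises(st.StatsError):
            st.class_count_table(ds, labelled(ds), scope="nope")

    def test_incomplete_spines_skipped(self):
        ds = make_dataset(seed=5, n_per_dendrite=5, n_dendrites=1)
        ds.neurons[0].dendrites[0].spines[0].complete = False
        table = st.class_count_table(ds, labelled(ds))
        assert table.counts.sum() == 4


class TestPearsonChiSquare:
    def test_homogeneous_table(self):
        res = st.pearson_chi_square(np.array([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # 2x2 closed form: N (ad - bc)^2 / (r1 r2 c1 c2) = 40
        res = st.pearson_chi_square(np.array([[20, 0], [0, 20]]))
        assert res.statistic == pytest.approx(40.0, abs=1e-9)
        assert res.df == 1
        assert res.p == pytest.approx(2.5396e-10, rel=1e-3)

    def test_count_scaling(self):
        t = np.array([[12, 5, 3], [4, 9, 7]])
        r1 = st.pearson_chi_square(t)
        r10 = st.pearson_chi_square(10 * t)
        assert r10.statistic == pytest.approx(10 * r1.statistic, rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 40, size=(4, 4))
        res = st.pearson_chi_square(t)
        chi2, p, df, _ = chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)
        assert res.df == df

    def test_zero_row_errors(self):
        with pytest.raises(st.StatsError, match="zero row"):
            st.pearson_chi_square(np.array([[0, 0], [5, 5]]))

    def test_all_zero_column_dropped(self):
        with_zero = st.pearson_chi_square(np.array([[10, 0, 5], [5, 0, 10]]))
        without = st.pearson_chi_square(np.array([[10, 5], [5, 10]]))
        assert with_zero.statistic == pytest.approx(without.statistic)
        assert with_zero.df == without.df

    def test_low_expected_flagged(self):
        res = st.pearson_chi_square(np.array([[2, 3], [3, 2]]))
        assert "expected<5" in res.note


class TestPairwise:
    def test_identical_dendrites_adjusted_p_one(self):
        table = np.array([[10, 10, 10], [10, 10, 10], [10, 10, 10]])
        for res in st.pairwise_dendrite_tests(table):
            assert res.p_adjusted == pytest.approx(1.0)

    def test_three_dendrites_three_pairs(self):
        table = np.array([[10, 5], [5, 10], [8, 7]])
        results = st.pairwise_dendrite_tests(table)
        assert len(results) == 3
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, res.p * 3))

    def test_failed_pair_recorded_not_raised(self):
        table = np.array([[10, 5], [0, 0], [8, 7]])
        results = st.pairwise_dendrite_tests(table)
        notes = [r.note for r in results]
        assert any("failed" in n for n in notes)
        assert sum("failed" not in n for n in notes) == 1  # pair (0, 2) still runs


class TestKruskalWallis:
    def test_identical_distributions(self):
        res = st.kruskal_wallis({"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])})
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = st.kruskal_wallis({"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])})
        assert res.statistic == pytest.approx(3.857, abs=1e-3)
        assert res.p == pytest.approx(0.0495, abs=1e-3)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.uniform(0, 10, 12) for g in "abc"}
        r1 = st.kruskal_wallis(groups)
        r2 = st.kruskal_wallis({g: np.exp(v) for g, v in groups.items()})
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_all_nan_group_dropped_with_note(self):
        groups = {
            "a": np.array([1.0, 2, 3]),
            "b": np.array([4.0, 5, 6]),
            "c": np.array([np.nan, np.nan]),
        }
        res = st.kruskal_wallis(groups)
        assert "c" in res.note
        assert res.df == 1

    def test_dunn_posthoc_properties(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(2, 1, 15),
            "c": rng.normal(0, 1, 15),
        }
        omnibus, posthoc = st.kruskal_wallis_by_dendrite(groups)
        assert len(posthoc) == 3
        for r in posthoc:
            assert r.p_adjusted >= r.p
            assert r.p_adjusted <= 1.0
        worst = min(posthoc, key=lambda r: r.p)
        assert set(worst.comparison) in ({"a", "b"}, {"b", "c"})


class TestShuffleControl:
    def test_zero_shuffles_empty(self):
        ds = make_dataset(seed=6, n_per_dendrite=5, n_dendrites=2)
        summary = st.shuffle_control(ds, labelled(ds), n_shuffles=0)
        assert summary.empty()
        assert summary.rejection_fraction == {}

    def test_counts_preserved_and_calibrated(self):
        ds = make_dataset(
            seed=7,
            n_per_dendrite=80,
            n_dendrites=2,
            mixtures=[(0.7, 0.1, 0.1, 0.1), (0.1, 0.1, 0.1, 0.7)],
        )
        labels = labelled(ds)
        # the unshuffled contrast is overwhelmingly significant
        omnibus = st.pearson_chi_square(st.class_count_table(ds, labels))
        assert omnibus.p < 1e-6
        summary = st.shuffle_control(
            ds, labels, n_shuffles=200, rng=np.random.default_rng(0)
        )
        # under shuffling the rejection rate collapses to ~alpha
        assert summary.rejection_fraction["chi_square"] < 0.2

    def test_requires_rng(self):
        ds = make_dataset(seed=8, n_per_dendrite=5, n_dendrites=2)
        with pytest.raises(st.StatsError, match="rng"):
            st.shuffle_control(ds, labelled(ds), n_shuffles=5)

    def test_descriptor_families_reported(self):
        ds = make_dataset(seed=9, n_per_dendrite=20, n_dendrites=2)
        labels = labelled(ds)
        desc = pd.DataFrame(
            {
                "spine_id": ds.spine_ids(),
                "spine_length": np.random.default_rng(1).uniform(300, 2500, 40),
            }
        )
        summary = st.shuffle_control(
            ds, labels, n_shuffles=20, rng=np.random.default_rng(2), descriptors=desc
        )
        assert "kruskal_wallis:spine_length" in summary.rejection_fraction


class TestPowerAndNull:
    def test_power_quick(self):
        detected = 0
        for seed in range(10):
            ds = make_dataset(
                seed=seed,
                n_per_dendrite=100,
                n_dendrites=2,
                mixtures=[(0.7, 0.1, 0.1, 0.1), (0.1, 0.1, 0.1, 0.7)],
            )
            table = st.class_count_table(ds, labelled(ds))
            (res,) = st.pairwise_dendrite_tests(table)
            if res.p_adjusted < 0.001:
                detected += 1
        assert detected == 10

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            counts = rng.multinomial(100, [0.25] * 4, size=2)
            res = st.pearson_chi_square(counts)
            rejections += res.p < 0.05
        # binomial 99.9% interval around 0.05
        sd = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3.3 * sd + 0.01


@settings(max_examples=200, deadline=None)
@given(
    p=hst.floats(min_value=0.0, max_value=1.0),
    m=hst.integers(min_value=1, max_value=1000),
)
def test_bonferroni_bounds(p, m):
    adj = st._bonferroni(p, m)
    assert adj >= p
    assert adj <= 1.0


def test_significance_bands():
    assert st.significance_band(0.2) == 0
    assert st.significance_band(0.04) == 1
    assert st.significance_band(0.009) == 2
    assert st.significance_band(0.0005) == 3
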