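import numpy as np
import pytest

from kinbind.classify import ClassifierSpec
from kinbind.evaluate import (
    ConfusionCounts,
    SplitSpec,
    compute_metrics,
    majority_baseline,
    make_splits,
    mixed_insertion_counts,
    optimize_theta,
    probability_product_baseline,
    randomize_features,
    restrict_to_test_molecules,
    run_experiment,
)
from kinbind.io import BindingMatrix, ValidationError

from conftest import make_feature_table


def all_splits(m, n, spec, limit=None):
    out = []
    for i, s in enumerate(make_splits(m, n, spec)):
        out.append(s)
        if limit and i + 1 >= limit:
            break
    return out


class TestSplitSizes:
    @pytest.mark.parametrize("seed", range(6))
    def test_size_formulas(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 31))
        n = int(rng.integers(2, 31))
        frac = float(rng.uniform(0.0, 1.0))
        for s in all_splits(m, n, SplitSpec(case="soft"), limit=10):
            assert len(s.train) == m * n - 1
        for s in all_splits(m, n, SplitSpec(case="hard"), limit=10):
            assert len(s.train) == (m - 1) * (n - 1)
        spec = SplitSpec(case="mixed", kinase_amount=frac, inhibitor_amount=frac)
        r_k, r_i = mixed_insertion_counts(m, n, spec)
        for s in all_splits(m, n, spec, limit=10):
            assert len(s.train) == (m - 1) * (n - 1) + r_k + r_i

    def test_full_screen_reference_sizes(self):
        soft = next(make_splits(113, 20, SplitSpec(case="soft")))
        assert len(soft.train) == 2259
        hard = next(make_splits(113, 20, SplitSpec(case="hard")))
        assert len(hard.train) == 2128
        spec = SplitSpec(case="mixed", kinase_amount=0.5, inhibitor_amount=0.5)
        assert mixed_insertion_counts(113, 20, spec) == (57, 10)

    def test_absolute_count_bounds(self):
        spec = SplitSpec(case="mixed_mixed", kinase_amount=5, inhibitor_amount=3)
        assert mixed_insertion_counts(10, 6, spec) == (5, 3)
        bad = SplitSpec(case="mixed_mixed", kinase_amount=10, inhibitor_amount=0)
        with pytest.raises(ValidationError, match="exceeds"):
            mixed_insertion_counts(10, 6, bad)

    def test_fraction_one_approaches_soft(self):
        spec = SplitSpec(case="mixed", kinase_amount=1.0, inhibitor_amount=1.0)
        s = next(make_splits(5, 4, spec))
        assert len(s.train) == 5 * 4 - 1

    def test_mixed_requires_equal_fractions(self):
        with pytest.raises(ValidationError):
            SplitSpec(case="mixed", kinase_amount=0.5, inhibitor_amount=0.3)

    def test_minimum_dimensions(self):
        with pytest.raises(ValidationError):
            next(make_splits(1, 5, SplitSpec(case="soft")))


class TestNoLeakage:
    @pytest.mark.parametrize("case", ["soft", "hard", "mixed", "mixed_mixed"])
    def test_test_pair_never_in_training(self, case):
        spec = (
            SplitSpec(case=case, kinase_amount=0.5, inhibitor_amount=0.5)
            if case in ("mixed", "mixed_mixed")
            else SplitSpec(case=case)
        )
        for s in make_splits(5, 4, spec):
            assert s.test not in s.train
            assert len(set(s.train)) == len(s.train)

    def test_hard_shares_no_ids(self):
        for s in make_splits(6, 5, SplitSpec(case="hard")):
            ki, ii = s.test
            assert all(a != ki and b != ii for a, b in s.train)

    def test_mixed_insertions_touch_test_molecules(self):
        spec = SplitSpec(case="mixed", kinase_amount=0.5, inhibitor_amount=0.5)
        r_k, r_i = mixed_insertion_counts(8, 6, spec)
        for s in make_splits(8, 6, spec):
            ki, ii = s.test
            with_inh = [(a, b) for a, b in s.train if b == ii]
            with_kin = [(a, b) for a, b in s.train if a == ki]
            assert len(with_inh) == r_k and len(with_kin) == r_i


class TestRestrictedTraining:
    def test_full_screen_size(self):
        soft = next(make_splits(113, 20, SplitSpec(case="soft")))
        assert len(restrict_to_test_molecules(soft).train) == 131

    @pytest.mark.parametrize("m,n", [(2, 2), (5, 3), (7, 7)])
    def test_size_is_m_plus_n_minus_two(self, m, n):
        for s in make_splits(m, n, SplitSpec(case="soft")):
            r = restrict_to_test_molecules(s)
            assert len(r.train) == (m - 1) + (n - 1)
            ki, ii = r.test
            assert all(a == ki or b == ii for a, b in r.train)


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert m.accuracy == m.recall_pos == m.precision_pos == 1.0

    def test_majority_predictor_on_screen_counts(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=1663, fn=597))
        assert round(m.accuracy, 3) == 0.736
        assert m.recall_pos == 0.0
        assert m.precision_pos is None  # undefined, not zero

    @pytest.mark.parametrize("seed", range(5))
    def test_accuracy_identity(self, seed):
        """accuracy == pi*TPR + (1-pi)*TNR for any confusion counts."""
        rng = np.random.default_rng(seed)
        c = ConfusionCounts(*[int(x) for x in rng.integers(1, 50, size=4)])
        m = compute_metrics(c)
        pi = (c.tp + c.fn) / c.total
        assert m.accuracy == pytest.approx(
            pi * m.recall_pos + (1 - pi) * m.recall_neg
        )

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionCounts())


class TestMajorityBaseline:
    def test_majority_and_ties(self):
        assert majority_baseline([0, 0, 1]) == 0
        assert majority_baseline([1, 1, 0]) == 1
        assert majority_baseline([0, 1]) == 0  # tie -> no-binding
        assert majority_baseline([1, 1]) == 1


class TestProbabilityProduct:
    def test_strict_threshold(self, toy_matrix):
        split = next(make_splits(3, 3, SplitSpec(case="soft")))
        # p_kin * p_inh == theta exactly -> no-binding
        from kinbind.evaluate import _pair_probabilities

        p_kin, p_inh = _pair_probabilities(toy_matrix, split)
        theta = p_kin * p_inh
        assert probability_product_baseline(toy_matrix, split, theta) == 0
        assert probability_product_baseline(toy_matrix, split, theta - 1e-9) == 1

    def test_hard_case_errors(self, toy_matrix):
        split = next(make_splits(3, 3, SplitSpec(case="hard")))
        with pytest.raises(ValidationError, match="non-hard"):
            probability_product_baseline(toy_matrix, split, 0.5)

    def test_toy_matrix_truth_table(self, toy_matrix):
        """Predictions match hand-computed probabilities over all 9 pairs."""
        labels = toy_matrix.labels
        for split in make_splits(3, 3, SplitSpec(case="soft")):
            ki, ii = split.test
            kin_pairs = [(ki, b) for b in range(3) if b != ii]
            inh_pairs = [(a, ii) for a in range(3) if a != ki]
            p_kin = np.mean([labels[p] for p in kin_pairs])
            p_inh = np.mean([labels[p] for p in inh_pairs])
            for theta in (0.0, 0.2, 0.5, 0.9):
                expected = 1 if p_kin * p_inh > theta else 0
                assert (
                    probability_product_baseline(toy_matrix, split, theta)
                    == expected
                )

    def test_invariant_under_permutation(self, toy_matrix):
        perm_k = [2, 0, 1]
        perm_i = [1, 2, 0]
        permuted = BindingMatrix(
            [toy_matrix.kinase_ids[i] for i in perm_k],
            [toy_matrix.inhibitor_ids[j] for j in perm_i],
            toy_matrix.labels[np.ix_(perm_k, perm_i)],
        )
        splits = list(make_splits(3, 3, SplitSpec(case="soft")))
        for s in splits:
            ki, ii = s.test
            pki, pii = perm_k.index(ki), perm_i.index(ii)
            s2 = next(
                sp
                for sp in make_splits(3, 3, SplitSpec(case="soft"))
                if sp.test == (pki, pii)
            )
            assert probability_product_baseline(
                toy_matrix, s, 0.3
            ) == probability_product_baseline(permuted, s2, 0.3)


class TestOptimizeTheta:
    def test_all_negative_matrix_returns_grid_minimum(self):
        m = BindingMatrix(["k1", "k2"], ["i1", "i2"], np.zeros((2, 2), dtype=int))
        splits = list(make_splits(2, 2, SplitSpec(case="soft")))
        assert optimize_theta(m, splits, grid=(0.1, 0.5, 0.9)) == 0.1

    def test_singleton_grid(self, toy_matrix):
        splits = list(make_splits(3, 3, SplitSpec(case="soft")))
        assert optimize_theta(toy_matrix, splits, grid=(0.42,)) == 0.42

    def test_strictly_best_theta_found(self):
        # block matrix: first kinase binds everything, second binds nothing
        labels = np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0]])
        m = BindingMatrix(["k1", "k2", "k3"], ["i1", "i2", "i3"], labels)
        splits = list(make_splits(3, 3, SplitSpec(case="soft")))
        theta = optimize_theta(m, splits, grid=np.arange(0.0, 1.01, 0.05))
        # grid evaluation oracle
        accs = {}
        for t in np.arange(0.0, 1.01, 0.05):
            correct = sum(
                probability_product_baseline(m, s, t) == m.labels[s.test]
                for s in splits
            )
            accs[round(float(t), 2)] = correct
        best = max(accs.values())
        assert accs[round(theta, 2)] == best


class TestRandomizeFeatures:
    def _table(self):
        return make_feature_table(
            ["a", "b", "c"],
            [
                ("s1", "numeric", "locAli", [3.0, 7.0, 5.0]),
                ("s2", "numeric", "locAli", [3.0, 3.0, 3.0]),
                ("other", "numeric", "CF", [1.0, 2.0, 3.0]),
            ],
        )

    def test_bounds_and_untouched_columns(self):
        t = self._table()
        out = randomize_features(t, ["locAli"], seed=0)
        assert out.data["s1"].min() >= 3 and out.data["s1"].max() <= 7
        assert list(out.data["other"]) == [1.0, 2.0, 3.0]

    def test_constant_column_stays(self):
        out = randomize_features(self._table(), ["locAli"], seed=1)
        assert list(out.data["s2"]) == [3.0, 3.0, 3.0]

    def test_seeds_differ_bounds_hold(self):
        big = make_feature_table(
            ["x%d" % i for i in range(50)],
            [("s", "numeric", "glAli", list(np.linspace(0, 100, 50)))],
        )
        o1 = randomize_features(big, ["glAli"], seed=1)
        o2 = randomize_features(big, ["glAli"], seed=2)
        assert not np.array_equal(o1.data["s"], o2.data["s"])
        o1b = randomize_features(big, ["glAli"], seed=1)
        np.testing.assert_array_equal(o1.data["s"], o1b.data["s"])

    def test_nominal_group_rejected(self):
        t = make_feature_table(["a"], [("c", "nominal", "MS", ["x"])])
        with pytest.raises(ValidationError, match="nominal"):
            randomize_features(t, ["MS"], seed=0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            randomize_features(self._table(), ["PSF"], seed=0)


class TestRunExperiment:
    def _tiny(self, seed=0, signal=1.0):
        from kinbind.synth import SynthSpec, generate_bundle
        from kinbind.kinase_features import phylo_features, position_specific_features
        from kinbind.inhibitor_features import inhibitor_nominal_features
        from kinbind.io import FeatureTable

        spec = SynthSpec(
            m=6, n=4, seq_len=40, n_active_columns=4, n_signal_columns=2,
            signal=signal, positive_rate=0.3, seed=seed,
        )
        bundle, truth = generate_bundle(spec)
        kin = FeatureTable.concat(
            [
                phylo_features(bundle.kinases),
                position_specific_features(
                    bundle.msa, bundle.kinases, bundle.active_columns
                ),
            ]
        )
        inh = inhibitor_nominal_features(bundle.inhibitors)
        return bundle, kin, inh

    def test_repeat_bookkeeping(self):
        bundle, kin, inh = self._tiny()
        spec = SplitSpec(
            case="mixed", kinase_amount=0.5, inhibitor_amount=0.5, repeats=3, seed=0
        )
        report = run_experiment(
            bundle.matrix, kin, inh, spec, ClassifierSpec(kind="tree"),
        )
        assert len(report.per_repeat_test) == 3
        assert report.test.counts.total == 3 * 6 * 4
        assert report.test_accuracy_std >= 0.0

    def test_soft_case_runs_and_scores(self):
        bundle, kin, inh = self._tiny()
        report = run_experiment(
            bundle.matrix, kin, inh, SplitSpec(case="soft"),
            ClassifierSpec(kind="tree"), include_knn=True,
        )
        assert report.test.counts.total == 24
        assert 0.0 <= report.test.accuracy <= 1.0

    def test_hard_case_knn_warns(self):
        bundle, kin, inh = self._tiny()
        with pytest.warns(UserWarning, match="hard case"):
            run_experiment(
                bundle.matrix, kin, inh, SplitSpec(case="hard"),
                ClassifierSpec(kind="tree"), include_knn=True,
            )

    def test_external_overlap_rejected(self):
        from kinbind.evaluate import LeakageError

        bundle, kin, inh = self._tiny()
        with pytest.raises(LeakageError, match="overlap"):
            run_experiment(
                bundle.matrix, kin, inh, SplitSpec(case="hard"),
                ClassifierSpec(kind="tree"),
                external=(bundle.matrix, kin, inh),
            )

    def test_external_disjoint_bundle(self):
        bundle, kin, inh = self._tiny(seed=0)
        bundle2, kin2, inh2 = self._tiny(seed=5)
        # rename to guarantee disjoint ids
        bundle2.matrix.kinase_ids = [f"X{k}" for k in bundle2.matrix.kinase_ids]
        bundle2.matrix.inhibitor_ids = [f"X{i}" for i in bundle2.matrix.inhibitor_ids]
        kin2.data.index = bundle2.matrix.kinase_ids
        kin2.entity_ids = list(bundle2.matrix.kinase_ids)
        inh2.data.index = bundle2.matrix.inhibitor_ids
        inh2.entity_ids = list(bundle2.matrix.inhibitor_ids)
        report = run_experiment(
            bundle.matrix, kin, inh, SplitSpec(case="hard"),
            ClassifierSpec(kind="tree"),
            external=(bundle2.matrix, kin2, inh2),
        )
        assert report.test.counts.total == 24
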