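"""Cohort splitting, batch-mean selection, AUC and test-set evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from chscreen import batch_accuracy, evaluate, grid_search, roc_auc, split_cohorts, split_counts
from chscreen.evaluation import GridSearchResult, TEST, TRAIN, VALIDATION, roc_points
from chscreen.model import FeatureMatrix, build_vaf_matrix, dichotomize, fit_logistic

# development-cohort sizes with their published train/val/test triples
DEV_ROWS = [
    ("prjeb50602", 16, 9, 3, 4),
    ("prjna439205", 4, 2, 1, 1),
    ("prjna610493", 32, 18, 6, 8),
    ("prjna613408", 13, 6, 3, 4),
    ("tcga-luad", 440, 247, 83, 110),
    ("prjeb35045", 58, 32, 11, 15),
    ("prjna167318", 163, 91, 31, 41),
    ("prjna262923", 190, 106, 36, 48),
    ("prjna342304", 46, 25, 9, 12),
    ("prjna790003", 200, 112, 38, 50),
]


class TestSplitCounts:
    @pytest.mark.parametrize("cid,n,tr,va,te", DEV_ROWS)
    def test_ceil_rule_reproduces_published_triples(self, cid, n, tr, va, te):
        assert split_counts(n) == (tr, va, te)

    def test_totals_across_development_cohorts(self):
        tr = sum(split_counts(n)[0] for _, n, *_ in DEV_ROWS)
        va = sum(split_counts(n)[1] for _, n, *_ in DEV_ROWS)
        te = sum(split_counts(n)[2] for _, n, *_ in DEV_ROWS)
        assert (tr, va, te) == (648, 221, 293)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            split_counts(0)
        with pytest.raises(ValueError):
            split_counts(10, test_frac=0.0)


class TestSplitCohorts:
    def test_partitions_disjoint_and_exhaustive(self):
        sizes = {cid: n for cid, n, *_ in DEV_ROWS}
        sizes["indep1"] = 30
        sizes["indep2"] = 12
        split = split_cohorts(sizes, development=[c for c, *_ in DEV_ROWS], seed=5)
        assert len(split) == sum(sizes.values())
        assert not split["sample_id"].duplicated().any()
        for cid, n, tr, va, te in DEV_ROWS:
            sub = split[split["cohort_id"] == cid]["partition"].value_counts()
            assert (sub.get(TRAIN, 0), sub.get(VALIDATION, 0), sub.get(TEST, 0)) == (tr, va, te)
        indep = split[split["role"] == "independent_test"]
        assert set(indep["cohort_id"]) == {"indep1", "indep2"}
        assert (indep["partition"] == TEST).all()

    def test_membership_randomized_by_seed(self):
        sizes = {"a": 40, "b": 40}
        s1 = split_cohorts(sizes, ["a", "b"], seed=1)
        s2 = split_cohorts(sizes, ["a", "b"], seed=2)
        assert not s1["partition"].equals(s2["partition"])
        pd.testing.assert_frame_equal(s1, split_cohorts(sizes, ["a", "b"], seed=1))

    def test_unknown_development_cohort(self):
        with pytest.raises(ValueError):
            split_cohorts({"a": 5}, ["zzz"], seed=0)

    def test_zero_size_cohort(self):
        with pytest.raises(ValueError):
            split_cohorts({"a": 0}, ["a"], seed=0)


class TestBatchAccuracy:
    def test_single_batch_equals_pooled(self):
        per, mean = batch_accuracy([1, 0, 1, 1], [1, 0, 0, 1], ["a"] * 4)
        assert per == {"a": 0.75}
        assert mean == 0.75

    def test_unweighted_mean_ignores_batch_sizes(self):
        pred = [1] * 10 + [0] * 1000
        lab = [1] * 10 + [0] * 500 + [1] * 500
        batch = ["small"] * 10 + ["big"] * 1000
        per, mean = batch_accuracy(pred, lab, batch)
        assert per == {"big": 0.5, "small": 1.0}
        assert mean == pytest.approx(0.75)

    def test_matches_groupby_oracle(self, rng):
        n = 200
        pred = rng.integers(0, 2, n)
        lab = rng.integers(0, 2, n)
        batch = rng.choice(list("abcde"), n)
        per, mean = batch_accuracy(pred, lab, batch)
        df = pd.DataFrame({"p": pred, "y": lab, "b": batch})
        oracle = df.assign(ok=df.p == df.y).groupby("b")["ok"].mean()
        for b, acc in per.items():
            assert acc == pytest.approx(oracle[b])
        assert mean == pytest.approx(oracle.mean())

    def test_order_invariance(self, rng):
        n = 50
        pred = rng.integers(0, 2, n)
        lab = rng.integers(0, 2, n)
        batch = rng.choice(["x", "y"], n)
        perm = rng.permutation(n)
        _, m1 = batch_accuracy(pred, lab, batch)
        _, m2 = batch_accuracy(pred[perm], lab[perm], batch[perm])
        assert m1 == pytest.approx(m2)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        s = rng.choice(np.round(rng.random(8), 2), 30)  # forced ties
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        pairs = [
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in s[y == 1]
            for b in s[y == 0]
        ]
        assert roc_auc(s, y) == pytest.approx(np.mean(pairs), abs=1e-12)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert roc_auc(np.exp(3 * s), y) == pytest.approx(roc_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


def _matrix(values, labels, cohorts):
    n, k = np.asarray(values).shape
    df = pd.DataFrame(np.asarray(values, float), columns=[f"v{j}" for j in range(k)])
    df.insert(0, "sample_id", [f"s{i:03d}" for i in range(n)])
    df.insert(1, "cohort_id", cohorts)
    df.insert(2, "label", labels)
    return build_vaf_matrix(df, [f"v{j}" for j in range(k)])


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        n = 40
        y = np.array([1] * 20 + [0] * 20)
        vals = np.where(y[:, None] == 1, 0.2, 0.0)
        fm = _matrix(vals, y, ["a"] * 20 + ["b"] * 20)
        model = fit_logistic(dichotomize(fm, 0.01))
        rep = evaluate(model, fm)
        assert rep.accuracy.p_hat == 1.0
        assert rep.accuracy.ci_high == 1.0  # clipped
        assert rep.auc == 1.0
        assert rep.confusion == {"tp": 20, "fp": 0, "tn": 20, "fn": 0}

    def test_unlabeled_test_set_rejected(self, rng):
        vals = rng.uniform(0, 0.2, (10, 2))
        df = pd.DataFrame(vals, columns=["v0", "v1"])
        df.insert(0, "sample_id", [f"s{i}" for i in range(10)])
        df.insert(1, "cohort_id", "a")
        fm = build_vaf_matrix(df, ["v0", "v1"])
        y = np.array([0, 1] * 10)
        model = fit_logistic((rng.random((20, 2)) < 0.5).astype(float), y)
        with pytest.raises(ValueError, match="unlabeled"):
            evaluate(model, fm)

    def test_roc_points_monotone(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        pts = roc_points(s, y)
        assert (np.diff(pts["fpr"]) >= 0).all()
        assert (np.diff(pts["tpr"]) >= 0).all()
        assert pts.iloc[-1]["tpr"] == 1.0 and pts.iloc[-1]["fpr"] == 1.0


class TestGridSearch:
    def _dataset(self, rng, n_per, effect=0.35):
        """Two cohorts per class; one informative mutation detectable above 0.01."""
        y = np.array([1] * (2 * n_per) + [0] * (2 * n_per))
        carrier_p = np.where(y == 1, 0.1 + effect, 0.1)
        carried = rng.random(len(y)) < carrier_p
        vaf = np.where(carried, rng.uniform(0.02, 0.25, len(y)), 0.0)
        noise = rng.uniform(0, 0.009, (len(y), 1))  # sub-cutoff noise feature
        vals = np.column_stack([vaf, noise])
        cohorts = (
            ["ca1"] * n_per + ["ca2"] * n_per + ["co1"] * n_per + ["co2"] * n_per
        )
        return _matrix(vals, y, cohorts)

    def test_single_configuration_grid(self, rng):
        train = self._dataset(rng, 40)
        val = self._dataset(rng, 25)
        gs = grid_search(train, val, [0.01], [{"class_weight": {0: 1, 1: 1}, "l2_strength": 1.0}])
        assert gs.best_config["cutoff"] == 0.01
        assert len(gs.leaderboard) == 1

    def test_engineered_ordering(self, rng):
        """The configuration with the higher known batch accuracy wins."""
        train = self._dataset(rng, 40)
        val = self._dataset(rng, 25)
        # cutoff 0.5 kills every feature -> intercept-only, poor batch mean;
        # cutoff 0.01 keeps the informative mutation
        gs = grid_search(
            train, val, [0.01, 0.5],
            [{"class_weight": {0: 1, 1: 1}, "l2_strength": 1.0}],
        )
        assert gs.best_config["cutoff"] == 0.01
        board = gs.leaderboard.set_index("cutoff")["batch_mean_accuracy"]
        assert board[0.01] > board[0.5]

    def test_failed_configurations_recorded_not_fatal(self, rng):
        train = self._dataset(rng, 40)
        val = self._dataset(rng, 25)
        gs = grid_search(
            train, val, [0.01],
            [
                {"class_weight": {0: 1, 1: 1}, "l2_strength": 1.0},
                {"class_weight": {0: 1, 1: 1}, "l2_strength": -5.0},  # invalid
            ],
        )
        assert gs.leaderboard["failed"].sum() == 1
        assert not gs.leaderboard.iloc[0]["failed"]

    def test_requires_two_validation_batches(self, rng):
        train = self._dataset(rng, 40)
        val = self._dataset(rng, 25)
        val.cohorts[:] = "only"
        with pytest.raises(ValueError, match="batch"):
            grid_search(train, val, [0.01], [{"class_weight": {0: 1, 1: 1}, "l2_strength": 1.0}])
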