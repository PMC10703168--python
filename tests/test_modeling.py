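import numpy as np
import pytest

from microbiomegsm.errors import ModelingError
from microbiomegsm.grouping import group_features, lineages_for
from microbiomegsm.modeling import (METRIC_NAMES, ModelingConfig, compute_metrics,
                                    cumulative_model_eval, run_mccv, stratified_split)
from microbiomegsm.profile_io import AbundanceMatrix
from microbiomegsm.scoring import ScoringConfig, derive_seed, make_classifier


def _matrix(n_pos, n_neg, n_species=3, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    values = rng.dirichlet(np.ones(n_species), size=n)
    return AbundanceMatrix(
        sample_ids=[f"S{i:03d}" for i in range(n)],
        species_ids=[f"k__A|g__G{j}|s__sp{j}" for j in range(n_species)],
        values=values,
        labels=np.array([1] * n_pos + [0] * n_neg),
    )


class TestStratifiedSplit:
    def test_per_class_counts_round_half_up(self):
        train, test = stratified_split(_matrix(60, 40), 0.8, seed=1)
        assert int(train.labels.sum()) == 48 and int((1 - train.labels).sum()) == 32
        assert int(test.labels.sum()) == 12 and int((1 - test.labels).sum()) == 8

    def test_split_is_disjoint_and_exhaustive(self):
        m = _matrix(13, 9)
        train, test = stratified_split(m, 0.8, seed=3)
        assert set(train.sample_ids).isdisjoint(test.sample_ids)
        assert sorted(train.sample_ids + test.sample_ids) == sorted(m.sample_ids)

    def test_same_seed_gives_identical_split(self):
        m = _matrix(20, 20)
        a = stratified_split(m, 0.8, seed=7)
        b = stratified_split(m, 0.8, seed=7)
        assert a[0].sample_ids == b[0].sample_ids and a[1].sample_ids == b[1].sample_ids

    def test_minimal_two_plus_two(self):
        train, test = stratified_split(_matrix(2, 2), 0.5, seed=0)
        for side in (train, test):
            assert sorted(side.labels.tolist()) == [0, 1]

    def test_class_below_two_samples_is_an_error(self):
        with pytest.raises(ModelingError, match="need >= 2"):
            stratified_split(_matrix(5, 1), 0.8, seed=0)


class TestComputeMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        y = np.array([1, 1, 0, 0])
        ms = compute_metrics(y, np.array([0.9, 0.8, 0.1, 0.2]))
        assert all(getattr(ms, name) == 1.0 for name in METRIC_NAMES)
        assert (ms.tp, ms.fp, ms.tn, ms.fn) == (2, 0, 2, 0)

    def test_degenerate_all_positive_predictions(self):
        y = np.array([1] * 5 + [0] * 5)
        ms = compute_metrics(y, np.ones(10))
        assert ms.sensitivity == 1.0 and ms.specificity == 0.0
        assert ms.accuracy == 0.5 and ms.precision == 0.5
        assert ms.f1 == pytest.approx(2 / 3)
        assert ms.auc == 0.5  # full ties contribute 1/2

    def test_no_positive_predictions_flags_precision(self):
        ms = compute_metrics(np.array([1, 1, 0, 0]), np.zeros(4))
        assert ms.precision == 0.0 and not ms.precision_defined
        assert ms.f1 == 0.0

    def test_one_class_labels_are_an_error(self):
        with pytest.raises(ModelingError, match="one-class"):
            compute_metrics(np.ones(4, dtype=int), np.linspace(0, 1, 4))

    def test_auc_equals_pair_counting(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            y = rng.integers(0, 2, 20)
            if len(np.unique(y)) < 2:
                continue
            s = rng.choice(np.linspace(0, 1, 7), size=20)  # force some ties
            ms = compute_metrics(y, s)
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert ms.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


@pytest.fixture(scope="module")
def grouped_cohort():
    rng = np.random.default_rng(21)
    n = 60
    labels = np.array([1] * 30 + [0] * 30)
    clades = [f"k__B|p__P|c__C|o__O|f__F|g__G{g}|s__G{g}_sp{s}"
              for g in range(5) for s in range(2)]
    values = rng.gamma(1.0, 1.0, (n, len(clades)))
    values[labels == 1, :2] *= 6.0  # genus G0 carries the signal
    values /= values.sum(axis=1, keepdims=True)
    matrix = AbundanceMatrix(sample_ids=[f"S{i:03d}" for i in range(n)],
                             species_ids=clades, values=values, labels=labels)
    gmap = group_features(lineages_for(clades), "genus")
    return matrix, gmap


class TestCumulativeEval:
    def test_depth_one_equals_single_group_fit(self, grouped_cohort):
        matrix, gmap = grouped_cohort
        cfg = ModelingConfig(n_iterations=1, k=3, global_seed=5)
        train, test = stratified_split(matrix, 0.8, derive_seed(5, 1, "split"))
        metrics, n_feat = cumulative_model_eval(train, test, ["G0", "G1"], gmap,
                                                cfg, iteration=1)
        clf = make_classifier("random_forest", 100, derive_seed(5, 1, "model", 1))
        clf.fit(train.species_values(gmap.groups["G0"]), train.labels)
        proba = clf.predict_proba(test.species_values(gmap.groups["G0"]))
        pos = proba[:, int(np.flatnonzero(clf.classes_ == 1)[0])]
        expected = compute_metrics(test.labels, pos, 0.5)
        assert metrics[0] == expected

    def test_feature_counts_are_running_group_sums(self, grouped_cohort):
        matrix, gmap = grouped_cohort
        cfg = ModelingConfig(n_iterations=1, k=5, global_seed=5)
        train, test = stratified_split(matrix, 0.8, seed=2)
        ranked = list(gmap.groups)
        _, n_feat = cumulative_model_eval(train, test, ranked, gmap, cfg)
        sizes = [len(gmap.groups[g]) for g in ranked]
        assert n_feat == list(np.cumsum(sizes))


class TestRunMCCV:
    def test_single_iteration_single_group_reduces_to_one_eval(self, grouped_cohort):
        matrix, gmap = grouped_cohort
        res = run_mccv(matrix, gmap, ModelingConfig(n_iterations=1, k=1, global_seed=3),
                       ScoringConfig(seed=3, n_estimators=25))
        assert res.n_iterations == 1
        it = res.per_iteration[0]
        assert len(it.ranked_groups) == 1
        assert len(it.cumulative_metrics) == 1
        assert res.metric_means["auc"][0] == it.cumulative_metrics[0].auc

    def test_identical_seed_gives_byte_identical_results(self, grouped_cohort):
        matrix, gmap = grouped_cohort
        cfg = ModelingConfig(n_iterations=2, k=3, global_seed=17, n_estimators=25)
        scfg = ScoringConfig(seed=17, n_estimators=25)
        a = run_mccv(matrix, gmap, cfg, scfg)
        b = run_mccv(matrix, gmap, cfg, scfg)
        assert a.to_json() == b.to_json()

    def test_metric_means_are_arithmetic_means(self, grouped_cohort):
        matrix, gmap = grouped_cohort
        res = run_mccv(matrix, gmap,
                       ModelingConfig(n_iterations=3, k=2, global_seed=9, n_estimators=25),
                       ScoringConfig(seed=9, n_estimators=25))
        for name in METRIC_NAMES:
            per_iter = np.array([[getattr(ms, name) for ms in it.cumulative_metrics]
                                 for it in res.per_iteration])
            assert np.allclose(res.metric_means[name], per_iter.mean(axis=0), atol=1e-12)

    def test_signal_group_leads_the_ranking(self, grouped_cohort):
        matrix, gmap = grouped_cohort
        res = run_mccv(matrix, gmap,
                       ModelingConfig(n_iterations=3, k=5, global_seed=1, n_estimators=50),
                       ScoringConfig(seed=1, n_estimators=50))
        firsts = [it.ranked_groups[0] for it in res.per_iteration]
        assert firsts.count("G0") >= 2
        assert res.metric_means["auc"][-1] > 0.7
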