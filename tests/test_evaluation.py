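"""Splitting, AUC machinery, correlated-AUC tests and the cutoff sweep."""

import itertools

import numpy as np
import pytest

import parosal as ps
from parosal import (
    EvaluationConfig,
    GeneratorConfig,
    NeuralNetConfig,
    SplitSpec,
    auc,
    compare_auc,
    cutoff_auc_analysis,
    generate_cohort,
    split_cohort,
)


class TestSplit:
    def test_510_patients_split_357_153(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=510, seed=1))
        train, test = split_cohort(cohort, SplitSpec(seed=0))
        assert len(train) == 357
        assert len(test) == 153

    def test_partition_is_disjoint_and_exhaustive(self, medium_cohort):
        train, test = split_cohort(medium_cohort, SplitSpec(seed=3))
        ids = {r.patient_id for r in train} | {r.patient_id for r in test}
        assert len(ids) == len(medium_cohort)
        assert not ({r.patient_id for r in train} & {r.patient_id for r in test})

    def test_same_seed_reproduces_partition(self, medium_cohort):
        a = split_cohort(medium_cohort, SplitSpec(seed=5))
        b = split_cohort(medium_cohort, SplitSpec(seed=5))
        assert [r.patient_id for r in a[0]] == [r.patient_id for r in b[0]]

    def test_stratification_balances_event_rates(self):
        for seed in range(5):
            cohort = generate_cohort(GeneratorConfig(n_patients=400, seed=seed))
            train, test = split_cohort(cohort, SplitSpec(seed=seed))
            gap = abs(train.labels(0.5).mean() - test.labels(0.5).mean())
            assert gap < 0.05

    def test_too_small_cohort_rejected(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=5, seed=0))
        with pytest.raises(ValueError):
            split_cohort(cohort, SplitSpec(seed=0))


def pair_counting_auc(scores, labels):
    """Exhaustive concordant/discordant pair enumeration (independent oracle)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting_on_toy_set(self):
        scores = [0.1, 0.4, 0.4, 0.35, 0.8, 0.8, 0.2, 0.7]
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(0, 2, size=8)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_score_negation_symmetry_for_tie_free_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestCompareAUC:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        with pytest.warns(UserWarning, match="zero variance"):
            assert compare_auc(s, s, y) == 1.0

    def test_power_against_pure_noise(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, size=300)
            y[:2] = [0, 1]
            strong = y + rng.normal(scale=0.45, size=300)
            noise = rng.normal(size=300)
            hits += compare_auc(strong, noise, y) < 0.01
        assert hits >= 9

    def test_delong_agrees_with_permutation_on_small_sample(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        a = y + rng.normal(scale=0.9, size=30)
        b = y + rng.normal(scale=1.6, size=30)
        p_delong = compare_auc(a, b, y)
        p_perm = compare_auc(a, b, y, method="permutation", n_permutations=10000, seed=1)
        assert p_delong == pytest.approx(p_perm, abs=0.02)


FAST_EVAL = EvaluationConfig(
    nn_config=NeuralNetConfig(hidden_units=6, max_iter=150, n_restarts=1, seed=0),
    spline_expansion_knots=0,
)


@pytest.fixture(scope="module")
def result_and_split():
    cohort = generate_cohort(GeneratorConfig(n_patients=400, seed=50))
    train, test = split_cohort(cohort, SplitSpec(seed=0))
    res = cutoff_auc_analysis(train, test, cutoff_grid=(0.25, 0.5), config=FAST_EVAL)
    return res, train, test


class TestCutoffAnalysis:
    def test_single_cutoff_bookkeeping(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=300, seed=51))
        train, test = split_cohort(cohort, SplitSpec(seed=0))
        res = cutoff_auc_analysis(train, test, cutoff_grid=(0.5,), config=FAST_EVAL)
        assert res.cutoffs.shape == (1,)
        assert len(res.auc_by_model) == 4
        assert len(res.pairwise_p) == 6
        frame = res.to_frame()
        assert len(frame) == 4
        assert np.isfinite(frame["auc"]).all()

    def test_empty_grid_rejected(self, result_and_split):
        _, train, test = result_and_split
        with pytest.raises(ValueError):
            cutoff_auc_analysis(train, test, cutoff_grid=())

    def test_scores_are_cutoff_independent(self, result_and_split):
        res, _, _ = result_and_split
        # one score vector per model, reused across the grid
        for name, scores in res.scores.items():
            assert scores.shape == (res.n_test,)
            assert np.all((scores >= 0) & (scores <= 1))

    def test_event_counts_monotone_in_cutoff(self, result_and_split):
        res, _, _ = result_and_split
        assert np.all(np.diff(res.n_events_by_cutoff) >= 0)

    def test_literature_scores_do_not_depend_on_split(self):
        cohort = generate_cohort(GeneratorConfig(n_patients=200, seed=52))
        from parosal.lkb import _CohortArrays
        from parosal.evaluation import LITERATURE_PARAMS

        _, test_a = split_cohort(cohort, SplitSpec(seed=1))
        _, test_b = split_cohort(cohort, SplitSpec(seed=2))
        by_id_a = dict(zip([r.patient_id for r in test_a],
                           _CohortArrays(test_a).ntcp(LITERATURE_PARAMS)))
        by_id_b = dict(zip([r.patient_id for r in test_b],
                           _CohortArrays(test_b).ntcp(LITERATURE_PARAMS)))
        shared = set(by_id_a) & set(by_id_b)
        assert shared
        for pid in shared:
            assert by_id_a[pid] == pytest.approx(by_id_b[pid], abs=1e-15)

    def test_well_specified_lkb_is_competitive_at_reference_cutoff(self):
        # on data generated from the LKB truth, the fitted LKB model should be
        # the best model or statistically indistinguishable from it at 0.25
        wins = 0
        for rep in range(5):
            cohort = generate_cohort(GeneratorConfig(n_patients=400, seed=60 + rep))
            train, test = split_cohort(cohort, SplitSpec(seed=rep))
            res = cutoff_auc_analysis(train, test, cutoff_grid=(0.25,), config=FAST_EVAL)
            lkb = res.auc_by_model["lkb_fitted"][0]
            ok = True
            for other in ("spline", "neural_net"):
                if res.auc_by_model[other][0] > lkb:
                    key = tuple(sorted(("lkb_fitted", other),
                                       key=("lkb_fitted", "lkb_literature",
                                            "spline", "neural_net").index))
                    if res.pairwise_p[key][0] < 0.05:
                        ok = False
            wins += ok
        assert wins >= 3
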