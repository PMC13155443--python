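import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mislabel import (
    DetectionConfig,
    MislabelDetector,
    OracleClassifier,
    TrainConfig,
    VotingRule,
    apply_rule,
    plan_folds,
    recover_labels,
    run_detection,
    run_round,
    tally_votes,
)
from mislabel.filtering import PredictionRecord

from conftest import random_records


def _rec(q, j, proba, round_id=0):
    proba = np.asarray(proba, dtype=float)
    pred = int(np.argmax(proba))
    return PredictionRecord(q, j, proba, pred, float(proba[pred]), round_id)


class TestPlanFolds:
    def test_760_by_10_gives_folds_of_76(self):
        plan = plan_folds(760, 10, seed=0)
        sizes = np.bincount(plan.assignment, minlength=10)
        assert (sizes == 76).all()

    def test_remainder_goes_to_earliest_folds(self):
        plan = plan_folds(7, 3, seed=0, shuffled=False)
        sizes = np.bincount(plan.assignment, minlength=3)
        assert tuple(sizes) == (3, 2, 2)

    def test_unshuffled_folds_are_contiguous(self):
        plan = plan_folds(6, 3, shuffled=False)
        np.testing.assert_array_equal(plan.assignment, [0, 0, 1, 1, 2, 2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(N=st.integers(4, 200), n=st.integers(2, 10), seed=st.integers(0, 1000))
    def test_folds_partition_all_indices(self, N, n, seed):
        if n > N:
            n = N
        plan = plan_folds(N, n, seed=seed)
        all_idx = np.concatenate([plan.fold_indices(f) for f in range(n)])
        assert sorted(all_idx) == list(range(N))
        sizes = np.bincount(plan.assignment, minlength=n)
        assert sizes.max() - sizes.min() <= 1

    def test_n_larger_than_N_rejected(self):
        with pytest.raises(ValueError):
            plan_folds(3, 5)


class TestVotingRule:
    def test_majority_threshold_is_more_than_half(self):
        assert VotingRule.majority(5).k == 3
        assert VotingRule.majority(3).k == 2
        assert VotingRule.majority(4).k == 3

    def test_consensus_requires_all(self):
        assert VotingRule.consensus(5).k == 5

    def test_parse_attaches_names(self):
        assert VotingRule.parse("3/5").name == "MF"
        assert VotingRule.parse("5/5").name == "CF"
        assert VotingRule.parse("4/5").name == "custom"

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            VotingRule.parse("6/5")
        with pytest.raises(ValueError):
            VotingRule.parse("nonsense")


class TestTallyVotes:
    def test_confident_disagreement_votes(self):
        records = [_rec(0, 0, [0.1, 0.85, 0.05])]
        tally = tally_votes(records, np.array([0]), delta=0.8, m=1)
        assert tally.votes[0] == 1

    def test_underconfident_disagreement_does_not_vote(self):
        records = [_rec(0, 0, [0.2, 0.75, 0.05])]
        tally = tally_votes(records, np.array([0]), delta=0.8, m=1)
        assert tally.votes[0] == 0

    def test_threshold_is_strict(self):
        records = [_rec(0, 0, [0.2, 0.8, 0.0])]
        tally = tally_votes(records, np.array([0]), delta=0.8, m=1)
        assert tally.votes[0] == 0

    def test_correct_prediction_never_votes(self):
        records = [_rec(0, 0, [0.99, 0.01])]
        for delta in (0.0, 0.5, 0.9):
            assert tally_votes(records, np.array([0]), delta, m=1).votes[0] == 0

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            tally_votes([_rec(5, 0, [0.9, 0.1])], np.array([0]), 0.5)

    def test_duplicate_record_rejected(self):
        records = [_rec(0, 0, [0.9, 0.1]), _rec(0, 0, [0.8, 0.2])]
        with pytest.raises(ValueError, match="duplicate"):
            tally_votes(records, np.array([0]), 0.5)


class TestApplyRule:
    def test_majority_flags_at_three_of_five(self):
        rng = np.random.default_rng(0)
        records = random_records(rng, 30, 5, 3, confident=True)
        assigned = np.zeros(30, dtype=int)
        tally = tally_votes(records, assigned, delta=0.0, m=5)
        mf = apply_rule(tally, VotingRule.majority(5))
        assert mf == {q for q, v in tally.votes.items() if v >= 3}
        cf = apply_rule(tally, VotingRule.consensus(5))
        assert cf == {q for q, v in tally.votes.items() if v == 5}

    def test_flagged_sets_nest_in_k(self):
        rng = np.random.default_rng(1)
        records = random_records(rng, 50, 5, 4)
        tally = tally_votes(records, np.zeros(50, dtype=int), delta=0.2, m=5)
        sets = [apply_rule(tally, VotingRule(k, 5)) for k in range(1, 6)]
        for smaller, larger in zip(sets[1:], sets[:-1]):
            assert smaller <= larger

    def test_mismatched_ensemble_size_rejected(self):
        tally = tally_votes([_rec(0, 0, [0.9, 0.1])], np.array([1]), 0.5, m=1)
        with pytest.raises(ValueError):
            apply_rule(tally, VotingRule.majority(5))


class TestRecoverLabels:
    def test_unanimous_prediction_recovers_it(self):
        records = [_rec(0, j, [0.9, 0.05, 0.05]) for j in range(5)]
        assert recover_labels(records, {0}) == {0: 0}

    def test_one_dissenter_does_not_change_plurality(self):
        probs = [[0.05, 0.9, 0.05]] * 4 + [[0.9, 0.05, 0.05]]
        records = [_rec(0, j, p) for j, p in enumerate(probs)]
        assert recover_labels(records, {0}) == {0: 1}

    def test_tie_broken_by_summed_probability(self):
        # three-way tie S/D/E; summed probabilities favour class 0
        probs = [[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.15, 0.15, 0.7]]
        records = [_rec(0, j, p) for j, p in enumerate(probs)]
        # sums: 1.15, 1.00, 0.85 -> class 0 wins
        assert recover_labels(records, {0}) == {0: 0}

    def test_exact_probability_tie_goes_to_lowest_index(self):
        probs = [[0.6, 0.4], [0.4, 0.6]]
        records = [_rec(0, j, p) for j, p in enumerate(probs)]
        assert recover_labels(records, {0}) == {0: 0}

    def test_flagged_sample_without_records_rejected(self):
        with pytest.raises(ValueError):
            recover_labels([], {3})


class TestRunRound:
    def test_record_count_is_m_times_fold_size(self, noisy_dataset, oracle_ensemble):
        noisy, _ = noisy_dataset
        plan = plan_folds(len(noisy), 4, seed=0)
        records = run_round(noisy, plan, 1, oracle_ensemble)
        assert len(records) == 5 * len(plan.fold_indices(1))

    def test_oracle_predictions_match_true_labels(self, noisy_dataset, oracle_ensemble):
        noisy, _ = noisy_dataset
        plan = plan_folds(len(noisy), 4, seed=0)
        for r in run_round(noisy, plan, 0, oracle_ensemble):
            assert r.predicted == noisy.true[r.index]

    def test_single_classifier_rejected(self, noisy_dataset, oracle_ensemble):
        noisy, _ = noisy_dataset
        plan = plan_folds(len(noisy), 4, seed=0)
        with pytest.raises(ValueError, match=">= 2"):
            run_round(noisy, plan, 0, oracle_ensemble[:1])


class TestDetection:
    def test_oracle_detector_reproduces_injection_exactly(self, noisy_dataset, oracle_ensemble):
        noisy, injection = noisy_dataset
        det = MislabelDetector(oracle_ensemble, n_folds=5, delta=0.5,
                               rules=("3/5", "5/5"), random_state=0)
        det.fit(noisy, noisy.assigned)
        for rule in ("3/5", "5/5"):
            assert set(det.flagged_[rule]) == injection.indices
        for i, orig, _ in injection.flipped:
            assert det.recovered_[i] == orig

    def test_no_injection_flags_nothing(self, small_dataset):
        oracles = [OracleClassifier.from_dataset(small_dataset) for _ in range(3)]
        det = MislabelDetector(oracles, n_folds=4, delta=0.5, rules=("2/3",), random_state=0)
        det.fit(small_dataset, small_dataset.assigned)
        assert det.flagged_["2/3"] == []

    def test_identical_config_identical_report(self, noisy_dataset, oracle_ensemble):
        noisy, _ = noisy_dataset
        reports = []
        for _ in range(2):
            det = MislabelDetector(oracle_ensemble, n_folds=5, delta=0.5,
                                   rules=("3/5",), random_state=3)
            det.fit(noisy, noisy.assigned)
            reports.append(det.report_)
        assert reports[0].config == reports[1].config
        assert reports[0].samples == reports[1].samples

    def test_flag_count_non_increasing_in_delta_on_frozen_records(self, noisy_dataset):
        noisy, _ = noisy_dataset
        oracles = [OracleClassifier.from_dataset(noisy, confidence=c)
                   for c in (0.95, 0.85, 0.75, 0.65, 0.55)]
        det = MislabelDetector(oracles, n_folds=5, delta=0.0, rules=("3/5",), random_state=0)
        det.fit(noisy, noisy.assigned)
        sizes = []
        for delta in (0.5, 0.6, 0.7, 0.8, 0.9):
            tally = tally_votes(det.records_, noisy.assigned, delta, m=5)
            sizes.append(len(apply_rule(tally, VotingRule.majority(5))))
        assert sizes == sorted(sizes, reverse=True)

    def test_rule_mismatching_ensemble_size_rejected(self, noisy_dataset, oracle_ensemble):
        noisy, _ = noisy_dataset
        det = MislabelDetector(oracle_ensemble, n_folds=5, rules=("2/3",), random_state=0)
        with pytest.raises(ValueError, match="ensemble size"):
            det.fit(noisy, noisy.assigned)

    def test_stratified_plan_still_partitions(self, noisy_dataset, oracle_ensemble):
        noisy, injection = noisy_dataset
        det = MislabelDetector(oracle_ensemble, n_folds=5, delta=0.5, rules=("3/5",),
                               stratify=True, random_state=0)
        det.fit(noisy, noisy.assigned)
        assert set(det.flagged_["3/5"]) == injection.indices

    def test_no_leakage_between_train_and_test(self, noisy_dataset, oracle_ensemble):
        noisy, _ = noisy_dataset
        det = MislabelDetector(oracle_ensemble, n_folds=5, random_state=0, rules=("3/5",))
        det.fit(noisy, noisy.assigned)
        for f in range(det.plan_.n):
            train = set(det.plan_.train_indices(f))
            test = set(det.plan_.fold_indices(f))
            assert not train & test
            assert train | test == set(range(len(noisy)))
        assert len(det.training_hashes_()) == 5

    def test_run_detection_wrapper_matches_detector(self, noisy_dataset, oracle_ensemble):
        noisy, injection = noisy_dataset
        cfg = DetectionConfig(classifiers=tuple(oracle_ensemble), n_subsets=5,
                              delta=0.5, rules=("3/5",), train=TrainConfig(), seed=0)
        report = run_detection(noisy, cfg)
        assert report.flagged_set("3/5") == injection.indices
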