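"""The detection engine: cross-validation rounds, confidence-gated voting,
k-of-m flag rules, and true-label recovery.

The core idea: split the dataset into n near-equal folds; in each round
train every ensemble member from scratch on the other n-1 folds and let it
predict the held-out fold, so each sample is judged exactly once by models
that never saw it. A member *votes* that a sample is mislabeled when its
prediction disagrees with the assigned label **and** its top softmax
probability strictly exceeds the confidence threshold δ. A sample is
flagged when its vote count reaches the rule's minimum k (majority
filtering: k = ⌊m/2⌋+1; consensus filtering: k = m), and its true label is
recovered as the plurality of the m per-member predictions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone

from .classifiers import ClassifierSpec, TrainConfig, build_classifier
from .datamodel import ImageDataset, MislabelReport, SampleEntry

__all__ = [
    "FoldPlan",
    "VotingRule",
    "PredictionRecord",
    "VoteTally",
    "DetectionConfig",
    "plan_folds",
    "run_round",
    "tally_votes",
    "apply_rule",
    "recover_labels",
    "run_detection",
    "MislabelDetector",
]


@dataclass(frozen=True)
class FoldPlan:
    """Partition of 0..N-1 into n folds whose sizes differ by at most 1."""

    n: int
    assignment: np.ndarray  # sample index -> fold id
    seed: int
    shuffled: bool

    def fold_indices(self, fold_id: int) -> np.ndarray:
        if not 0 <= fold_id < self.n:
            raise IndexError(f"fold id {fold_id} out of range")
        return np.flatnonzero(self.assignment == fold_id)

    def train_indices(self, fold_id: int) -> np.ndarray:
        if not 0 <= fold_id < self.n:
            raise IndexError(f"fold id {fold_id} out of range")
        return np.flatnonzero(self.assignment != fold_id)


def plan_folds(N: int, n: int, seed: int = 0, shuffled: bool = True) -> FoldPlan:
    """Split 0..N-1 into n contiguous blocks of a (possibly) shuffled order.

    The first N mod n folds get the extra sample, so sizes are ⌈N/n⌉ or
    ⌊N/n⌋.
    """
    if not 2 <= n <= N:
        raise ValueError(f"need 2 <= n <= N, got n={n}, N={N}")
    order = np.random.default_rng(seed).permutation(N) if shuffled else np.arange(N)
    sizes = np.full(n, N // n)
    sizes[: N % n] += 1
    assignment = np.empty(N, dtype=np.int64)
    start = 0
    for fold, size in enumerate(sizes):
        assignment[order[start : start + size]] = fold
        start += size
    return FoldPlan(n=n, assignment=assignment, seed=seed, shuffled=shuffled)


@dataclass(frozen=True)
class VotingRule:
    """k-of-m flag rule. MF: k = ⌊m/2⌋+1 (more than half); CF: k = m."""

    k: int
    m: int
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.m:
            raise ValueError(f"need 1 <= k <= m, got k={self.k}, m={self.m}")
        if self.name == "MF" and self.k != self.m // 2 + 1:
            raise ValueError("MF requires k = floor(m/2) + 1")
        if self.name == "CF" and self.k != self.m:
            raise ValueError("CF requires k = m")

    @classmethod
    def majority(cls, m: int) -> "VotingRule":
        return cls(k=m // 2 + 1, m=m, name="MF")

    @classmethod
    def consensus(cls, m: int) -> "VotingRule":
        return cls(k=m, m=m, name="CF")

    @classmethod
    def parse(cls, text: str) -> "VotingRule":
        """Parse 'k/m' (e.g. '3/5'); names MF/CF are attached automatically."""
        try:
            k_s, m_s = text.split("/")
            k, m = int(k_s), int(m_s)
        except ValueError as e:
            raise ValueError(f"cannot parse voting rule {text!r}; expected 'k/m'") from e
        if k == m:
            return cls(k, m, "CF")
        if k == m // 2 + 1:
            return cls(k, m, "MF")
        return cls(k, m, "custom")

    @property
    def label(self) -> str:
        return f"{self.k}/{self.m}"


@dataclass(frozen=True)
class PredictionRecord:
    """One classifier's verdict on one held-out sample in one round."""

    index: int
    classifier_id: int
    proba: np.ndarray
    predicted: int
    top_p: float
    round_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "proba", np.asarray(self.proba, dtype=np.float64))
        if int(np.argmax(self.proba)) != self.predicted:
            raise ValueError("predicted label must be the argmax of proba")
        if not np.isclose(self.proba[self.predicted], self.top_p):
            raise ValueError("top_p must be the max of proba")


@dataclass
class VoteTally:
    """Per-sample eligible-vote bookkeeping for one δ."""

    m: int
    delta: float
    votes: dict[int, int] = field(default_factory=dict)  # sample -> count
    voters: dict[int, list[int]] = field(default_factory=dict)
    predictions: dict[int, dict[int, tuple[int, float]]] = field(default_factory=dict)


def _record_from_proba(index, clf_id, proba, round_id) -> PredictionRecord:
    proba = np.asarray(proba, dtype=np.float64)
    pred = int(np.argmax(proba))
    return PredictionRecord(
        index=int(index),
        classifier_id=int(clf_id),
        proba=proba,
        predicted=pred,
        top_p=float(proba[pred]),
        round_id=int(round_id),
    )


def _materialize(clf, vocabulary, input_shape):
    if isinstance(clf, ClassifierSpec):
        return build_classifier(clf, vocabulary, input_shape)
    return clone(clf)


def run_round(
    dataset: ImageDataset,
    plan: FoldPlan,
    round_i: int,
    classifiers: list,
    train_cfg: TrainConfig | None = None,
) -> list[PredictionRecord]:
    """Train every member fresh on the n-1 training folds and predict the
    held-out fold. Returns m x |fold| prediction records.

    ``classifiers`` entries are ClassifierSpec or unfitted estimators; each
    is rebuilt/cloned here so no state leaks between rounds. A no-leakage
    assertion verifies train/test disjointness on every call.
    """
    if len(classifiers) < 2:
        raise ValueError("ensemble requires >= 2 classifiers")
    test_idx = plan.fold_indices(round_i)
    train_idx = plan.train_indices(round_i)
    assert not np.intersect1d(test_idx, train_idx).size, "train/test leakage"
    train_cfg = train_cfg or TrainConfig()
    records: list[PredictionRecord] = []
    X_train = dataset.images[train_idx]
    y_train = dataset.assigned[train_idx]
    X_test = dataset.images[test_idx]
    for clf_id, proto in enumerate(classifiers):
        clf = _materialize(proto, dataset.vocabulary, dataset.image_shape)
        params = clf.get_params() if isinstance(clf, BaseEstimator) else {}
        overrides = {
            k: v
            for k, v in (
                ("epochs", train_cfg.epochs),
                ("learning_rate", train_cfg.learning_rate),
                ("batch_size", train_cfg.batch_size),
                ("momentum", train_cfg.momentum),
            )
            if k in params
        }
        if overrides:
            clf.set_params(**overrides)
        clf.fit(X_train, y_train)
        probas = clf.predict_proba(X_test)
        for local_i, sample_i in enumerate(test_idx):
            records.append(
                _record_from_proba(sample_i, clf_id, probas[local_i], round_i)
            )
    return records


def tally_votes(
    records: list[PredictionRecord],
    assigned_labels: np.ndarray,
    delta: float,
    m: int | None = None,
) -> VoteTally:
    """Count eligible votes per sample at threshold δ.

    Classifier j votes on sample q iff predicted_j(q) != assigned(q) AND
    top_p_j(q) > δ (strictly). Correct or under-confident predictions never
    vote; the denominator stays m regardless of abstentions.
    """
    assigned_labels = np.asarray(assigned_labels)
    n = len(assigned_labels)
    clf_ids = sorted({r.classifier_id for r in records})
    m = m if m is not None else len(clf_ids)
    tally = VoteTally(m=m, delta=float(delta))
    seen: set[tuple[int, int]] = set()
    for r in records:
        if not 0 <= r.index < n:
            raise ValueError(f"record for unknown sample index {r.index}")
        key = (r.index, r.classifier_id)
        if key in seen:
            raise ValueError(f"duplicate record for sample {r.index}, classifier {r.classifier_id}")
        seen.add(key)
        tally.predictions.setdefault(r.index, {})[r.classifier_id] = (
            r.predicted,
            r.top_p,
        )
        tally.votes.setdefault(r.index, 0)
        tally.voters.setdefault(r.index, [])
        if r.predicted != assigned_labels[r.index] and r.top_p > delta:
            tally.votes[r.index] += 1
            tally.voters[r.index].append(r.classifier_id)
    return tally


def apply_rule(tally: VoteTally, rule: VotingRule) -> set[int]:
    """Flagged set C = { q : eligible_votes(q) >= rule.k }."""
    if rule.m != tally.m:
        raise ValueError(f"rule is for m={rule.m} but tally has m={tally.m}")
    return {q for q, v in tally.votes.items() if v >= rule.k}


def recover_labels(
    records: list[PredictionRecord], flagged: set[int]
) -> dict[int, int]:
    """Plurality of the m per-member predictions for each flagged sample.

    Ties are broken by the largest summed probability over the tied classes,
    then by the lowest class index.
    """
    by_sample: dict[int, list[PredictionRecord]] = {}
    for r in records:
        by_sample.setdefault(r.index, []).append(r)
    out: dict[int, int] = {}
    for q in sorted(flagged):
        recs = by_sample.get(q)
        if not recs:
            raise ValueError(f"flagged sample {q} has no prediction records")
        K = len(recs[0].proba)
        counts = np.zeros(K, dtype=np.int64)
        prob_sums = np.zeros(K, dtype=np.float64)
        for r in recs:
            counts[r.predicted] += 1
            prob_sums += r.proba
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            out[q] = int(tied[0])
        else:
            best = prob_sums[tied].max()
            near = tied[np.isclose(prob_sums[tied], best)]
            out[q] = int(near.min())
    return out


@dataclass(frozen=True)
class DetectionConfig:
    """Everything one detection run needs; all randomness flows from seed."""

    classifiers: tuple
    n_subsets: int = 10
    delta: float = 0.5
    rules: tuple[str, ...] = ("3/5",)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    shuffle_folds: bool = True
    stratify: bool = False


class MislabelDetector(BaseEstimator):
    """scikit-learn style front end for the detection engine.

    Parameters
    ----------
    estimators : list of ClassifierSpec or unfitted estimators
        The m ensemble members; each is rebuilt fresh every round.
    n_folds : int
        Number of cross-validation subsets n.
    delta : float
        Confidence threshold; a disagreeing vote counts only if its top
        softmax probability strictly exceeds delta (0 disables the gate).
    rules : sequence of str
        'k/m' flag rules evaluated on the shared vote tally.
    shuffle, stratify : bool
        Fold assignment: seeded shuffle (default) or original order;
        optionally stratified by assigned class.
    random_state : int
        Seed for fold shuffling.

    Attributes (after fit)
    ----------------------
    plan_ : FoldPlan;  records_ : list of PredictionRecord
    tally_ : VoteTally;  flagged_ : dict rule-label -> sorted index list
    recovered_ : dict index -> recovered class;  report_ : MislabelReport
    """

    def __init__(
        self,
        estimators,
        n_folds: int = 10,
        delta: float = 0.5,
        rules=("3/5",),
        train_config: TrainConfig | None = None,
        shuffle: bool = True,
        stratify: bool = False,
        random_state: int = 0,
    ):
        self.estimators = estimators
        self.n_folds = n_folds
        self.delta = delta
        self.rules = rules
        self.train_config = train_config
        self.shuffle = shuffle
        self.stratify = stratify
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y):
        dataset = self._as_dataset(X, y)
        N = len(dataset)
        m = len(self.estimators)
        rules = [VotingRule.parse(r) if isinstance(r, str) else r for r in self.rules]
        for rule in rules:
            if rule.m != m:
                raise ValueError(f"rule {rule.label} does not match ensemble size {m}")
        plan = self._plan(dataset)
        train_cfg = self.train_config or TrainConfig()
        records: list[PredictionRecord] = []
        for round_i in range(plan.n):
            records.extend(
                run_round(dataset, plan, round_i, list(self.estimators), train_cfg)
            )
        # partition property: every sample judged exactly once per classifier
        seen = np.zeros(N, dtype=np.int64)
        for r in records:
            if r.classifier_id == 0:
                seen[r.index] += 1
        if not np.all(seen == 1):
            raise AssertionError("cross-validation rounds do not partition the dataset")
        self.plan_ = plan
        self.records_ = records
        self._finalize(dataset, records, rules, m)
        return self

    def _finalize(self, dataset, records, rules, m):
        tally = tally_votes(records, dataset.assigned, self.delta, m=m)
        flagged_by_rule = {r.label: sorted(apply_rule(tally, r)) for r in rules}
        union = set().union(*flagged_by_rule.values()) if flagged_by_rule else set()
        recovered = recover_labels(records, union)
        self.tally_ = tally
        self.flagged_ = flagged_by_rule
        self.recovered_ = recovered
        self.report_ = self._build_report(dataset, tally, flagged_by_rule, recovered, m)

    def _build_report(self, dataset, tally, flagged_by_rule, recovered, m):
        config = {
            "n_subsets": int(self.n_folds),
            "m": m,
            "delta": float(self.delta),
            "rules": list(flagged_by_rule),
            "seed": int(self.random_state),
            "shuffle_folds": bool(self.shuffle),
            "stratify": bool(self.stratify),
        }
        samples = []
        for q in range(len(dataset)):
            preds = [
                {
                    "classifier": int(cid),
                    "predicted": int(pred),
                    "top_p": float(p),
                }
                for cid, (pred, p) in sorted(tally.predictions[q].items())
            ]
            samples.append(
                SampleEntry(
                    index=q,
                    assigned_label=int(dataset.assigned[q]),
                    predictions=preds,
                    votes=int(tally.votes[q]),
                    flagged={lbl: q in set(idx) for lbl, idx in flagged_by_rule.items()},
                    recovered_label=recovered.get(q),
                )
            )
        return MislabelReport(config=config, samples=samples)

    # -- helpers ---------------------------------------------------------
    def _plan(self, dataset) -> FoldPlan:
        N = len(dataset)
        if not self.stratify:
            return plan_folds(N, self.n_folds, seed=self.random_state, shuffled=self.shuffle)
        # stratified: deal each class's (shuffled) samples round-robin
        rng = np.random.default_rng(self.random_state)
        assignment = np.empty(N, dtype=np.int64)
        next_fold = 0
        for c in np.unique(dataset.assigned):
            idx = np.flatnonzero(dataset.assigned == c)
            if self.shuffle:
                idx = rng.permutation(idx)
            for i in idx:
                assignment[i] = next_fold
                next_fold = (next_fold + 1) % self.n_folds
        return FoldPlan(
            n=self.n_folds, assignment=assignment, seed=self.random_state,
            shuffled=self.shuffle,
        )

    @staticmethod
    def _as_dataset(X, y) -> ImageDataset:
        if isinstance(X, ImageDataset):
            return X
        from .datamodel import ClassVocabulary

        y = np.asarray(y, dtype=np.int64)
        K = int(y.max()) + 1 if y.size else 2
        vocab = ClassVocabulary(tuple(f"class_{i:02d}" for i in range(max(K, 2))))
        return ImageDataset(np.asarray(X), y, vocab)

    def training_hashes_(self) -> list[str]:
        """Per-round sha256 of the sorted training index list (audit trail)."""
        return [
            hashlib.sha256(self.plan_.train_indices(i).tobytes()).hexdigest()
            for i in range(self.plan_.n)
        ]


def run_detection(dataset: ImageDataset, config: DetectionConfig) -> MislabelReport:
    """Full pipeline: plan folds -> n rounds -> tally -> rules -> recovery."""
    detector = MislabelDetector(
        estimators=list(config.classifiers),
        n_folds=config.n_subsets,
        delta=config.delta,
        rules=tuple(config.rules),
        train_config=config.train,
        shuffle=config.shuffle_folds,
        stratify=config.stratify,
        random_state=config.seed,
    )
    detector.fit(dataset, dataset.assigned)
    return detector.report_
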