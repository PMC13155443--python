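"""Scoring detection against injected ground truth, and δ x rule sweeps.

Detection is scored as a retrieval problem over the injected flips:
TP = flagged ∩ injected, FP = flagged \\ injected, FN = injected \\ flagged,
with precision = TP/(TP+FP), recall = TP/(TP+FN) and F1 their harmonic
mean. Recovery is the share of flagged injected samples whose recovered
label equals the original (pre-flip) label.

Sweeps retrain nothing: one cross-validation pass produces the frozen
prediction records, and every (δ, rule) cell re-tallies those records, so
the δ comparison is not confounded by training noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ImageDataset, MislabelReport, NoiseInjectionRecord
from .filtering import (
    DetectionConfig,
    MislabelDetector,
    VotingRule,
    apply_rule,
    recover_labels,
    tally_votes,
)

__all__ = ["EvaluationResult", "score_detection", "score_recovery", "sweep"]


@dataclass(frozen=True)
class EvaluationResult:
    rule: str
    delta: float
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float
    recovery_fraction: float | None = None
    undefined: tuple[str, ...] = ()  # metrics whose denominator was zero


def _metrics(TP: int, FP: int, FN: int) -> tuple[float, float, float, tuple[str, ...]]:
    undefined = []
    if TP + FP > 0:
        precision = TP / (TP + FP)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if TP + FN > 0:
        recall = TP / (TP + FN)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    return precision, recall, f1, tuple(undefined)


def score_detection(
    report: MislabelReport,
    injection: NoiseInjectionRecord,
    rule: str | VotingRule,
    delta: float | None = None,
) -> EvaluationResult:
    """Confusion counts and metrics for one rule of a detection report."""
    label = rule.label if isinstance(rule, VotingRule) else VotingRule.parse(rule).label
    if label not in report.rules:
        raise ValueError(f"rule {label} not present in report (has {report.rules})")
    sample_indices = {s.index for s in report.samples}
    if not injection.indices <= sample_indices:
        raise ValueError("injection indices not covered by the report")
    flagged = report.flagged_set(label)
    injected = injection.indices
    TP = len(flagged & injected)
    FP = len(flagged - injected)
    FN = len(injected - flagged)
    precision, recall, f1, undefined = _metrics(TP, FP, FN)
    return EvaluationResult(
        rule=label,
        delta=float(report.config["delta"] if delta is None else delta),
        TP=TP,
        FP=FP,
        FN=FN,
        precision=precision,
        recall=recall,
        f1=f1,
        recovery_fraction=score_recovery(report, injection, label),
        undefined=undefined,
    )


def score_recovery(
    report: MislabelReport,
    injection: NoiseInjectionRecord,
    rule: str | VotingRule,
) -> float | None:
    """Share of flagged injected samples recovered to their original label.

    Returns None when no injected sample was flagged (the fraction is
    undefined).
    """
    label = rule.label if isinstance(rule, VotingRule) else VotingRule.parse(rule).label
    flagged = report.flagged_set(label)
    original = {i: orig for i, orig, _ in injection.flipped}
    hits = total = 0
    for q in flagged & injection.indices:
        total += 1
        if report.entry(q).recovered_label == original[q]:
            hits += 1
    return None if total == 0 else hits / total


def sweep(
    dataset: ImageDataset,
    injection: NoiseInjectionRecord,
    deltas: list[float],
    rules: list[str],
    config: DetectionConfig,
) -> pd.DataFrame:
    """|deltas| x |rules| evaluation grid from one frozen prediction set.

    Columns: rule, delta, TP, FP, FN, precision, recall, f1,
    recovery_fraction.
    """
    if not deltas or not rules:
        raise ValueError("deltas and rules must be non-empty")
    parsed = [VotingRule.parse(r) for r in rules]
    m = len(config.classifiers)
    for rule in parsed:
        if rule.m != m:
            raise ValueError(f"rule {rule.label} does not match ensemble size {m}")
    detector = MislabelDetector(
        estimators=list(config.classifiers),
        n_folds=config.n_subsets,
        delta=0.0,  # gate is applied per-cell below
        rules=(parsed[0].label,),
        train_config=config.train,
        shuffle=config.shuffle_folds,
        stratify=config.stratify,
        random_state=config.seed,
    )
    detector.fit(dataset, dataset.assigned)
    records = detector.records_
    injected = injection.indices
    original = {i: orig for i, orig, _ in injection.flipped}
    rows = []
    for delta in deltas:
        tally = tally_votes(records, dataset.assigned, delta, m=m)
        for rule in parsed:
            flagged = apply_rule(tally, rule)
            recovered = recover_labels(records, flagged & injected)
            TP = len(flagged & injected)
            FP = len(flagged - injected)
            FN = len(injected - flagged)
            precision, recall, f1, _ = _metrics(TP, FP, FN)
            hits = sum(recovered[q] == original[q] for q in flagged & injected)
            rows.append(
                {
                    "rule": rule.label,
                    "delta": float(delta),
                    "TP": TP,
                    "FP": FP,
                    "FN": FN,
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                    "recovery_fraction": (hits / TP) if TP else np.nan,
                }
            )
    return pd.DataFrame(rows)
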