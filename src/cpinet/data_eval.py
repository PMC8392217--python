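"""Dataset assembly, target-disjoint splitting and virtual-screening metrics.

A sample pair is (target, ligand, label): label 1 for an active (the
molecule docks with the target), 0 for a decoy.  Datasets are assembled per
target at a controlled positive:negative ratio — all actives plus ``ratio``
randomly selected decoys per active — and split by protein so no target is
seen at both train and test time.  Evaluation reports overall and per-target
ROC AUC (Mann–Whitney: probability a random positive outscores a random
negative, ties counted one half), counts of targets whose AUC strictly
exceeds 0.7/0.8/0.9, and precision/recall/F1 at the threshold maximizing F1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Callable, NamedTuple

import numpy as np

logger = logging.getLogger(__name__)


class SamplePair(NamedTuple):
    target_id: str
    ligand_id: str
    label: int


@dataclass(frozen=True)
class DatasetSplit:
    train_pairs: list[SamplePair]
    test_pairs: list[SamplePair]
    train_targets: frozenset[str]
    test_targets: frozenset[str]


@dataclass(frozen=True)
class EvalReport:
    """Overall and per-target screening statistics; rates in [0, 1]."""

    overall_auc: float
    per_target_auc: dict[str, float]
    threshold_counts: tuple[int, int, int]  # strictly > 0.7 / 0.8 / 0.9
    threshold: float
    precision: float
    recall: float
    f1: float
    excluded_targets: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "overall_auc": self.overall_auc,
            "per_target_auc": self.per_target_auc,
            "targets_auc_above": {
                "0.7": self.threshold_counts[0],
                "0.8": self.threshold_counts[1],
                "0.9": self.threshold_counts[2],
            },
            "threshold": self.threshold,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "excluded_targets": list(self.excluded_targets),
        }


# ---------------------------------------------------------------------------
# assembly and splitting
# ---------------------------------------------------------------------------

def assemble(
    actives: dict[str, list[str]],
    decoys: dict[str, list[str]],
    ratio: int = 1,
    seed: int = 0,
) -> list[SamplePair]:
    """Build sample pairs per target: every active labeled 1 plus ``ratio``
    seeded-randomly selected decoys per active labeled 0.

    Targets with zero actives are excluded with a warning; targets with too
    few decoys contribute all they have, with a warning.
    """
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    rng = np.random.default_rng(seed)
    pairs: list[SamplePair] = []
    for target in sorted(actives):
        ligs = actives[target]
        if not ligs:
            logger.warning("target %s has no actives: excluded", target)
            continue
        pool = list(decoys.get(target, []))
        wanted = ratio * len(ligs)
        if len(pool) < wanted:
            logger.warning(
                "target %s: %d decoys available, %d requested", target, len(pool), wanted
            )
            chosen = pool
        else:
            chosen = [pool[i] for i in rng.choice(len(pool), size=wanted, replace=False)]
        pairs.extend(SamplePair(target, lig, 1) for lig in ligs)
        pairs.extend(SamplePair(target, dec, 0) for dec in chosen)
    return pairs


def split_by_target(
    pairs: list[SamplePair],
    train_targets,
    test_targets,
) -> DatasetSplit:
    """Partition pairs by protein target; the two target sets must be disjoint."""
    train_targets = frozenset(train_targets)
    test_targets = frozenset(test_targets)
    overlap = train_targets & test_targets
    if overlap:
        raise ValueError(f"targets on both sides of the split: {sorted(overlap)}")
    train = [p for p in pairs if p.target_id in train_targets]
    test = [p for p in pairs if p.target_id in test_targets]
    return DatasetSplit(train, test, train_targets, test_targets)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """ROC AUC (ties counted one half).  Raises on single-class input."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined when only one class is present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def per_target_auc(
    pairs: list[SamplePair],
    scores,
) -> tuple[dict[str, float], tuple[int, int, int], list[str]]:
    """Per-target AUC plus counts of targets with AUC strictly above
    0.7 / 0.8 / 0.9.  Single-class targets are excluded with a warning and
    returned in the third element."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(pairs):
        raise ValueError("one score per pair is required")
    by_target: dict[str, list[int]] = {}
    for i, p in enumerate(pairs):
        by_target.setdefault(p.target_id, []).append(i)
    aucs: dict[str, float] = {}
    excluded: list[str] = []
    for target in sorted(by_target):
        idx = np.array(by_target[target])
        y = np.array([pairs[i].label for i in idx])
        if len(np.unique(y)) < 2:
            logger.warning("target %s has a single class: excluded from per-target AUC", target)
            excluded.append(target)
            continue
        aucs[target] = roc_auc(scores[idx], y)
    counts = threshold_counts(list(aucs.values()))
    return aucs, counts, excluded


def threshold_counts(aucs, thresholds=(0.7, 0.8, 0.9)) -> tuple[int, ...]:
    """How many AUC values strictly exceed each threshold."""
    aucs = np.asarray(list(aucs), dtype=float)
    return tuple(int(np.sum(aucs > t)) for t in thresholds)


def best_f1_threshold(scores, labels) -> tuple[float, float, float, float]:
    """Scan candidate thresholds (0, every distinct score, 1) and return
    ``(threshold, precision, recall, f1)`` at the F1 maximum; ties break
    toward the lower threshold.  Predictions are positive when
    score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("F1 threshold needs both classes present")
    candidates = np.concatenate([[0.0], np.unique(scores), [1.0]])
    best = None
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        if best is None or f1 > best[3]:
            best = (float(t), precision, recall, f1)
    return best


def evaluate(pairs: list[SamplePair], scores) -> EvalReport:
    """Full screening report on one scored pair set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.array([p.label for p in pairs])
    overall = roc_auc(scores, labels)
    aucs, counts, excluded = per_target_auc(pairs, scores)
    threshold, precision, recall, f1 = best_f1_threshold(scores, labels)
    return EvalReport(
        overall_auc=overall,
        per_target_auc=aucs,
        threshold_counts=counts,
        threshold=threshold,
        precision=precision,
        recall=recall,
        f1=f1,
        excluded_targets=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def target_folds(targets, k: int, seed: int) -> list[list[str]]:
    """Partition targets into k disjoint folds, seeded and reproducible."""
    targets = sorted(set(targets))
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(targets) < k:
        raise ValueError(f"{len(targets)} targets cannot form {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    return [[targets[i] for i in order[f::k]] for f in range(k)]


def kfold_cv(
    pairs: list[SamplePair],
    fit_predict: Callable[[list[SamplePair], list[SamplePair]], np.ndarray],
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Target-disjoint k-fold cross-validation.

    ``fit_predict(train_pairs, val_pairs)`` trains on the first argument and
    returns scores for the second.  Returns per-fold AUCs and their mean.
    """
    folds = target_folds([p.target_id for p in pairs], k, seed)
    fold_aucs = []
    for f, val_targets in enumerate(folds):
        val_set = frozenset(val_targets)
        train = [p for p in pairs if p.target_id not in val_set]
        val = [p for p in pairs if p.target_id in val_set]
        scores = fit_predict(train, val)
        auc = roc_auc(scores, [p.label for p in val])
        fold_aucs.append(auc)
        logger.info("fold %d: %d train / %d val pairs, AUC %.4f", f, len(train), len(val), auc)
    return {"fold_aucs": fold_aucs, "mean_auc": float(np.mean(fold_aucs)), "folds": folds}


# ---------------------------------------------------------------------------
# I/O and bundled benchmark bookkeeping
# ---------------------------------------------------------------------------

def read_pairs(path) -> list[SamplePair]:
    """Read a pairs TSV with header ``target_id  ligand_id  label``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        SamplePair(str(r.target_id), str(r.ligand_id), int(r.label))
        for r in df.itertuples(index=False)
    ]


def write_pairs(path, pairs: list[SamplePair]) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\tligand_id\tlabel\n")
        for p in pairs:
            fh.write(f"{p.target_id}\t{p.ligand_id}\t{p.label}\n")


def write_report(path, report: EvalReport) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def benchmark_positive_counts() -> dict[str, dict[str, int]]:
    """The bundled per-target active counts of the 91-protein screening
    benchmark, keyed by split ('train': 68 targets, 'test': 23 targets)."""
    out: dict[str, dict[str, int]] = {"train": {}, "test": {}}
    text = resources.files("cpinet.data").joinpath("dude_counts.tsv").read_text()
    for line in text.splitlines()[1:]:
        split, target, count = line.split("\t")
        out[split][target] = int(count)
    return out


def bookkeeping_pairs(ratio: int = 1, seed: int = 0) -> DatasetSplit:
    """Rebuild the benchmark's pair bookkeeping from the bundled per-target
    active counts: synthetic ligand/decoy identifiers stand in for the real
    molecules, so pair counts (not chemistry) are reproduced."""
    counts = benchmark_positive_counts()
    pairs_by_split = {}
    for split, per_target in counts.items():
        actives = {t: [f"{t}_act{i}" for i in range(n)] for t, n in per_target.items()}
        decoys = {t: [f"{t}_dec{i}" for i in range(ratio * n)] for t, n in per_target.items()}
        pairs_by_split[split] = assemble(actives, decoys, ratio=ratio, seed=seed)
    return split_by_target(
        pairs_by_split["train"] + pairs_by_split["test"],
        train_targets=counts["train"],
        test_targets=counts["test"],
    )
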