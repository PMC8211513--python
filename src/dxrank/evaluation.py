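"""Evaluation protocol: stratified k-fold cross-validation and top-k hit
accuracy, with the eight-variant comparison grid run on shared folds.

A test record is a *hit* when its true disease appears anywhere in the
top-k ranked output; records with an empty candidate set count as misses
and are tallied separately. Grid accuracies pool predictions across folds
(record-weighted); per-fold accuracies are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .corpus import MedicalRecord
from .model import CooccurrenceModel, VariantConfig, table_variants

__all__ = [
    "EvaluationResult",
    "FoldOutcome",
    "kfold_split",
    "single_split",
    "topk_hit_accuracy",
    "run_variant_grid",
    "grid_table",
]


def kfold_split(
    records: Sequence[MedicalRecord],
    k: int,
    seed: int,
    stratify: bool = True,
) -> list[list[int]]:
    """Partition record indices into k disjoint folds.

    Stratified by disease where class counts allow: within each class the
    indices are shuffled and dealt round-robin across folds with a rotating
    offset, so classes with fewer than k members degrade gracefully to a
    plain spread instead of failing. Deterministic under a fixed seed.
    """
    n = len(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the corpus size {n}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratify:
        by_class: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_class.setdefault(r.disease, []).append(i)
        offset = 0
        for disease in sorted(by_class):
            idx = np.array(by_class[disease])
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                folds[(offset + j) % k].append(int(i))
            offset = (offset + len(idx)) % k
    else:
        perm = rng.permutation(n)
        for j, i in enumerate(perm):
            folds[j % k].append(int(i))
    return [sorted(f) for f in folds]


def single_split(
    records: Sequence[MedicalRecord],
    test_fraction: float = 1 / 3,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list[int], list[int]]:
    """One train/test split (default 2/3-1/3), realized as the first fold
    of a round(1/test_fraction)-fold partition."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    k = max(2, round(1 / test_fraction))
    folds = kfold_split(records, k, seed, stratify)
    test = folds[0]
    test_set = set(test)
    train = [i for i in range(len(records)) if i not in test_set]
    return train, test


class FoldOutcome(NamedTuple):
    """Hit bookkeeping for one evaluated test set."""

    hits: int
    n_test: int
    n_no_candidate: int
    record_hits: tuple[bool, ...]


def topk_hit_accuracy(
    model: CooccurrenceModel,
    test_records: Sequence[MedicalRecord],
    config: VariantConfig,
) -> FoldOutcome:
    """Score every test record and apply the hit rule: the true disease
    anywhere in the top-k ranking counts as correct."""
    if not test_records:
        raise ValueError("empty test set")
    rec_hits: list[bool] = []
    n_no_candidate = 0
    for r in test_records:
        pred = model.predict_topk(r.symptoms, config)
        if pred.status == "no_candidates":
            n_no_candidate += 1
            rec_hits.append(False)
        else:
            rec_hits.append(any(d == r.disease for d, _ in pred.ranked))
    return FoldOutcome(sum(rec_hits), len(rec_hits), n_no_candidate, tuple(rec_hits))


@dataclass(frozen=True)
class EvaluationResult:
    """Pooled cross-validated outcome for one variant."""

    variant: str
    accuracy: float
    hits: int
    n_test: int
    n_no_candidate: int
    per_fold: tuple[float, ...]
    per_fold_n: tuple[int, ...]
    record_indices: tuple[int, ...]
    record_hits: tuple[bool, ...]


def run_variant_grid(
    records: Sequence[MedicalRecord],
    configs: Mapping[str, VariantConfig] | None = None,
    k: int = 3,
    seed: int = 0,
    stratify: bool = True,
) -> dict[str, EvaluationResult]:
    """Evaluate every variant on the SAME k folds (paired comparison).

    One model is fitted per fold (the counts do not depend on the variant)
    and reused across all variants. Returns one result per variant with
    pooled (record-weighted) accuracy, per-fold accuracies, and per-record
    hit flags aligned with ``record_indices`` for downstream slicing
    (e.g. rare-class accuracy).
    """
    configs = dict(configs) if configs is not None else table_variants()
    folds = kfold_split(records, k, seed, stratify)
    acc: dict[str, dict] = {
        name: {
            "hits": 0,
            "n_test": 0,
            "n_no_candidate": 0,
            "per_fold": [],
            "per_fold_n": [],
            "record_indices": [],
            "record_hits": [],
        }
        for name in configs
    }
    for fold in folds:
        fold_set = set(fold)
        train = [records[i] for i in range(len(records)) if i not in fold_set]
        test = [records[i] for i in fold]
        model = CooccurrenceModel.fit(train)
        for name, cfg in configs.items():
            out = topk_hit_accuracy(model, test, cfg)
            bucket = acc[name]
            bucket["hits"] += out.hits
            bucket["n_test"] += out.n_test
            bucket["n_no_candidate"] += out.n_no_candidate
            bucket["per_fold"].append(out.hits / out.n_test)
            bucket["per_fold_n"].append(out.n_test)
            bucket["record_indices"].extend(fold)
            bucket["record_hits"].extend(out.record_hits)
    return {
        name: EvaluationResult(
            variant=name,
            accuracy=b["hits"] / b["n_test"],
            hits=b["hits"],
            n_test=b["n_test"],
            n_no_candidate=b["n_no_candidate"],
            per_fold=tuple(b["per_fold"]),
            per_fold_n=tuple(b["per_fold_n"]),
            record_indices=tuple(b["record_indices"]),
            record_hits=tuple(b["record_hits"]),
        )
        for name, b in acc.items()
    }


def grid_table(results: Mapping[str, EvaluationResult]) -> pd.DataFrame:
    """Tabulate grid results: one row per variant, pooled accuracy first,
    then per-fold columns."""
    rows = []
    for name, res in results.items():
        row = {
            "variant": name,
            "accuracy": res.accuracy,
            "hits": res.hits,
            "n_test": res.n_test,
            "n_no_candidate": res.n_no_candidate,
        }
        for j, (a, nj) in enumerate(zip(res.per_fold, res.per_fold_n), start=1):
            row[f"fold{j}_accuracy"] = a
            row[f"fold{j}_n"] = nj
        rows.append(row)
    return pd.DataFrame(rows)
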