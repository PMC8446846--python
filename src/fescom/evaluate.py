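"""Experimental harness: train/test partitioning, error-vs-feature-count
curves, and the hybrid-vs-plain-wrapper comparison.

The harness mirrors a standard evaluation design: the feature table is
stratified-split into a training and a testing part; feature selection runs
on the training part only (with five-fold cross-validated error as the
wrapper criterion); the selected subsets are then scored once on the held-out
testing part.  Search cost is reported as the classifier-fit count, a
hardware-independent quantity, alongside optional wall-clock time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import ParameterError, StratificationError
from .features import FeatureTable
from .selection import (
    DEFAULT_FOLDS,
    DEFAULT_THRESHOLD,
    ClassifierSpec,
    cv_error_rate,
    fescom_select,
    wrapper_select,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything that determines one comparison experiment."""

    classifiers: tuple[ClassifierSpec, ...] = (
        ClassifierSpec("knn"),
        ClassifierSpec("nb"),
        ClassifierSpec("rf"),
    )
    threshold: float = DEFAULT_THRESHOLD
    folds: int = DEFAULT_FOLDS
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ParameterError("train_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")


def split(
    table: FeatureTable, train_fraction: float = 0.7, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified random train/test split, deterministic per seed.

    Both parts contain every class; the parts are disjoint and their union is
    the original table (rows permuted).
    """
    if not (0 < train_fraction < 1):
        raise ParameterError("train_fraction must lie in (0, 1)")
    labels = np.asarray(table.labels)
    for cls in table.class_set:
        if int(np.sum(labels == cls)) < 2:
            raise StratificationError(
                f"class '{cls}' is too small to appear in both parts"
            )
    idx = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=labels
    )
    def _take(rows: np.ndarray) -> FeatureTable:
        return FeatureTable(
            matrix=table.matrix[rows],
            names=table.names,
            labels=tuple(table.labels[i] for i in rows),
        )
    return _take(np.sort(train_idx)), _take(np.sort(test_idx))


def holdout_error(
    train: FeatureTable,
    test: FeatureTable,
    feature_subset: Sequence[int],
    spec: ClassifierSpec,
) -> float:
    """Error rate on the test part of a classifier trained on the train part."""
    subset = list(feature_subset)
    clf = spec.build()
    clf.fit(train.matrix[:, subset], np.asarray(train.labels))
    pred = clf.predict(test.matrix[:, subset])
    return float(np.mean(pred != np.asarray(test.labels)))


def error_curve(
    table: FeatureTable,
    ranked_features: Sequence[int],
    spec: ClassifierSpec,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> tuple[list[tuple[int, float]], int]:
    """CV error of the top-j ranked features for j = 1..len(ranked_features).

    Returns the curve as ``[(n_features, cv_error), ...]`` and the optimal
    feature count (the smallest j attaining the minimum error).
    """
    ranked = list(ranked_features)
    if not ranked:
        raise ParameterError("ranked_features must be non-empty")
    curve = []
    for j in range(1, len(ranked) + 1):
        err = cv_error_rate(table.restrict(ranked[:j]), spec, folds, seed)
        curve.append((j, err))
    errors = [e for _, e in curve]
    optimal = curve[int(np.argmin(errors))][0]
    return curve, optimal


@dataclass(frozen=True)
class MethodResult:
    """One (method, classifier) cell of the comparison report."""

    method: str  # "fescom" | "wrapper"
    classifier: str
    selected: tuple[int, ...]
    selected_names: tuple[str, ...]
    n_selected: int
    n_candidates: int
    train_cv_error: float
    test_error: float
    fit_count: int
    wall_clock_s: float


@dataclass(frozen=True)
class ComparisonReport:
    """Hybrid-vs-wrapper comparison across classifiers."""

    results: tuple[MethodResult, ...]
    config: ExperimentConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": r.method,
                    "classifier": r.classifier,
                    "n_candidates": r.n_candidates,
                    "n_selected": r.n_selected,
                    "train_cv_error": r.train_cv_error,
                    "test_error": r.test_error,
                    "fit_count": r.fit_count,
                }
                for r in self.results
            ]
        )

    def error_grid(self) -> pd.DataFrame:
        """Method x classifier grid of test error rates (percent)."""
        frame = self.to_frame()
        grid = frame.pivot(index="method", columns="classifier", values="test_error")
        return 100.0 * grid

    def to_json(self) -> str:
        payload = {
            "config": {
                "threshold": self.config.threshold,
                "folds": self.config.folds,
                "train_fraction": self.config.train_fraction,
                "seed": self.config.seed,
            },
            "results": [
                {
                    "method": r.method,
                    "classifier": r.classifier,
                    "selected": list(r.selected),
                    "selected_names": list(r.selected_names),
                    "n_candidates": r.n_candidates,
                    "train_cv_error": r.train_cv_error,
                    "test_error": r.test_error,
                    "fit_count": r.fit_count,
                    "wall_clock_s": r.wall_clock_s,
                }
                for r in self.results
            ],
        }
        return json.dumps(payload, indent=2)


def compare_methods(
    table: FeatureTable, config: ExperimentConfig
) -> ComparisonReport:
    """Run the hybrid method and the plain wrapper on the same split.

    Both methods select features on the training part; the selected subsets
    are then scored on the held-out testing part.  Fit counts come straight
    from each method's search trace.
    """
    train, test = split(table, config.train_fraction, config.seed)
    results: list[MethodResult] = []
    for clf_spec in config.classifiers:
        for method in ("wrapper", "fescom"):
            t0 = time.perf_counter()
            if method == "fescom":
                candidates, trace = fescom_select(
                    train, clf_spec, config.threshold, config.folds, config.seed
                )
            else:
                candidates, trace = wrapper_select(
                    train, clf_spec, config.folds, config.seed
                )
            elapsed = time.perf_counter() - t0
            test_err = holdout_error(train, test, trace.selected, clf_spec)
            logger.info(
                "%s/%s: %d candidates, %d selected, cv=%.4f test=%.4f fits=%d",
                method,
                clf_spec.name,
                len(candidates),
                len(trace.selected),
                trace.final_error,
                test_err,
                trace.fit_count,
            )
            results.append(
                MethodResult(
                    method=method,
                    classifier=clf_spec.name,
                    selected=trace.selected,
                    selected_names=tuple(train.names[i] for i in trace.selected),
                    n_selected=len(trace.selected),
                    n_candidates=len(candidates),
                    train_cv_error=trace.final_error,
                    test_error=test_err,
                    fit_count=trace.fit_count,
                    wall_clock_s=elapsed,
                )
            )
    return ComparisonReport(results=tuple(results), config=config)
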