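"""FESCOM: hybrid filter-wrapper feature selection.

The filter stage scores every feature with a *significance index* built from
pairwise two-sample t tests: for feature ``k`` and every unordered class pair
``(i, j)`` a Welch t test on the per-class feature values yields a two-sided
P value ``P_k(i, j)``; the index is

    s_k = mean(P_k) + sd(P_k)

over the ``C(C-1)/2`` pairs.  A small mean says the feature separates class
pairs on average; a small SD says it does so uniformly — so smaller ``s``
means stronger discriminative capacity.  Features with ``s`` below a
threshold (0.05 by default) form the candidate set, ranked ascending.

The wrapper stage runs sequential forward selection (SFS) over the candidate
set: starting from the empty set, each step evaluates the cross-validated
error of the current set extended by each remaining candidate, keeps the best
extension, and stops when no extension strictly reduces the error.  The
wrapping component is a pluggable classifier (kNN, Gaussian naive Bayes, or a
random forest of 20 trees).  Search cost is accounted as the number of
classifier fits (folds per candidate evaluation), a hardware-independent
proxy for wall-clock search time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .errors import (
    DegenerateTestWarning,
    EmptyCandidateSetError,
    ParameterError,
    SampleSizeError,
    StratificationError,
    ValidationError,
)
from .features import FeatureTable

DEFAULT_THRESHOLD = 0.05
DEFAULT_FOLDS = 5


# ---------------------------------------------------------------------------
# Filter stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    """Two-sample Welch t test: statistic, degrees of freedom, two-sided P."""

    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sample t test with unpooled variances (Welch).

    ``t = (mean(x) - mean(y)) / sqrt(s_x^2/n + s_y^2/m)`` with sample standard
    deviations ``s_x, s_y`` and sizes ``n, m``; degrees of freedom by the
    Welch–Satterthwaite approximation; P is the two-sided tail probability.

    If both samples have zero variance, the result is degenerate: ``t = 0,
    p = 1`` for equal means (flagged with :class:`DegenerateTestWarning`),
    or an infinite statistic with ``p = 0`` for distinct means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise SampleSizeError(f"both samples need >= 2 values, got {n} and {m}")
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    dmean = float(np.mean(x) - np.mean(y))
    se2 = vx / n + vy / m
    if se2 == 0.0:
        if dmean == 0.0:
            warnings.warn(
                "degenerate t test: both samples constant and equal",
                DegenerateTestWarning,
                stacklevel=2,
            )
            return TTestResult(t=0.0, df=float(n + m - 2), p=1.0, degenerate=True)
        return TTestResult(
            t=float(np.sign(dmean)) * np.inf,
            df=float(n + m - 2),
            p=0.0,
            degenerate=True,
        )
    t = dmean / np.sqrt(se2)
    denom = (vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1)
    # denom can underflow to 0 for near-constant samples; fall back to pooled df
    df = se2**2 / denom if denom > 0 and np.isfinite(denom) else float(n + m - 2)
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def mean_plus_sd(pairwise_p: np.ndarray) -> float:
    """Default significance-index aggregator: mean + sample SD of the P values."""
    sd = float(np.std(pairwise_p, ddof=1)) if pairwise_p.size > 1 else 0.0
    return float(np.mean(pairwise_p)) + sd


def significance_index(
    pairwise_p: Sequence[float],
    aggregator: Callable[[np.ndarray], float] = mean_plus_sd,
) -> float:
    """Collapse a feature's pairwise P values into its significance index ``s``.

    The default aggregator is ``mean + SD`` (sample SD, divisor ``count - 1``,
    defined 0 for a single pair); alternatives can be swapped in via
    ``aggregator``.
    """
    p = np.asarray(pairwise_p, dtype=float)
    if p.size == 0:
        raise ValidationError("pairwise_p must contain at least one value")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("P values must lie in [0, 1]")
    return aggregator(p)


@dataclass(frozen=True)
class SignificanceRecord:
    """Per-feature filter-stage summary: pairwise P values, their mean/SD, s, rank."""

    feature_index: int
    feature_name: str
    pairwise_p: tuple[float, ...]
    mean_p: float
    sd_p: float
    s: float
    rank: int


def class_pairs(classes: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered class pairs ``(i, j)`` with ``i`` before ``j`` in the class order."""
    return [
        (classes[i], classes[j])
        for i in range(len(classes))
        for j in range(i + 1, len(classes))
    ]


def rank_features(
    table: FeatureTable,
    aggregator: Callable[[np.ndarray], float] = mean_plus_sd,
) -> list[SignificanceRecord]:
    """Score and rank every feature by its significance index, ascending.

    For each feature, a Welch t test is run on every unordered class pair;
    rank 1 is the most significant (smallest ``s``).  Ties in ``s`` are broken
    by ascending feature index, so the ranking is a deterministic permutation.
    """
    labels = np.asarray(table.labels)
    classes = table.class_set
    for cls in classes:
        if int(np.sum(labels == cls)) < 2:
            raise SampleSizeError(f"class '{cls}' has fewer than 2 samples")
    masks = {cls: labels == cls for cls in classes}
    pairs = class_pairs(classes)

    scored = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateTestWarning)
        for k in range(table.n_features):
            col = table.matrix[:, k]
            pvals = np.array(
                [welch_t_test(col[masks[a]], col[masks[b]]).p for a, b in pairs]
            )
            sd = float(np.std(pvals, ddof=1)) if pvals.size > 1 else 0.0
            scored.append(
                {
                    "feature_index": k,
                    "feature_name": table.names[k],
                    "pairwise_p": tuple(float(p) for p in pvals),
                    "mean_p": float(np.mean(pvals)),
                    "sd_p": sd,
                    "s": significance_index(pvals, aggregator),
                }
            )

    order = sorted(range(len(scored)), key=lambda k: (scored[k]["s"], k))
    records = [None] * len(scored)
    for rank0, k in enumerate(order):
        records[k] = SignificanceRecord(rank=rank0 + 1, **scored[k])
    return [records[k] for k in order]


@dataclass(frozen=True)
class CandidateSet:
    """Filter-stage output: feature indices with ``s < threshold``, ascending in ``s``."""

    ordered_features: tuple[int, ...]
    threshold: float
    s_values: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.ordered_features)


def build_candidate_set(
    records: Sequence[SignificanceRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> CandidateSet:
    """Keep features with significance index strictly below ``threshold``.

    Raises :class:`EmptyCandidateSetError` when no feature qualifies — the
    remedy is a larger threshold, trading search time for coverage.
    """
    if not (0 < threshold <= 1):
        raise ParameterError(f"threshold must lie in (0, 1], got {threshold}")
    kept = sorted(
        (r for r in records if r.s < threshold),
        key=lambda r: (r.s, r.feature_index),
    )
    if not kept:
        raise EmptyCandidateSetError(
            f"no feature has significance index < {threshold}; "
            "raise the threshold to admit candidates"
        )
    return CandidateSet(
        ordered_features=tuple(r.feature_index for r in kept),
        threshold=threshold,
        s_values=tuple(r.s for r in kept),
    )


def significance_report(records: Sequence[SignificanceRecord]) -> pd.DataFrame:
    """Tabular report (feature_name, mean_p, sd_p, s, rank), sorted by rank."""
    frame = pd.DataFrame(
        [
            {
                "feature_name": r.feature_name,
                "mean_p": r.mean_p,
                "sd_p": r.sd_p,
                "s": r.s,
                "rank": r.rank,
            }
            for r in records
        ]
    )
    return frame.sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Wrapper stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier wraps the search, with its hyperparameters and seed.

    ``name`` is one of ``knn`` (Euclidean k-nearest neighbours, default
    ``k=1``), ``nb`` (Gaussian naive Bayes — per-feature Gaussian likelihoods
    for these continuous features), or ``rf`` (random forest, default 20
    trees, bootstraps seeded from ``seed``).
    """

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("knn", "nb", "rf"):
            raise ParameterError(f"unknown classifier '{self.name}' (use knn, nb or rf)")
        if self.name == "knn" and self.hyperparameters.get("k", 1) < 1:
            raise ParameterError("knn requires k >= 1")
        if self.name == "rf" and self.hyperparameters.get("n_trees", 20) < 1:
            raise ParameterError("rf requires n_trees >= 1")

    def build(self):
        """Instantiate a fresh (unfitted) scikit-learn estimator."""
        if self.name == "knn":
            return KNeighborsClassifier(
                n_neighbors=self.hyperparameters.get("k", 1), metric="euclidean"
            )
        if self.name == "nb":
            return GaussianNB()
        return RandomForestClassifier(
            n_estimators=self.hyperparameters.get("n_trees", 20),
            random_state=self.seed,
        )


def cv_error_rate(
    table: FeatureTable,
    spec: ClassifierSpec,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> float:
    """Stratified k-fold cross-validated classification error rate.

    The error is the mean over folds of (misclassified held-out instances /
    held-out instances); fold assignment is stratified by class and fully
    determined by ``seed``.
    """
    if folds < 2:
        raise ParameterError(f"folds must be >= 2, got {folds}")
    labels = np.asarray(table.labels)
    for cls in table.class_set:
        count = int(np.sum(labels == cls))
        if count < folds:
            raise StratificationError(
                f"class '{cls}' has {count} samples, fewer than {folds} folds"
            )
    X = table.matrix
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = []
    for train_idx, test_idx in skf.split(X, labels):
        clf = spec.build()
        clf.fit(X[train_idx], labels[train_idx])
        pred = clf.predict(X[test_idx])
        errors.append(float(np.mean(pred != labels[test_idx])))
    return float(np.mean(errors))


@dataclass(frozen=True)
class SFSEvaluation:
    """One candidate evaluation inside the greedy search."""

    step: int
    candidate: int
    cv_error: float
    accepted: bool
    fit_count: int  # cumulative classifier fits after this evaluation


@dataclass(frozen=True)
class SFSTrace:
    """Complete record of a sequential-forward-selection run."""

    evaluations: tuple[SFSEvaluation, ...]
    selected: tuple[int, ...]
    accepted_errors: tuple[float, ...]
    final_error: float
    fit_count: int
    folds: int
    seed: int

    def to_jsonl(self) -> str:
        """One JSON record per candidate evaluation."""
        lines = [
            json.dumps(
                {
                    "step": e.step,
                    "candidate": e.candidate,
                    "cv_error": e.cv_error,
                    "accepted": e.accepted,
                    "fit_count": e.fit_count,
                }
            )
            for e in self.evaluations
        ]
        return "\n".join(lines)


def sfs(
    table: FeatureTable,
    candidates: CandidateSet,
    spec: ClassifierSpec,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> SFSTrace:
    """Sequential forward selection over the candidate set.

    Each step evaluates the CV error of the current subset extended by every
    remaining candidate (in candidate order, i.e. ascending significance
    index), accepts the extension with the strictly lowest error — ties go to
    the earlier candidate — and stops as soon as the best extension fails to
    strictly reduce the current error.  Every candidate evaluation costs
    ``folds`` classifier fits, accumulated in ``fit_count``.
    """
    if len(candidates) == 0:
        raise ValidationError("candidate set is empty")
    remaining = list(candidates.ordered_features)
    selected: list[int] = []
    accepted_errors: list[float] = []
    evaluations: list[SFSEvaluation] = []
    current_error = np.inf
    fit_count = 0
    step = 0
    while remaining:
        best_candidate = None
        best_error = np.inf
        step_evals = []
        for cand in remaining:
            err = cv_error_rate(table.restrict(selected + [cand]), spec, folds, seed)
            fit_count += folds
            step_evals.append((cand, err))
            if err < best_error:  # strict: ties keep the earlier (smaller-s) candidate
                best_error = err
                best_candidate = cand
        improved = best_error < current_error
        for cand, err in step_evals:
            evaluations.append(
                SFSEvaluation(
                    step=step,
                    candidate=cand,
                    cv_error=err,
                    accepted=improved and cand == best_candidate,
                    fit_count=folds * (len(evaluations) + 1),
                )
            )
        if not improved:
            break
        selected.append(best_candidate)
        remaining.remove(best_candidate)
        accepted_errors.append(best_error)
        current_error = best_error
        step += 1
        if current_error == 0.0:
            break  # zero error cannot be improved further
    return SFSTrace(
        evaluations=tuple(evaluations),
        selected=tuple(selected),
        accepted_errors=tuple(accepted_errors),
        final_error=float(current_error) if selected else np.inf,
        fit_count=fit_count,
        folds=folds,
        seed=seed,
    )


def fescom_select(
    table: FeatureTable,
    spec: ClassifierSpec,
    threshold: float = DEFAULT_THRESHOLD,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    aggregator: Callable[[np.ndarray], float] = mean_plus_sd,
) -> tuple[CandidateSet, SFSTrace]:
    """The full hybrid pipeline: rank -> threshold -> sequential forward selection.

    Deterministic given ``seed``: the same table, classifier spec, threshold
    and seed always yield the same candidate set and trace.
    """
    records = rank_features(table, aggregator)
    candidates = build_candidate_set(records, threshold)
    trace = sfs(table, candidates, spec, folds, seed)
    return candidates, trace


def wrapper_select(
    table: FeatureTable,
    spec: ClassifierSpec,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    aggregator: Callable[[np.ndarray], float] = mean_plus_sd,
) -> tuple[CandidateSet, SFSTrace]:
    """The plain-wrapper baseline: SFS over *all* features, no filter stage.

    Candidates are still ordered by ascending significance index so that
    tie-breaking matches the hybrid method; with a threshold that passes every
    feature, :func:`fescom_select` and this baseline coincide.
    """
    records = rank_features(table, aggregator)
    ordered = sorted(records, key=lambda r: (r.s, r.feature_index))
    candidates = CandidateSet(
        ordered_features=tuple(r.feature_index for r in ordered),
        threshold=1.0,
        s_values=tuple(r.s for r in ordered),
    )
    trace = sfs(table, candidates, spec, folds, seed)
    return candidates, trace
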