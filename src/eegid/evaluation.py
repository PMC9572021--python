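"""Evaluation protocol: stratified 80/20 split, 5-fold cross-validation,
one-vs-rest multiclass metrics, the 104-case channel-reduction study grid,
and the final retrain-and-test step.

Metric definitions (all reported as percentages):

* average accuracy — mean over classes of one-vs-rest binary accuracy
  ``(TP_k + TN_k) / (TP_k + TN_k + FP_k + FN_k)``;
* macro precision / recall — per-class precision and recall averaged with
  equal class weight;
* macro F1 — harmonic mean of macro precision and macro recall (not the
  mean of per-class F1 scores);
* plain accuracy — trace over total, reported alongside as a diagnostic
  because for K classes the one-vs-rest average accuracy is systematically
  higher than trace accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import DataShapeError, ScenarioError, SplitError
from .model import ModelConfig, TrainConfig, TrainedModel, build_model, predict, train
from .preprocess import (
    RegionSelection,
    SegmentSet,
    apply_normalization,
    fit_normalization,
    reduce_and_rereference,
)
from .synthetic import TASKS

INDIVIDUAL_SCENARIOS: tuple[str, ...] = ("rest", "level1", "level2", "level3")
FUSION_SCENARIOS: tuple[str, ...] = ("game_fusion", "all_fusion")
SCENARIOS: tuple[str, ...] = INDIVIDUAL_SCENARIOS + FUSION_SCENARIOS

#: region pairs examined for the individual-task scenarios
REGION_PAIRS: tuple[tuple[str, str], ...] = (
    ("F", "C"), ("F", "O"), ("F", "P"), ("C", "O"), ("C", "P"), ("P", "O"),
)
#: the three pairs retained for the fusion scenarios
FUSION_REGION_PAIRS: tuple[tuple[str, str], ...] = (("F", "P"), ("C", "P"), ("C", "O"))
SINGLE_REGIONS: tuple[tuple[str], ...] = (("F",), ("C",), ("P",), ("O",))

METRIC_NAMES = ("average_accuracy", "macro_precision", "macro_recall", "macro_f1", "plain_accuracy")


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DataShapeError(f"confusion matrix must be square, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise DataShapeError("confusion matrix counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class ``k``."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum()) - tp
        fn = int(self.counts[k, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass(frozen=True)
class MetricsReport:
    """The four study metrics plus diagnostic plain accuracy, in percent."""

    average_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    plain_accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion(y_true, y_pred, K: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise DataShapeError(f"label length mismatch: {y_true.shape} vs {y_pred.shape}")
    if len(y_true) and (
        y_true.min() < 0 or y_true.max() >= K or y_pred.min() < 0 or y_pred.max() >= K
    ):
        raise DataShapeError(f"labels outside [0, {K})")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Evaluate the one-vs-rest metric family on a confusion matrix.

    Per-class precision/recall terms with a zero denominator contribute 0 to
    the macro average and trigger a warning.
    """
    total = cm.total
    if total == 0:
        raise DataShapeError("cannot compute metrics on an empty confusion matrix")
    K = cm.n_classes
    acc_terms, prec_terms, rec_terms = [], [], []
    degenerate = []
    for k in range(K):
        tp, fp, fn, tn = cm.one_vs_rest(k)
        acc_terms.append((tp + tn) / total)
        if tp + fp == 0:
            prec_terms.append(0.0)
            degenerate.append(("precision", k))
        else:
            prec_terms.append(tp / (tp + fp))
        if tp + fn == 0:
            rec_terms.append(0.0)
            degenerate.append(("recall", k))
        else:
            rec_terms.append(tp / (tp + fn))
    if degenerate:
        warnings.warn(
            f"zero-denominator terms contributed 0 to macro averages: {degenerate}",
            stacklevel=2,
        )
    avg_acc = 100.0 * float(np.mean(acc_terms))
    macro_p = 100.0 * float(np.mean(prec_terms))
    macro_r = 100.0 * float(np.mean(rec_terms))
    macro_f1 = 0.0 if macro_p + macro_r == 0 else 2 * macro_p * macro_r / (macro_p + macro_r)
    plain = 100.0 * float(np.trace(cm.counts)) / total
    return MetricsReport(avg_acc, macro_p, macro_r, macro_f1, plain)


# ---------------------------------------------------------------------------
# splitting


def _warn_small_classes(labels: np.ndarray, minimum: int = 5) -> None:
    values, counts = np.unique(labels, return_counts=True)
    small = values[counts < minimum]
    if small.size:
        warnings.warn(
            f"subjects {small.tolist()} have fewer than {minimum} segments; "
            "stratification may be degenerate",
            stacklevel=3,
        )


def split_dataset(
    s: SegmentSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SegmentSet, SegmentSet]:
    """Stratified-by-subject train/test split, deterministic under ``seed``."""
    if not (0.0 < train_fraction < 1.0):
        raise SplitError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(s) < 2:
        raise SplitError("need at least 2 segments to split")
    _warn_small_classes(s.subject_labels)
    idx = np.arange(len(s))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=s.subject_labels,
        random_state=seed,
        shuffle=True,
    )
    return s.subset(np.sort(train_idx)), s.subset(np.sort(test_idx))


def split_dataset_by_record(
    s: SegmentSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SegmentSet, SegmentSet]:
    """Leakage-averse alternative: whole contiguous window blocks of each
    source recording go to one side, so no 500-sample overlap spans the
    boundary.  The last ``1 - train_fraction`` of each recording's windows
    becomes test data."""
    if not (0.0 < train_fraction < 1.0):
        raise SplitError(f"train_fraction must be in (0, 1), got {train_fraction}")
    train_mask = np.zeros(len(s), dtype=bool)
    for rid in np.unique(s.record_ids):
        rows = np.flatnonzero(s.record_ids == rid)
        order = rows[np.argsort(s.start_samples[rows])]
        n_train = int(round(train_fraction * len(order)))
        train_mask[order[:n_train]] = True
    return s.subset(np.flatnonzero(train_mask)), s.subset(np.flatnonzero(~train_mask))


def kfold_partition(
    train_set: SegmentSet, k: int = 5, seed: int = 0
) -> list[tuple[SegmentSet, SegmentSet]]:
    """Stratified k-fold: k disjoint, exhaustive validation folds of equal
    size (+/-1), each paired with the remaining training segments."""
    if k < 2:
        raise SplitError(f"k must be >= 2, got {k}")
    if k > len(train_set):
        raise SplitError(f"k={k} exceeds {len(train_set)} segments")
    _warn_small_classes(train_set.subject_labels, minimum=k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pairs = []
    for tr_idx, va_idx in skf.split(np.zeros(len(train_set)), train_set.subject_labels):
        pairs.append((train_set.subset(tr_idx), train_set.subset(va_idx)))
    return pairs


def shuffle_labels(s: SegmentSet, seed: int = 0) -> SegmentSet:
    """Permutation control: same data, randomly permuted subject labels."""
    rng = np.random.default_rng(seed)
    out = s.subset(np.arange(len(s)))
    out.subject_labels = rng.permutation(out.subject_labels)
    return out


# ---------------------------------------------------------------------------
# study grid


@dataclass(frozen=True)
class StudyCase:
    """One (variant, scenario, channel subset) cell of the study grid."""

    variant: str
    scenario: str
    regions: RegionSelection

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ScenarioError(f"unknown scenario {self.scenario!r}")
        n = len(self.regions.regions)
        region_set = set(self.regions.regions)
        if self.scenario in FUSION_SCENARIOS:
            allowed = [set(p) for p in FUSION_REGION_PAIRS]
            if n != 4 and region_set not in allowed:
                raise ScenarioError(
                    f"fusion scenarios allow the full montage or pairs "
                    f"{FUSION_REGION_PAIRS}, got {self.regions.regions}"
                )
        elif n not in (1, 2, 4):
            raise ScenarioError(f"individual scenarios allow 1, 2 or 4 regions, got {n}")

    def label(self) -> str:
        return f"{self.variant}/{self.scenario}/{self.regions.label()}"


def enumerate_cases(variants: tuple[str, ...] = ("A", "B")) -> list[StudyCase]:
    """The full study grid in deterministic (variant, scenario, subset) order.

    Per variant: each individual task crossed with the full montage, the six
    region pairs, and the four single regions; each fusion scenario crossed
    with the full montage and the three retained pairs.  Both variants
    together give 2 x [4 x (1+6+4) + 2 x (1+3)] = 104 cases.
    """
    cases: list[StudyCase] = []
    for variant in variants:
        for scenario in INDIVIDUAL_SCENARIOS:
            subsets = [tuple("FCPO")] + list(REGION_PAIRS) + list(SINGLE_REGIONS)
            for subset in subsets:
                cases.append(StudyCase(variant, scenario, RegionSelection(subset)))
        for scenario in FUSION_SCENARIOS:
            for subset in [tuple("FCPO")] + list(FUSION_REGION_PAIRS):
                cases.append(StudyCase(variant, scenario, RegionSelection(subset)))
    return cases


def build_scenario(segments: SegmentSet, scenario: str) -> SegmentSet:
    """Select the segments belonging to a task scenario.

    ``rest``/``level1``/``level2``/``level3`` keep one task; ``game_fusion``
    concatenates the three game levels; ``all_fusion`` keeps everything.
    Provenance is retained unchanged.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}")
    present = set(segments.task_ids.tolist())
    needed = (
        {scenario}
        if scenario in INDIVIDUAL_SCENARIOS
        else set(TASKS[1:]) if scenario == "game_fusion" else set(TASKS)
    )
    missing = needed - present
    if missing:
        raise ScenarioError(f"scenario {scenario!r} needs tasks {sorted(missing)} not present")
    mask = np.isin(segments.task_ids.astype(str), sorted(needed))
    return segments.subset(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# cross-validation driver


@dataclass
class CVResult:
    """Per-fold metrics plus mean and sample SD (ddof=1) across folds."""

    case: StudyCase
    per_fold: list[MetricsReport]

    @property
    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([getattr(r, m) for r in self.per_fold])) for m in METRIC_NAMES
        }

    @property
    def sd(self) -> dict[str, float]:
        return {
            m: float(np.std([getattr(r, m) for r in self.per_fold], ddof=1))
            for m in METRIC_NAMES
        }


def _prepare_case_pool(
    case: StudyCase,
    segments: SegmentSet,
    train_fraction: float,
    split_seed: int,
    split_by_record: bool,
) -> tuple[SegmentSet, SegmentSet]:
    """Scenario selection, channel reduction + CAR, then the 80/20 split."""
    scen = build_scenario(segments, case.scenario)
    reduced = reduce_and_rereference(scen, case.regions)
    splitter = split_dataset_by_record if split_by_record else split_dataset
    return splitter(reduced, train_fraction, seed=split_seed)


def run_cv_case(
    case: StudyCase,
    segments: SegmentSet,
    tc: TrainConfig = TrainConfig(),
    k: int = 5,
    train_fraction: float = 0.8,
    split_seed: int = 0,
    model_seed: int = 0,
    split_by_record: bool = False,
) -> CVResult:
    """Train and evaluate one study case under stratified k-fold CV.

    ``segments`` is the full-montage, filtered + segmented dataset for the
    whole cohort; channel reduction, CAR, the 80/20 split, per-fold
    normalization, training, and metric computation all happen here.  The
    held-out 20% test partition is never touched.
    """
    pool, _test = _prepare_case_pool(case, segments, train_fraction, split_seed, split_by_record)
    n_classes = int(np.max(segments.subject_labels)) + 1
    reports: list[MetricsReport] = []
    for fold_i, (tr, va) in enumerate(kfold_partition(pool, k=k, seed=split_seed)):
        stats = fit_normalization(tr)
        tr_n = apply_normalization(tr, stats)
        va_n = apply_normalization(va, stats)
        cfg = ModelConfig(case.variant, n_channels=tr_n.n_channels, n_classes=n_classes)
        net = build_model(cfg, seed=model_seed + fold_i)
        trained = train(net, tr_n, va_n, tc)
        y_pred, _ = predict(trained, va_n)
        reports.append(compute_metrics(confusion(va_n.subject_labels, y_pred, n_classes)))
    return CVResult(case=case, per_fold=reports)


def finalize(
    case: StudyCase,
    segments: SegmentSet,
    tc: TrainConfig = TrainConfig(),
    train_fraction: float = 0.8,
    internal_val_fraction: float = 0.1,
    split_seed: int = 0,
    model_seed: int = 0,
    split_by_record: bool = False,
) -> tuple[MetricsReport, TrainedModel]:
    """Retrain on the full training pool and evaluate once on the 20% test
    partition.

    Checkpoint selection needs a validation signal, so 10% of the pool is
    held out internally; normalization statistics are fitted on the
    remaining 90% actually used for weight updates.
    """
    pool, test = _prepare_case_pool(case, segments, train_fraction, split_seed, split_by_record)
    if len(np.unique(test.subject_labels)) < 2:
        raise SplitError("test partition covers fewer than 2 subjects; refusing to evaluate")
    # provenance audit: no test segment may appear in the training pool
    overlap = set(pool.provenance()) & set(test.provenance())
    if overlap:
        raise SplitError(f"{len(overlap)} segments leak between pool and test")
    inner_tr, inner_va = split_dataset(pool, 1.0 - internal_val_fraction, seed=split_seed)
    stats = fit_normalization(inner_tr)
    tr_n = apply_normalization(inner_tr, stats)
    va_n = apply_normalization(inner_va, stats)
    te_n = apply_normalization(test, stats)
    n_classes = int(np.max(segments.subject_labels)) + 1
    cfg = ModelConfig(case.variant, n_channels=tr_n.n_channels, n_classes=n_classes)
    trained = train(build_model(cfg, seed=model_seed), tr_n, va_n, tc)
    y_pred, _ = predict(trained, te_n)
    report = compute_metrics(confusion(te_n.subject_labels, y_pred, n_classes))
    return report, trained


# ---------------------------------------------------------------------------
# tidy export


def results_table(results: list[CVResult]):
    """One row per case x fold plus aggregate mean/sd rows, as a DataFrame."""
    import pandas as pd

    rows = []
    for res in results:
        base = {
            "variant": res.case.variant,
            "scenario": res.case.scenario,
            "regions": res.case.regions.label(),
        }
        for i, rep in enumerate(res.per_fold):
            rows.append({**base, "fold": str(i), **rep.as_dict()})
        rows.append({**base, "fold": "mean", **res.mean})
        rows.append({**base, "fold": "sd", **res.sd})
    return pd.DataFrame(rows)
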