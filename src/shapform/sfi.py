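"""Repeated stratified k-fold cross-validation with top-k attribution counts.

Each repetition splits the cohort into k stratified folds; every fold-model
is fit on the out-of-fold rows, attributions are computed (held-out rows by
default), and the top-k items by global importance are recorded.  The count
of fold-model top-k appearances per item is the SFI statistic; its ceiling
is n_reps * n_folds (every fold-model of every repetition contributes one
top-k set, so with 1,000 repetitions of 4 folds a ubiquitous item reaches
4,000).

Reproducibility contract: repetition ``r`` uses ``seed + r`` for its fold
shuffle, so runs are deterministic given the master seed and config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .instrument import ItemBank, ValidationError
from .metrics import MetricsReport, SingleClassMetricError, compute_metrics
from .models import FittedLinearModel, SingleClassError, make_model
from .shapley import global_importance, kernel_shap_matrix, linear_shapley

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    n_folds: int = 4
    n_reps: int = 1000
    top_k: int = 20
    seed: int = 0
    model_spec: dict = field(default_factory=lambda: {"kind": "logistic", "l2_penalty": 1.0})
    shap_rows: str = "test_fold"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.shap_rows not in ("test_fold", "train_fold"):
            raise ValidationError("shap_rows must be 'test_fold' or 'train_fold'")


@dataclass
class FoldAssignment:
    fold_of: np.ndarray   # respondent index -> fold index
    rep_index: int = 0

    def train_mask(self, fold: int) -> np.ndarray:
        return self.fold_of != fold

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold


@dataclass
class SFITable:
    counts: dict[str, int]
    n_fold_models: int
    outcome_label: str = "SI"

    def __post_init__(self) -> None:
        bad = [i for i, c in self.counts.items() if not 0 <= c <= self.n_fold_models]
        if bad:
            raise ValidationError(f"SFI out of [0, n_fold_models] for {bad}")

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RankingRow:
    rank: int
    item_id: str
    sfi: int
    criterion: str


@dataclass
class RankingTable:
    rows: list[RankingRow]
    outcome_label: str = "SI"
    tie_rule: str = "bank_order"

    def __post_init__(self) -> None:
        sfis = [r.sfi for r in self.rows]
        if any(a < b for a, b in zip(sfis, sfis[1:])):
            raise ValidationError("SFI must be non-increasing in rank")
        if [r.rank for r in self.rows] != list(range(1, len(self.rows) + 1)):
            raise ValidationError("ranks must be 1..p contiguous")

    def item_ids(self, top_n: int | None = None) -> list[str]:
        rows = self.rows if top_n is None else self.rows[:top_n]
        return [r.item_id for r in rows]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": [r.rank for r in self.rows],
                "item_id": [r.item_id for r in self.rows],
                "sfi": [r.sfi for r in self.rows],
                "criterion": [r.criterion for r in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, outcome_label: str = "SI") -> "RankingTable":
        import pandas as pd

        df = pd.read_csv(path)
        rows = [
            RankingRow(int(r["rank"]), str(r["item_id"]), int(r["sfi"]), str(r["criterion"]))
            for _, r in df.iterrows()
        ]
        return cls(rows=rows, outcome_label=outcome_label)


def stratified_kfold_indices(y, n_folds: int, seed: int, rep_index: int = 0) -> FoldAssignment:
    """Shuffle each class independently, then deal round-robin into folds.

    Guarantees per-class fold sizes differ by at most one, so every fold's
    case proportion tracks the global one as closely as integer counts allow.
    """
    y = np.asarray(y).ravel()
    fold_of = np.empty(y.size, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < n_folds:
            raise ValidationError(
                f"class {cls} has {idx.size} members, fewer than {n_folds} folds"
            )
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % n_folds
    return FoldAssignment(fold_of=fold_of, rep_index=rep_index)


def _fit_and_attribute(X, y, item_ids, assignment, fold, config):
    train = assignment.train_mask(fold)
    test = assignment.test_mask(fold)
    model = make_model(config.model_spec)
    if hasattr(model, "l2_penalty"):  # deferred logistic spec
        fitted = model.fit(X[train], y[train], item_ids=item_ids)
    else:
        fitted = model.fit(X[train], y[train])
    rows = X[test] if config.shap_rows == "test_fold" else X[train]
    if isinstance(fitted, FittedLinearModel):
        shap = linear_shapley(fitted, rows)
    else:
        background = X[train][: min(100, train.sum())]
        shap = kernel_shap_matrix(
            fitted.predict_margin, rows, background, item_ids=item_ids,
            seed=config.seed,
        )
    return fitted, shap, test


def run_fold_model(X, y, item_ids, assignment: FoldAssignment, fold: int,
                   config: CVConfig) -> list[str]:
    """Fit one fold-model and return its ordered top-k item ids.

    Ranking is by descending global importance with ties broken by bank
    (column) order; ``top_k`` is capped at the number of items.
    """
    _, shap, _ = _fit_and_attribute(X, y, item_ids, assignment, fold, config)
    importance = global_importance(shap)
    return top_k_items(importance, item_ids, config.top_k)


def top_k_items(importance: np.ndarray, item_ids, top_k: int) -> list[str]:
    k = min(top_k, len(item_ids))
    order = np.argsort(-importance, kind="stable")  # stable => bank-order ties
    return [item_ids[j] for j in order[:k]]


def accumulate_sfi(fold_results, bank: ItemBank, outcome_label: str = "SI") -> SFITable:
    """Count, per item, the fold-model top-k sets it appears in."""
    fold_results = list(fold_results)
    if not fold_results:
        raise ValidationError("no fold-model results to accumulate")
    counts = {item_id: 0 for item_id in bank.item_ids}
    for result in fold_results:
        for item_id in result:
            if item_id not in counts:
                raise ValidationError(f"unknown item id {item_id!r} in fold result")
            counts[item_id] += 1
    return SFITable(counts=counts, n_fold_models=len(fold_results),
                    outcome_label=outcome_label)


def rank_items(sfi: SFITable, bank: ItemBank) -> RankingTable:
    """Sort by SFI descending, ties by bank order (stable)."""
    ordered = sorted(
        sfi.counts.items(), key=lambda kv: (-kv[1], bank.position(kv[0]))
    )
    rows = [
        RankingRow(rank=r + 1, item_id=item_id, sfi=count,
                   criterion=bank.criterion_of(item_id))
        for r, (item_id, count) in enumerate(ordered)
    ]
    return RankingTable(rows=rows, outcome_label=sfi.outcome_label)


@dataclass
class CVResult:
    sfi_table: SFITable
    ranking: RankingTable
    metrics_mean: MetricsReport
    n_failed_fold_models: int = 0


def run_repeated_cv(X, y, bank: ItemBank, config: CVConfig,
                    outcome_label: str = "SI") -> CVResult:
    """The full procedure: R repetitions of stratified k-fold CV.

    Per fold-model: fit, attribute, store the top-k item set, and score the
    held-out rows.  Fold-models whose training labels degenerate to a single
    class are dropped (logged), shrinking the SFI denominator rather than
    aborting the run.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    item_ids = bank.item_ids
    if X.shape[1] != len(item_ids):
        raise ValidationError("feature matrix does not align with bank")

    results: list[list[str]] = []
    metric_rows = []
    n_failed = 0
    for rep in range(config.n_reps):
        assignment = stratified_kfold_indices(
            y, config.n_folds, seed=config.seed + rep, rep_index=rep
        )
        for fold in range(config.n_folds):
            try:
                fitted, shap, test = _fit_and_attribute(
                    X, y, item_ids, assignment, fold, config
                )
            except SingleClassError as exc:
                n_failed += 1
                logger.warning("rep %d fold %d dropped: %s", rep, fold, exc)
                continue
            importance = global_importance(shap)
            results.append(top_k_items(importance, item_ids, config.top_k))
            try:
                metric_rows.append(
                    compute_metrics(
                        y[test], fitted.predict_proba(X[test]),
                        threshold=config.threshold,
                    )
                )
            except SingleClassMetricError:
                pass  # degenerate test fold: skip its metric row only

    sfi_table = accumulate_sfi(results, bank, outcome_label=outcome_label)
    if len(item_ids) > config.top_k:
        total = sfi_table.total()
        expected = min(config.top_k, len(item_ids)) * sfi_table.n_fold_models
        assert total == expected, (
            f"SFI conservation violated: {total} != {expected}"
        )
    ranking = rank_items(sfi_table, bank)
    metrics_mean = _mean_metrics(metric_rows, config.threshold)
    return CVResult(sfi_table=sfi_table, ranking=ranking,
                    metrics_mean=metrics_mean, n_failed_fold_models=n_failed)


def _mean_metrics(rows: list[MetricsReport], threshold: float) -> MetricsReport:
    if not rows:
        return MetricsReport(*([float("nan")] * 6), threshold=threshold)
    fields = ("accuracy", "auroc", "precision", "recall",
              "balanced_accuracy", "auprc")
    means = {f: float(np.mean([getattr(r, f) for r in rows])) for f in fields}
    return MetricsReport(threshold=threshold, **means)
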