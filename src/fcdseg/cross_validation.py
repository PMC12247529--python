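"""Five-fold cross-validation harness with a pluggable segmenter.

The harness partitions a case collection into k balanced folds, trains the
configured segmenter on the out-of-fold cases, records a per-epoch
validation pseudo-Dice trace for each fold, and summarizes the study as a
fold table ("mean pseudo dice" and "pseudo dice at final epoch" per fold)
with descriptive statistics, 95% confidence intervals and the paired t-test
between the two columns.

Per-epoch trace values are the mean over validation cases of the pseudo-
Dice at that epoch; the per-case scores at the final epoch are persisted
alongside, so both granularities (per-sample and per-epoch) are available.
Everything is reproducible from (seed, config).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cases import Case, CaseCollection
from .exceptions import InsufficientDataError, UndefinedMetricError, ZeroVarianceError
from .io import read_mask, read_volume, write_volume
from .metrics import MetricConfig, ScoreTrace, mean_pds, moving_average_pds, pseudo_dice, dice
from .preprocess import PreprocessConfig, preprocess_case
from .segmenters import make_segmenter
from .slices import select_case
from .stats import FoldSummary, PairedTResult, StatReport, describe, paired_t, round_half_up

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "FoldResult",
    "StudySummary",
    "make_folds",
    "prepare_cases",
    "run_fold",
    "run_study",
    "summarize_study",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Balanced assignment of case ids to folds 1..k, reproducible from seed."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignments.items() if f == fold]


@dataclass
class TrainConfig:
    """Training-schedule parameters handed to the segmenter.

    Defaults mirror the full-scale schedule (100 epochs, batch size 4,
    SGD with learning rate 0.01, momentum 0.99, Nesterov); the default
    segmenter is the deterministic quantile-threshold baseline.
    """

    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 0.01
    momentum: float = 0.99
    nesterov: bool = True
    segmenter: str = "quantile_threshold"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FoldResult:
    """One fold's per-epoch trace plus its two headline scores."""

    fold_id: int
    trace: ScoreTrace
    case_ids: list[str]
    case_dice: np.ndarray
    case_pds: np.ndarray
    summary: FoldSummary = field(init=False)

    def __post_init__(self) -> None:
        self.case_dice = np.asarray(self.case_dice, dtype=float)
        self.case_pds = np.asarray(self.case_pds, dtype=float)
        self.summary = FoldSummary(
            fold_id=self.fold_id,
            mean_pds=mean_pds(self.trace),
            pds_at_final=float(self.trace.values[-1]),
        )

    def save(self, out_dir) -> Path:
        """Persist the per-epoch trace (and moving average) as a TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        n = len(self.trace)
        w = MetricConfig().window
        frame = pd.DataFrame(
            {
                "fold": self.fold_id,
                "epoch": np.arange(1, n + 1),
                "pseudo_dice": self.trace.values,
                "moving_average": [
                    moving_average_pds(self.trace, min(w, t), t) for t in range(1, n + 1)
                ],
            }
        )
        path = out_dir / f"fold_{self.fold_id}_trace.tsv"
        frame.to_csv(path, sep="\t", index=False)
        return path


def make_folds(cases: CaseCollection, k: int = 5, seed: int = 0) -> FoldPlan:
    """Random balanced fold assignment (fold sizes differ by at most one)."""
    n = len(cases)
    if n < k:
        raise ValueError(f"cannot split {n} cases into {k} folds")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(sorted(cases.case_ids))
    assignments = {str(cid): (i % k) + 1 for i, cid in enumerate(order)}
    return FoldPlan(k=k, assignments=assignments, seed=int(seed))


def prepare_cases(
    collection: CaseCollection,
    out_dir,
    preprocess_cfg: PreprocessConfig | None = None,
    select: bool = True,
    criterion: str = "lesion_area",
    k_slices: int = 5,
) -> CaseCollection:
    """Preprocess (and optionally slice-select) every case, writing the
    processed NIfTI pairs, a manifest, and a per-case slice-score report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = preprocess_cfg or PreprocessConfig()
    cases, reports = [], []
    for case in collection:
        vol = read_volume(case.image)
        mask = read_mask(case.mask, vol)
        vol, mask = preprocess_case(vol, mask, cfg)
        if select:
            vol, mask, ranking = select_case(vol, mask, criterion=criterion, k=k_slices)
            rep = ranking.to_frame()
            rep.insert(0, "case_id", case.case_id)
            reports.append(rep)
        img_path = out_dir / f"{case.case_id}_flair.nii.gz"
        msk_path = out_dir / f"{case.case_id}_mask.nii.gz"
        write_volume(vol, img_path)
        write_volume(mask, msk_path)
        cases.append(Case(case.case_id, img_path, msk_path))
        log.info("prepared %s: shape %s", case.case_id, vol.shape)
    prepared = CaseCollection(cases=tuple(cases), provenance=collection.provenance)
    prepared.to_manifest(out_dir / "manifest.tsv")
    if reports:
        pd.concat(reports, ignore_index=True).to_csv(
            out_dir / "slice_report.tsv", sep="\t", index=False
        )
    return prepared


def _load(collection: CaseCollection, ids: list[str]):
    by_id = {c.case_id: c for c in collection}
    images, masks = [], []
    for cid in ids:
        vol = read_volume(by_id[cid].image)
        masks.append(read_mask(by_id[cid].mask, vol).data)
        images.append(vol.data)
    return images, masks


def _epoch_score(seg, images, masks, metric_cfg: MetricConfig) -> tuple[float, np.ndarray, np.ndarray]:
    preds = seg.predict(images)
    pds = np.array([pseudo_dice(p, m, metric_cfg) for p, m in zip(preds, masks)])
    dsc = np.array([_safe_dice(p, m) for p, m in zip(preds, masks)])
    return float(pds.mean()), pds, dsc


def _safe_dice(a, b) -> float:
    try:
        return dice(a, b)
    except UndefinedMetricError:
        return np.nan


def run_fold(
    collection: CaseCollection,
    plan: FoldPlan,
    fold_id: int,
    train_cfg: TrainConfig | None = None,
    metric_cfg: MetricConfig | None = None,
) -> FoldResult:
    """Train on the out-of-fold cases and trace validation pseudo-Dice per epoch.

    Cases are expected to be preprocessed (and, for the standard protocol,
    slice-selected) already — see :func:`prepare_cases`.
    """
    train_cfg = train_cfg or TrainConfig()
    metric_cfg = metric_cfg or MetricConfig()
    if not 1 <= fold_id <= plan.k:
        raise ValueError(f"fold_id must be in 1..{plan.k}, got {fold_id}")
    val_ids = sorted(plan.fold_ids(fold_id))
    train_ids = sorted(cid for cid in plan.assignments if plan.assignments[cid] != fold_id)
    if not train_ids:
        raise ValueError(f"fold {fold_id}: empty training split")

    train_x, train_y = _load(collection, train_ids)
    val_x, val_y = _load(collection, val_ids)

    seed = (int(plan.seed) * 9973 + fold_id) % (2**31)
    seg = make_segmenter(train_cfg.segmenter, train_cfg, random_state=seed)

    if hasattr(seg, "partial_fit"):
        trace = np.empty(train_cfg.epochs)
        for epoch in range(train_cfg.epochs):
            seg.partial_fit(train_x, train_y)
            trace[epoch], case_pds, case_dice = _epoch_score(seg, val_x, val_y, metric_cfg)
            log.info("fold %d epoch %d: pseudo-dice %.4f", fold_id, epoch + 1, trace[epoch])
    else:
        seg.fit(train_x, train_y)
        value, case_pds, case_dice = _epoch_score(seg, val_x, val_y, metric_cfg)
        trace = np.full(train_cfg.epochs, value)
        log.info("fold %d: pseudo-dice %.4f (non-iterative segmenter)", fold_id, value)

    return FoldResult(
        fold_id=fold_id,
        trace=ScoreTrace(trace),
        case_ids=val_ids,
        case_dice=case_dice,
        case_pds=case_pds,
    )


def run_study(
    collection: CaseCollection,
    k: int = 5,
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
    metric_cfg: MetricConfig | None = None,
) -> list[FoldResult]:
    """Full k-fold study: split, then run every fold."""
    plan = make_folds(collection, k=k, seed=seed)
    return [run_fold(collection, plan, f, train_cfg, metric_cfg) for f in range(1, k + 1)]


@dataclass
class StudySummary:
    """Fold table plus the study-level statistics."""

    table: pd.DataFrame
    mean_pds_stats: StatReport
    final_pds_stats: StatReport
    ttest: PairedTResult | None

    def to_text(self) -> str:
        lines = [self.table.to_string(index=False), ""]
        lines.append(self.mean_pds_stats.to_text("mean pseudo dice"))
        lines.append(self.final_pds_stats.to_text("pseudo dice at final epoch"))
        if self.ttest is None:
            lines.append("paired t-test: degenerate (zero-variance differences)")
        else:
            lines.append(
                f"paired t-test: t = {round_half_up(self.ttest.t_statistic)}, "
                f"p = {round_half_up(self.ttest.p_value)}, df = {self.ttest.df}"
            )
        return "\n".join(lines)


def summarize_study(results: list[FoldResult] | list[FoldSummary]) -> StudySummary:
    """Fold table, descriptives and CIs for both score columns, paired t-test.

    A degenerate paired test (all per-fold differences identical, as happens
    with a non-iterative segmenter whose trace is constant) is surfaced as a
    warning; the table and descriptive statistics are still produced.
    """
    if len(results) < 2:
        raise InsufficientDataError("study summary needs at least two folds")
    summaries = [r.summary if isinstance(r, FoldResult) else r for r in results]
    x = np.array([s.mean_pds for s in summaries])
    y = np.array([s.pds_at_final for s in summaries])
    table = pd.DataFrame(
        {
            "fold": [s.fold_id for s in summaries],
            "mean_pseudo_dice": [round_half_up(v) for v in x],
            "pseudo_dice_at_final_epoch": [round_half_up(v) for v in y],
        }
    )
    try:
        ttest = paired_t(x, y)
    except ZeroVarianceError as exc:
        warnings.warn(f"paired t-test not computable: {exc}", stacklevel=2)
        ttest = None
    return StudySummary(
        table=table,
        mean_pds_stats=describe(x),
        final_pds_stats=describe(y),
        ttest=ttest,
    )
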