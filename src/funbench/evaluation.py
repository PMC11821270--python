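"""Scoring annotation methods against sibling labels.

The evaluation protocol: for a method and a labelled pair dataset, accept
per-term predictions at a prediction-score threshold tau_p, convert each
annotatable pair into a similarity score S with a kernel, and call a pair a
sibling when S >= tau_s.  Both thresholds are swept over the distinct
observed values; F1max is the maximum F1 over the (tau_p, tau_s) grid.
Because unlabeled pairs vastly outnumber siblings, metrics are computed on
balanced sets obtained by under-sampling the unlabeled pairs to the sibling
count, repeated ``n_iter`` times with per-iteration seeds, and reported as
mean +/- standard deviation.

Confusion counting treats unlabeled pairs as negatives (positive-unlabeled
caveat: some "false positives" may be real siblings the gate missed) and is
restricted to pairs the method can annotate at the current tau_p; the
method's coverage enters separately, via the annotatable fractions and the
recall weight of the threshold-free separation statistic Delta-S.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .pair_dataset import SIBLING, PairDataset, undersample_balanced
from .predictions import AnnotationSets, EmbeddingTable, PredictionTable, threshold_annotations

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "AnnotationMethod",
    "EmbeddingMethod",
    "score_pairs",
    "confusion_at",
    "precision_recall_f1",
    "sweep_f1max",
    "pr_roc_auc",
    "delta_s",
    "delta_s_max",
    "recall_max_ppf50",
    "run_resampled_evaluation",
    "evaluate_binary_reference",
    "compare_methods",
]


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Method abstraction: anything that can score pairs at a tau_p


@dataclass
class AnnotationMethod:
    """A prediction table plus a set kernel, sweepable over tau_p."""

    table: PredictionTable
    kernel: Callable
    name: str = ""
    max_tau_p_grid: int | None = None

    def __post_init__(self):
        if not self.name:
            self.name = self.table.method or "method"

    def tau_p_grid(self) -> np.ndarray:
        return self.table.tau_p_grid(self.max_tau_p_grid)

    def score(self, tau_p: float, pairs: Iterable) -> dict:
        sets = threshold_annotations(self.table, tau_p)
        return score_pairs(sets, pairs, self.kernel)


@dataclass
class EmbeddingMethod:
    """Per-protein embeddings plus a vector kernel.

    Embeddings carry no per-term confidence, so the tau_p grid degenerates
    to the single accept-everything sentinel.
    """

    embeddings: EmbeddingTable
    kernel: Callable
    name: str = "embedding"

    def tau_p_grid(self) -> np.ndarray:
        return np.array([-np.inf])

    def score(self, tau_p: float, pairs: Iterable) -> dict:
        out = {}
        for pair in pairs:
            id1, id2 = _pair_key(pair)
            if id1 in self.embeddings and id2 in self.embeddings:
                out[(id1, id2)] = self.kernel(self.embeddings[id1], self.embeddings[id2])
        return out


def _pair_key(pair) -> tuple:
    if hasattr(pair, "id1"):
        return pair.id1, pair.id2
    return pair[0], pair[1]


def score_pairs(sets: AnnotationSets, pairs: Iterable, kernel: Callable) -> dict:
    """Similarity score for every pair with both proteins annotated.

    Pairs whose kernel value is NaN (e.g. zero information-accretion mass in
    the union) are excluded.
    """
    out = {}
    for pair in pairs:
        id1, id2 = _pair_key(pair)
        if id1 in sets and id2 in sets:
            s = kernel(sets[id1], sets[id2])
            if not np.isnan(s):
                out[(id1, id2)] = float(s)
    return out


# ---------------------------------------------------------------------------
# Confusion counting and point metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    tau_p: float = float("nan")
    tau_s: float = float("nan")


def confusion_at(scores: Mapping, labels: Mapping, tau_s: float) -> ConfusionCounts:
    """Count TP/FP/FN/TN calling a pair positive when S >= tau_s (inclusive).

    ``labels`` maps pair key -> 'sibling' / 'unlabeled'; unlabeled pairs are
    counted as negatives.  Every scored pair must carry a label.
    """
    tp = fp = fn = tn = 0
    for key, s in scores.items():
        if key not in labels:
            raise EvaluationError(f"scored pair {key} has no label")
        positive = s >= tau_s
        if labels[key] == SIBLING:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, tau_s=tau_s)


def precision_recall_f1(c: ConfusionCounts) -> tuple:
    """(precision, recall, F1) with 0-denominator conventions.

    Precision is reported as 0.0 when nothing is called positive; F1 is 0
    when precision and recall are both 0.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def _f1_over_tau_s(s: np.ndarray, y: np.ndarray) -> tuple:
    """Best F1 over the distinct similarity thresholds, ties to smaller tau_s.

    Returns (f1max, tau_s_opt, precision, recall) for predicted positive
    S >= tau_s, vectorised over the distinct observed scores.
    """
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts when thresholding at each sorted score
    tp_cum = np.cumsum(y_sorted)
    pp_cum = np.arange(1, len(s) + 1)
    # distinct thresholds: last index of each tie group (S >= tau_s includes ties)
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    n_pos = int(y.sum())
    tp = tp_cum[distinct].astype(float)
    pp = pp_cum[distinct].astype(float)
    precision = np.divide(tp, pp, out=np.zeros_like(tp), where=pp > 0)
    recall = tp / n_pos if n_pos else np.zeros_like(tp)
    pr_sum = precision + recall
    f1 = np.divide(2 * precision * recall, pr_sum, out=np.zeros_like(tp), where=pr_sum > 0)
    # ties toward smaller tau_s: thresholds descend along `distinct`, so take
    # the last occurrence of the maximum
    best = len(f1) - 1 - int(np.argmax(f1[::-1]))
    return float(f1[best]), float(s_sorted[distinct][best]), float(precision[best]), float(recall[best])


@dataclass(frozen=True)
class SweepResult:
    f1max: float
    tau_p_opt: float
    tau_s_opt: float
    precision: float
    recall: float


def sweep_f1max(method, dataset: PairDataset) -> SweepResult:
    """Maximise F1 over the (tau_p, tau_s) grid.

    The tau_p grid is the method's distinct prediction scores plus a -inf
    sentinel; for each tau_p, tau_s ranges over the distinct similarity
    scores of the annotatable pairs.  Ties are broken toward smaller tau_p,
    then smaller tau_s.
    """
    labels = dataset.labels()
    best: SweepResult | None = None
    any_scored = False
    for tau_p in method.tau_p_grid():
        scores = method.score(tau_p, dataset.pairs)
        if not scores:
            continue
        any_scored = True
        keys = list(scores)
        s = np.array([scores[k] for k in keys], dtype=float)
        y = np.array([labels[k] == SIBLING for k in keys], dtype=float)
        f1, tau_s, precision, recall = _f1_over_tau_s(s, y)
        if best is None or f1 > best.f1max:
            best = SweepResult(f1, float(tau_p), tau_s, precision, recall)
    if not any_scored:
        raise EvaluationError("no annotatable pair at any tau_p")
    return best


def pr_roc_auc(scores: Mapping, labels: Mapping) -> tuple:
    """(PR AUC, ROC AUC) over all distinct similarity thresholds.

    PR AUC is the step-wise (non-interpolated) threshold summation; ROC AUC
    uses the trapezoid rule, which averages over score ties.  Requires at
    least one sibling and one non-sibling among the scored pairs.
    """
    keys = list(scores)
    s = np.array([scores[k] for k in keys], dtype=float)
    y = np.array([labels[k] == SIBLING for k in keys], dtype=int)
    if y.min() == y.max():
        raise EvaluationError("PR/ROC AUC undefined for single-class input")
    return float(average_precision_score(y, s)), float(roc_auc_score(y, s))


def delta_s(scores: Mapping, labels: Mapping, coverage_recall: float) -> float:
    """Recall-weighted separation of sibling vs unlabeled score means.

    Delta-S = coverage_recall * (mean S over siblings - mean S over
    unlabeled), in [-1, 1].  ``coverage_recall`` is the fraction of the
    dataset's siblings the method can score at the current tau_p, making the
    statistic independent of tau_s.
    """
    sib = [s for k, s in scores.items() if labels[k] == SIBLING]
    unl = [s for k, s in scores.items() if labels[k] != SIBLING]
    if not sib or not unl:
        raise EvaluationError("Delta-S needs at least one scored pair of each class")
    if not 0 <= coverage_recall <= 1:
        raise EvaluationError(f"coverage_recall {coverage_recall} outside [0, 1]")
    return coverage_recall * (float(np.mean(sib)) - float(np.mean(unl)))


def delta_s_max(method, dataset: PairDataset) -> float:
    """Maximum Delta-S over the tau_p grid (ties toward smaller tau_p).

    tau_p values at which either class has no scored pair are skipped; if no
    tau_p is feasible the result is NaN.
    """
    labels = dataset.labels()
    n_sib_total = dataset.n_siblings
    best = -np.inf
    for tau_p in method.tau_p_grid():
        scores = method.score(tau_p, dataset.pairs)
        n_sib = sum(1 for k in scores if labels[k] == SIBLING)
        n_unl = len(scores) - n_sib
        if n_sib == 0 or n_unl == 0:
            continue
        coverage = n_sib / n_sib_total if n_sib_total else 0.0
        value = delta_s(scores, labels, coverage)
        if value > best:
            best = value
    return best if best > -np.inf else float("nan")


def recall_max_ppf50(method, dataset: PairDataset, ppf_max: float = 0.5) -> float:
    """Maximum recall over (tau_p, tau_s) with predicted-positive fraction
    strictly below ``ppf_max``.

    PPf = predicted positives / scored pairs at (tau_p, tau_s).  Guards
    against trivial all-positive overprediction; returns 0.0 when no
    threshold pair satisfies the constraint.
    """
    labels = dataset.labels()
    best = 0.0
    for tau_p in method.tau_p_grid():
        scores = method.score(tau_p, dataset.pairs)
        if not scores:
            continue
        keys = list(scores)
        s = np.array([scores[k] for k in keys], dtype=float)
        y = np.array([labels[k] == SIBLING for k in keys], dtype=float)
        n_pos = y.sum()
        if n_pos == 0:
            continue
        order = np.argsort(-s, kind="mergesort")
        s_sorted, y_sorted = s[order], y[order]
        tp_cum = np.cumsum(y_sorted)
        pp_cum = np.arange(1, len(s) + 1)
        distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
        ppf = pp_cum[distinct] / len(s)
        feasible = ppf < ppf_max
        if feasible.any():
            recall = tp_cum[distinct][feasible] / n_pos
            best = max(best, float(recall.max()))
    return best


# ---------------------------------------------------------------------------
# Resampled protocol


@dataclass
class MetricReport:
    """Per-method evaluation results over balanced resampling iterations."""

    method: str
    per_iteration: pd.DataFrame
    n_iter: int
    seed: int
    annotatable_fraction: float = float("nan")
    annotatable_sibling_fraction: float = float("nan")
    notes: tuple = (
        "Unlabeled pairs are counted as negatives (positive-unlabeled data): "
        "reported false positives may include unrecognised siblings.",
    )

    METRICS = (
        "f1max",
        "tau_p_opt",
        "tau_s_opt",
        "precision",
        "recall",
        "pr_auc",
        "roc_auc",
        "delta_s",
        "delta_s_max",
        "recall_max_ppf50",
    )

    def summary(self) -> dict:
        out = {"method": self.method, "n_iter": self.n_iter, "seed": self.seed,
               "annotatable_fraction": self.annotatable_fraction,
               "annotatable_sibling_fraction": self.annotatable_sibling_fraction}
        for m in self.per_iteration.columns:
            col = self.per_iteration[m].to_numpy(dtype=float)
            # tau_p_opt may hold the -inf accept-everything sentinel
            with np.errstate(invalid="ignore"):
                out[f"{m}_mean"] = float(np.nanmean(col)) if np.isfinite(col).any() else float(col[0])
                if self.n_iter > 1:
                    out[f"{m}_std"] = float(np.nanstd(col, ddof=1))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.summary()])


def iteration_seeds(master_seed: int, n_iter: int) -> list:
    """Independent per-iteration seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_iter)]


def evaluate_once(method, subset: PairDataset, ppf_max: float = 0.5, ppf_dataset=None) -> dict:
    """All metrics for one balanced subset, in a single pass over the tau_p
    grid.

    F1max and its optima come from the full (tau_p, tau_s) sweep; PR/ROC AUC
    and Delta-S are computed at tau_p_opt sweeping only tau_s (they are
    tau_s-free by construction); Delta-S-max and Recall-max-PPf50 maximise
    over the same grid.  Equivalent to calling :func:`sweep_f1max`,
    :func:`delta_s_max` and :func:`recall_max_ppf50` separately.

    ``ppf_dataset`` optionally supplies a different (typically the full,
    unbalanced) pair set for the predicted-positive-fraction constraint: on
    an exactly balanced subset a perfect binary scorer calls precisely half
    the pairs positive, which the strict PPf < 0.5 cap excludes, so the cap
    is meant to be taken over the method-specific dataset.  Pass ``False``
    to skip the constrained-recall computation entirely (reported as NaN).
    """
    labels = subset.labels()
    n_sib_total = subset.n_siblings
    best: SweepResult | None = None
    best_scores: dict | None = None
    best_ds = -np.inf
    best_recall_ppf = 0.0
    any_scored = False
    for tau_p in method.tau_p_grid():
        scores = method.score(tau_p, subset.pairs)
        if not scores:
            continue
        any_scored = True
        keys = list(scores)
        s = np.array([scores[k] for k in keys], dtype=float)
        y = np.array([labels[k] == SIBLING for k in keys], dtype=float)
        n_pos = y.sum()
        # F1 over tau_s
        f1, tau_s, precision, recall = _f1_over_tau_s(s, y)
        if best is None or f1 > best.f1max:
            best = SweepResult(f1, float(tau_p), tau_s, precision, recall)
            best_scores = scores
        # Delta-S with coverage recall
        if 0 < n_pos < len(s):
            coverage = n_pos / n_sib_total if n_sib_total else 0.0
            ds = coverage * (s[y == 1].mean() - s[y == 0].mean())
            if ds > best_ds:
                best_ds = ds
        # recall under the predicted-positive-fraction cap
        if ppf_dataset is None and n_pos:
            order = np.argsort(-s, kind="mergesort")
            s_sorted, y_sorted = s[order], y[order]
            distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
            ppf = (distinct + 1) / len(s)
            feasible = ppf < ppf_max
            if feasible.any():
                recall_c = np.cumsum(y_sorted)[distinct][feasible] / n_pos
                best_recall_ppf = max(best_recall_ppf, float(recall_c.max()))
    if not any_scored:
        raise EvaluationError("no annotatable pair at any tau_p")
    if ppf_dataset is False:
        best_recall_ppf = float("nan")
    elif ppf_dataset is not None:
        best_recall_ppf = recall_max_ppf50(method, ppf_dataset, ppf_max=ppf_max)
    n_sib_scored = sum(1 for k in best_scores if labels[k] == SIBLING)
    n_unl_scored = len(best_scores) - n_sib_scored
    if n_sib_scored and n_unl_scored:
        pr_auc, roc_auc = pr_roc_auc(best_scores, labels)
        coverage = n_sib_scored / n_sib_total if n_sib_total else 0.0
        ds_opt = delta_s(best_scores, labels, coverage)
    else:
        pr_auc = roc_auc = ds_opt = float("nan")
    return {
        "f1max": best.f1max,
        "tau_p_opt": best.tau_p_opt,
        "tau_s_opt": best.tau_s_opt,
        "precision": best.precision,
        "recall": best.recall,
        "pr_auc": pr_auc,
        "roc_auc": roc_auc,
        "delta_s": ds_opt,
        "delta_s_max": best_ds if best_ds > -np.inf else float("nan"),
        "recall_max_ppf50": best_recall_ppf,
    }


def run_resampled_evaluation(
    dataset: PairDataset,
    method,
    n_iter: int = 100,
    seed: int = 0,
) -> MetricReport:
    """Balanced under-sampling protocol: ``n_iter`` iterations, all metrics.

    Each iteration under-samples the unlabeled pairs to the sibling count
    with its own derived seed, evaluates the method on the balanced subset,
    and the report aggregates mean and standard deviation per metric.
    Recall-max-PPf50 is the exception: its predicted-positive cap refers to
    the method-specific full dataset (on an exactly balanced subset the cap
    would exclude any scorer that calls all true siblings positive), so it
    is computed once on ``dataset`` and carried as a constant column.
    """
    rows = []
    for it_seed in iteration_seeds(seed, n_iter):
        subset = undersample_balanced(dataset, it_seed)
        rows.append(evaluate_once(method, subset, ppf_dataset=False))
    per_iteration = pd.DataFrame(rows)
    per_iteration["recall_max_ppf50"] = recall_max_ppf50(method, dataset)
    # coverage on the full dataset at the accept-everything sentinel
    grid = method.tau_p_grid()
    scores_all = method.score(grid[0], dataset.pairs)
    labels = dataset.labels()
    n_sib = dataset.n_siblings
    frac_all = len(scores_all) / len(dataset) if len(dataset) else float("nan")
    frac_sib = (
        sum(1 for k in scores_all if labels[k] == SIBLING) / n_sib if n_sib else float("nan")
    )
    return MetricReport(
        method=getattr(method, "name", "method"),
        per_iteration=per_iteration,
        n_iter=n_iter,
        seed=seed,
        annotatable_fraction=frac_all,
        annotatable_sibling_fraction=frac_sib,
    )


def evaluate_binary_reference(
    pair_labels: Mapping,
    dataset: PairDataset,
    n_iter: int = 100,
    seed: int = 0,
) -> tuple:
    """Ideal-predictor protocol: binary same/different reference labels.

    ``pair_labels`` maps pair key -> 'same'/'different' (e.g. from EC
    identity at the third level).  A pair is predicted positive iff 'same';
    there is no threshold sweep.  Returns (mean precision, mean recall) over
    balanced resampling; pairs without a reference label are skipped.
    """
    precisions, recalls = [], []
    for it_seed in iteration_seeds(seed, n_iter):
        subset = undersample_balanced(dataset, it_seed)
        tp = fp = fn = tn = 0
        for p in subset.pairs:
            ref = pair_labels.get(p.key)
            if ref is None:
                continue
            positive = ref == "same"
            if p.label == SIBLING:
                tp += positive
                fn += not positive
            else:
                fp += positive
                tn += not positive
        precision, recall, _ = precision_recall_f1(ConfusionCounts(tp, fp, fn, tn))
        precisions.append(precision)
        recalls.append(recall)
    return float(np.mean(precisions)), float(np.mean(recalls))


# ---------------------------------------------------------------------------
# Method comparison


def _safe_tests(a: np.ndarray, b: np.ndarray) -> tuple:
    """(wilcoxon_stat, wilcoxon_p, t_stat, t_p) robust to zero variance."""
    if np.array_equal(a, b):
        return 0.0, 1.0, 0.0, 1.0
    w_stat, w_p = stats.ranksums(a, b)
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate t-test: equal constants handled above, unequal -> p=0
        t_stat, t_p = (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    else:
        t_stat, t_p = stats.ttest_ind(a, b)
    return float(w_stat), float(w_p), float(t_stat), float(t_p)


def compare_methods(
    reports: Sequence[MetricReport],
    metrics: Sequence[str] = ("delta_s", "f1max", "pr_auc", "roc_auc"),
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum and Student t-tests on per-iteration metric
    samples, Benjamini-Hochberg-adjusted within each metric family.

    All reports must share the iteration count.
    """
    n_iters = {r.n_iter for r in reports}
    if len(n_iters) > 1:
        raise EvaluationError(f"reports have mismatched iteration counts: {sorted(n_iters)}")
    rows = []
    for metric in metrics:
        for i, ra in enumerate(reports):
            for rb in reports[i + 1 :]:
                a = ra.per_iteration[metric].to_numpy(dtype=float)
                b = rb.per_iteration[metric].to_numpy(dtype=float)
                w_stat, w_p, t_stat, t_p = _safe_tests(a, b)
                rows.append(
                    {
                        "metric": metric,
                        "method_a": ra.method,
                        "method_b": rb.method,
                        "wilcoxon_stat": w_stat,
                        "wilcoxon_p": w_p,
                        "t_stat": t_stat,
                        "t_p": t_p,
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for col in ("wilcoxon_p", "t_p"):
        adjusted = np.empty(len(df))
        for metric in metrics:
            mask = (df["metric"] == metric).to_numpy()
            if mask.any():
                adjusted[mask] = multipletests(df.loc[mask, col], method="fdr_bh")[1]
        df[f"{col}_bh"] = adjusted
    return df
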