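"""Empirical random baselines.

Two chance references anchor every method comparison: a *random classifier*
that draws pair similarity scores from Uniform(0, 1) (its balanced-data ROC
AUC converges to 0.5 and its F1max to 2/3, attained by the all-positive
call), and a *random annotator* that keeps a method's scores but permutes
the sibling/unlabeled labels, preserving the score distribution while
destroying any association with function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluation import MetricReport, evaluate_once, iteration_seeds
from .pair_dataset import PairDataset, undersample_balanced

__all__ = [
    "BaselineSpec",
    "random_classifier_scores",
    "random_annotator_labels",
    "baseline_report",
]


@dataclass(frozen=True)
class BaselineSpec:
    kind: str  # 'random_classifier' | 'random_annotator'
    n_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("random_classifier", "random_annotator"):
            raise ValueError(f"unknown baseline kind: {self.kind!r}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def random_classifier_scores(pairs, seed) -> dict:
    """I.i.d. Uniform(0, 1) similarity score per pair, deterministic in seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = [(p.id1, p.id2) if hasattr(p, "id1") else (p[0], p[1]) for p in pairs]
    values = rng.uniform(0.0, 1.0, size=len(keys))
    return dict(zip(keys, values.tolist()))


def random_annotator_labels(dataset: PairDataset, seed) -> PairDataset:
    """Uniformly permute the sibling/unlabeled labels across pairs.

    The label multiset is conserved; only the assignment changes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [p.label for p in dataset.pairs]
    perm = rng.permutation(len(labels))
    shuffled = [
        replace(p, label=labels[perm[i]]) for i, p in enumerate(dataset.pairs)
    ]
    return PairDataset(pairs=shuffled, tm_min=dataset.tm_min, snn_min=dataset.snn_min)


class _RandomClassifierMethod:
    """One fixed Uniform(0, 1) score draw per pair; no prediction threshold."""

    name = "random_classifier"

    def __init__(self, pairs, seed):
        self._scores = random_classifier_scores(pairs, seed)

    def tau_p_grid(self) -> np.ndarray:
        return np.array([-np.inf])

    def score(self, tau_p, pairs) -> dict:
        keys = [(p.id1, p.id2) if hasattr(p, "id1") else (p[0], p[1]) for p in pairs]
        return {k: self._scores[k] for k in keys if k in self._scores}


def baseline_report(
    dataset: PairDataset,
    spec: BaselineSpec,
    method=None,
) -> MetricReport:
    """Baseline metrics under the same resampled protocol as real methods.

    ``random_classifier`` ignores ``method`` and scores with fresh uniform
    draws per iteration.  ``random_annotator`` evaluates ``method`` (any
    object with ``tau_p_grid``/``score``) against per-iteration
    label-shuffled balanced subsets.
    """
    rows = []
    for it_seed in iteration_seeds(spec.seed, spec.n_iter):
        subset = undersample_balanced(dataset, it_seed)
        if spec.kind == "random_classifier":
            iter_method = _RandomClassifierMethod(subset.pairs, np.random.default_rng(it_seed))
        else:
            if method is None:
                raise ValueError("random_annotator baseline requires a method to score")
            subset = random_annotator_labels(subset, np.random.default_rng(it_seed + 1))
            iter_method = method
        rows.append(evaluate_once(iter_method, subset))
    return MetricReport(
        method=f"baseline:{spec.kind}",
        per_iteration=pd.DataFrame(rows),
        n_iter=spec.n_iter,
        seed=spec.seed,
    )
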