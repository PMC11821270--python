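"""Per-method annotation predictions: loading, score orientation, and the
prediction-score threshold tau_p.

A method's raw output is a table of (protein, term, score) records.  Scores
come in two orientations: higher-is-better confidences and lower-is-better
E-values.  Internally every table is normalised to higher-is-better: E-values
are mapped through -log10 (with a cap for exact zeros) so that a single
inclusive threshold ``score >= tau_p`` works uniformly.  Thresholding an
E-value table at tau_p is then exactly keeping E <= 10**(-tau_p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictionTable",
    "EmbeddingTable",
    "AnnotationSets",
    "load_predictions",
    "threshold_annotations",
    "annotatable_pairs",
]

#: internal score assigned to an E-value of exactly zero
DEFAULT_EVALUE_CAP = 300.0


class PredictionError(ValueError):
    pass


@dataclass
class PredictionTable:
    """Deduplicated per-protein, per-term prediction records for one method.

    ``data`` holds columns ``protein``, ``term``, ``score`` (internal,
    higher-is-better) and ``raw_score``.  Duplicate (protein, term) rows are
    collapsed to the best score at construction.
    """

    data: pd.DataFrame
    vocabulary: str = "custom"
    method: str = ""
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        required = {"protein", "term", "score"}
        missing = required - set(self.data.columns)
        if missing:
            raise PredictionError(f"prediction table missing columns: {sorted(missing)}")
        if not np.isfinite(self.data["score"].to_numpy(dtype=float)).all():
            raise PredictionError("prediction scores must be finite")
        if "raw_score" not in self.data.columns:
            self.data = self.data.assign(raw_score=self.data["score"])
        # collapse duplicates to the best internal score
        self.data = (
            self.data.sort_values("score", ascending=False, kind="mergesort")
            .drop_duplicates(subset=["protein", "term"], keep="first")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def proteins(self) -> set:
        return set(self.data["protein"])

    def tau_p_grid(self, max_size: int | None = None) -> np.ndarray:
        """Sorted distinct internal scores plus a -inf sentinel.

        The sentinel accepts every prediction; the distinct observed values
        make the grid exhaustive for an inclusive ``>=`` threshold.  When
        ``max_size`` is given, the distinct values are thinned to evenly
        spaced quantiles (endpoints kept).
        """
        values = np.unique(self.data["score"].to_numpy(dtype=float))
        if max_size is not None and len(values) > max_size:
            idx = np.unique(np.linspace(0, len(values) - 1, max_size).round().astype(int))
            values = values[idx]
        return np.concatenate([[-np.inf], values])


@dataclass
class EmbeddingTable:
    """Fixed-length real-valued vector per protein."""

    vectors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.vectors.values()}
        if len(lengths) > 1:
            raise PredictionError(f"embedding vectors have mixed lengths: {sorted(lengths)}")
        self.vectors = {p: np.asarray(v, dtype=float) for p, v in self.vectors.items()}
        for p, v in self.vectors.items():
            if not np.isfinite(v).all():
                raise PredictionError(f"non-finite embedding for protein {p!r}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[0] if self.vectors else 0

    def __contains__(self, protein) -> bool:
        return protein in self.vectors

    def __getitem__(self, protein) -> np.ndarray:
        return self.vectors[protein]


@dataclass
class AnnotationSets:
    """Per-protein accepted term sets at a given tau_p.

    Proteins whose every term fell below the threshold are absent: the method
    cannot annotate them at this operating point, so no empty sets are stored.
    """

    sets: dict
    tau_p: float
    vocabulary: str = "custom"

    def __post_init__(self) -> None:
        empties = [p for p, s in self.sets.items() if not s]
        if empties:
            raise PredictionError(f"empty annotation sets stored for: {empties[:5]}")
        self.sets = {p: frozenset(s) for p, s in self.sets.items()}

    def __contains__(self, protein) -> bool:
        return protein in self.sets

    def __getitem__(self, protein) -> frozenset:
        return self.sets[protein]

    def __len__(self) -> int:
        return len(self.sets)


def load_predictions(
    path,
    method: str = "",
    vocabulary: str = "custom",
    higher_is_better: bool = True,
    columns: Sequence[str] = ("protein", "term", "score"),
    evalue_cap: float = DEFAULT_EVALUE_CAP,
    sep: str = "\t",
) -> PredictionTable:
    """Read a CAFA-style tab-separated prediction file.

    Parameters
    ----------
    columns : sequence of str
        Names of the columns holding protein ID, term ID and raw score, in
        that order (other columns are ignored).
    higher_is_better : bool
        Orientation of the raw scores.  Lower-is-better inputs (E-values)
        are transformed to internal scores via ``-log10(raw)``, with zeros
        mapped to ``evalue_cap``.
    """
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise PredictionError(f"empty prediction file: {path}")
    prot_col, term_col, score_col = columns
    for col in columns:
        if col not in df.columns:
            raise PredictionError(f"{path}: missing column {col!r}")
    raw = pd.to_numeric(df[score_col], errors="coerce")
    bad = raw.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise PredictionError(f"{path}: non-numeric score at line {line}")
    raw = raw.to_numpy(dtype=float)
    if higher_is_better:
        score = raw
    else:
        if (raw < 0).any():
            raise PredictionError(f"{path}: negative E-values not allowed")
        with np.errstate(divide="ignore"):
            score = np.where(raw > 0, -np.log10(np.maximum(raw, 1e-323)), evalue_cap)
        score = np.minimum(score, evalue_cap)
    out = pd.DataFrame(
        {
            "protein": df[prot_col].astype(str),
            "term": df[term_col],
            "score": score,
            "raw_score": raw,
        }
    )
    return PredictionTable(
        data=out, vocabulary=vocabulary, method=method, higher_is_better=True
    )


def threshold_annotations(table: PredictionTable, tau_p: float) -> AnnotationSets:
    """Accept terms with internal score >= tau_p (inclusive).

    Proteins with no accepted term are dropped, marking them unannotatable
    at this threshold.
    """
    if np.isnan(tau_p) or tau_p == np.inf:
        raise PredictionError("tau_p must be finite or -inf")
    kept = table.data[table.data["score"] >= tau_p]
    sets = kept.groupby("protein", sort=False)["term"].agg(frozenset).to_dict()
    return AnnotationSets(sets=sets, tau_p=tau_p, vocabulary=table.vocabulary)


def annotatable_pairs(sets: AnnotationSets, pairs: Iterable) -> tuple:
    """Pairs for which both proteins carry annotations.

    Returns ``(kept_pairs, fraction_annotatable)`` where the fraction is over
    all input pairs.  Pairs may be any objects exposing ``id1``/``id2``
    attributes or plain 2-tuples of protein IDs.
    """
    pairs = list(pairs)
    kept = []
    for pair in pairs:
        id1, id2 = _pair_ids(pair)
        if id1 in sets and id2 in sets:
            kept.append(pair)
    fraction = len(kept) / len(pairs) if pairs else 0.0
    return kept, fraction


def _pair_ids(pair) -> tuple:
    if hasattr(pair, "id1"):
        return pair.id1, pair.id2
    return pair[0], pair[1]
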