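"""Orphan filtering, sibling labelling, and balanced under-sampling.

The evaluation data are *positive-unlabeled*: a pair passing both the
structural gate (TM-score >= 0.7) and the functional gate (SNN score >= 0.98)
is confidently labelled a *sibling*; every other pair is merely *unlabeled* —
mostly non-siblings, but with no guarantee.  Downstream metrics treat
unlabeled pairs as negatives for confusion counting, which every report
should caveat.

Orphan proteins are defined by four filters applied to protein metadata:
sequence identity to the reference database strictly below 30%, length at
most 400 residues, and predicted-structure confidence pLDDT and pTM both
strictly above 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ontology import ECNumber, truncate_ec

__all__ = [
    "ProteinRecord",
    "PairRecord",
    "PairDataset",
    "filter_orphans",
    "label_siblings",
    "undersample_balanced",
    "binary_ec_labels",
]

SIBLING = "sibling"
UNLABELED = "unlabeled"


class PairDataError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """Protein metadata used by the orphan filters."""

    protein: str
    length: int
    identity_to_reference: float  # percent, [0, 100]
    plddt: float  # [0, 1]
    ptm: float  # [0, 1]
    truncated: bool = False

    def __post_init__(self):
        if self.length < 1:
            raise PairDataError(f"{self.protein}: length must be >= 1")
        if not 0 <= self.identity_to_reference <= 100:
            raise PairDataError(f"{self.protein}: identity must be in [0, 100]")
        for name in ("plddt", "ptm"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PairDataError(f"{self.protein}: {name} must be in [0, 1]")


@dataclass(frozen=True)
class PairRecord:
    """A canonically ordered protein pair with its similarity scores."""

    id1: str
    id2: str
    tm_score: float
    snn_score: float
    seq_identity: float = 0.0  # percent
    label: str = UNLABELED

    def __post_init__(self):
        if self.id1 == self.id2:
            raise PairDataError(f"self-pair rejected: {self.id1}")
        if self.id1 > self.id2:
            a, b = self.id2, self.id1
            object.__setattr__(self, "id1", a)
            object.__setattr__(self, "id2", b)
        for name in ("tm_score", "snn_score"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PairDataError(f"{name}={v} outside [0, 1] for pair ({self.id1}, {self.id2})")

    @property
    def key(self) -> tuple:
        return (self.id1, self.id2)


@dataclass
class PairDataset:
    """Labelled pair collection with the gate thresholds that produced it."""

    pairs: list
    tm_min: float = 0.7
    snn_min: float = 0.98

    def __post_init__(self):
        seen = set()
        for p in self.pairs:
            if p.key in seen:
                raise PairDataError(f"duplicate pair: {p.key}")
            seen.add(p.key)

    @property
    def siblings(self) -> list:
        return [p for p in self.pairs if p.label == SIBLING]

    @property
    def unlabeled(self) -> list:
        return [p for p in self.pairs if p.label == UNLABELED]

    @property
    def n_siblings(self) -> int:
        return sum(1 for p in self.pairs if p.label == SIBLING)

    @property
    def n_unlabeled(self) -> int:
        return len(self.pairs) - self.n_siblings

    def labels(self) -> dict:
        return {p.key: p.label for p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id1": [p.id1 for p in self.pairs],
                "id2": [p.id2 for p in self.pairs],
                "tm_score": [p.tm_score for p in self.pairs],
                "snn_score": [p.snn_score for p in self.pairs],
                "seq_identity": [p.seq_identity for p in self.pairs],
                "label": [p.label for p in self.pairs],
            }
        )


def filter_orphans(
    records: Iterable[ProteinRecord],
    id_max: float = 30.0,
    len_max: int = 400,
    plddt_min: float = 0.9,
    ptm_min: float = 0.9,
) -> list:
    """Keep orphan proteins: identity < id_max (strict), length <= len_max,
    pLDDT > plddt_min and pTM > ptm_min (both strict), not truncated."""
    kept = []
    for rec in records:
        if (
            rec.identity_to_reference < id_max
            and rec.length <= len_max
            and rec.plddt > plddt_min
            and rec.ptm > ptm_min
            and not rec.truncated
        ):
            kept.append(rec)
    return kept


def label_siblings(
    pairs: Iterable[PairRecord], tm_min: float = 0.7, snn_min: float = 0.98
) -> PairDataset:
    """Label pairs passing both gates (inclusive >=) as siblings."""
    labelled = []
    for p in pairs:
        label = SIBLING if (p.tm_score >= tm_min and p.snn_score >= snn_min) else UNLABELED
        labelled.append(replace(p, label=label))
    return PairDataset(pairs=labelled, tm_min=tm_min, snn_min=snn_min)


def undersample_balanced(dataset: PairDataset, seed) -> PairDataset:
    """All siblings plus an equal-size sample of unlabeled pairs.

    Sampling is without replacement and deterministic given ``seed`` (an int
    or a :class:`numpy.random.Generator`).
    """
    siblings = dataset.siblings
    unlabeled = dataset.unlabeled
    if len(unlabeled) < len(siblings):
        raise PairDataError(
            f"cannot balance: {len(unlabeled)} unlabeled < {len(siblings)} siblings"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(unlabeled), size=len(siblings), replace=False)
    sampled = [unlabeled[i] for i in sorted(idx)]
    return PairDataset(
        pairs=siblings + sampled, tm_min=dataset.tm_min, snn_min=dataset.snn_min
    )


def binary_ec_labels(
    annotations: Mapping[str, Iterable],
    pairs: Iterable,
    level: int = 3,
) -> dict:
    """Same/different function labels from EC identity at a hierarchy level.

    A pair is "same" iff the two proteins' EC sets, truncated to ``level``,
    share at least one complete code.  Pairs with a missing annotation are
    skipped with a warning.
    """
    ec_sets = {}
    for protein, ecs in annotations.items():
        truncated = set()
        for ec in ecs:
            t = truncate_ec(ec if isinstance(ec, ECNumber) else ECNumber.parse(str(ec)), level)
            if t.is_complete:
                truncated.add(t)
        ec_sets[protein] = truncated
    out = {}
    skipped = 0
    for pair in pairs:
        id1, id2 = (pair.id1, pair.id2) if hasattr(pair, "id1") else (pair[0], pair[1])
        s1 = ec_sets.get(id1)
        s2 = ec_sets.get(id2)
        if not s1 or not s2:
            skipped += 1
            continue
        out[(id1, id2)] = "same" if s1 & s2 else "different"
    if skipped:
        warnings.warn(f"binary_ec_labels: skipped {skipped} pairs lacking EC annotations")
    return out
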