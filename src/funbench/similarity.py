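"""Pairwise functional-similarity kernels.

Each kernel maps a pair of per-protein predictions (term sets or embedding
vectors) to a single similarity score S in [0, 1].  All kernels are symmetric
in their two arguments.

Set kernels: plain Jaccard, information-accretion-weighted Jaccard (for GO,
weighting each term by its specificity), and the shared-term indicator used
for EC/Pfam/ortholog vocabularies ("functionally similar if they share even
one common annotation").  Embedding kernels: a bounded transform of Euclidean
distance, S = 0.5 / (0.5 + d/2), and shifted cosine similarity on
L2-normalised vectors, S = (e1.e2 + 1) / 2.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .ontology import OntologyDAG, propagate

__all__ = [
    "jaccard",
    "ia_weighted_jaccard",
    "binary_shared",
    "euclidean_similarity",
    "cosine_similarity",
    "KERNELS",
]


class SimilarityError(ValueError):
    pass


def jaccard(set1, set2) -> float:
    """Jaccard coefficient |intersection| / |union| of two term sets."""
    s1, s2 = set(set1), set(set2)
    if not s1 and not s2:
        raise SimilarityError("Jaccard undefined for two empty sets")
    return len(s1 & s2) / len(s1 | s2)


def ia_weighted_jaccard(
    set1,
    set2,
    ia: Mapping,
    dag: OntologyDAG | None = None,
) -> float:
    """Information-accretion-weighted Jaccard over propagated GO sets.

    S = sum of Ia over the intersection / sum of Ia over the union.  When a
    ``dag`` is supplied, both sets are ancestor-propagated (roots removed)
    first; pass ``dag=None`` for sets that are already propagated.

    Returns NaN when the union carries zero information (the pair cannot be
    scored; callers should exclude it).
    """
    s1 = propagate(dag, set1) if dag is not None else frozenset(set1)
    s2 = propagate(dag, set2) if dag is not None else frozenset(set2)
    if not s1 and not s2:
        raise SimilarityError("weighted Jaccard undefined for two empty sets")
    union_mass = sum(ia[t] for t in s1 | s2)
    if union_mass <= 0:
        return float("nan")
    inter_mass = sum(ia[t] for t in s1 & s2)
    return inter_mass / union_mass


def binary_shared(set1, set2) -> float:
    """1.0 if the sets share at least one term, else 0.0."""
    s1, s2 = set(set1), set(set2)
    if not s1 and not s2:
        raise SimilarityError("shared-term indicator undefined for two empty sets")
    return 1.0 if s1 & s2 else 0.0


def euclidean_similarity(e1, e2) -> float:
    """Bounded similarity from Euclidean distance: S = 0.5 / (0.5 + d/2).

    S = 1 iff the vectors coincide; S -> 0 as the distance grows.
    """
    v1 = np.asarray(e1, dtype=float)
    v2 = np.asarray(e2, dtype=float)
    if v1.shape != v2.shape:
        raise SimilarityError(f"embedding length mismatch: {v1.shape} vs {v2.shape}")
    d = float(np.linalg.norm(v1 - v2))
    return 0.5 / (0.5 + d / 2.0)


def cosine_similarity(e1, e2) -> float:
    """Shifted cosine on L2-normalised vectors: S = (e1.e2 + 1) / 2 in [0, 1]."""
    v1 = np.asarray(e1, dtype=float)
    v2 = np.asarray(e2, dtype=float)
    if v1.shape != v2.shape:
        raise SimilarityError(f"embedding length mismatch: {v1.shape} vs {v2.shape}")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise SimilarityError("cosine similarity undefined for a zero vector")
    s = (float(v1 @ v2) / (n1 * n2) + 1.0) / 2.0
    return min(1.0, max(0.0, s))


#: registry of set kernels by name, for configuration files
KERNELS = {
    "jaccard": jaccard,
    "binary_shared": binary_shared,
}
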