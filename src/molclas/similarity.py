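"""Rank-weighted similarity between binary fingerprints.

The similarity index of two vectors ``u``, ``v`` under a weight scheme
``a`` is

    r(u, v) = sum_k t_k * a_k**k,   t_k = 1 if u_k == v_k else 0,

so a match at rank k contributes ``a_k**k`` and a mismatch nothing. The
index lives in [0, self-similarity], where the self-similarity
``sum_k a_k**k`` is the diagonal of every similarity matrix and is < 1
for finite k.

The same index applies in *property space*: transpose the item x feature
bit table and compare feature columns (each of length n_items) with
weights ``a_k**k`` running along the molecule axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import PropertyVector, SimilarityMatrix, WeightScheme

__all__ = [
    "similarity_index",
    "similarity_matrix",
    "property_space_matrix",
    "bin_diagram",
    "BinDiagram",
    "BIN_EDGES",
]

#: Similarity thresholds of the correlation-diagram bins, highest first.
BIN_EDGES: dict[str, tuple[float, float]] = {
    "high": (0.75, 1.0),
    "medium": (0.50, 0.75),
    "low": (0.25, 0.50),
    "zero": (0.0, 0.25),
}


def _bit_matrix(items: Sequence[PropertyVector]) -> np.ndarray:
    arrs = [v.as_array() for v in items]
    k = len(arrs[0])
    if any(len(a) != k for a in arrs):
        raise ValueError("all property vectors must have the same length")
    return np.stack(arrs)


def similarity_index(u: PropertyVector, v: PropertyVector, w: WeightScheme) -> float:
    """Weighted fraction of matching positions between two fingerprints."""
    if len(u) != len(v):
        raise ValueError(f"vector lengths differ: {len(u)} vs {len(v)}")
    if w.n_positions != len(u):
        raise ValueError("weight scheme does not cover all positions")
    t = u.as_array() == v.as_array()
    return float(w.effective_weights()[t].sum())


def _pairwise(bits: np.ndarray, w: WeightScheme) -> np.ndarray:
    """All-pairs weighted-match similarity for a 0/1 matrix (rows = items)."""
    eff = w.effective_weights()
    # agreement indicator per pair/position: 1 - |u_k - v_k| for binary bits
    agree = 1 - np.abs(bits[:, None, :] - bits[None, :, :])
    return agree @ eff


def similarity_matrix(
    items: Sequence[PropertyVector],
    w: WeightScheme | None = None,
    item_ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Raw (unstabilized) similarity matrix over items.

    The diagonal equals the self-similarity ``sum_k a_k**k``; with the
    default equal weights a_k = 0.5 and six positions this is 0.984375.
    """
    if len(items) < 2:
        raise ValueError("need at least two items")
    bits = _bit_matrix(items)
    if w is None:
        w = WeightScheme.equal(bits.shape[1])
    if w.n_positions != bits.shape[1]:
        raise ValueError("weight scheme does not cover all positions")
    ids = tuple(item_ids) if item_ids is not None else tuple(str(i + 1) for i in range(len(items)))
    return SimilarityMatrix(_pairwise(bits, w), ids, w, stabilized=False)


def property_space_matrix(
    items: Sequence[PropertyVector],
    w: WeightScheme | None = None,
    feature_ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Similarity matrix between *feature columns* rather than items.

    The item x feature table is transposed; each pair of features is
    compared across the n_items molecules with weights ``a_k**k``,
    k = 1..n_items. With nine molecules and equal weights 0.5 the
    self-similarity is ``sum_{k=1..9} 0.5**k`` = 0.998047.
    """
    cols = _bit_matrix(items).T  # features x items
    n_items = cols.shape[1]
    if w is None:
        w = WeightScheme.equal(n_items)
    if w.n_positions != n_items:
        raise ValueError("weight scheme must cover the molecule axis")
    if feature_ids is None:
        feature_ids = tuple(f"i{j+1}" for j in range(cols.shape[0]))
    return SimilarityMatrix(_pairwise(cols, w), tuple(feature_ids), w, stabilized=False)


@dataclass
class BinDiagram:
    """Pairs of items binned by raw similarity, diagram-style."""

    counts: dict[str, int]
    pairs: dict[str, list[tuple[str, str]]]

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    def edge_list(self) -> list[tuple[str, str, str]]:
        """(source, target, bin) triples for graph export."""
        return [(a, b, name) for name, ps in self.pairs.items() for a, b in ps]


def bin_diagram(m: SimilarityMatrix) -> BinDiagram:
    """Assign every unordered item pair to a similarity bin.

    Bins: high r >= 0.75, medium 0.50 <= r < 0.75, low 0.25 <= r < 0.50,
    zero r < 0.25. Applies to the raw matrix (the stabilized one would
    inflate the top bin by construction).
    """
    if m.stabilized:
        raise ValueError("bin diagram is defined on the raw similarity matrix")
    counts = {name: 0 for name in BIN_EDGES}
    pairs: dict[str, list[tuple[str, str]]] = {name: [] for name in BIN_EDGES}
    n = m.n_items
    for i in range(n):
        for j in range(i + 1, n):
            r = m.values[i, j]
            if r >= 0.75:
                name = "high"
            elif r >= 0.50:
                name = "medium"
            elif r >= 0.25:
                name = "low"
            else:
                name = "zero"
            counts[name] += 1
            pairs[name].append((m.item_ids[i], m.item_ids[j]))
    return BinDiagram(counts, pairs)
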