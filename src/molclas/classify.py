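"""Entropy-based classification of compounds from a similarity matrix.

The pipeline, for a chosen grouping level ``b`` in [0, 1]:

1. *Stabilize* the raw similarity matrix by iterating the max-min
   composition ``(R o R)_ij = max_k min(r_ik, r_kj)`` to its fixed point.
   The result is min-transitive (``r_ik >= min(r_ij, r_jk)`` for every
   triple), so thresholding it yields a genuine equivalence relation.
2. *Group*: items i, j share a class iff the stabilized ``r_ij >= b``.
3. Build the *class matrix*: off-diagonal (A, B) entries are the largest
   RAW similarity between a member of A and a member of B; the diagonal
   is the self-similarity of the weight scheme.
4. Score the classification by its *information entropy*

       h = sum over all N^2 class-matrix entries of
           -x ln x - (1 - x) ln(1 - x)

   (natural log, 0 ln 0 := 0). Entropy falls monotonically as classes
   merge: coarser classifications carry less residual imprecision.

Scanning b from 1 down to 0 produces an entropy-vs-level staircase. The
*equipartition conjecture* prefers, among candidate weight schemes, the
one whose staircase is closest (least squared deviation) to the straight
line ``h = h_max * b`` — entropy production spread most uniformly across
levels. A seeded stochastic hill climb (``learn_weights``) searches
weight schemes whose similarity matrix is closest to a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import xlogy

from .datamodel import (
    EntropyProfile,
    Partition,
    PropertyVector,
    SimilarityMatrix,
    WeightScheme,
)
from .similarity import similarity_matrix

__all__ = [
    "stabilize",
    "group",
    "class_matrix",
    "entropy",
    "binary_entropy",
    "level_scan",
    "auto_levels",
    "equipartition_ssd",
    "select_by_equipartition",
    "distance_between",
    "LearningConfig",
    "learn_weights",
    "DendrogramNode",
    "dendrogram",
]


# ---------------------------------------------------------------------------
# stabilization and grouping


def _maxmin_compose(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """(R o S)_ij = max_k min(r_ik, s_kj) — matrix product under (min, max)."""
    return np.minimum(r[:, :, None], s[None, :, :]).max(axis=1)


def stabilize(m: SimilarityMatrix, max_iter: int = 1000) -> SimilarityMatrix:
    """Min-transitive closure of a similarity matrix via max-min composition.

    Iterates ``R(n+1) = R(n) o R`` until the fixed point. Entries only
    grow (``r_ij(n) >= r_ij``): the stabilized value of a pair is the
    best "path" between them, maximizing over chains the weakest link.
    Idempotent; a 2-item matrix is already stable.
    """
    r = m.values
    for _ in range(max_iter):
        nxt = np.maximum(r, _maxmin_compose(r, m.values))
        if np.array_equal(nxt, r):
            break
        r = nxt
    else:  # pragma: no cover - closure converges in <= n iterations
        raise RuntimeError("max-min composition failed to converge")
    return SimilarityMatrix(r, m.item_ids, m.weight_scheme, stabilized=True)


def group(m_stab: SimilarityMatrix, b: float) -> Partition:
    """Partition items into classes of the relation ``r_ij(n) >= b``.

    Requires a stabilized matrix (min-transitivity guarantees the
    relation is an equivalence). Classes are returned in order of first
    member appearance; members keep input order.
    """
    if not m_stab.stabilized:
        raise ValueError("grouping requires a stabilized matrix; call stabilize() first")
    if not (0.0 <= b <= 1.0):
        raise ValueError(f"grouping level b={b} outside [0, 1]")
    n = m_stab.n_items
    classes: list[list[int]] = []
    for i in range(n):
        for cls in classes:
            if m_stab.values[i, cls[0]] >= b:
                cls.append(i)
                break
        else:
            classes.append([i])
    ids = m_stab.item_ids
    return Partition(
        level_b=b,
        classes=tuple(tuple(ids[i] for i in cls) for cls in classes),
    )


def class_matrix(raw: SimilarityMatrix, p: Partition) -> np.ndarray:
    """Similarity matrix between classes.

    Off-diagonal (A, B) = max over s in A, t in B of the RAW r_st —
    the closest pair across the two classes. Diagonal = self-similarity
    of the weight scheme. For the all-singletons partition this is the
    raw matrix itself.
    """
    index = {item: i for i, item in enumerate(raw.item_ids)}
    if sorted(index) != sorted(p.items()):
        raise ValueError("partition does not cover exactly the matrix items")
    groups = [[index[item] for item in cls] for cls in p.classes]
    m = len(groups)
    out = np.empty((m, m))
    np.fill_diagonal(out, raw.weight_scheme.self_similarity)
    for a in range(m):
        for b_ in range(a + 1, m):
            v = raw.values[np.ix_(groups[a], groups[b_])].max()
            out[a, b_] = out[b_, a] = v
    return out


# ---------------------------------------------------------------------------
# information entropy


def binary_entropy(x: np.ndarray | float) -> np.ndarray:
    """Elementwise -x ln x - (1-x) ln(1-x), with 0 ln 0 := 0."""
    x = np.asarray(x, dtype=float)
    return -(xlogy(x, x) + xlogy(1.0 - x, 1.0 - x))


def entropy(mat: np.ndarray) -> float:
    """Information entropy of a similarity (or class) matrix.

    Sums the binary Shannon entropy of every one of the N^2 entries,
    diagonal included, in natural-log units. Zero iff all entries are
    crisp (0 or 1); each entry contributes most at 0.5, where the
    similarity statement is maximally imprecise.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.min() < -1e-12 or mat.max() > 1 + 1e-12:
        raise ValueError("entropy requires entries in [0, 1]")
    return float(binary_entropy(np.clip(mat, 0.0, 1.0)).sum())


# ---------------------------------------------------------------------------
# level scans and equipartition


def auto_levels(m_stab: SimilarityMatrix) -> list[float]:
    """Every grouping level at which the partition can change.

    Distinct stabilized off-diagonal values are the merge points; 1.0 is
    prepended so the scan always starts from all singletons.
    """
    vals = set(np.round(m_stab.off_diagonal_values(), 12))
    return sorted(vals | {1.0}, reverse=True)


def level_scan(
    raw: SimilarityMatrix,
    levels: Sequence[float] | None = None,
) -> EntropyProfile:
    """Classify at each level and record (b, n_classes, entropy) rows.

    ``levels=None`` scans all distinct merge points of the stabilized
    matrix. ``h_max`` is the entropy of the finest classification
    (b = 1, all singletons), i.e. of the raw matrix itself, and anchors
    the equipartition line. The profile's ``ssd`` is filled in.
    """
    stab = stabilize(raw)
    lv = sorted(levels, reverse=True) if levels is not None else auto_levels(stab)
    h_max = entropy(class_matrix(raw, group(stab, 1.0)))
    rows = []
    for b in lv:
        part = group(stab, b)
        h = entropy(class_matrix(raw, part))
        rows.append((float(b), part.n_classes, h))
    profile = EntropyProfile(rows=tuple(rows), h_max=h_max)
    profile.ssd = equipartition_ssd(profile)
    return profile


def equipartition_ssd(profile: EntropyProfile) -> float:
    """Squared deviation of the h-b staircase from the line h = h_max * b."""
    if not profile.rows:
        raise ValueError("empty entropy profile")
    h = profile.entropies()
    b = profile.levels()
    return float(((h - profile.h_max * b) ** 2).sum())


def select_by_equipartition(
    candidates: Sequence[WeightScheme],
    items: Sequence[PropertyVector],
    levels: Sequence[float] | None = None,
) -> tuple[WeightScheme, list[float]]:
    """Pick the weight scheme whose scan best matches equipartition.

    Evaluates every candidate's level scan and returns the one with the
    smallest sum of squared deviations (ties: first occurrence), along
    with all candidate SSDs in input order.
    """
    if not candidates:
        raise ValueError("no candidate weight schemes")
    ssds = [
        level_scan(similarity_matrix(items, w), levels).ssd  # type: ignore[arg-type]
        for w in candidates
    ]
    best = int(np.argmin(ssds))
    return candidates[best], [float(x) for x in ssds]


# ---------------------------------------------------------------------------
# distance between similarity matrices, weight learning


def _sym_kl_terms(r: np.ndarray, s: np.ndarray, eps: float) -> np.ndarray:
    r = np.clip(r, eps, 1.0 - eps)
    s = np.clip(s, eps, 1.0 - eps)
    return (r - s) * (np.log(r / s) - np.log((1.0 - r) / (1.0 - s)))


def distance_between(
    r: SimilarityMatrix,
    s: SimilarityMatrix,
    divergence: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    eps: float = 1e-12,
) -> float:
    """Divergence between two similarity matrices of the same items.

    Default form: each entry pair is treated as two Bernoulli
    probabilities and scored by the symmetrized Kullback-Leibler
    divergence

        (r - s) * [ln(r/s) - ln((1-r)/(1-s))],

    summed over all ordered entries. Nonnegative, symmetric, zero iff
    the matrices are equal; endpoints are guarded by ``eps``. Pass
    ``divergence`` to plug in another elementwise form.
    """
    if r.values.shape != s.values.shape:
        raise ValueError("matrices must have the same shape")
    if divergence is None:
        terms = _sym_kl_terms(r.values, s.values, eps)
    else:
        terms = divergence(r.values, s.values)
    return float(np.sum(terms))


@dataclass
class LearningConfig:
    """Controls for the stochastic weight-learning loop.

    The first weight ``a_1`` is held fixed (it sets the scale of the
    scheme); only ``a_2..a_k`` are perturbed.
    """

    reference: SimilarityMatrix
    n_iterations: int = 1000
    step_size: float = 0.05
    seed: int = 0
    fixed_first_weight: bool = True
    initial: WeightScheme | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")


@dataclass
class LearningTrace:
    """Accepted steps of a learning run: (iteration, distance) pairs."""

    steps: list[tuple[int, float]] = field(default_factory=list)

    def distances(self) -> list[float]:
        return [d for _, d in self.steps]


def learn_weights(
    items: Sequence[PropertyVector],
    cfg: LearningConfig,
) -> tuple[WeightScheme, LearningTrace]:
    """Seeded hill climb over weight schemes toward a reference matrix.

    Starting from ``cfg.initial`` (default: equal weights 0.5), each
    iteration perturbs the free weights with Gaussian noise of scale
    ``step_size`` (clipped to [0, 1]) and keeps the move iff it lowers
    ``distance_between(similarity_matrix(items, a), reference)``. The
    accepted-step trace is therefore monotone nonincreasing, and runs
    with the same seed are identical.
    """
    k = len(items[0])
    scheme = cfg.initial if cfg.initial is not None else WeightScheme.equal(k)
    if scheme.n_positions != k:
        raise ValueError("initial scheme does not cover all positions")
    rng = np.random.default_rng(cfg.seed)
    ref = cfg.reference

    def score(w: WeightScheme) -> float:
        return distance_between(similarity_matrix(items, w, ref.item_ids), ref)

    best = np.asarray(scheme.a, dtype=float)
    best_d = score(scheme)
    trace = LearningTrace(steps=[(0, best_d)])
    lo = 1 if cfg.fixed_first_weight else 0
    ranks = np.arange(1, k + 1)
    for it in range(1, cfg.n_iterations + 1):
        cand = best.copy()
        cand[lo:] = np.clip(cand[lo:] + rng.normal(0.0, cfg.step_size, k - lo), 0.0, 1.0)
        if (cand**ranks).sum() > 1.0:  # infeasible: similarities would leave [0, 1]
            continue
        d = score(WeightScheme(tuple(cand)))
        if d < best_d:
            best, best_d = cand, d
            trace.steps.append((it, d))
    return WeightScheme(tuple(best)), trace


# ---------------------------------------------------------------------------
# dendrograms


@dataclass
class DendrogramNode:
    """Binary (or multifurcating, in threshold mode) merge-tree node.

    ``height`` is 1 - merge similarity; leaves sit at height 0.
    """

    name: str | None = None
    height: float = 0.0
    children: list["DendrogramNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        return [leaf for c in self.children for leaf in c.leaves()]

    def cut(self, b: float) -> Partition:
        """Partition obtained by cutting the tree at grouping level b."""
        height = 1.0 - b
        classes: list[tuple[str, ...]] = []

        def walk(node: DendrogramNode) -> None:
            if node.is_leaf or node.height <= height + 1e-12:
                classes.append(tuple(node.leaves()))
            else:
                for c in node.children:
                    walk(c)

        walk(self)
        return Partition(level_b=b, classes=tuple(classes))


def _threshold_tree(raw: SimilarityMatrix) -> DendrogramNode:
    stab = stabilize(raw)
    nodes = [DendrogramNode(name=i) for i in raw.item_ids]
    clusters: list[tuple[DendrogramNode, list[int]]] = [
        (nodes[i], [i]) for i in range(raw.n_items)
    ]
    for b in auto_levels(stab):
        if b >= 1.0 or len(clusters) == 1:
            continue
        part = group(stab, b)
        # merge clusters that now share a class, preserving input order
        cls_of = {item: ci for ci, cls in enumerate(part.classes) for item in cls}
        merged: dict[int, list[tuple[DendrogramNode, list[int]]]] = {}
        order: list[int] = []
        for node, members in clusters:
            ci = cls_of[raw.item_ids[members[0]]]
            if ci not in merged:
                merged[ci] = []
                order.append(ci)
            merged[ci].append((node, members))
        new_clusters = []
        for ci in order:
            parts = merged[ci]
            if len(parts) == 1:
                new_clusters.append(parts[0])
            else:
                node = DendrogramNode(
                    height=1.0 - b, children=[p[0] for p in parts]
                )
                new_clusters.append((node, [i for p in parts for i in p[1]]))
        clusters = new_clusters
    if len(clusters) > 1:  # disconnected at every level > 0: join at height 1
        return DendrogramNode(height=1.0, children=[c[0] for c in clusters])
    return clusters[0][0]


def _scipy_tree(raw: SimilarityMatrix, method: str) -> DendrogramNode:
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    d = 1.0 - raw.values
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method=method)
    nodes = [DendrogramNode(name=i) for i in raw.item_ids]
    for row in z:
        a, b_, dist = int(row[0]), int(row[1]), float(row[2])
        nodes.append(DendrogramNode(height=dist, children=[nodes[a], nodes[b_]]))
    return nodes[-1]


def dendrogram(raw: SimilarityMatrix, linkage: str = "threshold") -> DendrogramNode:
    """Merge tree of the items under the chosen linkage.

    ``threshold`` (default) merges exactly at the distinct
    stabilized-similarity levels — equivalent to single linkage under
    the max-min closure but possibly multifurcating. ``single`` and
    ``complete`` run standard agglomerative linkage on d = 1 - r.
    Node heights are 1 - merge similarity in all modes.
    """
    if raw.n_items < 2:
        raise ValueError("need at least two items")
    if linkage == "threshold":
        return _threshold_tree(raw)
    if linkage in ("single", "complete"):
        return _scipy_tree(raw, linkage)
    raise ValueError(f"unknown linkage {linkage!r}")
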