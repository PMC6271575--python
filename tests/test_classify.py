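"""Stabilization, grouping, entropy, equipartition, learning, dendrograms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molclas import (
    LearningConfig,
    WeightScheme,
    class_matrix,
    dendrogram,
    distance_between,
    entropy,
    equipartition_ssd,
    generate_reference_scheme,
    generate_vectors,
    group,
    learn_weights,
    level_scan,
    select_by_equipartition,
    similarity_matrix,
    stabilize,
)
from molclas.classify import auto_levels
from molclas.datamodel import EntropyProfile
from molclas.io import to_newick

TABLE2_LEVELS = (1.00, 0.98, 0.96, 0.93, 0.87, 0.76, 0.51, 0.10)
TABLE2_COUNTS = (9, 7, 6, 5, 4, 3, 2, 1)
TABLE2_ENTROPIES = (32.49, 20.01, 15.13, 10.70, 6.77, 3.71, 1.47, 0.08)


def maxmin_path_oracle(values: np.ndarray) -> np.ndarray:
    """Brute-force closure: best path between i and j, maximizing the
    weakest link, enumerated over all simple paths (small n only)."""
    n = values.shape[0]
    out = values.copy()
    for i, j in itertools.combinations(range(n), 2):
        best = values[i, j]
        others = [k for k in range(n) if k not in (i, j)]
        for r in range(1, len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (i, *mid, j)
                weakest = min(values[a, b] for a, b in zip(path, path[1:]))
                best = max(best, weakest)
        out[i, j] = out[j, i] = best
    return out


# ---------------------------------------------------------------------------
# stabilization


def test_stabilize_matches_path_oracle_on_benchmark(raw_matrix):
    stab = stabilize(raw_matrix)
    assert np.allclose(stab.values, maxmin_path_oracle(raw_matrix.values))
    # thiabendazole-diazinone rises from 0.765625 via the TPP bridge
    assert raw_matrix.values[2, 6] == pytest.approx(0.765625)
    assert stab.values[2, 6] == pytest.approx(0.828125)


@pytest.mark.parametrize("seed", range(6))
def test_stabilize_oracle_idempotence_and_transitivity_synthetic(seed):
    items = generate_vectors(seed % 3 + 5, 6, 0.5, seed=seed)  # n = 5..7
    m = similarity_matrix(items)
    stab = stabilize(m)
    assert np.allclose(stab.values, maxmin_path_oracle(m.values))
    # idempotent and elementwise >= raw
    again = stabilize(stab)
    assert np.array_equal(again.values, stab.values)
    assert np.all(stab.values >= m.values - 1e-15)
    # min-transitivity over every triple
    v = stab.values
    n = len(items)
    for i, j, k in itertools.product(range(n), repeat=3):
        assert v[i, k] >= min(v[i, j], v[j, k]) - 1e-12


def test_two_item_matrix_already_stable():
    items = generate_vectors(2, 6, 0.5, seed=3)
    m = similarity_matrix(items)
    assert np.array_equal(stabilize(m).values, m.values)


# ---------------------------------------------------------------------------
# grouping and class matrices


def test_benchmark_partitions_at_printed_levels(raw_matrix):
    stab = stabilize(raw_matrix)
    p93 = group(stab, 0.93)
    assert [len(c) for c in p93.classes] == [1, 1, 3, 1, 3]
    assert p93.classes[2] == ("Thiabendazole", "Pyrimethanil", "Cyprodinil")
    assert p93.classes[4] == ("Diazinone", "Pyrazophos", "Chlorpyrifos")
    p76 = group(stab, 0.76)
    assert [len(c) for c in p76.classes] == [1, 1, 7]
    # above the self-similarity no off-diagonal entry qualifies
    assert group(stab, 0.99).n_classes == 9
    assert group(stab, 0.0).n_classes == 1


def test_group_requires_stabilized_matrix(raw_matrix):
    with pytest.raises(ValueError, match="stabilized"):
        group(raw_matrix, 0.9)


def test_class_matrix_takes_max_raw_cross_similarity(raw_matrix):
    stab = stabilize(raw_matrix)
    p = group(stab, 0.93)
    cm = class_matrix(raw_matrix, p)
    # ({TPP}, {diazinone, pyrazophos, chlorpyrifos}) -> max raw r
    assert cm[3, 4] == pytest.approx(0.921875)
    assert np.allclose(np.diag(cm), 0.984375)
    # singletons reproduce the raw matrix; one class collapses to 1x1
    singles = group(stab, 1.0)
    assert np.allclose(class_matrix(raw_matrix, singles), raw_matrix.values)
    one = group(stab, 0.0)
    assert class_matrix(raw_matrix, one).shape == (1, 1)


# ---------------------------------------------------------------------------
# entropy


def test_entropy_printed_values(raw_matrix):
    stab = stabilize(raw_matrix)
    cm93 = class_matrix(raw_matrix, group(stab, 0.93))
    assert entropy(cm93) == pytest.approx(10.70, abs=0.01)
    assert entropy(raw_matrix.values) == pytest.approx(32.49, abs=0.01)
    cm10 = class_matrix(raw_matrix, group(stab, 0.10))
    assert entropy(cm10) == pytest.approx(0.08, abs=0.01)


def test_entropy_edge_cases():
    assert entropy(np.array([[0.5]])) == pytest.approx(math.log(2))
    assert entropy(np.array([[0.0, 1.0], [1.0, 0.0]])) == 0.0
    with pytest.raises(ValueError):
        entropy(np.array([[1.5]]))


def test_level_scan_reproduces_printed_staircase(raw_matrix):
    profile = level_scan(raw_matrix, TABLE2_LEVELS)
    assert tuple(profile.class_counts()) == TABLE2_COUNTS
    assert np.allclose(profile.entropies(), TABLE2_ENTROPIES, atol=0.01)
    assert profile.h_max == pytest.approx(32.49, abs=0.01)


def test_auto_levels_hit_every_merge_point(raw_matrix):
    stab = stabilize(raw_matrix)
    profile = level_scan(raw_matrix)
    # 3 identical-vector pairs merge simultaneously, so 8 never occurs;
    # the reachable counts are exactly those of the published scan
    assert sorted(set(profile.class_counts())) == [1, 2, 3, 4, 5, 6, 7, 9]
    assert 1.0 in auto_levels(stab)


@pytest.mark.parametrize("seed", range(25))
def test_nesting_and_entropy_monotone_on_random_sets(seed):
    """Coarser levels merge whole classes and never gain entropy."""
    items = generate_vectors(9, 6, 0.5, seed=seed)
    raw = similarity_matrix(items)
    stab = stabilize(raw)
    levels = auto_levels(stab)
    prev_part, prev_h = None, None
    for b in levels:  # descending
        part = group(stab, b)
        h = entropy(class_matrix(raw, part))
        if prev_part is not None:
            # each finer class is inside one coarser class
            for fine in prev_part.as_sets():
                assert any(fine <= coarse for coarse in part.as_sets())
            assert h <= prev_h + 1e-9
        prev_part, prev_h = part, h


# ---------------------------------------------------------------------------
# equipartition


def test_equipartition_ssd_arithmetic():
    rows = tuple(zip(TABLE2_LEVELS, TABLE2_COUNTS, TABLE2_ENTROPIES))
    profile = EntropyProfile(rows=rows, h_max=32.49)
    expected = sum((h - 32.49 * b) ** 2 for b, _, h in rows)
    assert equipartition_ssd(profile) == pytest.approx(expected)
    # a staircase exactly on the line has zero deviation
    on_line = EntropyProfile(
        rows=tuple((b, 1, 32.49 * b) for b in TABLE2_LEVELS), h_max=32.49
    )
    assert equipartition_ssd(on_line) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        equipartition_ssd(EntropyProfile(rows=(), h_max=1.0))


def test_select_by_equipartition_matches_exhaustive_argmin():
    items = generate_vectors(8, 6, 0.5, seed=42)
    candidates = [WeightScheme.equal(6, a) for a in (0.2, 0.3, 0.4, 0.5)]
    best, ssds = select_by_equipartition(candidates, items)
    assert best is candidates[int(np.argmin(ssds))]
    # brute-force recomputation of each candidate's SSD
    for w, ssd in zip(candidates, ssds):
        assert level_scan(similarity_matrix(items, w)).ssd == pytest.approx(ssd)
    single, _ = select_by_equipartition([candidates[0]], items)
    assert single is candidates[0]


# ---------------------------------------------------------------------------
# distance and learning


def test_distance_is_a_premetric(raw_matrix):
    stab = stabilize(raw_matrix)
    assert distance_between(raw_matrix, raw_matrix) == 0.0
    d1 = distance_between(raw_matrix, stab)
    assert d1 > 0
    assert distance_between(stab, raw_matrix) == pytest.approx(d1)


def test_distance_grows_with_perturbation_size():
    items = generate_vectors(3, 6, 0.5, seed=5)
    m = similarity_matrix(items)
    dists = []
    for eps in (0.01, 0.02, 0.05, 0.1):
        shifted = np.clip(m.values + eps * (1 - np.eye(3)), 0, 1)
        pert = similarity_matrix(items)  # same metadata
        pert.values = np.maximum(shifted, shifted.T)
        dists.append(distance_between(m, pert))
    assert dists == sorted(dists)
    assert dists[0] > 0


def test_learn_weights_recovers_hidden_scheme():
    hidden, reference, items = generate_reference_scheme(6, seed=11)
    cfg = LearningConfig(reference=reference, n_iterations=2000, step_size=0.05, seed=7)
    scheme, trace = learn_weights(items, cfg)
    d = trace.distances()
    assert d == sorted(d, reverse=True)  # monotone nonincreasing
    assert d[-1] <= 0.1 * d[0]  # >= 90% reduction
    # matched-level classifications agree with the reference's
    learned = similarity_matrix(items, scheme)
    for b in (0.5, 0.7):
        got = group(stabilize(learned), b).as_sets()
        want = group(stabilize(reference), b).as_sets()
        assert got == want


def test_learn_weights_deterministic_and_degenerate_cases():
    _, reference, items = generate_reference_scheme(6, seed=11)
    cfg = LearningConfig(reference=reference, n_iterations=200, step_size=0.05, seed=3)
    s1, t1 = learn_weights(items, cfg)
    s2, t2 = learn_weights(items, cfg)
    assert s1.a == s2.a and t1.steps == t2.steps
    # zero iterations: initial scheme unchanged
    s0, t0 = learn_weights(items, LearningConfig(reference=reference, n_iterations=0))
    assert s0.a == WeightScheme.equal(6).a and len(t0.steps) == 1
    # reference built from the initial scheme: distance 0, nothing accepted
    ref0 = similarity_matrix(items, WeightScheme.equal(6), reference.item_ids)
    _, tref = learn_weights(items, LearningConfig(reference=ref0, n_iterations=100, seed=1))
    assert tref.distances()[0] == pytest.approx(0.0, abs=1e-9)
    assert len(tref.steps) == 1
    with pytest.raises(ValueError):
        LearningConfig(reference=reference, step_size=0.0)


# ---------------------------------------------------------------------------
# dendrograms


def test_threshold_dendrogram_cuts_match_partitions(raw_matrix):
    tree = dendrogram(raw_matrix, "threshold")
    assert sorted(tree.leaves()) == sorted(raw_matrix.item_ids)
    cut93 = tree.cut(0.93)
    stab = stabilize(raw_matrix)
    assert cut93.as_sets() == group(stab, 0.93).as_sets()
    assert tree.cut(0.76).n_classes == 3
    assert tree.cut(0.87).n_classes == 4


def test_two_items_merge_at_their_similarity():
    items = generate_vectors(2, 6, 0.5, seed=1)
    m = similarity_matrix(items)
    tree = dendrogram(m, "threshold")
    assert tree.height == pytest.approx(1.0 - m.values[0, 1])
    assert len(tree.children) == 2


def test_single_linkage_agrees_with_threshold_partitions(raw_matrix):
    """Under max-min closure, single linkage gives the same flat cuts."""
    single = dendrogram(raw_matrix, "single")
    threshold = dendrogram(raw_matrix, "threshold")
    for b in (0.93, 0.87, 0.76, 0.51):
        assert single.cut(b).as_sets() == threshold.cut(b).as_sets()


def test_newick_export_is_well_formed(raw_matrix):
    nwk = to_newick(dendrogram(raw_matrix))
    assert nwk.endswith(";")
    assert nwk.count("(") == nwk.count(")")
    for name in raw_matrix.item_ids:
        assert name in nwk
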