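"""Mutual-information similarity, Ward clustering, exclusivity, Newick."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from drugspread.events_io import AdoptionRecord
from drugspread.taxonomy import (
    BernoulliJoint,
    bernoulli_joint,
    build_drug_sets,
    exclusivity,
    export_newick,
    mi_similarity_matrix,
    mi_to_distance,
    mutual_information,
    newick_string,
    ward_cluster,
)


def _adoptions(sets: dict[str, set[str]]) -> list[AdoptionRecord]:
    return [
        AdoptionRecord(time=2000.0, drug_id=d, disease_id=dis)
        for dis, drugs in sets.items()
        for d in drugs
    ]


def _sets(raw: dict[str, set[str]], min_drugs: int = 1):
    return build_drug_sets(_adoptions(raw), min_drugs=min_drugs)


def test_build_drug_sets_threshold():
    raw = {"X": {"a", "b", "c"}, "Y": {"a"}, "Z": {"b", "c"}}
    sets = build_drug_sets(_adoptions(raw), min_drugs=2)
    assert set(sets.sets) == {"X", "Z"}
    assert sets.universe == {"a", "b", "c"}
    all_kept = build_drug_sets(_adoptions(raw), min_drugs=1)
    assert set(all_kept.sets) == {"X", "Y", "Z"}


def test_build_drug_sets_threshold_too_high():
    with pytest.raises(ValueError, match="no disease adopted"):
        build_drug_sets(_adoptions({"X": {"a", "b"}}), min_drugs=3)


def test_bernoulli_joint_enumerable():
    sets = _sets({"X": {"a", "b"}, "Y": {"a", "c"}, "W": {"d"}})
    joint = bernoulli_joint(sets, "X", "Y")
    assert joint.n == 4
    # neither, j-only / i-only, both
    assert joint.counts.tolist() == [[1, 1], [1, 1]]
    assert joint.probs.sum() == 1.0


def test_bernoulli_joint_identical_sets():
    sets = _sets({"X": {"a", "b"}, "Y": {"a", "b"}, "W": {"c"}})
    joint = bernoulli_joint(sets, "X", "Y")
    assert joint.counts[1, 0] == 0 and joint.counts[0, 1] == 0


def test_bernoulli_joint_matches_brute_force():
    rng = np.random.default_rng(21)
    drugs = [f"d{i}" for i in range(30)]
    raw = {
        dis: {d for d in drugs if rng.random() < 0.4} | {f"seed_{dis}"}
        for dis in ["A", "B", "C"]
    }
    sets = _sets(raw)
    joint = bernoulli_joint(sets, "A", "B")
    counts = np.zeros((2, 2), dtype=int)
    for d in sets.universe:
        counts[int(d in sets.sets["A"]), int(d in sets.sets["B"])] += 1
    assert joint.counts.tolist() == counts.tolist()


def test_mutual_information_independence_and_dependence():
    independent = BernoulliJoint(counts=np.array([[1, 1], [1, 1]]), n=4)
    assert mutual_information(independent) == 0.0
    dependent = BernoulliJoint(counts=np.array([[1, 0], [0, 1]]), n=2)
    assert mutual_information(dependent) == pytest.approx(math.log(2))


@given(
    c=st.tuples(*(st.integers(min_value=0, max_value=50) for _ in range(4))).filter(
        lambda c: sum(c) > 0
    )
)
def test_mutual_information_matches_direct_sum(c):
    counts = np.array(c).reshape(2, 2)
    n = int(counts.sum())
    joint = BernoulliJoint(counts=counts, n=n)
    p = counts / n
    px, py = p.sum(axis=1), p.sum(axis=0)
    expected = sum(
        p[x, y] * math.log(p[x, y] / (px[x] * py[y]))
        for x in (0, 1)
        for y in (0, 1)
        if p[x, y] > 0
    )
    assert mutual_information(joint) == pytest.approx(max(expected, 0.0), abs=1e-12)
    assert mutual_information(joint) >= 0.0


def test_mi_matrix_symmetric_and_bounded_by_entropy():
    rng = np.random.default_rng(22)
    drugs = [f"d{i}" for i in range(40)]
    raw = {dis: {d for d in drugs if rng.random() < 0.5} for dis in "ABCDE"}
    raw = {k: v for k, v in raw.items() if v}
    sets = _sets(raw)
    m = mi_similarity_matrix(sets)
    assert np.allclose(m.to_numpy(), m.to_numpy().T)
    for i in m.index:
        for j in m.columns:
            if i != j:
                assert m.loc[i, j] <= min(m.loc[i, i], m.loc[j, j]) + 1e-12
                assert m.loc[i, j] >= 0


def test_mi_invariant_under_drug_relabeling():
    raw = {"X": {"a", "b", "c"}, "Y": {"b", "c", "d"}, "Z": {"e"}}
    relabeled = {
        dis: {f"rx_{d}" for d in drugs} for dis, drugs in raw.items()
    }
    m1 = mi_similarity_matrix(_sets(raw))
    m2 = mi_similarity_matrix(_sets(relabeled))
    assert np.allclose(m1.to_numpy(), m2.to_numpy())


def test_mi_to_distance_properties():
    sim = pd.DataFrame(
        [[1.0, 0.4, 0.0], [0.4, 1.2, 0.1], [0.0, 0.1, 0.9]],
        index=list("ABC"),
        columns=list("ABC"),
    )
    d = mi_to_distance(sim)
    assert d.loc["A", "B"] == 0.0  # the pair attaining I_max
    assert d.loc["A", "C"] == pytest.approx(0.4)  # I = 0 -> distance I_max
    assert np.all(np.diag(d.to_numpy()) == 0)
    # monotone decreasing in similarity
    off = [(i, j) for i in d.index for j in d.columns if i < j]
    for (i1, j1) in off:
        for (i2, j2) in off:
            if sim.loc[i1, j1] > sim.loc[i2, j2]:
                assert d.loc[i1, j1] < d.loc[i2, j2]


def _naive_ward(d: np.ndarray):
    """O(n^3) Ward via the Lance-Williams recurrence; lowest-index ties."""
    n = d.shape[0]
    d = d.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = min(
            ((dist[tuple(sorted((a, b)))], a, b) for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        merges.append((min(a, b), max(a, b), h, sizes[a] + sizes[b]))
        for c in active:
            if c in (a, b):
                continue
            na, nb, nc = sizes[a], sizes[b], sizes[c]
            dac = dist[tuple(sorted((a, c)))]
            dbc = dist[tuple(sorted((b, c)))]
            dab = dist[tuple(sorted((a, b)))]
            new = math.sqrt(
                ((na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * dab**2) / (na + nb + nc)
            )
            dist[tuple(sorted((next_id, c)))] = new
        sizes[next_id] = sizes[a] + sizes[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return merges


def _random_distance_matrix(rng, n):
    m = rng.random((n, n)) + 0.1
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_ward_matches_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    m = _random_distance_matrix(rng, 8)
    labels = [f"L{i}" for i in range(8)]
    tree = ward_cluster(pd.DataFrame(m, index=labels, columns=labels))
    naive = _naive_ward(m)
    heights_scipy = sorted(tree.heights)
    heights_naive = sorted(h for (_, _, h, _) in naive)
    assert np.allclose(heights_scipy, heights_naive)
    sizes_scipy = sorted(tree.linkage_matrix[:, 3])
    sizes_naive = sorted(s for (_, _, _, s) in naive)
    assert sizes_scipy == pytest.approx(sizes_naive)


def test_ward_identical_leaves_merge_first():
    m = np.array(
        [
            [0.0, 0.0, 5.0],
            [0.0, 0.0, 5.0],
            [5.0, 5.0, 0.0],
        ]
    )
    tree = ward_cluster(pd.DataFrame(m, index=list("ABC"), columns=list("ABC")))
    first = tree.linkage_matrix[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == 0.0


def test_ward_two_separated_pairs():
    m = np.full((4, 4), 10.0)
    np.fill_diagonal(m, 0.0)
    m[0, 1] = m[1, 0] = 0.5
    m[2, 3] = m[3, 2] = 0.5
    tree = ward_cluster(pd.DataFrame(m, index=list("ABCD"), columns=list("ABCD")))
    merged = [{int(r[0]), int(r[1])} for r in tree.linkage_matrix[:2]]
    assert {0, 1} in merged and {2, 3} in merged


def test_ward_rejects_asymmetric():
    m = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        ward_cluster(pd.DataFrame(m, index=list("AB"), columns=list("AB")))


def test_block_structure_recovered_in_top_split():
    # Two groups of diseases sharing drugs within groups only.  Within-group
    # similarity must come from strong overlap (a shared core): MI is an
    # unsigned dependence measure, so two large disjoint sets also score
    # high, and weakly overlapping groups would not separate.
    group1, group2 = ["A1", "A2", "A3"], ["B1", "B2", "B3"]
    core1 = {f"c1_{i}" for i in range(18)}
    core2 = {f"c2_{i}" for i in range(18)}
    raw = {}
    for k, dis in enumerate(group1):
        raw[dis] = core1 | {f"p1_{k}_{i}" for i in range(2)}
    for k, dis in enumerate(group2):
        raw[dis] = core2 | {f"p2_{k}_{i}" for i in range(2)}
    sets = _sets(raw)
    tree = ward_cluster(mi_to_distance(mi_similarity_matrix(sets)))
    t = dendropy.Tree.get(data=newick_string(tree), schema="newick")
    root_children = t.seed_node.child_nodes()
    sides = [
        {leaf.taxon.label for leaf in child.leaf_iter()} for child in root_children
    ]
    assert set(group1) in sides and set(group2) in sides


def test_exclusivity_counts():
    sets = _sets({"X": {"a", "b", "c", "d"}, "Y": {"d", "e"}})
    report = exclusivity(sets)
    assert report.loc["X", "n_drugs"] == 4
    assert report.loc["X", "n_exclusive"] == 3
    assert report.loc["X", "fraction_exclusive"] == 0.75
    shared = _sets({"X": {"a", "b"}, "Y": {"a", "b"}})
    rep2 = exclusivity(shared)
    assert (rep2["fraction_exclusive"] == 0.0).all()


def test_exclusivity_matches_brute_force():
    rng = np.random.default_rng(31)
    drugs = [f"d{i}" for i in range(25)]
    raw = {dis: {d for d in drugs if rng.random() < 0.4} for dis in "ABCD"}
    raw = {k: v for k, v in raw.items() if v}
    sets = _sets(raw)
    report = exclusivity(sets)
    for dis in sets.diseases:
        n_excl = sum(
            1
            for d in sets.sets[dis]
            if not any(d in sets.sets[o] for o in sets.diseases if o != dis)
        )
        assert report.loc[dis, "n_exclusive"] == n_excl


def test_newick_two_leaves(tmp_path):
    m = np.array([[0.0, 3.0], [3.0, 0.0]])
    tree = ward_cluster(pd.DataFrame(m, index=["A", "B"], columns=["A", "B"]))
    s = newick_string(tree)
    h = tree.heights[0]
    assert s == f"(A:{h:g},B:{h:g});"


def test_newick_roundtrip_topology(tmp_path):
    rng = np.random.default_rng(33)
    m = _random_distance_matrix(rng, 8)
    labels = [f"L{i}" for i in range(8)]
    tree = ward_cluster(pd.DataFrame(m, index=labels, columns=labels))
    path = tmp_path / "tree.nwk"
    export_newick(tree, path)
    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(labels)
    # every internal merge of the linkage appears as a clade in the parsed tree
    n = len(labels)
    Z = tree.linkage_matrix
    members = {i: {labels[i]} for i in range(n)}
    clades = []
    for k, row in enumerate(Z):
        members[n + k] = members[int(row[0])] | members[int(row[1])]
        clades.append(frozenset(members[n + k]))
    parsed_clades = {
        frozenset(leaf.taxon.label for leaf in nd.leaf_iter())
        for nd in parsed.preorder_internal_node_iter()
    }
    for clade in clades:
        assert clade in parsed_clades
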