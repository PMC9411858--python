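import itertools

import numpy as np
import pytest

from vhfold.repertoire import (EMBEDDING_DIM, StructuralDistanceMatrix,
                               cluster_cost, concordance, distance_matrix,
                               embed_sequences, k_medoids, project_2d,
                               read_distance_matrix, structural_distance,
                               write_distance_matrix)

from conftest import straight_structure


def test_distance_to_self_is_zero(family_records):
    s = family_records[0].structure
    assert structural_distance(s, s) == 0.0


def test_distance_one_when_no_ca_within_cutoff():
    a = straight_structure(10)
    b = straight_structure(10, offset=(0.0, 50.0, 0.0))
    assert structural_distance(a, b) == 1.0


def test_distance_arithmetic_with_partial_match():
    # |V| = 100, |W| = 50, exactly 25 matchable CA pairs -> 1 - 25/50 = 0.5
    v = straight_structure(100)
    w_matchable = straight_structure(25)
    w_far = straight_structure(25, offset=(0.0, 30.0, 0.0))
    w = straight_structure(50)
    for i in range(25):
        for name in w.residues[i].coords:
            w.residues[i].coords[name] = w_matchable.residues[i].coords[name]
    for i in range(25, 50):
        for name in w.residues[i].coords:
            w.residues[i].coords[name] = w_far.residues[i - 25].coords[name]
    assert structural_distance(v, w) == 0.5


def test_matching_is_one_to_one():
    # many V atoms near one W atom must yield at most one match per W atom
    v = straight_structure(10, spacing=0.2)  # all CAs within 1 A of each other
    w = straight_structure(2, spacing=50.0)
    d = structural_distance(v, w)
    assert d == 1.0 - 1 / 2  # only one pair can match


def test_distance_matrix_properties(family_records):
    structs = [r.structure for r in family_records[:6]]
    m = distance_matrix(structs, [r.record_id for r in family_records[:6]])
    m.validate()
    assert np.allclose(np.diag(m.D), 0.0)
    assert np.allclose(m.D, m.D.T)
    identical = distance_matrix([structs[0]] * 3, ids=["a", "b", "c"])
    assert np.allclose(identical.D, 0.0)


def test_k_medoids_recovers_two_separated_families():
    rng = np.random.default_rng(0)
    d = np.zeros((8, 8))
    labels = [0, 0, 0, 0, 1, 1, 1, 1]
    for i in range(8):
        for j in range(i + 1, 8):
            base = 0.05 if labels[i] == labels[j] else 0.8
            d[i, j] = d[j, i] = base + rng.uniform(0, 0.02)
    m = StructuralDistanceMatrix([str(i) for i in range(8)], d)
    assignment = k_medoids(m, k=2, seed=0, restarts=5)
    got = [assignment.labels[str(i)] for i in range(8)]
    assert len(set(got[:4])) == 1 and len(set(got[4:])) == 1
    assert got[0] != got[4]

    # brute force over all medoid pairs confirms PAM found the optimal cost
    costs = [np.minimum(d[:, a], d[:, b]).sum()
             for a, b in itertools.combinations(range(8), 2)]
    assert np.isclose(cluster_cost(m, assignment), min(costs))


def test_k_medoids_k_equals_n_and_determinism(family_records):
    structs = [r.structure for r in family_records[:5]]
    m = distance_matrix(structs, [r.record_id for r in family_records[:5]])
    full = k_medoids(m, k=5, seed=1)
    assert cluster_cost(m, full) == 0.0
    a1 = k_medoids(m, k=2, seed=7)
    a2 = k_medoids(m, k=2, seed=7)
    assert a1.labels == a2.labels and a1.medoids == a2.medoids
    with pytest.raises(ValueError):
        k_medoids(m, k=9)


def test_embedding_dimensions_and_block_structure(family_records):
    pairs = [(r.record_id, r.sequence) for r in family_records[:6]]
    ids, matrix, skipped = embed_sequences(pairs)
    assert not skipped
    assert matrix.shape == (6, EMBEDDING_DIM)
    assert EMBEDDING_DIM == 2646
    blocks = matrix.reshape(len(ids), 126, 21)
    assert np.all(blocks.sum(axis=2) == 1.0)  # each 21-block is one-hot
    # identical sequences embed identically
    ids2, m2, _ = embed_sequences([("x", pairs[0][1]), ("y", pairs[0][1])])
    assert np.array_equal(m2[0], m2[1])


def test_embedding_skips_unnumberable():
    good = ("ok", "A" * 21 + "C" + "AAA" + "AAAAA" + "W" + "A" * 18 + "AAAAA"
            + "A" * 31 + "C" + "AA" + "AAAAAAA" + "WGQG" + "A" * 8)
    bad = ("bad", "A" * 100)
    ids, matrix, skipped = embed_sequences([good, bad])
    assert skipped == ["bad"]
    assert ids == ["ok"]


def test_project_2d_contract(family_records):
    pairs = [(r.record_id, r.sequence) for r in family_records[:10]]
    _, matrix, _ = embed_sequences(pairs)
    matrix = np.vstack([matrix, matrix[:1]])  # plant a duplicate
    coords = project_2d(matrix, perplexity=5, seed=0)
    assert coords.shape == (11, 2)
    coords2 = project_2d(matrix, perplexity=5, seed=0)
    assert np.array_equal(coords, coords2)
    # the duplicated vector lands essentially on its twin
    spread = np.linalg.norm(coords - coords.mean(axis=0), axis=1).mean()
    assert np.linalg.norm(coords[0] - coords[10]) < 0.1 * spread
    with pytest.raises(ValueError):
        project_2d(matrix[:3], seed=0)


def test_concordance_cases():
    from vhfold.repertoire import ClusterAssignment
    labels = {f"s{i}": i // 4 for i in range(8)}
    assignment = ClusterAssignment(labels, ["s0", "s4"], 2)
    assert concordance(assignment, labels) == 1.0
    permuted = {k: 1 - v for k, v in labels.items()}
    assert concordance(assignment, permuted) == 1.0  # label names irrelevant
    one_cluster = {k: 0 for k in labels}
    assert concordance(assignment, one_cluster) <= 0.01
    with pytest.raises(ValueError):
        concordance(assignment, {"other": 0})


def test_distance_matrix_file_roundtrip(tmp_path, family_records):
    structs = [r.structure for r in family_records[:4]]
    m = distance_matrix(structs, ["a", "b", "c", "d"])
    path = str(tmp_path / "d.tsv")
    write_distance_matrix(m, path)
    back = read_distance_matrix(path)
    assert back.ids == m.ids
    assert np.allclose(back.D, m.D, atol=1e-12)
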