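import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhfold.dataset import (DatasetSplit, align_to_reference, decode_one_hot,
                            make_example, max_train_identity, one_hot_encode,
                            read_manifest, read_split, sequence_identity,
                            split_by_identity, write_manifest, write_split)
from vhfold.geometry import RigidTransform
from vhfold.structure_io import CANONICAL_AA

sequences = st.text(alphabet=CANONICAL_AA + "X", min_size=1, max_size=140)


def test_one_hot_shape_and_padding():
    mat = one_hot_encode("A" * 100)
    assert mat.shape == (140, 22)
    assert np.all(mat.sum(axis=1) == 1.0)
    assert mat[100:, 21].sum() == 40  # exactly 40 insertion-channel rows
    assert mat[:100, 21].sum() == 0


def test_one_hot_unknown_channel_and_errors():
    mat = one_hot_encode("AAAAAXAA")
    assert mat[5, 20] == 1.0 and mat[5].sum() == 1.0
    with pytest.raises(ValueError):
        one_hot_encode("")
    with pytest.raises(ValueError):
        one_hot_encode("A" * 141)
    with pytest.raises(ValueError):
        one_hot_encode("AB")


@settings(max_examples=50, derandomize=True)
@given(sequences)
def test_encoding_is_invertible(seq):
    assert decode_one_hot(one_hot_encode(seq)) == seq


def test_make_example_layout(family_records):
    rec = family_records[0]
    ex = make_example(rec.sequence, rec.structure, rec.record_id)
    n = len(rec.sequence)
    assert ex.mask.sum() == n
    assert np.all(ex.mask[n:] == 0)
    assert np.all(ex.target[n:] == 0.0)
    # CA triple occupies components 4-6 (0-based 3:6)
    ca = rec.structure.ca_coords()
    assert np.allclose(ex.target[:n, 3:6], ca)
    for i, aa in enumerate(rec.sequence):
        assert ex.cb_mask[i] == (0.0 if aa == "G" else 1.0)
        if aa == "G":
            assert np.all(ex.target[i, 12:15] == 0.0)
    with pytest.raises(ValueError):
        make_example(rec.sequence + "A", rec.structure)


def test_sequence_identity_closed_forms():
    assert sequence_identity("EVQLV", "EVQLV") == 100.0
    assert np.isclose(sequence_identity("AAAA", "AAAT"), 75.0)
    assert np.isclose(sequence_identity("AAAA", "AAA"),
                      sequence_identity("AAA", "AAAA"))


@settings(max_examples=25, derandomize=True)
@given(st.text(alphabet=CANONICAL_AA, min_size=3, max_size=30),
       st.text(alphabet=CANONICAL_AA, min_size=3, max_size=30))
def test_sequence_identity_symmetric_and_bounded(a, b):
    v = sequence_identity(a, b)
    assert 0.0 <= v <= 100.0
    assert np.isclose(v, sequence_identity(b, a))


def test_split_respects_cutoff_exhaustively(family_records):
    seqs = {r.record_id: r.sequence for r in family_records[:20]}
    split = split_by_identity(seqs, cutoff=99.0, validation_fraction=0.15,
                              test_fraction=0.25, seed=0)
    split.validate_disjoint()
    assert set(split.train + split.validation + split.test) == set(seqs)
    for t in split.test:
        for tr in split.train:
            assert sequence_identity(seqs[t], seqs[tr]) <= 99.0


def test_identical_sequences_always_share_a_part():
    seqs = {"a": "EVQLV" * 20, "b": "EVQLV" * 20, "c": "KKKKK" * 20,
            "d": "RRRRR" * 20}
    for seed in range(5):
        split = split_by_identity(seqs, cutoff=90.0, seed=seed,
                                  validation_fraction=0.25, test_fraction=0.25)
        parts = {rid: part for part, ids in
                 (("train", split.train), ("val", split.validation),
                  ("test", split.test)) for rid in ids}
        assert parts["a"] == parts["b"]


def test_split_rejects_bad_cutoff_and_tiny_input():
    with pytest.raises(ValueError):
        split_by_identity({"a": "EVQ" * 30, "b": "QVE" * 30, "c": "VEQ" * 30},
                          cutoff=0.0)
    with pytest.raises(ValueError):
        split_by_identity({"a": "EVQ" * 30, "b": "QVE" * 30}, cutoff=90.0)


def test_max_train_identity(family_records):
    seqs = [r.sequence for r in family_records[:5]]
    assert max_train_identity(seqs[0], seqs) == 100.0
    assert max_train_identity(seqs[0], [seqs[1]]) == sequence_identity(seqs[0], seqs[1])
    assert max_train_identity(seqs[0], seqs[1:]) >= sequence_identity(seqs[0], seqs[2])
    with pytest.raises(ValueError):
        max_train_identity(seqs[0], [])


def test_align_to_reference_self_and_rigid_recovery(family_records):
    rec = family_records[0]
    aligned = align_to_reference(rec.structure, rec.structure, rec.regions,
                                 rec.regions)
    assert aligned.alignment_info["frame_ca_rmsd"] < 1e-9
    assert np.allclose(aligned.atom_coords(), rec.structure.atom_coords(), atol=1e-9)

    rng = np.random.default_rng(5)
    from scipy.spatial.transform import Rotation
    t = RigidTransform(Rotation.random(random_state=4).as_matrix(), rng.normal(0, 8, 3))
    moved = rec.structure.transformed(t)
    recovered = align_to_reference(moved, rec.structure, rec.regions, rec.regions)
    assert np.allclose(recovered.atom_coords(), rec.structure.atom_coords(), atol=1e-4)


def test_align_to_reference_is_rigid_motion_invariant(family_records):
    a, ref = family_records[4], family_records[0]
    out1 = align_to_reference(a.structure, ref.structure, a.regions, ref.regions)
    t = RigidTransform(np.eye(3), np.array([10.0, -4.0, 2.0]))
    out2 = align_to_reference(a.structure.transformed(t), ref.structure,
                              a.regions, ref.regions)
    assert np.allclose(out1.atom_coords(), out2.atom_coords(), atol=1e-4)
    assert out1.alignment_info["frame_ca_rmsd"] < 1.0  # same-template family member


def test_manifest_and_split_files_roundtrip(tmp_path):
    rows = [{"id": "x1", "path": "a.pdb", "chain": "H", "resolution": 2.0,
             "is_nanobody": True}]
    mpath = str(tmp_path / "manifest.tsv")
    write_manifest(rows, mpath)
    df = read_manifest(mpath)
    assert df.iloc[0]["id"] == "x1" and df.iloc[0]["chain"] == "H"

    split = DatasetSplit(["a", "b"], ["c"], ["d"], 90.0)
    spath = str(tmp_path / "split.tsv")
    write_split(split, spath)
    back = read_split(spath, cutoff=90.0)
    assert back.train == ["a", "b"] and back.validation == ["c"] and back.test == ["d"]
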