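"""Model-ready example construction, sequence identity, and identity-aware splits.

Training targets are coordinates in a common reference frame: every training
structure is superposed onto one designated reference structure using the
frame CA atoms at shared canonical positions, which is what gives the
coordinate regression its translational/rotational invariance. Sequences are
one-hot encoded into the fixed 140 x 22 input (20 amino acids alphabetically,
then the unknown channel, then the insertion channel used for padding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from . import regions as regions_mod
from .geometry import kabsch_superpose
from .structure_io import BackboneStructure, CANONICAL_AA

logger = logging.getLogger(__name__)

MAX_LEN = 140
N_CHANNELS = 22
UNKNOWN_CHANNEL = 20
INSERTION_CHANNEL = 21
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}  # alphabetical one-letter order


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a sequence into the padded 140 x 22 one-hot input matrix."""
    n = len(sequence)
    if not 1 <= n <= MAX_LEN:
        raise ValueError(f"sequence length {n} outside [1, {MAX_LEN}]")
    mat = np.zeros((MAX_LEN, N_CHANNELS))
    for i, aa in enumerate(sequence):
        if aa in AA_INDEX:
            mat[i, AA_INDEX[aa]] = 1.0
        elif aa == "X":
            mat[i, UNKNOWN_CHANNEL] = 1.0
        else:
            raise ValueError(f"invalid amino acid {aa!r} at position {i}")
    mat[n:, INSERTION_CHANNEL] = 1.0  # pad rows use the insertion channel
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of one_hot_encode on the unpadded prefix."""
    mat = np.asarray(mat)
    if mat.shape != (MAX_LEN, N_CHANNELS):
        raise ValueError("expected a 140 x 22 matrix")
    letters = CANONICAL_AA + "X"
    out = []
    for row in mat:
        ch = int(np.argmax(row))
        if ch == INSERTION_CHANNEL:
            break
        out.append(letters[ch])
    return "".join(out)


@dataclass
class EncodedExample:
    """One training/evaluation example in the padded model frame."""

    input: np.ndarray     # (140, 22)
    target: np.ndarray    # (140, 15): N, CA, C, O, CB triples in the reference frame
    mask: np.ndarray      # (140,) 1 = real residue
    cb_mask: np.ndarray   # (140,) 1 = CB present (0 for glycine and pad)
    example_id: str = ""

    @property
    def length(self) -> int:
        return int(self.mask.sum())


def align_to_reference(structure: BackboneStructure, reference: BackboneStructure,
                       regions: regions_mod.RegionMap, ref_regions: regions_mod.RegionMap,
                       min_shared: int = 10) -> BackboneStructure:
    """Superpose a structure's frame onto the reference frame via shared canonical positions.

    Frame CA atoms occupying the same canonical slot in both sequences are
    paired and Kabsch-fit; the returned structure carries all atoms in the
    reference frame plus an ``alignment_info`` attribute with the matched
    position count and post-fit frame CA RMSD.
    """
    def frame_slots(seq: str, rm: regions_mod.RegionMap):
        aln = regions_mod.canonical_align(seq)
        frame = set(rm.frame_indices(len(seq)))
        return {slot: src for slot, src in enumerate(aln.source_sequence_map)
                if src is not None and src in frame}

    slots_a = frame_slots(structure.sequence, regions)
    slots_b = frame_slots(reference.sequence, ref_regions)
    shared = sorted(set(slots_a) & set(slots_b))
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared frame positions (< {min_shared})")
    mobile = structure.ca_coords([slots_a[s] for s in shared])
    target = reference.ca_coords([slots_b[s] for s in shared])
    transform, fit_rmsd = kabsch_superpose(mobile, target)
    logger.info("align_to_reference: %d matched frame positions, post-fit CA RMSD %.3f A",
                len(shared), fit_rmsd)
    moved = structure.transformed(transform)
    moved.alignment_info = {"n_matched": len(shared), "frame_ca_rmsd": fit_rmsd}
    return moved


def make_example(sequence: str, aligned_structure: BackboneStructure,
                 example_id: str = "") -> EncodedExample:
    """Build the padded (input, target, masks) tuple for one aligned structure."""
    if len(sequence) != len(aligned_structure):
        raise ValueError("sequence/structure length mismatch")
    inp = one_hot_encode(sequence)
    target = np.zeros((MAX_LEN, 15))
    mask = np.zeros(MAX_LEN)
    cb_mask = np.zeros(MAX_LEN)
    for i, res in enumerate(aligned_structure.residues):
        mask[i] = 1.0
        for j, name in enumerate(("N", "CA", "C", "O")):
            target[i, 3 * j:3 * j + 3] = res.coords[name]
        if res.cb_present:
            target[i, 12:15] = res.coords["CB"]
            cb_mask[i] = 1.0
    return EncodedExample(inp, target, mask, cb_mask, example_id)


# ---------------------------------------------------------------------------
# sequence identity and splits

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0  # linear gap penalty
    return aligner


_ALIGNER = _make_aligner()


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity in percent: matches / alignment columns x 100."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    columns = alignment.shape[1]
    return 100.0 * counts.identities / columns


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    cutoff: float

    def validate_disjoint(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise ValueError("split parts overlap")


def split_by_identity(sequences: dict[str, str] | list[tuple[str, str]],
                      cutoff: float, validation_fraction: float = 0.075,
                      test_fraction: float = 0.15, seed: int = 0) -> DatasetSplit:
    """Greedy single-linkage grouping at the identity cutoff; whole groups per part.

    Any two sequences with identity > cutoff are linked into one group, so no
    test sequence can exceed the cutoff against any train sequence.
    """
    if not 0 < cutoff <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 3:
        raise ValueError("need at least 3 sequences to split")
    ids = [i for i, _ in items]
    seqs = [s for _, s in items]
    n = len(items)

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(seqs[i], seqs[j]) > cutoff:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    group_list = sorted(groups.values(), key=lambda g: g[0])
    rng = np.random.default_rng(seed)
    rng.shuffle(group_list)

    n_test = round(test_fraction * n)
    n_val = round(validation_fraction * n)
    test: list[str] = []
    validation: list[str] = []
    train: list[str] = []
    for group in group_list:
        if len(test) < n_test:
            test.extend(group)
        elif len(validation) < n_val:
            validation.extend(group)
        else:
            train.extend(group)
    split = DatasetSplit(train, validation, test, cutoff)
    split.validate_disjoint()
    return split


def max_train_identity(test_sequence: str, train_sequences: list[str]) -> float:
    """Maximal sequence identity (MSI) of a test sequence to the training set."""
    if not train_sequences:
        raise ValueError("train set is empty")
    return max(sequence_identity(test_sequence, t) for t in train_sequences)


# ---------------------------------------------------------------------------
# manifests

MANIFEST_COLUMNS = ["id", "path", "chain", "resolution", "is_nanobody"]


def write_manifest(rows: list[dict], path: str) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "path": str, "chain": str})


def write_split(split: DatasetSplit, path: str) -> None:
    rows = ([{"id": i, "part": "train"} for i in split.train]
            + [{"id": i, "part": "validation"} for i in split.validation]
            + [{"id": i, "part": "test"} for i in split.test])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_split(path: str, cutoff: float = float("nan")) -> DatasetSplit:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "part": str})
    parts = {p: df.loc[df["part"] == p, "id"].tolist()
             for p in ("train", "validation", "test")}
    return DatasetSplit(parts["train"], parts["validation"], parts["test"], cutoff)
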