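"""Synthetic VH-like structure families with a learnable sequence-to-conformation map.

The generator emulates what matters about immunoglobulin variable domains for
this package: a rigid conserved frame shared by every member (one template
per run), three variable loops whose conformation is a deterministic function
of loop sequence, planted anchor motifs (the two conserved cysteines, the
CDR1-closing tryptophan, the C-terminal W-G-x-G) so the heuristic numbering
works, consecutive CA spacing pinned near 3.8 A, and family structure in both
sequence and conformation space.

Mechanics. The frame template is grown once by sequential natural-extension
(NeRF) placement with ideal bond lengths (N-CA 1.458, CA-C 1.525, C-N 1.329 A).
Loop CA traces are grown in virtual-CA geometry — virtual bonds of exactly
3.8 A whose bend and torsion angles come from a per-family lookup table
indexed by amino-acid class (family base angles, well separated between
families, plus small class-dependent offsets) — and are closed exactly onto
the downstream frame anchor with FABRIK inverse kinematics, which preserves
virtual bond lengths by construction. Backbone N/C/O/CB atoms are then placed
with ideal in-residue bond lengths in local frames along the CA trace. The
map from loop sequence to loop coordinates is therefore deterministic, smooth
and near-linear in the one-hot encoding. Coordinate noise is a chain-smooth
Gaussian field (per-residue displacement, marginal sd about ``noise_sd``) so
bond geometry survives.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import dataset as dataset_mod
from .regions import RegionMap
from .structure_io import BackboneStructure, Residue, write_backbone, write_fasta

# ideal backbone geometry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0
CA_VIRTUAL_BOND = 3.8

# frame segment lengths (f4 absorbs frame_length changes)
F1_LEN, F2_LEN, F3_LEN = 25, 19, 34
CYS1_POS = 21          # within F1; CDR1 starts at CYS1_POS + 4 = F1_LEN
CYS2_OFFSET = 31       # within F3; CDR3 starts 3 residues later = F3 end
F4_MOTIF = "WGQGTQVTVSSA"

FRAME_ALPHABET = "ADEFGHIKLMNPQRSTVY"   # no C/W so planted anchors stay unique
LOOP_ALPHABET = "ADEFGHIKLMNPQRSTVY"

# amino-acid classes indexing the loop-geometry tables
AA_CLASS = {}
for _aa in "AVLIMF":
    AA_CLASS[_aa] = 0
for _aa in "STNQYGP":
    AA_CLASS[_aa] = 1
for _aa in "DEKRH":
    AA_CLASS[_aa] = 2
for _aa in "CWX":
    AA_CLASS[_aa] = 3
N_CLASSES = 4


@dataclass(frozen=True)
class FamilyConfig:
    n_structures: int = 200
    frame_length: int = 90
    cdr1_range: tuple[int, int] = (5, 7)
    cdr2_range: tuple[int, int] = (5, 5)   # Chothia CDR2 is essentially fixed-length
    cdr3_range: tuple[int, int] = (6, 14)
    n_families: int = 4
    conformation_rule_seed: int = 0
    noise_sd: float = 0.1
    global_seed: int = 0
    frame_mut_per_member: int = 2
    loop_mut_prob: float = 0.12
    class_delta_sd_deg: float = 6.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_length < F1_LEN + F2_LEN + F3_LEN + len("WG.G"):
            raise ValueError("frame_length too short for the planted anchors")
        max_total = (self.frame_length + self.cdr1_range[1] + self.cdr2_range[1]
                     + self.cdr3_range[1])
        if max_total > 140:
            raise ValueError(f"maximal total length {max_total} exceeds 140")
        if self.n_structures < self.n_families:
            raise ValueError("need at least one structure per family")

    @property
    def f4_length(self) -> int:
        return self.frame_length - (F1_LEN + F2_LEN + F3_LEN)


@dataclass
class SyntheticRecord:
    record_id: str
    sequence: str
    structure: BackboneStructure
    regions: RegionMap
    family: int


# ---------------------------------------------------------------------------
# geometry primitives

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d), dihedral(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _extend_residue(n_prev, ca_prev, c_prev, psi_prev: float, phi: float):
    """Grow one residue's N, CA, C from the previous residue's atoms."""
    n = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
    ca = _place_atom(ca_prev, c_prev, n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
    c = _place_atom(c_prev, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
    return n, ca, c


def _build_chain(phis: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """Backbone N/CA/C for a chain from torsions; returns (n, 3, 3)."""
    n_res = len(phis)
    atoms = np.zeros((n_res, 3, 3))
    atoms[0, 0] = [0.0, 0.0, 0.0]
    atoms[0, 1] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(ANGLE_N_CA_C)
    atoms[0, 2] = atoms[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        atoms[i] = _extend_residue(atoms[i - 1, 0], atoms[i - 1, 1], atoms[i - 1, 2],
                                   psis[i - 1], phis[i])
    return atoms


def _place_o(ca, c, n_next) -> np.ndarray:
    """Carbonyl O in the peptide plane, anti to the bisector of CA and next N."""
    u1 = (c - ca) / np.linalg.norm(c - ca)
    u2 = (c - n_next) / np.linalg.norm(c - n_next)
    bis = u1 + u2
    return c + BOND_C_O * bis / np.linalg.norm(bis)


def _place_terminal_o(n, ca, c) -> np.ndarray:
    return _place_atom(n, ca, c, BOND_C_O, 120.8, 180.0)


def _place_cb(n, ca, c) -> np.ndarray:
    """Ideal tetrahedral CB from backbone N, CA, C."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * cc


# ---------------------------------------------------------------------------
# loop construction: virtual-CA trace + FABRIK closure

def _virtual_trace(seed_cas: np.ndarray, classes: list[int],
                   table: np.ndarray) -> np.ndarray:
    """Initial loop CA trace grown by NeRF in virtual-CA geometry.

    ``seed_cas`` are the last three frame CA atoms before the loop; each loop
    residue adds one virtual bond of 3.8 A with class/family bend and torsion
    from the lookup table.
    """
    pts = [seed_cas[0], seed_cas[1], seed_cas[2]]
    for cls in classes:
        bend, torsion = table[cls]
        pts.append(_place_atom(pts[-3], pts[-2], pts[-1], CA_VIRTUAL_BOND,
                               bend, torsion))
    return np.array(pts[3:])


def _fabrik_close(start: np.ndarray, trace: np.ndarray, target: np.ndarray,
                  bond: float = CA_VIRTUAL_BOND, tol: float = 1e-6,
                  max_iter: int = 200) -> np.ndarray:
    """FABRIK inverse kinematics: move the trace so its virtual chain connects
    ``start`` to ``target`` with every consecutive distance exactly ``bond``.

    Iterates backward/forward reaching passes; bond lengths are exact after
    every forward pass, so closure never distorts CA spacing.
    """
    pts = np.vstack([start, trace, target])
    n = len(pts)
    for _ in range(max_iter):
        # backward pass: anchor the target end
        pts[-1] = target
        for i in range(n - 2, 0, -1):
            direction = pts[i] - pts[i + 1]
            pts[i] = pts[i + 1] + bond * direction / np.linalg.norm(direction)
        # forward pass: anchor the start
        pts[0] = start
        for i in range(1, n):
            direction = pts[i] - pts[i - 1]
            pts[i] = pts[i - 1] + bond * direction / np.linalg.norm(direction)
        if np.linalg.norm(pts[-1] - target) < tol:
            break
    return pts[1:-1]


def _loop_atoms_from_trace(prev_ca: np.ndarray, trace: np.ndarray,
                           next_ca: np.ndarray) -> np.ndarray:
    """Backbone N/CA/C for loop residues from their CA trace.

    N and C are placed with ideal in-residue bond lengths in a local frame
    built from the neighbouring CA atoms.
    """
    n_loop = len(trace)
    cas = np.vstack([prev_ca, trace, next_ca])
    atoms = np.zeros((n_loop, 3, 3))
    for j in range(n_loop):
        ca = cas[j + 1]
        d_prev = cas[j] - ca
        d_next = cas[j + 2] - ca
        d_prev = d_prev / np.linalg.norm(d_prev)
        d_next = d_next / np.linalg.norm(d_next)
        w = np.cross(d_prev, d_next)
        wn = np.linalg.norm(w)
        if wn < 1e-8:  # collinear neighbours: any perpendicular will do
            helper = np.array([1.0, 0.0, 0.0])
            if abs(d_prev @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            w = np.cross(d_prev, helper)
            wn = np.linalg.norm(w)
        w = w / wn
        bis = d_prev + d_next
        bn = np.linalg.norm(bis)
        bis = bis / bn if bn > 1e-8 else np.zeros(3)
        n_dir = 0.85 * d_prev - 0.25 * bis + 0.35 * w
        c_dir = 0.85 * d_next - 0.25 * bis - 0.35 * w
        atoms[j, 0] = ca + BOND_N_CA * n_dir / np.linalg.norm(n_dir)
        atoms[j, 1] = ca
        atoms[j, 2] = ca + BOND_CA_C * c_dir / np.linalg.norm(c_dir)
    return atoms


# ---------------------------------------------------------------------------
# lookup tables and template

def _loop_tables(n_families: int, rng: np.random.Generator,
                 class_delta_sd: float) -> np.ndarray:
    """(family, class, 2) table of virtual-CA (bend, torsion) angles in degrees.

    Family bases are drawn from stratified, well-separated windows; class
    offsets are small so within-family conformations vary smoothly with
    sequence while families stay structurally distinct.
    """
    tables = np.zeros((n_families, N_CLASSES, 2))
    bend_edges = np.linspace(85.0, 135.0, n_families + 1)
    torsion_edges = np.linspace(-150.0, 150.0, n_families + 1)
    torsion_order = rng.permutation(n_families)
    for f in range(n_families):
        bend_f = rng.uniform(bend_edges[f] + 3, bend_edges[f + 1] - 3)
        g = torsion_order[f]
        torsion_f = rng.uniform(torsion_edges[g] + 8, torsion_edges[g + 1] - 8)
        deltas = rng.normal(0.0, class_delta_sd, (N_CLASSES, 2))
        tables[f] = np.array([bend_f, torsion_f]) + deltas
    return tables


def _frame_torsions(length: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Blockwise secondary-structure-like torsions for the frame template."""
    bins = np.array([[-120.0, 130.0], [-60.0, -45.0], [-75.0, 150.0]])
    phis = np.zeros(length)
    psis = np.zeros(length)
    i = 0
    while i < length:
        block = min(int(rng.integers(6, 11)), length - i)
        b = bins[int(rng.integers(len(bins)))]
        phis[i:i + block] = b[0] + rng.normal(0, 4.0, block)
        psis[i:i + block] = b[1] + rng.normal(0, 4.0, block)
        i += block
    return phis, psis


class _Template:
    """The fixed frame scaffold shared by every generated member."""

    def __init__(self, config: FamilyConfig, rng: np.random.Generator):
        self.config = config
        base_loops = (config.cdr1_range[0], config.cdr2_range[0], config.cdr3_range[0])
        seg_lengths = [F1_LEN, base_loops[0], F2_LEN, base_loops[1], F3_LEN,
                       base_loops[2], config.f4_length]
        total = sum(seg_lengths)
        phis, psis = _frame_torsions(total, rng)
        # compact torsions for template loop positions keep anchors reachable
        starts = np.cumsum([0] + seg_lengths[:-1])
        self.seg_lengths = seg_lengths
        for si in (1, 3, 5):
            s, e = starts[si], starts[si] + seg_lengths[si]
            phis[s:e], psis[s:e] = -60.0, -30.0
        self.phis, self.psis = phis, psis
        self.atoms = _build_chain(phis, psis)
        self.atoms -= self.atoms[:, 1].mean(axis=0)  # centre CAs at the origin
        self.starts = starts


# ---------------------------------------------------------------------------
# sequences

def _consensus(rng: np.random.Generator, config: FamilyConfig):
    """Global frame consensus with planted anchors, plus per-family variants."""
    def draw(n):
        return list(rng.choice(list(FRAME_ALPHABET), size=n))

    f1 = draw(F1_LEN)
    f1[CYS1_POS] = "C"
    f2 = draw(F2_LEN)
    f2[0] = "W"
    f3 = draw(F3_LEN)
    f3[CYS2_OFFSET] = "C"
    f4 = list(F4_MOTIF[:config.f4_length])
    frame = {"f1": f1, "f2": f2, "f3": f3, "f4": f4}
    anchors = {"f1": {CYS1_POS}, "f2": {0}, "f3": {CYS2_OFFSET},
               "f4": set(range(config.f4_length))}

    family_frames = []
    family_loops = []
    for _ in range(config.n_families):
        variant = {k: list(v) for k, v in frame.items()}
        for seg in ("f1", "f2", "f3"):
            free = [i for i in range(len(variant[seg])) if i not in anchors[seg]]
            picks = rng.choice(free, size=min(4, len(free)), replace=False)
            for p in picks:
                variant[seg][int(p)] = str(rng.choice(list(FRAME_ALPHABET)))
        family_frames.append(variant)
        lengths = {
            "cdr1": int(rng.integers(config.cdr1_range[0], config.cdr1_range[1] + 1)),
            "cdr2": int(rng.integers(config.cdr2_range[0], config.cdr2_range[1] + 1)),
            "cdr3": int(rng.integers(config.cdr3_range[0], config.cdr3_range[1] + 1)),
        }
        consensus_loops = {k: list(rng.choice(list(LOOP_ALPHABET), size=v))
                           for k, v in lengths.items()}
        family_loops.append(consensus_loops)
    return family_frames, family_loops, anchors


def _member_sequence(rng, config, family_frame, family_loops, anchors):
    segs = {k: list(v) for k, v in family_frame.items()}
    for _ in range(config.frame_mut_per_member):
        seg = str(rng.choice(["f1", "f2", "f3"]))
        free = [i for i in range(len(segs[seg])) if i not in anchors[seg]]
        pos = int(rng.choice(free))
        segs[seg][pos] = str(rng.choice(list(FRAME_ALPHABET)))
    loops = {}
    for name, cons in family_loops.items():
        # clonal families share loop lengths; members vary by point mutations
        seq = list(cons)
        for i in range(len(seq)):
            if rng.random() < config.loop_mut_prob:
                seq[i] = str(rng.choice(list(LOOP_ALPHABET)))
        loops[name] = seq
    return segs, loops


# ---------------------------------------------------------------------------
# member assembly

def _build_member_backbone(template: _Template, loops: dict[str, list[str]],
                           table: np.ndarray) -> tuple[np.ndarray, RegionMap]:
    """Assemble N/CA/C for one member: template frame + closed loop traces."""
    cfg = template.config
    seg_names = ["f1", "cdr1", "f2", "cdr2", "f3", "cdr3", "f4"]
    pieces = []
    for si, name in enumerate(seg_names):
        t_start = template.starts[si]
        t_len = template.seg_lengths[si]
        if name.startswith("f"):
            pieces.append(template.atoms[t_start:t_start + t_len].copy())
            continue
        loop_seq = loops[name]
        classes = [AA_CLASS[aa] for aa in loop_seq]
        seed_cas = template.atoms[t_start - 3:t_start, 1]
        trace = _virtual_trace(seed_cas, classes, table)
        prev_ca = template.atoms[t_start - 1, 1]
        next_ca = template.atoms[t_start + t_len, 1]
        trace = _fabrik_close(prev_ca, trace, next_ca)
        pieces.append(_loop_atoms_from_trace(prev_ca, trace, next_ca))

    backbone = np.concatenate(pieces, axis=0)
    lengths = [F1_LEN, len(loops["cdr1"]), F2_LEN, len(loops["cdr2"]), F3_LEN,
               len(loops["cdr3"]), cfg.f4_length]
    s = [int(v) for v in np.cumsum([0] + lengths)]
    rm = RegionMap((s[1], s[2]), (s[3], s[4]), (s[5], s[6]))
    return backbone, rm


def _smooth_noise(n_res: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Chain-smooth Gaussian displacement field, (n_res, 3)."""
    if sd == 0:
        return np.zeros((n_res, 3))
    n_knots = max(4, n_res // 15)
    knots_x = np.linspace(0, n_res - 1, n_knots)
    values = rng.normal(0.0, sd, (n_knots, 3))
    pos = np.arange(n_res)
    return np.column_stack([np.interp(pos, knots_x, values[:, d]) for d in range(3)])


def _to_structure(backbone: np.ndarray, sequence: str, record_id: str,
                  noise: np.ndarray) -> BackboneStructure:
    n_res = backbone.shape[0]
    residues = []
    for i, aa in enumerate(sequence):
        n_at, ca_at, c_at = backbone[i]
        if i + 1 < n_res:
            o_at = _place_o(ca_at, c_at, backbone[i + 1, 0])
        else:
            o_at = _place_terminal_o(n_at, ca_at, c_at)
        coords = {"N": n_at + noise[i], "CA": ca_at + noise[i],
                  "C": c_at + noise[i], "O": o_at + noise[i]}
        cb_present = aa != "G"
        if cb_present:
            coords["CB"] = _place_cb(n_at, ca_at, c_at) + noise[i]
        residues.append(Residue(i, aa, coords, cb_present))
    return BackboneStructure("H", residues, source_id=record_id)


def generate_family(config: FamilyConfig) -> list[SyntheticRecord]:
    """Generate ``n_structures`` members across ``n_families`` families.

    Deterministic: identical config (including seeds) yields bitwise-identical
    output. Structures are emitted in the common template frame.
    """
    config.validate()
    rule_rng = np.random.default_rng(config.conformation_rule_seed)
    template = _Template(config, rule_rng)
    tables = _loop_tables(config.n_families, rule_rng, config.class_delta_sd_deg)
    family_frames, family_loops, anchors = _consensus(rule_rng, config)

    member_rng = np.random.default_rng(config.global_seed)
    records = []
    for i in range(config.n_structures):
        fam = i % config.n_families
        segs, loops = _member_sequence(member_rng, config, family_frames[fam],
                                       family_loops[fam], anchors)
        sequence = (
            "".join(segs["f1"]) + "".join(loops["cdr1"]) + "".join(segs["f2"])
            + "".join(loops["cdr2"]) + "".join(segs["f3"]) + "".join(loops["cdr3"])
            + "".join(segs["f4"]))
        backbone, rm = _build_member_backbone(template, loops, tables[fam])
        noise = _smooth_noise(backbone.shape[0], config.noise_sd, member_rng)
        record_id = f"fam{fam}_{i:04d}"
        structure = _to_structure(backbone, sequence, record_id, noise)
        records.append(SyntheticRecord(record_id, sequence, structure, rm, fam))
    return records


# ---------------------------------------------------------------------------
# benchmark emission

def records_to_examples(records: list[SyntheticRecord],
                        reference: SyntheticRecord | None = None
                        ) -> list[dataset_mod.EncodedExample]:
    """Align every record onto the reference and encode model-ready examples."""
    if reference is None:
        reference = min(records, key=lambda r: r.record_id)
    examples = []
    for rec in records:
        aligned = dataset_mod.align_to_reference(rec.structure, reference.structure,
                                                 rec.regions, reference.regions)
        examples.append(dataset_mod.make_example(rec.sequence, aligned, rec.record_id))
    return examples


def make_benchmark(config: FamilyConfig, out_dir: str, cutoff: float = 99.0,
                   validation_fraction: float = 0.1, test_fraction: float = 0.15,
                   split_seed: int = 0) -> tuple[str, str, str]:
    """Generate families, write PDBs + FASTA + manifests, split by identity.

    Returns the paths of the train/validation/test manifest files.
    """
    records = generate_family(config)
    os.makedirs(os.path.join(out_dir, "pdb"), exist_ok=True)
    fasta_records = []
    rows = {}
    for rec in records:
        pdb_path = os.path.join(out_dir, "pdb", f"{rec.record_id}.pdb")
        with open(pdb_path, "w") as fh:
            fh.write(write_backbone(rec.structure))
        fasta_records.append((rec.record_id, rec.sequence))
        rows[rec.record_id] = {"id": rec.record_id, "path": pdb_path, "chain": "H",
                               "resolution": 2.0, "is_nanobody": True}
    with open(os.path.join(out_dir, "sequences.fasta"), "w") as fh:
        fh.write(write_fasta(fasta_records))

    split = dataset_mod.split_by_identity({r.record_id: r.sequence for r in records},
                                          cutoff=cutoff,
                                          validation_fraction=validation_fraction,
                                          test_fraction=test_fraction, seed=split_seed)
    dataset_mod.write_split(split, os.path.join(out_dir, "split.tsv"))
    paths = []
    for part, ids in (("train", split.train), ("validation", split.validation),
                      ("test", split.test)):
        path = os.path.join(out_dir, f"{part}_manifest.tsv")
        dataset_mod.write_manifest([rows[i] for i in ids], path)
        paths.append(path)
    return tuple(paths)
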