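"""Single-chain backbone structure and sequence I/O.

Structures are plain PDB-format text (ATOM records, one chain at a time) and
carry only the five model-facing atoms N, CA, C, O, CB per residue. Parsing
resolves alternate locations to the highest-occupancy conformer (ties broken
by file order), drops residues missing any of N/CA/C/O, and reports how many
residues were dropped or absent so curation filters can reject gapped chains
instead of fabricating coordinates.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
ATOM_ORDER = ("N", "CA", "C", "O", "CB")
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
VALID_AA = CANONICAL_AA + "X"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is common in X-ray structures
    "MSE": "M",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items() if k != "MSE"}
AA1_TO_3["X"] = "UNK"


class StructureError(ValueError):
    """Raised on unparsable or contract-violating structure input."""


@dataclass
class Residue:
    """One residue with its backbone (and optionally CB) coordinates in Angstrom."""

    index: int
    aa: str
    coords: dict[str, np.ndarray]
    cb_present: bool = True
    author_number: tuple[int, str] | None = None  # (resseq, icode) metadata

    def validate(self) -> None:
        if self.aa not in VALID_AA:
            raise StructureError(f"residue {self.index}: invalid amino acid {self.aa!r}")
        for name in BACKBONE_ATOMS:
            if name not in self.coords:
                raise StructureError(f"residue {self.index}: missing backbone atom {name}")
        if self.cb_present and "CB" not in self.coords:
            raise StructureError(f"residue {self.index}: cb_present but no CB coordinates")
        for name, xyz in self.coords.items():
            if not np.all(np.isfinite(xyz)):
                raise StructureError(f"residue {self.index}: non-finite {name} coordinates")

    def atom_names(self) -> tuple[str, ...]:
        return ATOM_ORDER if self.cb_present else BACKBONE_ATOMS


@dataclass
class BackboneStructure:
    """An ordered single chain of residues with dense 0-based indexing."""

    chain_id: str
    residues: list[Residue]
    source_id: str = ""
    gap_report: int = 0

    def __post_init__(self) -> None:
        for i, res in enumerate(self.residues):
            res.index = i

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def atom_coords(self, atoms=BACKBONE_ATOMS, indices=None) -> np.ndarray:
        """Stack coordinates of the requested atoms for the requested residues, (n, 3)."""
        if indices is None:
            indices = range(len(self.residues))
        rows = []
        for i in indices:
            res = self.residues[i]
            for name in atoms:
                if name in res.coords:
                    rows.append(res.coords[name])
        return np.asarray(rows, dtype=float)

    def ca_coords(self, indices=None) -> np.ndarray:
        return self.atom_coords(atoms=("CA",), indices=indices)

    def transformed(self, transform) -> "BackboneStructure":
        """Return a copy with `transform` (a geometry.RigidTransform) applied to every atom."""
        new = []
        for res in self.residues:
            coords = {n: transform.apply(c[None, :])[0] for n, c in res.coords.items()}
            new.append(Residue(res.index, res.aa, coords, res.cb_present, res.author_number))
        return BackboneStructure(self.chain_id, new, self.source_id, self.gap_report)

    def validate(self) -> None:
        if not self.residues:
            raise StructureError("empty structure")
        for res in self.residues:
            res.validate()


def read_backbone(pdb_text: str, chain_id: str) -> BackboneStructure:
    """Parse one chain's backbone from PDB-format text.

    Only the first MODEL is read (later models are ignored with a warning).
    Residues missing any of N/CA/C/O are dropped; the count of dropped plus
    numbering-implied missing residues is stored in ``gap_report``.
    """
    # residue key -> atom name -> (occupancy, xyz); keys kept in file order
    residues: dict[tuple[int, str], dict] = {}
    order: list[tuple[int, str]] = []
    resnames: dict[tuple[int, str], str] = {}
    chain_seen = False
    model_count = 0
    past_first_model = False

    for line in io.StringIO(pdb_text):
        rec = line[:6]
        if rec == "MODEL ":
            model_count += 1
            if model_count > 1:
                past_first_model = True
                logger.warning("read_backbone: ignoring models beyond the first")
        elif rec == "ENDMDL":
            past_first_model = model_count >= 1
        if past_first_model:
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            continue
        if line[21] != chain_id:
            continue
        resname = line[17:20].strip()
        if resname not in AA3_TO_1:
            continue  # waters/ligands on the same chain
        chain_seen = True
        atom = line[12:16].strip()
        if atom not in ATOM_ORDER:
            continue
        try:
            resseq = int(line[22:26])
        except ValueError:
            continue
        icode = line[26].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        occ_str = line[54:60].strip()
        occ = float(occ_str) if occ_str else 1.0
        key = (resseq, icode)
        if key not in residues:
            residues[key] = {}
            order.append(key)
            resnames[key] = resname
        # altloc rule: keep the highest occupancy; strict > keeps the first on ties
        if atom not in residues[key] or occ > residues[key][atom][0]:
            residues[key][atom] = (occ, xyz)

    if not chain_seen:
        raise StructureError(f"chain {chain_id!r} not found in PDB text")

    kept: list[Residue] = []
    dropped = 0
    dropped_keys: list[tuple[int, str]] = []
    for key in order:
        atoms = residues[key]
        if any(a not in atoms for a in BACKBONE_ATOMS):
            dropped += 1
            dropped_keys.append(key)
            continue
        aa = AA3_TO_1[resnames[key]]
        coords = {name: atoms[name][1] for name in ATOM_ORDER if name in atoms}
        kept.append(Residue(0, aa, coords, cb_present="CB" in coords, author_number=key))

    if not kept:
        raise StructureError(f"chain {chain_id!r}: no residues with a complete backbone")

    # numbering-implied gaps: jumps in author resseq beyond +1 (same icode
    # stream), not already accounted for by residues dropped above
    missing = 0
    for a, b in zip(kept[:-1], kept[1:]):
        if a.author_number and b.author_number and not a.author_number[1] and not b.author_number[1]:
            lo, hi = a.author_number[0], b.author_number[0]
            if hi - lo > 1:
                in_between = sum(1 for seq, _ in dropped_keys if lo < seq < hi)
                missing += max(0, hi - lo - 1 - in_between)
    struct = BackboneStructure(chain_id, kept, gap_report=dropped + missing)
    if dropped or missing:
        logger.info("read_backbone: chain %s gap report = %d (dropped %d, missing %d)",
                    chain_id, struct.gap_report, dropped, missing)
    return struct


def write_backbone(structure: BackboneStructure) -> str:
    """Emit standard PDB ATOM records (N, CA, C, O, CB per residue; no CB for glycine)."""
    structure.validate()
    lines = []
    serial = 1
    for res in structure.residues:
        res3 = AA1_TO_3.get(res.aa, "UNK")
        if res.author_number is not None:
            resseq, icode = res.author_number
        else:
            resseq, icode = res.index + 1, ""
        for name in res.atom_names():
            x, y, z = res.coords[name]
            element = name[0]
            name_field = f" {name:<3}"  # single-letter elements start in column 14
            lines.append(
                f"ATOM  {serial:>5} {name_field} {res3:>3} {structure.chain_id}"
                f"{resseq:>4}{icode or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


class FastaError(ValueError):
    """Raised on malformed FASTA records."""


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into (id, sequence) pairs, order preserved.

    Sequences must use the 20 canonical one-letter codes plus X.
    """
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"record {rec.id!r}: empty sequence")
        bad = sorted(set(seq) - set(VALID_AA))
        if bad:
            raise FastaError(f"record {rec.id!r}: illegal characters {bad}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]]) -> str:
    out = []
    for rid, seq in records:
        if not seq:
            raise FastaError(f"record {rid!r}: empty sequence")
        out.append(f">{rid}")
        out.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    return "\n".join(out) + "\n"
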