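import numpy as np
import pytest

from vhfold.structure_io import BackboneStructure, Residue
from vhfold.synthetic_data import FamilyConfig, generate_family, records_to_examples


@pytest.fixture(scope="session")
def family_records():
    """24 structures across 4 planted families; shared across tests."""
    cfg = FamilyConfig(n_structures=24, n_families=4, noise_sd=0.1,
                       conformation_rule_seed=0, global_seed=1)
    return generate_family(cfg)


@pytest.fixture(scope="session")
def family_examples(family_records):
    return records_to_examples(family_records)


def pdb_line(serial, atom, resname, chain, resseq, xyz, occ=1.0, altloc=" ",
             icode=" "):
    x, y, z = xyz
    name_field = f" {atom:<3}"
    return (f"ATOM  {serial:>5} {name_field}{altloc}{resname:>3} {chain}"
            f"{resseq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {atom[0]:>2}")


def toy_pdb(residues, chain="A"):
    """residues: list of dicts {resseq, resname, atoms: {name: (xyz, occ, altloc)}}."""
    lines = []
    serial = 1
    for res in residues:
        for name, spec in res["atoms"].items():
            xyz, occ, altloc = spec
            lines.append(pdb_line(serial, name, res["resname"], chain,
                                  res["resseq"], xyz, occ, altloc))
            serial += 1
    return "\n".join(lines) + "\nEND\n"


def straight_structure(n, chain="A", spacing=3.8, aa="A", offset=(0.0, 0.0, 0.0)):
    """A synthetic straight chain with full backbone + CB; spacing along x."""
    residues = []
    off = np.asarray(offset, dtype=float)
    for i in range(n):
        base = np.array([i * spacing, 0.0, 0.0]) + off
        coords = {
            "N": base + np.array([-0.5, 1.0, 0.0]),
            "CA": base,
            "C": base + np.array([0.5, 1.0, 0.0]),
            "O": base + np.array([0.5, 2.2, 0.0]),
            "CB": base + np.array([0.0, -1.0, 1.0]),
        }
        residues.append(Residue(i, aa, coords, cb_present=True))
    return BackboneStructure(chain, residues, source_id=f"straight{n}")
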