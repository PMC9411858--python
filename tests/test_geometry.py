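import copy

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from vhfold.geometry import (GeometryError, RigidTransform, capri_quality,
                             consecutive_ca_distances, kabsch_superpose,
                             region_rmsd, rmsd)
from vhfold.regions import assign_regions

from conftest import straight_structure


def brute_force_min_rmsd(mobile, target, coarse_deg=15.0):
    """Independent superposition oracle: Euler-angle grid + local refinement.

    Centroids are aligned analytically (optimal for any rotation); rotations
    are scanned on a coarse grid and the best is polished with Nelder-Mead.
    """
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)

    def cost(euler):
        r = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
        return np.sqrt(np.mean(np.sum((p @ r.T - q) ** 2, axis=1)))

    grid = np.arange(0.0, 360.0, coarse_deg)
    grid_b = np.arange(0.0, 180.0 + 1e-9, coarse_deg)
    best = None
    for a in grid:
        for b in grid_b:
            for c in grid:
                v = cost((a, b, c))
                if best is None or v < best[0]:
                    best = (v, (a, b, c))
    res = minimize(cost, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    return min(best[0], res.fun)


def random_rigid(rng):
    r = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    return RigidTransform(r, rng.normal(0, 5, 3))


def test_kabsch_identity_and_pure_translation():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.5]], dtype=float)
    t, val = kabsch_superpose(pts, pts)
    assert val < 1e-12
    moved = pts + np.array([1.0, 2.0, 3.0])
    t, val = kabsch_superpose(pts, moved)
    assert val < 1e-12
    assert np.allclose(t.translation, [1, 2, 3], atol=1e-9)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-9)


def test_kabsch_never_reflects_and_transform_valid():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        t, _ = kabsch_superpose(a, b)
        t.validate()
        assert np.linalg.det(t.rotation) > 0


def test_kabsch_matches_bruteforce_on_spec_example():
    mobile = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    target = np.array([[0.0, 0, 0], [3, 0, 0], [0, 1, 0]])
    _, val = kabsch_superpose(mobile, target)
    oracle = brute_force_min_rmsd(mobile, target)
    assert abs(val - oracle) < 1e-3


def test_kabsch_errors():
    with pytest.raises(GeometryError):
        kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    with pytest.raises(GeometryError):
        kabsch_superpose(line, line)


def test_rmsd_closed_forms():
    assert rmsd(np.zeros((4, 3)), np.zeros((4, 3))) == 0.0
    assert rmsd(np.array([[0.0, 0, 0]]), np.array([[2.0, 0, 0]])) == 2.0
    a = np.array([[0.0, 0, 0], [0, 0, 0]])
    b = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert np.isclose(rmsd(a, b), np.sqrt(2))
    with pytest.raises(GeometryError):
        rmsd(np.zeros((2, 3)), np.zeros((3, 3)))


def test_kabsch_never_worse_than_raw_rmsd():
    rng = np.random.default_rng(11)
    for _ in range(20):
        a = rng.normal(size=(6, 3)) * 3
        b = rng.normal(size=(6, 3)) * 3
        _, fitted = kabsch_superpose(a, b)
        assert fitted <= rmsd(a, b) + 1e-12


def test_consecutive_ca_distances():
    s = straight_structure(5, spacing=3.8)
    assert np.allclose(consecutive_ca_distances(s), 3.8)
    ca = np.array([[0.0, 0, 0], [0, 3, 4]])
    assert np.allclose(consecutive_ca_distances(ca), [5.0])
    with pytest.raises(GeometryError):
        consecutive_ca_distances(np.array([[0.0, 0, 0]]))


def test_region_rmsd_zero_for_identical_and_rigid_motions(family_records):
    rec = family_records[0]
    rm = assign_regions(rec.sequence)
    report = region_rmsd(rec.structure, rec.structure, rm)
    assert all(v < 1e-12 for v in report.as_dict().values())

    rng = np.random.default_rng(0)
    moved = rec.structure.transformed(random_rigid(rng))
    report = region_rmsd(moved, rec.structure, rm)
    assert all(v < 1e-6 for v in report.as_dict().values())


def test_region_rmsd_isolates_displaced_cdr3(family_records):
    rec = family_records[0]
    rm = assign_regions(rec.sequence)
    model = copy.deepcopy(rec.structure)
    for i in range(*rm.cdr3):
        for name in model.residues[i].coords:
            model.residues[i].coords[name] = model.residues[i].coords[name] + np.array([1.0, 0, 0])
    report = region_rmsd(model, rec.structure, rm)
    assert report.frame < 1e-9
    assert np.isclose(report.cdr3, 1.0, atol=1e-9)
    assert report.cdr1 < 1e-9 and report.cdr2 < 1e-9


def test_capri_exact_model_is_medium():
    receptor = straight_structure(6, chain="R")
    ligand = straight_structure(6, chain="L", offset=(0.0, 6.0, 0.0))
    rep = capri_quality(receptor, ligand, receptor, ligand)
    assert rep.ligand_rmsd < 1e-9
    assert rep.interface_rmsd < 1e-9
    assert rep.grade == "medium"


def test_capri_translated_ligand():
    receptor = straight_structure(6, chain="R")
    native_ligand = straight_structure(6, chain="L", offset=(0.0, 6.0, 0.0))
    model_ligand = straight_structure(6, chain="L", offset=(0.0, 12.0, 0.0))
    rep = capri_quality(receptor, model_ligand, receptor, native_ligand)
    assert np.isclose(rep.ligand_rmsd, 6.0, atol=1e-9)
    expected = "medium" if rep.interface_rmsd < 2.0 else "acceptable"
    assert rep.grade == expected


def test_capri_grade_thresholds_are_strict():
    # boundary values fall OUTSIDE the better class
    receptor = straight_structure(8, chain="R")
    native_ligand = straight_structure(8, chain="L", offset=(0.0, 6.0, 0.0))
    model_ligand = straight_structure(8, chain="L", offset=(0.0, 6.0, 20.0))
    rep = capri_quality(receptor, model_ligand, receptor, native_ligand)
    assert np.isclose(rep.ligand_rmsd, 20.0)
    assert rep.grade == ("incorrect" if rep.interface_rmsd >= 4.0 else rep.grade)


def test_capri_no_interface_is_an_error():
    receptor = straight_structure(4, chain="R")
    ligand = straight_structure(4, chain="L", offset=(0.0, 50.0, 0.0))
    with pytest.raises(GeometryError):
        capri_quality(receptor, ligand, receptor, ligand)
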