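"""Rigid-body superposition, RMSD machinery and chain-geometry measures.

The Kabsch solver here is the single source of all superpositions in the
package: frame-based loop evaluation, dataset alignment onto the training
reference, and the CAPRI-style docking-quality metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import BACKBONE_ATOMS, BackboneStructure


class GeometryError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rotation + translation; y = R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def validate(self, tol: float = 1e-6) -> None:
        r = self.rotation
        if abs(np.linalg.det(r) - 1.0) > tol:
            raise GeometryError("rotation determinant is not +1")
        if np.max(np.abs(r @ r.T - np.eye(3))) > tol:
            raise GeometryError("rotation is not orthogonal")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between paired points; no superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise GeometryError("empty point sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def _check_nondegenerate(points: np.ndarray, name: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-8:
        raise GeometryError(f"{name} point set is degenerate (collinear)")


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares optimal proper rigid superposition of mobile onto target.

    Returns ``(RigidTransform, rmsd_after_fit)``. A reflection is never
    chosen: the smallest singular direction is flipped when needed.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise GeometryError("kabsch: point sets differ in shape")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise GeometryError("kabsch: need at least 3 points of dimension 3")
    _check_nondegenerate(mobile, "mobile")
    _check_nondegenerate(target, "target")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = tc - rotation @ mc
    transform = RigidTransform(rotation, translation)
    return transform, rmsd(transform.apply(mobile), target)


def consecutive_ca_distances(structure) -> np.ndarray:
    """Euclidean distances between consecutive CA atoms.

    Accepts a BackboneStructure or an (N, 3) array of CA coordinates.
    """
    if isinstance(structure, BackboneStructure):
        ca = structure.ca_coords()
    else:
        ca = np.asarray(structure, dtype=float)
    if ca.ndim != 2 or ca.shape[0] < 2:
        raise GeometryError("need at least 2 CA atoms")
    return np.linalg.norm(np.diff(ca, axis=0), axis=1)


@dataclass
class RegionRMSDReport:
    """Backbone (N, CA, C, O) RMSDs in Angstrom; CB excluded throughout."""

    whole_domain: float  # after its own optimal superposition
    frame: float         # after the frame fit
    cdr1: float
    cdr2: float
    cdr3: float

    def as_dict(self) -> dict[str, float]:
        return {"whole_domain": self.whole_domain, "frame": self.frame,
                "cdr1": self.cdr1, "cdr2": self.cdr2, "cdr3": self.cdr3}


def region_rmsd(model: BackboneStructure, reference: BackboneStructure,
                regions) -> RegionRMSDReport:
    """Frame-fit loop RMSDs plus a globally fit whole-domain RMSD.

    The model is superposed onto the reference using the backbone atoms of
    the frame region only; CDR RMSDs are then measured in that frame fit, so
    loop error is not absorbed by the superposition. The whole-domain value
    uses its own optimal fit.
    """
    if len(model) != len(reference):
        raise GeometryError("model and reference must have the same length")
    frame_idx = regions.frame_indices(len(model))
    if len(frame_idx) < 3:
        raise GeometryError("frame region shorter than 3 residues")

    bb = BACKBONE_ATOMS
    frame_fit, frame_val = kabsch_superpose(
        model.atom_coords(bb, frame_idx), reference.atom_coords(bb, frame_idx))

    def fitted_region(interval) -> float:
        idx = range(*interval)
        moved = frame_fit.apply(model.atom_coords(bb, idx))
        return rmsd(moved, reference.atom_coords(bb, idx))

    _, whole = kabsch_superpose(model.atom_coords(bb), reference.atom_coords(bb))
    return RegionRMSDReport(
        whole_domain=whole,
        frame=frame_val,
        cdr1=fitted_region(regions.cdr1),
        cdr2=fitted_region(regions.cdr2),
        cdr3=fitted_region(regions.cdr3),
    )


@dataclass
class CapriReport:
    ligand_rmsd: float
    interface_rmsd: float
    grade: str  # "medium" | "acceptable" | "incorrect"


def _interface_residues(chain_a: BackboneStructure, chain_b: BackboneStructure,
                        cutoff: float) -> tuple[list[int], list[int]]:
    a = chain_a.atom_coords(BACKBONE_ATOMS)
    b = chain_b.atom_coords(BACKBONE_ATOMS)
    tree_b = cKDTree(b)
    tree_a = cKDTree(a)

    def residues_near(chain, tree_other):
        out = []
        for i, res in enumerate(chain.residues):
            pts = np.array([res.coords[n] for n in BACKBONE_ATOMS])
            if np.any(tree_other.query(pts)[0] < cutoff):
                out.append(i)
        return out

    return residues_near(chain_a, tree_b), residues_near(chain_b, tree_a)


def capri_quality(model_receptor: BackboneStructure, model_ligand: BackboneStructure,
                  native_receptor: BackboneStructure, native_ligand: BackboneStructure,
                  interface_cutoff: float = 10.0) -> CapriReport:
    """CAPRI-style docking quality: ligand RMSD and interface RMSD.

    Ligand RMSD: backbone RMSD of the ligand after superposing the receptors.
    Interface residues: native residues (either chain) with any backbone atom
    within ``interface_cutoff`` of the partner chain. Interface RMSD: backbone
    RMSD of those residues after superposing on the native interface.
    Grades use strict inequalities: medium if ligand < 5 or interface < 2,
    acceptable if ligand < 10 or interface < 4, else incorrect.
    """
    bb = BACKBONE_ATOMS
    rec_fit, _ = kabsch_superpose(model_receptor.atom_coords(bb),
                                  native_receptor.atom_coords(bb))
    ligand_val = rmsd(rec_fit.apply(model_ligand.atom_coords(bb)),
                      native_ligand.atom_coords(bb))

    rec_iface, lig_iface = _interface_residues(native_receptor, native_ligand,
                                               interface_cutoff)
    if not rec_iface and not lig_iface:
        raise GeometryError("no interface residues within cutoff in the native complex")

    native_iface = np.vstack([native_receptor.atom_coords(bb, rec_iface),
                              native_ligand.atom_coords(bb, lig_iface)])
    model_iface = np.vstack([model_receptor.atom_coords(bb, rec_iface),
                             model_ligand.atom_coords(bb, lig_iface)])
    _, interface_val = kabsch_superpose(model_iface, native_iface)

    if ligand_val < 5.0 or interface_val < 2.0:
        grade = "medium"
    elif ligand_val < 10.0 or interface_val < 4.0:
        grade = "acceptable"
    else:
        grade = "incorrect"
    return CapriReport(ligand_val, interface_val, grade)
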