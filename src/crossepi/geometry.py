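"""Rigid-body superposition, RMSD and spatial neighbor queries.

Superposition uses the closed-form Kabsch solution with the SVD sign fix
that forbids improper (reflecting) rotations; homolog pairing goes through
the alignment, not residue-number equality, so members with insertions pair
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .msa import Alignment, classify_columns
from .structio import Residue, Structure, StructureError

__all__ = [
    "GeometryError",
    "SuperpositionResult",
    "kabsch_superpose",
    "paired_ca_coords",
    "neighbor_residues",
    "representative_atom",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation mapping P onto Q, with its RMSD."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def as_matrix_3x4(self) -> np.ndarray:
        return np.hstack([self.rotation, self.translation[:, None]])


def kabsch_superpose(coords_p: np.ndarray, coords_q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q (proper rotations only).

    Returns the rotation R and translation t minimizing ||R p + t - q|| in
    the least-squares sense, with the determinant sign correction that turns
    a reflection into the best proper rotation. Degenerate inputs (fewer than
    3 points, length mismatch, collinear configurations) raise.
    """
    P = np.asarray(coords_p, dtype=float)
    Q = np.asarray(coords_q, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(f"coordinate sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("coordinates must be (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinear or coincident point sets leave the rotation under-determined
    for X, label in ((P0, "P"), (Q0, "Q")):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise GeometryError(f"degenerate (collinear/coincident) configuration in {label}")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def paired_ca_coords(
    struct_a: Structure,
    struct_b: Structure,
    alignment: Alignment,
    a_id: str,
    b_id: str,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Cα coordinate pairs over mutually non-gap alignment columns.

    Structures must be residue-numbered consistently with their sequences in
    the alignment (residue number n = ungapped position n). Returns the two
    (n, 3) arrays plus a table of (column, a_resnum, b_resnum).
    """
    profile = classify_columns(alignment)
    rec_a, rec_b = alignment.get(a_id), alignment.get(b_id)
    rows = []
    pa, pb = [], []
    for col in range(alignment.length):
        if rec_a.residues[col] == "-" or rec_b.residues[col] == "-":
            continue
        na = profile.column_to_residue_number(a_id, col)
        nb = profile.column_to_residue_number(b_id, col)
        res_a = struct_a.find_residue(na)
        res_b = struct_b.find_residue(nb)
        if res_a is None or res_b is None:
            continue
        ca_a, ca_b = res_a.atom("CA"), res_b.atom("CA")
        if ca_a is None or ca_b is None:
            continue
        pa.append(ca_a.coord)
        pb.append(ca_b.coord)
        rows.append({"column": col, "a_resnum": na, "b_resnum": nb})
    if not rows:
        raise GeometryError(f"no Cα pairs between {a_id!r} and {b_id!r}")
    return np.array(pa), np.array(pb), pd.DataFrame(rows)


def representative_atom(residue: Residue):
    """Side-chain anchor atom: Cβ, falling back to Cα (always Cα for Gly)."""
    atom = residue.atom("CB") if residue.name != "GLY" else None
    if atom is None:
        atom = residue.atom("CA")
    if atom is None:
        atom = residue.atoms[0]
    return atom


def neighbor_residues(
    structure: Structure,
    seed_residues: list[tuple[str, int, str]] | list[Residue],
    cutoff: float,
    atom_rule: str = "cb",
) -> set[tuple[str, int, str]]:
    """Residues with a qualifying atom within ``cutoff`` Å of any seed's.

    ``atom_rule='cb'`` uses the Cβ anchor (Cα for Gly); ``'any'`` uses every
    atom. Seeds are included in the result.
    """
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    seeds: list[Residue] = []
    for s in seed_residues:
        if isinstance(s, Residue):
            seeds.append(s)
        else:
            seeds.append(structure.residue(*s))
    if not seeds:
        raise GeometryError("empty seed set")

    def atoms_of(res: Residue) -> np.ndarray:
        if atom_rule == "cb":
            return representative_atom(res).coord[None, :]
        return np.array([a.coord for a in res.atoms])

    all_res = list(structure.residues())
    pts, owner = [], []
    for i, res in enumerate(all_res):
        for c in atoms_of(res):
            pts.append(c)
            owner.append(i)
    tree = cKDTree(np.array(pts))
    seed_pts = np.vstack([atoms_of(r) for r in seeds])
    hits = tree.query_ball_point(seed_pts, r=cutoff)
    found = {all_res[owner[j]].key for lst in hits for j in lst}
    found.update(r.key for r in seeds)
    return found
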