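"""Synthetic structures and alignments with planted, recoverable ground truth.

Every downstream stage — conservation classification, exclusive-difference
detection, superposition, surface area, patch status, electrostatic
comparison — is tested against inputs whose truth is known by construction:

* ideal peptide geometry (extended tripeptides and alpha helices) built from
  internal-coordinate tables by natural-extension (NeRF) placement;
* toy families with planted conserved columns, conservative variation,
  member-exclusive substitutions and a single-member insertion;
* homolog structure pairs differing by chosen side-chain substitutions and
  Gaussian coordinate jitter of known magnitude.

Side chains come from a compact per-residue Z-matrix (bond, angle, dihedral
relative to three already-placed atoms) with a single trans default rotamer:
geometry good enough for surface and charge work without a rotamer library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .msa import (
    AMINO_ACIDS,
    GAP,
    Alignment,
    CLUSTAL_STRONG_GROUPS,
    SequenceRecord,
    write_alignment,
)
from .structio import Atom, Residue, Structure, write_pdb

__all__ = [
    "SyntheticError",
    "ToyFamilySpec",
    "make_extended_tripeptide",
    "make_ideal_helix",
    "make_peptide",
    "make_toy_family",
    "make_homolog_pair",
    "emit_fixture_set",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
]


class SyntheticError(ValueError):
    pass


ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF: position of atom X bonded to p1 with angle X-p1-p2 and dihedral
    X-p1-p2-p3."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    b1 = p1 - p2
    b2 = p2 - p3
    b1 /= np.linalg.norm(b1)
    n = np.cross(b2, b1)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear reference frame; pick any perpendicular
        n = np.cross(b1, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(b1, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, b1)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return p1 + d[0] * b1 + d[1] * m + d[2] * n


# Side-chain Z-matrix per residue: (atom, p1, p2, p3, bond Å, angle°, dihedral°).
# CB is implicit for every non-Gly residue; chi defaults are trans (180°)
# except where ring closure dictates the value.
_CHI = 180.0
_CB = ("CB", "CA", "N", "C", 1.530, 110.5, -122.6)
_SIDE_CHAINS: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "CB", "CA", "N", 1.417, 110.8, _CHI)],
    "CYS": [("SG", "CB", "CA", "N", 1.808, 113.8, _CHI)],
    "THR": [("OG1", "CB", "CA", "N", 1.433, 109.6, _CHI),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, _CHI - 120.0)],
    "VAL": [("CG1", "CB", "CA", "N", 1.527, 110.5, _CHI),
            ("CG2", "CB", "CA", "N", 1.527, 110.5, _CHI - 122.0)],
    "LEU": [("CG", "CB", "CA", "N", 1.530, 116.3, _CHI),
            ("CD1", "CG", "CB", "CA", 1.521, 110.7, _CHI),
            ("CD2", "CG", "CB", "CA", 1.521, 110.7, _CHI - 122.0)],
    "ILE": [("CG1", "CB", "CA", "N", 1.530, 110.4, _CHI),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, _CHI - 122.0),
            ("CD1", "CG1", "CB", "CA", 1.513, 113.8, _CHI)],
    "MET": [("CG", "CB", "CA", "N", 1.520, 114.1, _CHI),
            ("SD", "CG", "CB", "CA", 1.803, 112.7, _CHI),
            ("CE", "SD", "CG", "CB", 1.791, 100.9, _CHI)],
    "PRO": [("CG", "CB", "CA", "N", 1.495, 104.5, 30.0),
            ("CD", "CG", "CB", "CA", 1.507, 106.1, -35.0)],
    "PHE": [("CG", "CB", "CA", "N", 1.502, 113.8, _CHI),
            ("CD1", "CG", "CB", "CA", 1.384, 120.8, 90.0),
            ("CD2", "CG", "CB", "CA", 1.384, 120.8, -90.0),
            ("CE1", "CD1", "CG", "CB", 1.382, 121.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.382, 121.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.382, 120.0, 0.0)],
    "TYR": [("CG", "CB", "CA", "N", 1.502, 113.8, _CHI),
            ("CD1", "CG", "CB", "CA", 1.387, 120.8, 90.0),
            ("CD2", "CG", "CB", "CA", 1.387, 120.8, -90.0),
            ("CE1", "CD1", "CG", "CB", 1.389, 121.1, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.389, 121.1, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.381, 119.6, 0.0),
            ("OH", "CZ", "CE1", "CD1", 1.376, 119.9, 180.0)],
    "TRP": [("CG", "CB", "CA", "N", 1.498, 113.6, _CHI),
            ("CD1", "CG", "CB", "CA", 1.365, 126.9, 90.0),
            ("CD2", "CG", "CB", "CA", 1.433, 126.7, -90.0),
            ("NE1", "CD1", "CG", "CB", 1.374, 110.2, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.409, 107.2, 180.0),
            ("CE3", "CD2", "CG", "CB", 1.398, 133.9, 0.0),
            ("CZ2", "CE2", "CD2", "CG", 1.398, 122.4, 180.0),
            ("CZ3", "CE3", "CD2", "CG", 1.392, 118.6, 180.0),
            ("CH2", "CZ2", "CE2", "CD2", 1.372, 117.5, 180.0)],
    "ASP": [("CG", "CB", "CA", "N", 1.516, 112.6, _CHI),
            ("OD1", "CG", "CB", "CA", 1.249, 118.4, 0.0),
            ("OD2", "CG", "CB", "CA", 1.249, 118.4, 180.0)],
    "ASN": [("CG", "CB", "CA", "N", 1.516, 112.6, _CHI),
            ("OD1", "CG", "CB", "CA", 1.231, 120.8, 0.0),
            ("ND2", "CG", "CB", "CA", 1.328, 116.4, 180.0)],
    "GLU": [("CG", "CB", "CA", "N", 1.520, 114.1, _CHI),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, _CHI),
            ("OE1", "CD", "CG", "CB", 1.249, 118.4, 0.0),
            ("OE2", "CD", "CG", "CB", 1.249, 118.4, 180.0)],
    "GLN": [("CG", "CB", "CA", "N", 1.520, 114.1, _CHI),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, _CHI),
            ("OE1", "CD", "CG", "CB", 1.231, 120.8, 0.0),
            ("NE2", "CD", "CG", "CB", 1.328, 116.4, 180.0)],
    "LYS": [("CG", "CB", "CA", "N", 1.520, 114.1, _CHI),
            ("CD", "CG", "CB", "CA", 1.520, 111.3, _CHI),
            ("CE", "CD", "CG", "CB", 1.520, 111.3, _CHI),
            ("NZ", "CE", "CD", "CG", 1.489, 111.9, _CHI)],
    "ARG": [("CG", "CB", "CA", "N", 1.520, 114.1, _CHI),
            ("CD", "CG", "CB", "CA", 1.520, 111.3, _CHI),
            ("NE", "CD", "CG", "CB", 1.461, 112.0, _CHI),
            ("CZ", "NE", "CD", "CG", 1.329, 124.2, 180.0),
            ("NH1", "CZ", "NE", "CD", 1.326, 120.0, 0.0),
            ("NH2", "CZ", "NE", "CD", 1.326, 120.0, 180.0)],
    "HIS": [("CG", "CB", "CA", "N", 1.497, 113.8, _CHI),
            ("ND1", "CG", "CB", "CA", 1.371, 122.7, 90.0),
            ("CD2", "CG", "CB", "CA", 1.356, 131.0, -90.0),
            ("CE1", "ND1", "CG", "CB", 1.319, 109.2, 180.0),
            ("NE2", "CD2", "CG", "CB", 1.374, 107.2, 180.0)],
}


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def make_peptide(
    sequence: str,
    phi: float,
    psi: float,
    omega: float = 180.0,
    structure_id: str = "peptide",
    chain: str = "A",
) -> Structure:
    """Build an all-heavy-atom peptide at uniform backbone dihedrals.

    Residue ``i`` (1-based) gets number ``i``; side chains are placed at the
    default trans rotamer from the internal Z-matrix table.
    """
    sequence = sequence.upper()
    if not sequence:
        raise SyntheticError("empty sequence")
    for ch in sequence:
        if ch not in ONE_TO_THREE:
            raise SyntheticError(f"invalid residue {ch!r}")

    # seed the first three backbone atoms
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + np.array([-_B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, len(sequence)):
        prev = backbone[-1]
        n = _place(prev["C"], prev["CA"], prev["N"], _B_C_N, _A_CA_C_N, psi)
        ca = _place(n, prev["C"], prev["CA"], _B_N_CA, _A_C_N_CA, omega)
        c = _place(ca, n, prev["C"], _B_CA_C, _A_N_CA_C, phi)
        backbone.append({"N": n, "CA": ca, "C": c})

    residues: list[Residue] = []
    serial = 0
    for i, one in enumerate(sequence):
        res3 = ONE_TO_THREE[one]
        bb = backbone[i]
        pos: dict[str, np.ndarray] = dict(bb)
        # carbonyl O: anti to the next N (trans peptide), psi-based for the last
        if i + 1 < len(sequence):
            next_n = backbone[i + 1]["N"]
            pos["O"] = _place(bb["C"], bb["CA"], next_n, _B_C_O, _A_CA_C_O, 180.0)
        else:
            pos["O"] = _place(bb["C"], bb["CA"], bb["N"], _B_C_O, _A_CA_C_O, psi - 180.0)
            pos["OXT"] = _place(bb["C"], bb["CA"], bb["N"], _B_C_O, _A_CA_C_O, psi)
        if res3 != "GLY":
            pos["CB"] = _place(bb["CA"], bb["N"], bb["C"], _CB[4], _CB[5], _CB[6])
        for name, p1, p2, p3, bond, angle, dihedral in _SIDE_CHAINS[res3]:
            pos[name] = _place(pos[p1], pos[p2], pos[p3], bond, angle, dihedral)

        order = ["N", "CA", "C", "O", "CB"] + [e[0] for e in _SIDE_CHAINS[res3]] + ["OXT"]
        atoms = []
        for name in order:
            if name not in pos:
                continue
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=_element_of(name), coord=pos[name]))
        residues.append(Residue(chain=chain, number=i + 1, name=res3, atoms=atoms))
    return Structure(id=structure_id, chains={chain: residues})


def make_extended_tripeptide(x_residue: str) -> Structure:
    """Gly-X-Gly at the fully extended backbone (phi = psi = omega = 180°).

    This is the reference conformation for relative-exposure normalization.
    """
    x = x_residue.upper()
    if len(x) == 3:
        x = THREE_TO_ONE.get(x, "")
    if x not in ONE_TO_THREE:
        raise SyntheticError(f"nonstandard residue {x_residue!r}")
    return make_peptide("G" + x + "G", phi=180.0, psi=180.0, omega=180.0,
                        structure_id=f"GXG_{ONE_TO_THREE[x]}")


def make_ideal_helix(sequence: str, structure_id: str = "helix") -> Structure:
    """Ideal alpha helix (phi = -57°, psi = -47°, omega = 180°), length >= 4."""
    if len(sequence) < 4:
        raise SyntheticError("helix needs at least 4 residues")
    return make_peptide(sequence, phi=-57.0, psi=-47.0, omega=180.0, structure_id=structure_id)


@dataclass
class ToyFamilySpec:
    """Specification of a toy alignment family with planted ground truth.

    Column indices are 0-based into the final alignment. Planted column sets
    must be disjoint; the family's deviant member is ``records[target_index]``.
    """

    n_members: int
    length: int
    seed: int
    conserved_columns: tuple[int, ...] = ()
    conservative_columns: tuple[int, ...] = ()
    exclusive_substitutions: tuple[tuple[int, str, str], ...] = ()  # (col, family, target)
    insertion: tuple[int, str] | None = None  # (col, target residue)
    target_index: int = -1

    def __post_init__(self) -> None:
        if self.n_members < 3:
            raise SyntheticError("need at least 3 members")
        planted: list[int] = list(self.conserved_columns) + list(self.conservative_columns)
        planted += [c for c, _, _ in self.exclusive_substitutions]
        if self.insertion is not None:
            planted.append(self.insertion[0])
        if len(set(planted)) != len(planted):
            raise SyntheticError("planted column sets overlap")
        if any(not 0 <= c < self.length for c in planted):
            raise SyntheticError("planted column outside alignment length")
        for col, fam, tgt in self.exclusive_substitutions:
            if fam == tgt or fam not in AMINO_ACIDS or tgt not in AMINO_ACIDS:
                raise SyntheticError(f"invalid exclusive substitution at column {col}")
        if self.insertion is not None and self.insertion[1] not in AMINO_ACIDS:
            raise SyntheticError("invalid insertion residue")


def make_toy_family(spec: ToyFamilySpec) -> tuple[Alignment, dict]:
    """Generate an alignment realizing exactly the planted structure.

    Returns the alignment and a ground-truth record with the planted events
    in detection order. Unplanted columns are random but constructed so the
    target never deviates exclusively there (the target copies a family
    member's residue), keeping planted truth exact.
    """
    rng = np.random.default_rng(spec.seed)
    aas = sorted(AMINO_ACIDS)
    n, L = spec.n_members, spec.length
    t = spec.target_index % n
    cols = np.empty((L, n), dtype="U1")

    conserved = set(spec.conserved_columns)
    conservative = set(spec.conservative_columns)
    exclusive = {c: (f, g) for c, f, g in spec.exclusive_substitutions}
    ins_col = None if spec.insertion is None else spec.insertion[0]

    for col in range(L):
        if col in conserved:
            cols[col, :] = rng.choice(aas)
        elif col in conservative:
            group = sorted(CLUSTAL_STRONG_GROUPS[rng.integers(len(CLUSTAL_STRONG_GROUPS))])
            picks = rng.choice(group, size=n)
            others = [i for i in range(n) if i != t]
            # force variation among the non-target members: guarantees the
            # column is conservative, never a spurious exclusive substitution
            if len({picks[i] for i in others}) == 1:
                alt = [g for g in group if g != picks[others[0]]]
                picks[others[int(rng.integers(len(others)))]] = alt[int(rng.integers(len(alt)))]
            cols[col, :] = picks
        elif col in exclusive:
            fam, tgt = exclusive[col]
            cols[col, :] = fam
            cols[col, t] = tgt
        elif col == ins_col:
            cols[col, :] = GAP
            cols[col, t] = spec.insertion[1]
        else:
            picks = rng.choice(aas, size=n)
            others = [i for i in range(n) if i != t]
            # target copies a family member so it can never be exclusive here
            picks[t] = picks[others[int(rng.integers(len(others)))]]
            cols[col, :] = picks

    records = []
    for i in range(n):
        rid = f"target" if i == t else f"member{i + 1}"
        records.append(SequenceRecord(rid, "".join(cols[:, i])))
    aln = Alignment(records, reference_id=records[t].id)

    truth = {
        "target_id": records[t].id,
        "substitutions": [
            {"column": c, "family_residue": f, "target_residue": g}
            for c, f, g in sorted(spec.exclusive_substitutions)
        ],
        "insertion": None
        if spec.insertion is None
        else {"column": spec.insertion[0], "target_residue": spec.insertion[1]},
        "conserved_columns": sorted(conserved),
        "conservative_columns": sorted(conservative),
    }
    return aln, truth


def make_homolog_pair(
    sequence: str,
    substitutions: dict[int, str] | None = None,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure, list[tuple[int, int]]]:
    """Ideal-helix homolog pair: B carries side-chain substitutions plus
    Gaussian jitter of ``jitter_sigma`` Å on every atom; pairing is positional.

    ``substitutions`` maps 1-based residue positions to new one-letter codes.
    """
    substitutions = substitutions or {}
    if jitter_sigma < 0:
        raise SyntheticError("jitter_sigma must be >= 0")
    seq_b = list(sequence.upper())
    for pos, new in substitutions.items():
        if not 1 <= pos <= len(seq_b):
            raise SyntheticError(f"substitution position {pos} out of range")
        if new.upper() not in ONE_TO_THREE:
            raise SyntheticError(f"invalid residue {new!r}")
        seq_b[pos - 1] = new.upper()
    a = make_ideal_helix(sequence, structure_id="homolog_a")
    b = make_ideal_helix("".join(seq_b), structure_id="homolog_b")
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        for _, atom in b.atoms():
            atom.coord = atom.coord + rng.normal(scale=jitter_sigma, size=3)
    pairing = [(i + 1, i + 1) for i in range(len(sequence))]
    return a, b, pairing


def make_analysis_bundle(out_dir: str | Path, seed: int = 7) -> dict:
    """Write a complete synthetic study to ``out_dir`` and return its ground truth.

    The bundle mirrors the structure of a real hypoallergen analysis: a
    6-member family in which the target member carries exactly four
    exclusive substitutions and one single-column insertion; helix
    structures for the target and one reference member whose sequences match
    the alignment; a five-patch table in reference numbering placing two
    patches on substituted columns, one next to the insertion and two on
    untouched conserved surface; and a ready-to-run pipeline config.

    Planted truth (0-based columns): substitutions at 2 (N->K), 7 (V->G),
    15 (Q->K), 18 (V->M); insertion S at column 30. Patch 1 contains the
    column-2 and column-7 substitutions, patch 3 the column-15 one; patch 2
    flanks the insertion on the helix; patches 4 and 5 are fully conserved
    and spatially remote from every planted change; the column-18
    substitution falls outside all patches.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    planted = {2, 7, 15, 18, 30}
    spec = ToyFamilySpec(
        n_members=6,
        length=60,
        seed=seed,
        conserved_columns=tuple(c for c in range(46) if c not in planted),
        conservative_columns=(48, 50),
        exclusive_substitutions=((2, "N", "K"), (7, "V", "G"), (15, "Q", "K"), (18, "V", "M")),
        insertion=(30, "S"),
    )
    aln, truth = make_toy_family(spec)
    reference_id = "member1"
    target_id = truth["target_id"]
    write_alignment(aln, out / "family.fasta")

    structures = {}
    for member in (reference_id, target_id):
        seq = aln.get(member).ungapped
        st = make_peptide(seq, phi=-57.0, psi=-47.0, structure_id=member)
        path = out / f"structure_{member}.pdb"
        write_pdb(st, path)
        structures[member] = str(path)

    # patch table in reference (member1) numbering; member1 is gapped only at
    # the insertion column, so resnum = column+1 before it and column after
    def ref_num(col: int) -> int:
        return col + 1 if col < 30 else col

    patch_rows = [
        (1, "cyan", [ref_num(c) for c in (2, 4, 7)]),
        (2, "red", [ref_num(c) for c in (32, 33, 34)]),
        (3, "yellow", [ref_num(c) for c in (15, 17)]),
        (4, "green", [ref_num(c) for c in (40, 41, 43, 44)]),
        (5, "blue", [ref_num(c) for c in (21, 23)]),
    ]
    patch_path = out / "patches.tsv"
    with open(patch_path, "w") as fh:
        fh.write("# synthetic patch table generated by make_analysis_bundle\n")
        fh.write("patch_id\tlabel\tresidue_number\n")
        for pid, label, nums in patch_rows:
            for n in nums:
                fh.write(f"{pid}\t{label}\t{n}\n")

    config = {
        "alignment_path": str(out / "family.fasta"),
        "alignment_format": "fasta",
        "target_id": target_id,
        "reference_id": reference_id,
        "structures": structures,
        "patch_path": str(patch_path),
        "output_dir": str(out / "results"),
        "seed": seed,
    }
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    truth.update(
        {
            "reference_id": reference_id,
            "config_path": str(config_path),
            "expected_patch_status": {
                1: "substituted",
                2: "insertion_adjacent",
                3: "substituted",
                4: "conserved",
                5: "conserved",
            },
            "n_substitutions_in_patches": 3,
        }
    )
    return truth


def emit_fixture_set(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Write a standard synthetic test set (PDBs + aligned FASTA) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    helix = make_ideal_helix("ADKLQESNVRGT", structure_id="helix")
    paths["helix.pdb"] = out / "helix.pdb"
    write_pdb(helix, paths["helix.pdb"])

    a, b, _ = make_homolog_pair("ADKLQESNVRGT", {3: "N"}, jitter_sigma=0.2, seed=seed)
    paths["homolog_a.pdb"] = out / "homolog_a.pdb"
    paths["homolog_b.pdb"] = out / "homolog_b.pdb"
    write_pdb(a, paths["homolog_a.pdb"])
    write_pdb(b, paths["homolog_b.pdb"])

    planted = {2, 7, 10, 15, 18}
    spec = ToyFamilySpec(
        n_members=6,
        length=40,
        seed=seed,
        conserved_columns=tuple(c for c in range(20) if c not in planted),
        conservative_columns=(22, 24),
        exclusive_substitutions=((2, "N", "K"), (7, "V", "G"), (15, "Q", "K"), (18, "V", "M")),
        insertion=(10, "S"),
    )
    aln, truth = make_toy_family(spec)
    paths["family.fasta"] = out / "family.fasta"
    write_alignment(aln, paths["family.fasta"])
    return paths
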