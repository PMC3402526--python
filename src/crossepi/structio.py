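"""PDB-format structure I/O and van-der-Waals radius assignment.

A deliberately small heavy-atom container sits between the file format and
the geometry/surface/electrostatics machinery: chains of residues of atoms,
each atom carrying coordinates, an element, an assignable van-der-Waals
radius, and a B-factor slot that doubles as a generic per-atom output channel
(solvent exposure, surface potential) for rendering in any structure viewer.

Parsing and writing go through gemmi; the policies applied on read are the
ones a surface calculation wants: first model only, highest-occupancy
alternate locations, waters and heteroatoms dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "RADII_SETS",
    "read_pdb",
    "write_pdb",
    "assign_radii",
]


class StructureError(ValueError):
    """Raised for unparseable, empty or inconsistent structures."""


#: Published protein heavy-atom radius sets (Å). The default "chothia" set
#: distinguishes carbonyl/carboxylate/aromatic sp2 carbon from aliphatic.
RADII_SETS: dict[str, dict[str, float]] = {
    "chothia": {"N": 1.65, "O": 1.40, "C_SP2": 1.76, "C": 1.87, "S": 1.85, "H": 1.00, "P": 1.80},
    "bondi": {"N": 1.55, "O": 1.52, "C_SP2": 1.70, "C": 1.70, "S": 1.80, "H": 1.20, "P": 1.80},
}

# side-chain carbons treated as sp2 (carbonyl/carboxylate/amide/aromatic/guanidinium)
_SP2_SIDE_CHAIN = {
    ("ASP", "CG"), ("ASN", "CG"), ("GLU", "CD"), ("GLN", "CD"), ("ARG", "CZ"),
    ("PHE", "CG"), ("PHE", "CD1"), ("PHE", "CD2"), ("PHE", "CE1"), ("PHE", "CE2"), ("PHE", "CZ"),
    ("TYR", "CG"), ("TYR", "CD1"), ("TYR", "CD2"), ("TYR", "CE1"), ("TYR", "CE2"), ("TYR", "CZ"),
    ("TRP", "CG"), ("TRP", "CD1"), ("TRP", "CD2"), ("TRP", "CE2"), ("TRP", "CE3"),
    ("TRP", "CZ2"), ("TRP", "CZ3"), ("TRP", "CH2"),
    ("HIS", "CG"), ("HIS", "CD2"), ("HIS", "CE1"),
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float | None = None
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise StructureError(f"atom {self.name}: vdw radius must be positive")


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_standard(self) -> bool:
        return self.name in _STANDARD_AA


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(self.chains.values()):
            raise StructureError(f"structure {self.id!r} is empty")
        seen: set[tuple[str, int, str]] = set()
        for residues in self.chains.values():
            for r in residues:
                if not r.atoms:
                    raise StructureError(f"residue {r.key} has no atoms")
                if r.key in seen:
                    raise StructureError(f"duplicate residue key {r.key}")
                seen.add(r.key)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for r in self.chains.get(chain, []):
            if r.number == number and r.icode == icode:
                return r
        raise StructureError(f"residue {(chain, number, icode)} not in structure {self.id!r}")

    def find_residue(self, number: int) -> Residue | None:
        """First residue with this number across chains (single-chain convenience)."""
        for r in self.residues():
            if r.number == number:
                return r
        return None

    def ca_atom(self, chain: str, number: int, icode: str = "") -> Atom | None:
        try:
            return self.residue(chain, number, icode).atom("CA")
        except StructureError:
            return None

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = [a.coord for _, a in self.atoms() if not (heavy_only and a.element == "H")]
        return np.array(pts, dtype=float)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


def _element_from_atom(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper().strip()
    if el and el != "X":
        return el
    name = atom.name.strip()
    if name[:1].isdigit():
        name = name[1:]
    for cand in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA"):
        if name.upper().startswith(cand) and len(name) > 1:
            return cand
    return name[:1].upper()


def read_pdb(
    path: str | Path,
    model_policy: str = "first",
    altloc_policy: str = "occupancy",
    het_policy: str = "drop",
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Policies: ``model_policy='first'`` keeps the first model;
    ``altloc_policy='occupancy'`` keeps the highest-occupancy alternate
    location (label order breaks ties); ``het_policy='drop'`` removes waters
    and other heteroatoms, ``'keep'`` retains non-water heteroatoms.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.remove_empty_chains()
    if len(st) == 0:
        raise StructureError(f"{path}: no ATOM records")
    if model_policy != "first":
        raise StructureError(f"unsupported model_policy {model_policy!r}")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    serial = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            is_water = res.name in ("HOH", "WAT", "DOD")
            is_het = res.het_flag == "H" and res.name not in _STANDARD_AA
            if is_water or (het_policy == "drop" and is_het):
                continue
            # group altlocs by atom name, keep the winner
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            atoms: list[Atom] = []
            for name, group in by_name.items():
                if altloc_policy == "occupancy" and len(group) > 1:
                    best = max(enumerate(group), key=lambda t: (t[1].occ, -t[0]))[1]
                else:
                    best = group[0]
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=_element_from_atom(best),
                        coord=np.array([best.pos.x, best.pos.y, best.pos.z]),
                        bfactor=best.b_iso,
                        occupancy=best.occ,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain=chain.name or "A",
                        number=res.seqid.num,
                        name=res.name,
                        atoms=atoms,
                        icode=(res.seqid.icode or "").strip(),
                    )
                )
        if residues:
            chains[chain.name or "A"] = residues
    if not chains:
        raise StructureError(f"{path}: no residues survive the read policies")
    return Structure(id=path.stem, chains=chains)


# PDB B-factor field is %6.2f
_BFACTOR_MIN, _BFACTOR_MAX = -9.99, 999.99


def write_pdb(
    structure: Structure,
    path: str | Path,
    bfactor_channel: Mapping[tuple[tuple[str, int, str], str], float] | None = None,
) -> None:
    """Write fixed-column PDB; optionally route per-atom values into B-factors.

    ``bfactor_channel`` maps ``(residue.key, atom_name)`` to a finite value;
    values are clamped to the field width [-9.99, 999.99]. Keys that match no
    atom raise.
    """
    if bfactor_channel is not None:
        known = {(r.key, a.name) for r, a in structure.atoms()}
        unknown = [k for k in bfactor_channel if k not in known]
        if unknown:
            raise StructureError(f"bfactor channel refers to unknown atoms: {unknown[:5]}")
        for v in bfactor_channel.values():
            if not math.isfinite(v):
                raise StructureError("bfactor channel values must be finite")

    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain_name, residues in structure.chains.items():
        chain = gemmi.Chain(chain_name)
        for res in residues:
            g = gemmi.Residue()
            g.name = res.name
            g.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                b = a.bfactor
                if bfactor_channel is not None:
                    b = bfactor_channel.get((res.key, a.name), 0.0)
                ga.b_iso = min(max(b, _BFACTOR_MIN), _BFACTOR_MAX)
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def assign_radii(structure: Structure, radii_set_id: str = "chothia") -> Structure:
    """Assign van-der-Waals radii in place (and return the structure).

    Backbone carbonyl carbons (atom name ``C``) and the sp2 side-chain
    carbons of the aromatic/amide/carboxylate groups take the set's sp2
    carbon radius; other carbons the aliphatic one. Unresolvable elements
    raise, listing the offending atoms.
    """
    try:
        table = RADII_SETS[radii_set_id]
    except KeyError:
        raise StructureError(
            f"unknown radii set {radii_set_id!r}; available: {sorted(RADII_SETS)}"
        ) from None
    unresolved: list[str] = []
    for res, atom in structure.atoms():
        el = atom.element.upper()
        if el == "C":
            key = "C_SP2" if (atom.name == "C" or (res.name, atom.name) in _SP2_SIDE_CHAIN) else "C"
        else:
            key = el
        if key not in table:
            unresolved.append(f"{res.key}/{atom.name} ({el})")
            continue
        atom.vdw_radius = table[key]
    if unresolved:
        raise StructureError(f"cannot assign radii to atoms: {unresolved[:10]}")
    return structure
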