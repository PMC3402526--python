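"""Shrake-Rupley solvent-accessible surface area and relative exposure.

Each heavy atom is inflated by the probe radius (1.4 Å water by default) and
covered with a deterministic generalized-spiral point lattice; the fraction
of lattice points not buried inside any neighboring inflated sphere gives
the atom's accessible area. Per-residue areas are normalized against the
same residue computed as X in an extended Gly-X-Gly tripeptide, yielding the
percent relative exposure used to call residues "exposed" (>= 30% here).

The lattice is expressed in a frame derived from the molecule's own
principal axes, so rigidly moving the whole structure moves the lattice with
it and leaves every area numerically unchanged — a property random-point
implementations lack and that makes reruns exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure, StructureError, assign_radii

__all__ = [
    "SasaError",
    "SasaTable",
    "sphere_lattice",
    "shrake_rupley",
    "gly_x_gly_reference",
    "relative_exposure",
    "exposed_set",
    "write_sasa_tsv",
]

ResKey = tuple[str, int, str]


class SasaError(ValueError):
    pass


@dataclass
class SasaTable:
    """Per-atom and per-residue accessible areas plus the parameters used.

    ``atom_directions`` stores, for each accessible atom, the mean outward
    unit vector of its accessible lattice points (None when fully buried) —
    the anchor used to place surface evaluation points for electrostatics.
    """

    atom_areas: dict[tuple[ResKey, str], float]
    residue_areas: dict[ResKey, float]
    residue_names: dict[ResKey, str]
    atom_directions: dict[tuple[ResKey, str], np.ndarray | None]
    params: dict = field(default_factory=dict)
    relative: dict[ResKey, float] | None = None
    over_100: list[ResKey] = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return float(sum(self.atom_areas.values()))


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) unit-sphere lattice."""
    if n_points < 60:
        raise SasaError("n_points must be >= 60 for a usable lattice")
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _molecule_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame tied to the molecule's principal axes.

    Signs are fixed deterministically (largest-magnitude component of each
    axis made positive; handedness restored on the last axis), so the frame
    co-rotates with rigid motions of the molecule.
    """
    if len(coords) < 2:
        return np.eye(3)
    X = coords - coords.mean(axis=0)
    cov = X.T @ X
    _, vecs = np.linalg.eigh(cov)
    axes = vecs.T[::-1].copy()  # descending variance
    for k in range(3):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k][j] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def shrake_rupley(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    seed: int | None = None,
    randomize: bool = False,
) -> SasaTable:
    """Heavy-atom Shrake-Rupley SASA with a deterministic lattice.

    ``randomize`` replaces the spiral lattice by a seeded random one (kept
    for convergence experiments; the default is exactly reproducible and
    rigid-motion invariant). Radii must have been assigned beforehand.
    """
    atoms = []
    for res, atom in structure.atoms():
        if atom.element == "H":
            continue
        if atom.vdw_radius is None:
            raise SasaError(
                f"atom {res.key}/{atom.name} has no vdw radius; run assign_radii first"
            )
        atoms.append((res, atom))
    if not atoms:
        raise SasaError("no heavy atoms")

    centers = np.array([a.coord for _, a in atoms])
    radii = np.array([a.vdw_radius + probe_radius for _, a in atoms])

    if randomize:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n_points, 3))
        unit = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        unit = sphere_lattice(n_points) @ _molecule_frame(centers)

    tree = cKDTree(centers)
    rmax = radii.max()
    point_area = 4.0 * math.pi / n_points

    atom_areas: dict[tuple[ResKey, str], float] = {}
    atom_dirs: dict[tuple[ResKey, str], np.ndarray | None] = {}
    residue_areas: dict[ResKey, float] = {}
    residue_names: dict[ResKey, str] = {}
    for i, (res, atom) in enumerate(atoms):
        pts = centers[i] + radii[i] * unit
        nbrs = [j for j in tree.query_ball_point(centers[i], radii[i] + rmax) if j != i]
        if nbrs:
            d2 = ((pts[:, None, :] - centers[nbrs][None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= (radii[nbrs] ** 2)[None, :]).all(axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        n_acc = int(accessible.sum())
        area = n_acc * point_area * radii[i] ** 2
        key = (res.key, atom.name)
        atom_areas[key] = area
        if n_acc:
            mean_dir = unit[accessible].mean(axis=0)
            norm = np.linalg.norm(mean_dir)
            atom_dirs[key] = mean_dir / norm if norm > 1e-12 else None
        else:
            atom_dirs[key] = None
        residue_areas[res.key] = residue_areas.get(res.key, 0.0) + area
        residue_names[res.key] = res.name

    params = {
        "probe_radius": probe_radius,
        "n_points": n_points,
        "heavy_atoms_only": True,
        "lattice": "random" if randomize else "spiral",
        "seed": seed,
    }
    return SasaTable(
        atom_areas=atom_areas,
        residue_areas=residue_areas,
        residue_names=residue_names,
        atom_directions=atom_dirs,
        params=params,
    )


@lru_cache(maxsize=128)
def _gxg_reference_cached(
    res_type: str, probe_radius: float, n_points: int, radii_set_id: str
) -> float:
    from .synthetic import make_extended_tripeptide

    tri = make_extended_tripeptide(res_type)
    assign_radii(tri, radii_set_id)
    table = shrake_rupley(tri, probe_radius=probe_radius, n_points=n_points)
    central = [k for k in table.residue_areas if k[1] == 2]
    return table.residue_areas[central[0]]


def gly_x_gly_reference(
    res_type: str,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii_set_id: str = "chothia",
) -> float:
    """Maximal accessible area (Å²) of residue X in an extended Gly-X-Gly.

    The tripeptide is generated internally with the same lattice parameters
    as the query structure, so the normalization is self-consistent rather
    than table-driven. Cached per parameter set.
    """
    res_type = res_type.upper()
    area = _gxg_reference_cached(res_type, float(probe_radius), int(n_points), radii_set_id)
    return area


def relative_exposure(
    table: SasaTable, radii_set_id: str = "chothia"
) -> dict[ResKey, float]:
    """Percent exposure per residue: residue SASA / Gly-X-Gly reference x100.

    Values above 100 (possible for distorted conformers) are kept as-is and
    the offending residues recorded in ``table.over_100``.
    """
    rel: dict[ResKey, float] = {}
    over: list[ResKey] = []
    for key, area in table.residue_areas.items():
        name = table.residue_names[key]
        ref = gly_x_gly_reference(
            name,
            probe_radius=table.params["probe_radius"],
            n_points=table.params["n_points"],
            radii_set_id=radii_set_id,
        )
        pct = 100.0 * area / ref
        rel[key] = pct
        if pct > 100.0:
            over.append(key)
    table.relative = rel
    table.over_100 = over
    table.params.setdefault("radii_set_id", radii_set_id)
    return rel


def exposed_set(table: SasaTable, threshold: float = 30.0) -> set[ResKey]:
    """Residues whose relative exposure meets the threshold (percent).

    A threshold of 0 returns every residue with positive area.
    """
    if table.relative is None:
        raise SasaError("relative exposure not computed; call relative_exposure first")
    if threshold == 0:
        return {k for k, a in table.residue_areas.items() if a > 0}
    return {k for k, v in table.relative.items() if v >= threshold}


def write_sasa_tsv(table: SasaTable, path: str | Path) -> None:
    """Atom- and residue-level TSV with a parameter header block."""
    with open(path, "w") as fh:
        for k, v in table.params.items():
            fh.write(f"# {k}\t{v}\n")
        fh.write("# atom-level\nchain\tresnum\ticode\tresname\tatom\tarea\n")
        for (rkey, aname), area in table.atom_areas.items():
            fh.write(
                f"{rkey[0]}\t{rkey[1]}\t{rkey[2]}\t{table.residue_names[rkey]}\t"
                f"{aname}\t{area:.4f}\n"
            )
        fh.write("# residue-level\nchain\tresnum\ticode\tresname\tarea\trelative\n")
        for rkey, area in table.residue_areas.items():
            rel = "" if table.relative is None else f"{table.relative[rkey]:.2f}"
            fh.write(
                f"{rkey[0]}\t{rkey[1]}\t{rkey[2]}\t{table.residue_names[rkey]}\t"
                f"{area:.4f}\t{rel}\n"
            )
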