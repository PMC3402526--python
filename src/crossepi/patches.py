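"""Conserved surface patches: areas, disruption status, spatial contiguity.

A patch is a predefined set of residues, given in the numbering of the
alignment's reference member, proposed as a conformational cross-reactive
epitope. For each patch this module measures the solvent-accessible area
contributed by its family-invariant members, asks whether a candidate
hypoallergen disrupts the patch (an exclusive substitution on a member, or
an exclusive insertion on or near it), and checks that the patch is a single
spatial cluster even though its members are non-contiguous in sequence.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import neighbor_residues
from .msa import (
    AlignmentError,
    ConservationClass,
    ConservationProfile,
    DifferenceKind,
    ExclusiveDifference,
)
from .structio import Structure

__all__ = [
    "PatchError",
    "PatchDefinition",
    "PatchStatus",
    "PatchReport",
    "load_patch_definitions",
    "write_patch_definitions",
    "patch_conserved_area",
    "patch_status",
    "patch_contiguity",
]


class PatchError(ValueError):
    pass


@dataclass(frozen=True)
class PatchDefinition:
    """A surface patch: reference-numbered member residues plus a label."""

    id: int
    label: str
    residue_numbers: tuple[int, ...]
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.residue_numbers:
            raise PatchError(f"patch {self.id}: empty residue list")


class PatchStatus(enum.Enum):
    CONSERVED = "conserved"
    SUBSTITUTED = "substituted"
    INSERTION_ADJACENT = "insertion_adjacent"
    SUBSTITUTED_AND_INSERTION_ADJACENT = "substituted_and_insertion_adjacent"


@dataclass
class PatchReport:
    patch_id: int
    label: str
    residues_found: list[int]
    residues_missing: list[int]
    conserved_area: float
    status: PatchStatus
    disruptions: list[ExclusiveDifference] = field(default_factory=list)
    contiguity_components: int | None = None

    def to_dict(self) -> dict:
        return {
            "patch_id": self.patch_id,
            "label": self.label,
            "residues_found": self.residues_found,
            "residues_missing": self.residues_missing,
            "conserved_area": self.conserved_area,
            "status": self.status.value,
            "disruptions": [
                {
                    "column": d.column,
                    "kind": d.kind.value,
                    "family_residue": d.family_residue,
                    "target_residue": d.target_residue,
                    "target_resnum": d.target_resnum,
                }
                for d in self.disruptions
            ],
            "contiguity_components": self.contiguity_components,
        }


def load_patch_definitions(path: str | Path) -> list[PatchDefinition]:
    """Read a patch TSV with columns patch_id, label, residue_number.

    Lines starting with ``#`` are header/provenance comments. Duplicate
    patch ids with conflicting labels, or empty patches, raise.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"patch_id", "label", "residue_number"}
    if not required <= set(df.columns):
        raise PatchError(f"patch file must have columns {sorted(required)}, got {list(df.columns)}")
    defs: list[PatchDefinition] = []
    for pid, grp in df.groupby("patch_id", sort=True):
        labels = set(grp["label"])
        if len(labels) != 1:
            raise PatchError(f"patch {pid}: conflicting labels {sorted(labels)}")
        nums = tuple(int(n) for n in grp["residue_number"])
        if len(set(nums)) != len(nums):
            raise PatchError(f"patch {pid}: duplicate residue numbers")
        defs.append(PatchDefinition(int(pid), labels.pop(), nums, source_note=str(path)))
    if not defs:
        raise PatchError(f"no patches in {path}")
    return defs


def write_patch_definitions(defs: list[PatchDefinition], path: str | Path,
                            header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("patch_id\tlabel\tresidue_number\n")
        for d in defs:
            for n in d.residue_numbers:
                fh.write(f"{d.id}\t{d.label}\t{n}\n")


def _reference_to_member_resnums(
    profile: ConservationProfile,
    reference_id: str,
    member_id: str,
    reference_resnums: tuple[int, ...],
) -> tuple[dict[int, int | None], dict[int, int]]:
    """Map reference residue numbers -> (member residue number or None, column)."""
    mapped: dict[int, int | None] = {}
    columns: dict[int, int] = {}
    for rn in reference_resnums:
        col = profile.residue_number_to_column(reference_id, rn)
        columns[rn] = col
        mapped[rn] = profile.column_to_residue_number(member_id, col)
    return mapped, columns


def patch_conserved_area(
    structure: Structure,
    sasa_table,
    patch: PatchDefinition,
    profile: ConservationProfile,
    reference_id: str,
    member_id: str | None = None,
) -> tuple[float, PatchReport]:
    """Summed SASA (Å²) of the patch members classified fully conserved.

    The patch is defined in ``reference_id`` numbering; ``member_id`` names
    the member the structure belongs to (defaults to the reference). Members
    absent from the structure are reported, never silently dropped.
    """
    member_id = member_id or reference_id
    mapped, columns = _reference_to_member_resnums(
        profile, reference_id, member_id, patch.residue_numbers
    )
    found: list[int] = []
    missing: list[int] = []
    area = 0.0
    n_mappable = 0
    for ref_rn in patch.residue_numbers:
        member_rn = mapped[ref_rn]
        res = structure.find_residue(member_rn) if member_rn is not None else None
        if res is None:
            missing.append(ref_rn)
            continue
        n_mappable += 1
        found.append(ref_rn)
        if profile.classes[columns[ref_rn]] is ConservationClass.FULLY_CONSERVED:
            if res.key not in sasa_table.residue_areas:
                raise PatchError(f"residue {res.key} missing from SASA table")
            area += sasa_table.residue_areas[res.key]
    if n_mappable == 0:
        raise PatchError(f"patch {patch.id}: no members mappable onto structure {structure.id!r}")
    report = PatchReport(
        patch_id=patch.id,
        label=patch.label,
        residues_found=found,
        residues_missing=missing,
        conserved_area=area,
        status=PatchStatus.CONSERVED,
    )
    return area, report


def patch_status(
    patch: PatchDefinition,
    profile: ConservationProfile,
    differences: list[ExclusiveDifference],
    structure: Structure,
    reference_id: str,
    target_id: str,
    adjacency_cutoff: float = 8.0,
) -> tuple[PatchStatus, list[ExclusiveDifference]]:
    """Classify how a target member's exclusive differences affect a patch.

    SUBSTITUTED when an exclusive substitution falls on a patch member
    column; INSERTION_ADJACENT when an exclusive insertion's residue lies on
    the patch or within ``adjacency_cutoff`` Å (Cβ rule) of a patch residue
    in the target's structure; both → the combined status; otherwise
    CONSERVED. ``structure`` is the target member's structure (its residue
    numbers are target numbering).
    """
    try:
        profile.col_to_resnum[target_id]
    except KeyError:
        raise AlignmentError(f"target {target_id!r} not in profile") from None
    patch_cols = {
        profile.residue_number_to_column(reference_id, rn) for rn in patch.residue_numbers
    }
    # patch residues in target numbering, for spatial adjacency
    target_patch_resnums = {
        profile.column_to_residue_number(target_id, c) for c in patch_cols
    } - {None}

    hits: list[ExclusiveDifference] = []
    substituted = insertion_adjacent = False
    for d in differences:
        if d.kind is DifferenceKind.SUBSTITUTION:
            if d.column in patch_cols:
                substituted = True
                hits.append(d)
        else:  # INSERTION
            if d.column in patch_cols or d.target_resnum in target_patch_resnums:
                insertion_adjacent = True
                hits.append(d)
                continue
            ins_res = structure.find_residue(d.target_resnum)
            if ins_res is None:
                continue
            near = neighbor_residues(structure, [ins_res], adjacency_cutoff, atom_rule="cb")
            near_nums = {k[1] for k in near}
            if near_nums & target_patch_resnums:
                insertion_adjacent = True
                hits.append(d)
    if substituted and insertion_adjacent:
        status = PatchStatus.SUBSTITUTED_AND_INSERTION_ADJACENT
    elif substituted:
        status = PatchStatus.SUBSTITUTED
    elif insertion_adjacent:
        status = PatchStatus.INSERTION_ADJACENT
    else:
        status = PatchStatus.CONSERVED
    return status, hits


def patch_contiguity(
    structure: Structure,
    patch_resnums: list[int],
    cutoff: float = 8.0,
) -> int:
    """Number of spatial connected components of the patch residue graph.

    Residues are nodes; an edge joins two patch residues whose Cβ anchors
    (Cα for Gly) lie within ``cutoff`` Å.
    """
    residues = [structure.find_residue(n) for n in patch_resnums]
    residues = [r for r in residues if r is not None]
    if not residues:
        raise PatchError("no patch residues present in structure")
    from .geometry import representative_atom
    import numpy as np
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    pts = np.array([representative_atom(r).coord for r in residues])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=cutoff)
    n = len(residues)
    if not pairs:
        return n
    rows = [i for i, j in pairs] + [j for i, j in pairs]
    cols = [j for i, j in pairs] + [i for i, j in pairs]
    graph = csr_matrix(([1] * len(rows), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(graph, directed=False)
    return int(n_comp)


def write_patch_reports(reports: list[PatchReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)
        fh.write("\n")
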