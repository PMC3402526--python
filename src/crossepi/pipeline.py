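"""End-to-end analysis: config file in, machine-readable report out.

``run_analysis`` chains the modules in the order the science requires —
conservation classification and exclusive-difference detection on the
alignment; Cα superposition of the two bound structures with worst-fit
segment ranking; solvent accessibility and relative exposure per structure;
patch areas, statuses and contiguity; surface-potential comparison per
patch — and writes a JSON report whose every number comes from a module
call, plus TSV side tables and B-factor-annotated PDBs. The report embeds a
full parameter provenance block and is byte-identical across reruns of the
same config and seed.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import electrostatics as es
from . import msa, patches as patches_mod, sasa as sasa_mod
from .geometry import GeometryError, kabsch_superpose, paired_ca_coords
from .structio import assign_radii, read_pdb, write_pdb

__all__ = ["AnalysisConfig", "ConfigError", "run_analysis", "worst_fit_segments"]


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Validated inputs and parameters of one full analysis run."""

    alignment_path: str
    alignment_format: str
    target_id: str
    structures: dict[str, str]  # member id -> PDB path
    patch_path: str
    reference_id: str | None = None
    output_dir: str = "crossepi_out"
    seed: int = 0
    probe_radius: float = 1.4
    n_points: int = 960
    radii_set_id: str = "chothia"
    exposure_threshold: float = 30.0
    adjacency_cutoff: float = 8.0
    electrostatics_mode: str = "screened-coulomb"  # or "fd-pb"
    epsilon_in: float = 4.0
    epsilon_out: float = 80.0
    ionic_strength_M: float = 0.15
    temperature_K: float = 298.15
    conserve_over_family_only: bool = True
    worst_fit_window: int = 3
    worst_fit_top_k: int = 5
    fd_grid_spacing: float = 1.0
    fd_padding: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        missing = {"alignment_path", "alignment_format", "target_id", "structures",
                   "patch_path"} - set(raw)
        if missing:
            raise ConfigError(f"missing config fields: {sorted(missing)}")
        return cls(**raw)

    def validate(self) -> None:
        errors: list[str] = []
        for label, p in [("alignment_path", self.alignment_path), ("patch_path", self.patch_path)]:
            if not Path(p).exists():
                errors.append(f"{label}: file not found: {p}")
        for member, p in self.structures.items():
            if not Path(p).exists():
                errors.append(f"structures[{member}]: file not found: {p}")
        if self.alignment_format not in ("fasta", "clustal"):
            errors.append(f"alignment_format must be fasta|clustal, got {self.alignment_format!r}")
        if self.electrostatics_mode not in ("screened-coulomb", "fd-pb"):
            errors.append(f"electrostatics_mode must be screened-coulomb|fd-pb")
        if errors:
            raise ConfigError("; ".join(errors))

    def provenance(self) -> dict:
        return {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}


def worst_fit_segments(
    resnums: list[int],
    deviations: np.ndarray,
    window: int = 3,
    top_k: int = 5,
) -> list[dict]:
    """Rank contiguous residue segments by mean superposition deviation.

    ``resnums`` are the (sorted, target-numbering) residue numbers of the
    superposed pairs and ``deviations`` the per-pair distances after
    superposition. Window means are ranked; the ``top_k`` non-overlapping
    best windows are kept (ties resolved toward the N-terminus) and each is
    extended while a flanking residue deviates at least half as much as the
    window mean, so a displaced loop is reported whole.
    """
    dev = np.asarray(deviations, dtype=float)
    if window < 1:
        raise GeometryError("window must be >= 1")
    if len(dev) < window:
        raise GeometryError(f"fewer pairs ({len(dev)}) than window ({window})")
    if len(resnums) != len(dev):
        raise GeometryError("resnums and deviations differ in length")

    means = np.convolve(dev, np.ones(window) / window, mode="valid")
    available = np.ones(len(means), dtype=bool)
    segments = []
    while len(segments) < top_k and available.any():
        cand = np.where(available)[0]
        best = cand[np.lexsort((cand, -means[cand]))][0]
        w_mean = means[best]
        lo, hi = best, best + window
        if w_mean > 0:  # grow over flanks that deviate at least half as much
            while lo > 0 and dev[lo - 1] >= 0.5 * w_mean:
                lo -= 1
            while hi < len(dev) and dev[hi] >= 0.5 * w_mean:
                hi += 1
        # mask every window overlapping the final segment
        w_lo, w_hi = max(0, lo - window + 1), min(len(means), hi)
        available[w_lo:w_hi] = False
        segments.append(
            {
                "start_resnum": int(resnums[lo]),
                "end_resnum": int(resnums[hi - 1]),
                "mean_deviation": float(dev[lo:hi].mean()),
                "window_mean": float(w_mean),
            }
        )
    return segments


def _atomic_write_json(obj: dict, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns the report dict and writes artifacts.

    A failure in the optional FD-PB electrostatics stage is recorded in the
    report and the stage skipped; failures in required stages abort with the
    stage name attached.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": config.provenance(), "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- conservation ---------------------------------------------------
    def _msa_stage():
        aln = msa.read_alignment(
            config.alignment_path, config.alignment_format, reference_id=config.reference_id
        )
        exclude = (config.target_id,) if config.conserve_over_family_only else ()
        profile = msa.classify_columns(aln, exclude_ids=exclude)
        diffs = msa.find_exclusive_differences(aln, config.target_id)
        return aln, profile, diffs

    aln, profile, diffs = stage("msa")(_msa_stage)
    report["stages"]["conservation"] = {
        "n_members": len(aln.records),
        "alignment_length": aln.length,
        "class_counts": profile.class_counts(),
        "conserved_excluding_target": config.conserve_over_family_only,
        "exclusive_differences": [
            {
                "column": d.column,
                "kind": d.kind.value,
                "family_residue": d.family_residue,
                "target_residue": d.target_residue,
                "target_resnum": d.target_resnum,
            }
            for d in diffs
        ],
    }
    msa.write_profile_tsv(profile, aln, out / "conservation.tsv")

    # --- structures -----------------------------------------------------
    def _read_structures():
        structs = {}
        for member, path in config.structures.items():
            aln.get(member)  # member must exist in the alignment
            structs[member] = assign_radii(read_pdb(path), config.radii_set_id)
        return structs

    structs = stage("structures")(_read_structures)

    # --- superposition --------------------------------------------------
    bound = list(config.structures)
    if len(bound) >= 2:
        a_id, b_id = bound[0], bound[1]

        def _superpose():
            pa, pb, table = paired_ca_coords(structs[a_id], structs[b_id], aln, a_id, b_id)
            sup = kabsch_superpose(pa, pb)
            dev = np.linalg.norm(sup.apply(pa) - pb, axis=1)
            segs_a = worst_fit_segments(
                list(table["a_resnum"]), dev, config.worst_fit_window, config.worst_fit_top_k
            )
            segs_b = worst_fit_segments(
                list(table["b_resnum"]), dev, config.worst_fit_window, config.worst_fit_top_k
            )
            return sup, dev, segs_a, segs_b

        sup, dev, segs_a, segs_b = stage("superposition")(_superpose)
        report["stages"]["superposition"] = {
            "a_id": a_id,
            "b_id": b_id,
            "rmsd": sup.rmsd,
            "n_pairs": sup.n_pairs,
            "worst_fit_segments": {a_id: segs_a, b_id: segs_b},
        }
        np.savetxt(out / "superposition_transform.txt", sup.as_matrix_3x4(), fmt="%.6f")

    # --- SASA -----------------------------------------------------------
    def _sasa_stage():
        tables = {}
        for member, st in structs.items():
            table = sasa_mod.shrake_rupley(
                st, probe_radius=config.probe_radius, n_points=config.n_points
            )
            sasa_mod.relative_exposure(table, radii_set_id=config.radii_set_id)
            tables[member] = table
        return tables

    tables = stage("sasa")(_sasa_stage)
    report["stages"]["sasa"] = {}
    for member, table in tables.items():
        exposed = sasa_mod.exposed_set(table, config.exposure_threshold)
        report["stages"]["sasa"][member] = {
            "total_area": table.total_area,
            "n_residues": len(table.residue_areas),
            "n_exposed": len(exposed),
            "exposure_threshold": config.exposure_threshold,
            "params": table.params,
        }
        sasa_mod.write_sasa_tsv(table, out / f"sasa_{member}.tsv")
        channel = {
            (rkey, aname): min(table.relative.get(rkey, 0.0), 999.0)
            for (rkey, aname) in table.atom_areas
        }
        write_pdb(structs[member], out / f"exposure_{member}.pdb", bfactor_channel=channel)

    # --- patches --------------------------------------------------------
    ref_id = aln.reference_id

    def _patch_stage():
        defs = patches_mod.load_patch_definitions(config.patch_path)
        reports = []
        target_struct = structs.get(config.target_id)
        for pd_ in defs:
            member_for_area = ref_id if ref_id in structs else next(iter(structs))
            area, rep = patches_mod.patch_conserved_area(
                structs[member_for_area], tables[member_for_area], pd_, profile,
                reference_id=ref_id, member_id=member_for_area,
            )
            if target_struct is not None:
                status, hits = patches_mod.patch_status(
                    pd_, profile, diffs, target_struct, ref_id, config.target_id,
                    adjacency_cutoff=config.adjacency_cutoff,
                )
                rep.status, rep.disruptions = status, hits
            member_nums = [
                profile.column_to_residue_number(
                    member_for_area, profile.residue_number_to_column(ref_id, rn)
                )
                for rn in pd_.residue_numbers
            ]
            rep.contiguity_components = patches_mod.patch_contiguity(
                structs[member_for_area],
                [n for n in member_nums if n is not None],
                cutoff=config.adjacency_cutoff,
            )
            reports.append(rep)
        return defs, reports

    defs, patch_reports = stage("patches")(_patch_stage)
    report["stages"]["patches"] = [r.to_dict() for r in patch_reports]
    patches_mod.write_patch_reports(patch_reports, out / "patches.json")

    # --- electrostatics -------------------------------------------------
    def _potential(member):
        st, table = structs[member], tables[member]
        charges = es.assign_formal_charges(st)
        pts, tags = es.surface_evaluation_points(st, table, offset=config.probe_radius)
        if config.electrostatics_mode == "fd-pb":
            return es.fd_poisson_boltzmann(
                st, charges, pts, tags,
                grid_spacing=config.fd_grid_spacing, padding=config.fd_padding,
                epsilon_in=config.epsilon_in, epsilon_out=config.epsilon_out,
                ionic_strength_M=config.ionic_strength_M,
                temperature_K=config.temperature_K,
            )
        return es.screened_potential(
            charges, pts, tags,
            epsilon_out=config.epsilon_out, temperature_K=config.temperature_K,
            ionic_strength_M=config.ionic_strength_M,
        )

    report["stages"]["electrostatics"] = {"mode": config.electrostatics_mode, "comparisons": []}
    maps: dict[str, es.PotentialMap] = {}
    try:
        for member in structs:
            maps[member] = _potential(member)
    except Exception as exc:
        if config.electrostatics_mode == "fd-pb":
            # optional mode: record and skip
            report["stages"]["electrostatics"]["skipped"] = str(exc)
            maps = {}
        else:
            raise RuntimeError(f"stage 'electrostatics' failed: {exc}") from exc

    if len(maps) >= 2 and config.target_id in maps:
        other = next(m for m in maps if m != config.target_id)
        prof_pairs = []
        for col in range(aln.length):
            ra = profile.column_to_residue_number(other, col)
            rb = profile.column_to_residue_number(config.target_id, col)
            if ra is not None and rb is not None:
                prof_pairs.append((ra, rb))
        for pd_ in defs:
            patch_nums = set(pd_.residue_numbers) if other == ref_id else {
                profile.column_to_residue_number(
                    other, profile.residue_number_to_column(ref_id, rn)
                )
                for rn in pd_.residue_numbers
            } - {None}
            try:
                comp = es.compare_patch_potentials(
                    maps[other], maps[config.target_id], prof_pairs, patch_nums
                )
            except es.ElectrostaticsError as exc:
                report["stages"]["electrostatics"]["comparisons"].append(
                    {"patch_id": pd_.id, "error": str(exc)}
                )
                continue
            report["stages"]["electrostatics"]["comparisons"].append(
                {
                    "patch_id": pd_.id,
                    "a_id": other,
                    "b_id": config.target_id,
                    "rms_difference": comp.rms_difference,
                    "sign_flips": comp.sign_flips,
                    "largest_difference": comp.largest_difference,
                    "largest_pair": comp.largest_pair,
                }
            )

    _atomic_write_json(report, out / "report.json")
    return report
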