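"""Patch definitions, conserved areas, disruption status, contiguity."""

import numpy as np
import pytest

from crossepi.msa import classify_columns, find_exclusive_differences, read_alignment
from crossepi.patches import (
    PatchDefinition,
    PatchError,
    PatchStatus,
    load_patch_definitions,
    patch_conserved_area,
    patch_contiguity,
    patch_status,
    write_patch_definitions,
)
from crossepi.sasa import shrake_rupley
from crossepi.structio import assign_radii, read_pdb
from crossepi.synthetic import make_ideal_helix


@pytest.fixture(scope="module")
def family_setup(bundle):
    aln = read_alignment(bundle["config_path"].replace("config.yaml", "family.fasta"),
                         reference_id=bundle["reference_id"])
    profile = classify_columns(aln, exclude_ids=(bundle["target_id"],))
    diffs = find_exclusive_differences(aln, bundle["target_id"])
    import yaml

    with open(bundle["config_path"]) as fh:
        cfg = yaml.safe_load(fh)
    structs = {m: assign_radii(read_pdb(p)) for m, p in cfg["structures"].items()}
    tables = {m: shrake_rupley(s) for m, s in structs.items()}
    defs = load_patch_definitions(cfg["patch_path"])
    return aln, profile, diffs, structs, tables, defs


class TestLoadDefinitions:
    def test_single_patch_file(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("patch_id\tlabel\tresidue_number\n1\tcyan\t3\n1\tcyan\t5\n1\tcyan\t9\n")
        defs = load_patch_definitions(p)
        assert len(defs) == 1
        assert defs[0].residue_numbers == (3, 5, 9)

    def test_conflicting_labels_error(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("patch_id\tlabel\tresidue_number\n1\tcyan\t3\n1\tred\t5\n")
        with pytest.raises(PatchError):
            load_patch_definitions(p)

    def test_duplicate_residue_error(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("patch_id\tlabel\tresidue_number\n1\tcyan\t3\n1\tcyan\t3\n")
        with pytest.raises(PatchError):
            load_patch_definitions(p)

    def test_empty_patch_rejected(self):
        with pytest.raises(PatchError):
            PatchDefinition(1, "cyan", ())

    def test_write_read_round_trip(self, tmp_path):
        defs = [PatchDefinition(1, "cyan", (3, 5)), PatchDefinition(2, "red", (9,))]
        p = tmp_path / "out.tsv"
        write_patch_definitions(defs, p, header="synthetic example")
        back = load_patch_definitions(p)
        assert [(d.id, d.label, d.residue_numbers) for d in back] == [
            (1, "cyan", (3, 5)), (2, "red", (9,))
        ]

    def test_five_patch_bundle_file(self, family_setup):
        _, _, _, _, _, defs = family_setup
        assert [d.id for d in defs] == [1, 2, 3, 4, 5]
        assert [d.label for d in defs] == ["cyan", "red", "yellow", "green", "blue"]


class TestConservedArea:
    def test_summation_oracle(self, family_setup):
        aln, profile, _, structs, tables, defs = family_setup
        ref = aln.reference_id
        st, table = structs[ref], tables[ref]
        for d in defs:
            area, rep = patch_conserved_area(st, table, d, profile, ref)
            expected = 0.0
            for rn in d.residue_numbers:
                col = profile.residue_number_to_column(ref, rn)
                if profile.classes[col].value == "fully_conserved":
                    expected += table.residue_areas[("A", rn, "")]
            assert area == pytest.approx(expected, abs=1e-9)

    def test_empty_conserved_subset_zero(self, family_setup):
        aln, profile, _, structs, tables, _ = family_setup
        ref = aln.reference_id
        # columns 46+ are random, never fully conserved; member1 resnums = column
        patch = PatchDefinition(9, "test", (52, 54))
        area, rep = patch_conserved_area(structs[ref], tables[ref], patch, profile, ref)
        assert area == 0.0

    def test_additive_and_monotone(self, family_setup):
        aln, profile, _, structs, tables, _ = family_setup
        ref = aln.reference_id
        a1, _ = patch_conserved_area(structs[ref], tables[ref],
                                     PatchDefinition(11, "x", (21,)), profile, ref)
        a2, _ = patch_conserved_area(structs[ref], tables[ref],
                                     PatchDefinition(12, "x", (23,)), profile, ref)
        both, _ = patch_conserved_area(structs[ref], tables[ref],
                                       PatchDefinition(13, "x", (21, 23)), profile, ref)
        assert both == pytest.approx(a1 + a2, abs=1e-9)
        bigger, _ = patch_conserved_area(structs[ref], tables[ref],
                                         PatchDefinition(14, "x", (21, 23, 24)), profile, ref)
        assert bigger >= both - 1e-9

    def test_patch_sum_below_total_sasa(self, family_setup):
        aln, profile, _, structs, tables, defs = family_setup
        ref = aln.reference_id
        total = tables[ref].total_area
        s = sum(
            patch_conserved_area(structs[ref], tables[ref], d, profile, ref)[0] for d in defs
        )
        assert s <= total

    def test_unmappable_patch_error(self, family_setup):
        aln, profile, _, structs, tables, _ = family_setup
        ref = aln.reference_id
        with pytest.raises(Exception):
            patch_conserved_area(structs[ref], tables[ref],
                                 PatchDefinition(15, "x", (999,)), profile, ref)


class TestPatchStatus:
    def test_no_differences_all_conserved(self, family_setup):
        aln, profile, _, structs, _, defs = family_setup
        target = [m for m in aln.ids if m != aln.reference_id][0]
        for d in defs:
            status, hits = patch_status(d, profile, [], structs[aln.reference_id],
                                        aln.reference_id, target)
            assert status is PatchStatus.CONSERVED and hits == []

    def test_planted_layout_reproduced(self, family_setup, bundle):
        aln, profile, diffs, structs, _, defs = family_setup
        target = bundle["target_id"]
        for d in defs:
            status, _ = patch_status(d, profile, diffs, structs[target],
                                     aln.reference_id, target)
            assert status.value == bundle["expected_patch_status"][d.id]

    def test_removing_disruption_flips_to_conserved(self, family_setup, bundle):
        aln, profile, diffs, structs, _, defs = family_setup
        target = bundle["target_id"]
        patch3 = next(d for d in defs if d.id == 3)
        kept = [d for d in diffs if d.column != 15]  # drop the patch-3 substitution
        status, _ = patch_status(patch3, profile, kept, structs[target],
                                 aln.reference_id, target)
        assert status is PatchStatus.CONSERVED


class TestContiguity:
    def test_single_residue_one_component(self):
        st = assign_radii(make_ideal_helix("ADKLQESN"))
        assert patch_contiguity(st, [3]) == 1

    def test_far_apart_residues_two_components(self):
        st = assign_radii(make_ideal_helix("A" * 30))
        # ~1.5 Å rise: residues 1 and 25 are ≈ 36 Å apart
        assert patch_contiguity(st, [1, 25], cutoff=8.0) == 2

    def test_helix_face_patch_connected(self):
        st = assign_radii(make_ideal_helix("A" * 12))
        assert patch_contiguity(st, [3, 4, 7, 8], cutoff=8.0) == 1

    def test_no_residues_error(self):
        st = assign_radii(make_ideal_helix("ADKL"))
        with pytest.raises(PatchError):
            patch_contiguity(st, [99])
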