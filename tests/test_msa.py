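"""Alignment reading, conservation classes, exclusive differences, identity."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from crossepi.msa import (
    CLUSTAL_STRONG_GROUPS,
    Alignment,
    AlignmentError,
    ConservationClass,
    DifferenceKind,
    SequenceRecord,
    classify_columns,
    find_exclusive_differences,
    pairwise_identity,
    read_alignment,
    write_alignment,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_aln(rows: dict[str, str]) -> Alignment:
    return Alignment([SequenceRecord(k, v) for k, v in rows.items()])


class TestReadAlignment:
    def test_fasta_round_trip_identity(self, tmp_path):
        aln = make_aln({"a": "ACDEFGHK", "b": "ACDEFGHK"})
        path = tmp_path / "x.fasta"
        write_alignment(aln, path)
        back = read_alignment(path)
        assert [r.id for r in back.records] == ["a", "b"]
        assert [r.residues for r in back.records] == ["ACDEFGHK", "ACDEFGHK"]

    def test_clustal_parse_matches_hand_transcription(self, tmp_path):
        text = (
            "CLUSTAL W multiple sequence alignment\n\n"
            "s1   ACD-EFG\n"
            "s2   ACDKEFG\n"
            "s3   ACDREFG\n"
        )
        path = tmp_path / "x.aln"
        path.write_text(text)
        aln = read_alignment(path, "clustal")
        assert [r.residues for r in aln.records] == ["ACD-EFG", "ACDKEFG", "ACDREFG"]

    def test_ragged_rows_name_offender(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACDE\n>bad\nACD\n")
        with pytest.raises(AlignmentError):
            read_alignment(path)

    def test_unknown_symbol_rejected_with_position(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACXE\n>b\nACDE\n")
        with pytest.raises(AlignmentError, match="position 2"):
            read_alignment(path)
        # configurable pass-through
        aln = read_alignment(path, allow_extended=True)
        assert aln.records[0].residues == "ACXE"

    def test_all_gap_column_rejected(self):
        with pytest.raises(AlignmentError, match="all-gaps"):
            make_aln({"a": "A-C", "b": "A-C"})


class TestPairwiseIdentity:
    def test_identical_sequences_100(self):
        pct, _ = pairwise_identity("ACDEFGH", "ACDEFGH")
        assert pct == 100.0

    def test_no_matches_0(self):
        pct, _ = pairwise_identity("AC-G", "WG-A")
        assert pct == 0.0

    def test_prealigned_unequal_lengths_error(self):
        with pytest.raises(AlignmentError):
            pairwise_identity("ACDE", "ACD")

    def test_gap_columns_excluded_from_denominator(self):
        # only the 2 mutually non-gap columns count; both match
        pct, _ = pairwise_identity("ACG-", "AC-G")
        assert pct == 100.0

    def test_align_first_agrees_with_affine_gotoh_oracle(self):
        """Global affine-gap DP (Gotoh) written independently, BLOSUM62 o10/e0.5."""
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        a, b = "ACDEFGHIKLMN", "ACDEFHIKLMN"  # one planted deletion (G)

        def gotoh_score(x, y, open_=10.0, ext=0.5):
            import numpy as np

            n, m = len(x), len(y)
            neg = -1e9
            M = np.full((n + 1, m + 1), neg)
            Ix = np.full((n + 1, m + 1), neg)  # gap in y
            Iy = np.full((n + 1, m + 1), neg)
            M[0, 0] = 0.0
            for i in range(1, n + 1):
                Ix[i, 0] = -open_ - (i - 1) * ext
            for j in range(1, m + 1):
                Iy[0, j] = -open_ - (j - 1) * ext
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = mat[x[i - 1], y[j - 1]]
                    M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
                    Ix[i, j] = max(M[i - 1, j] - open_, Ix[i - 1, j] - ext)
                    Iy[i, j] = max(M[i, j - 1] - open_, Iy[i, j - 1] - ext)
            return max(M[n, m], Ix[n, m], Iy[n, m])

        pct, (row_a, row_b) = pairwise_identity(a, b, align_first=True)
        # unique optimum: everything matches around a single G gap
        assert pct == 100.0
        assert row_b.replace("-", "") == b
        # aligner found the same optimal score as the independent DP
        score = sum(
            mat[x, y] for x, y in zip(row_a, row_b) if x != "-" and y != "-"
        ) - 10.0 - 0.0 * 0.5
        assert abs(score - gotoh_score(a, b)) < 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(3, 12), st.randoms(use_true_random=False))
    def test_identity_symmetric(self, length, rnd):
        a = "".join(rnd.choice(AA) for _ in range(length))
        b = "".join(rnd.choice(AA) for _ in range(length))
        pa, _ = pairwise_identity(a, b)
        pb, _ = pairwise_identity(b, a)
        assert pa == pytest.approx(pb, abs=1e-9)


class TestClassifyColumns:
    def test_single_record_all_fully_conserved(self):
        aln = make_aln({"only": "ACDEFG"})
        prof = classify_columns(aln)
        assert all(c is ConservationClass.FULLY_CONSERVED for c in prof.classes)

    def test_gap_forbids_fully_conserved(self):
        aln = make_aln({"a": "AS", "b": "-S", "c": "AS"})
        prof = classify_columns(aln)
        assert prof.classes[0] is not ConservationClass.FULLY_CONSERVED
        assert prof.classes[1] is ConservationClass.FULLY_CONSERVED

    def test_conservative_group_detected(self):
        aln = make_aln({"a": "SAW", "b": "TAF", "c": "AAY"})  # STA / identical / FYW
        prof = classify_columns(aln)
        assert prof.classes[0] is ConservationClass.CONSERVATIVE
        assert prof.classes[1] is ConservationClass.FULLY_CONSERVED
        assert prof.classes[2] is ConservationClass.CONSERVATIVE

    def test_brute_force_recount_on_random_alignments(self):
        """Classes equal an independent per-column recount, 100 random families."""
        import numpy as np

        rng = np.random.default_rng(42)
        aas = list(AA)
        for _ in range(100):
            n, L = rng.integers(2, 7), rng.integers(1, 21)
            rows = rng.choice(aas + ["-"], size=(n, L), p=[0.045] * 20 + [0.1])
            # repair all-gap columns
            for col in range(L):
                if all(rows[i, col] == "-" for i in range(n)):
                    rows[rng.integers(n), col] = rng.choice(aas)
            aln = make_aln({f"s{i}": "".join(rows[i]) for i in range(n)})
            prof = classify_columns(aln)
            for col in range(L):
                column = [rows[i, col] for i in range(n)]
                residues = {c for c in column if c != "-"}
                if not residues:
                    expected = ConservationClass.NON_CONSERVED
                elif len(residues) == 1 and "-" not in column:
                    expected = ConservationClass.FULLY_CONSERVED
                elif any(residues <= set(g) for g in CLUSTAL_STRONG_GROUPS):
                    expected = ConservationClass.CONSERVATIVE
                else:
                    expected = ConservationClass.NON_CONSERVED
                assert prof.classes[col] is expected

    def test_invariant_to_record_order(self, toy_family):
        aln, _ = toy_family
        prof = classify_columns(aln)
        rev = Alignment(list(reversed(aln.records)), reference_id=aln.reference_id)
        prof_rev = classify_columns(rev)
        assert prof.classes == prof_rev.classes

    def test_column_counts_consistent(self, toy_family):
        """Sum of non-gap positions per column equals members minus gaps."""
        aln, _ = toy_family
        prof = classify_columns(aln)
        for col in range(aln.length):
            column = aln.column(col)
            non_gap = sum(1 for m in aln.ids if prof.col_to_resnum[m][col] is not None)
            assert non_gap == len(aln.records) - Counter(column)["-"]


class TestExclusiveDifferences:
    def test_identical_target_empty(self):
        aln = make_aln({"a": "ACD", "b": "ACD", "t": "ACD"})
        assert find_exclusive_differences(aln, "t") == []

    def test_planted_events_recovered_exactly(self, toy_family):
        aln, truth = toy_family
        diffs = find_exclusive_differences(aln, truth["target_id"])
        subs = [d for d in diffs if d.kind is DifferenceKind.SUBSTITUTION]
        ins = [d for d in diffs if d.kind is DifferenceKind.INSERTION]
        assert [(d.column, d.family_residue, d.target_residue) for d in subs] == [
            (s["column"], s["family_residue"], s["target_residue"])
            for s in truth["substitutions"]
        ]
        assert len(ins) == 1
        assert ins[0].column == truth["insertion"]["column"]
        assert ins[0].target_residue == truth["insertion"]["target_residue"]

    def test_round_trip_reinsertion_is_silent(self, toy_family):
        """Removing a conforming member and re-adding it plants nothing."""
        aln, truth = toy_family
        other = next(i for i in aln.ids if i != truth["target_id"])
        rebuilt = Alignment(list(aln.records), reference_id=aln.reference_id)
        assert find_exclusive_differences(rebuilt, other) == []

    def test_unknown_target_error(self, toy_family):
        aln, _ = toy_family
        with pytest.raises(AlignmentError):
            find_exclusive_differences(aln, "nobody")


class TestNumberingMaps:
    def test_gapless_member_is_column_plus_one(self):
        aln = make_aln({"a": "ACDEF", "b": "AC-EF"})
        prof = classify_columns(aln)
        for col in range(5):
            assert prof.column_to_residue_number("a", col) == col + 1

    def test_leading_gaps_hand_count(self):
        aln = make_aln({"a": "--ACD", "b": "KKACD"})
        prof = classify_columns(aln)
        assert prof.column_to_residue_number("a", 4) == 3  # 2 leading gaps
        assert prof.column_to_residue_number("a", 1) is None

    def test_inverse_round_trips(self, toy_family):
        aln, _ = toy_family
        prof = classify_columns(aln)
        for m in aln.ids:
            for col in range(aln.length):
                rn = prof.column_to_residue_number(m, col)
                if rn is not None:
                    assert prof.residue_number_to_column(m, rn) == col

    def test_out_of_range_errors(self, toy_family):
        aln, _ = toy_family
        prof = classify_columns(aln)
        with pytest.raises(AlignmentError):
            prof.column_to_residue_number(aln.ids[0], aln.length)
        with pytest.raises(AlignmentError):
            prof.residue_number_to_column(aln.ids[0], 10_000)
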