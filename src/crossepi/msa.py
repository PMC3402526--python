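"""Multiple-alignment conservation analysis for homolog families.

The questions this module answers are the ones a cross-reactivity study asks
of an aligned allergen family: which alignment columns are invariant across
the family, which vary only conservatively, where does a single member (the
putative hypoallergen) deviate from an otherwise unanimous family, and how do
alignment columns map onto each member's own residue numbering.

Conventions: alignment columns are 0-based indices; residue numbers are
1-based positions in a member's ungapped sequence. Gaps are ``'-'``.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "CLUSTAL_STRONG_GROUPS",
    "SequenceRecord",
    "Alignment",
    "ConservationClass",
    "ConservationProfile",
    "DifferenceKind",
    "ExclusiveDifference",
    "read_alignment",
    "pairwise_identity",
    "classify_columns",
    "find_exclusive_differences",
    "write_profile_tsv",
]

GAP = "-"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
_EXTENDED = set("BZXJUO")

#: Clustal "strong" conservation groups; a column whose non-gap residues all
#: fall inside one group is conservatively substituted.
CLUSTAL_STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)


class AlignmentError(ValueError):
    """Raised for malformed alignments or invalid sequence content."""


@dataclass(frozen=True)
class SequenceRecord:
    """One (possibly gapped) member sequence of an alignment."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("sequence record id must be nonempty")

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def validate_vocabulary(self, allow_extended: bool = False) -> None:
        allowed = AMINO_ACIDS | {GAP} | (_EXTENDED if allow_extended else set())
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise AlignmentError(
                    f"record {self.id!r}: symbol {ch!r} at position {pos} is outside "
                    "the 20 amino-acid one-letter codes plus '-'"
                )


@dataclass
class Alignment:
    """Ordered equal-length gapped sequences with an optional reference member.

    The reference member (``reference_id``) defines the numbering used when
    patch definitions or reported substitution positions refer to "reference
    numbering"; it defaults to the first record.
    """

    records: list[SequenceRecord]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            bad = [r.id for r in self.records if len(r.residues) != len(self.records[0].residues)]
            raise AlignmentError(f"ragged alignment: records {bad} differ in length")
        if self.length == 0:
            raise AlignmentError("alignment length is zero")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise AlignmentError(f"duplicate record ids: {dup}")
        for col in range(self.length):
            if all(r.residues[col] == GAP for r in self.records):
                raise AlignmentError(f"column {col} is all-gaps")
        if self.reference_id is None:
            self.reference_id = self.records[0].id
        elif self.reference_id not in set(ids):
            raise AlignmentError(f"reference_id {self.reference_id!r} not among records")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, member_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == member_id:
                return r
        raise AlignmentError(f"member {member_id!r} not in alignment")

    def column(self, index: int) -> str:
        if not 0 <= index < self.length:
            raise AlignmentError(f"column {index} out of range [0, {self.length})")
        return "".join(r.residues[index] for r in self.records)

    def without(self, member_id: str) -> "Alignment":
        """Alignment restricted to the other members (all-gap columns kept as-is
        is impossible: removing a member may create all-gap columns, which are
        dropped)."""
        rest = [r for r in self.records if r.id != member_id]
        if not rest:
            raise AlignmentError("cannot drop the only record")
        keep = [c for c in range(self.length) if any(r.residues[c] != GAP for r in rest)]
        new = [
            SequenceRecord(r.id, "".join(r.residues[c] for c in keep), r.description)
            for r in rest
        ]
        ref = self.reference_id if self.reference_id != member_id else None
        return Alignment(new, reference_id=ref)


class ConservationClass(enum.Enum):
    FULLY_CONSERVED = "fully_conserved"
    CONSERVATIVE = "conservative"
    NON_CONSERVED = "non_conserved"


@dataclass
class ConservationProfile:
    """Per-column conservation classes plus column <-> residue-number maps.

    ``col_to_resnum[member][col]`` is the 1-based residue number of ``member``
    at alignment column ``col`` or ``None`` on a gap; ``resnum_to_col`` is the
    inverse on non-gap positions.
    """

    classes: list[ConservationClass]
    consensus: list[str]
    residue_counts: list[Counter]
    member_ids: list[str]
    col_to_resnum: dict[str, list[int | None]]
    excluded_ids: tuple[str, ...] = ()
    _resnum_to_col: dict[str, dict[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._resnum_to_col:
            self._resnum_to_col = {
                m: {n: c for c, n in enumerate(cols) if n is not None}
                for m, cols in self.col_to_resnum.items()
            }

    @property
    def length(self) -> int:
        return len(self.classes)

    def class_counts(self) -> dict[str, int]:
        c = Counter(cl.value for cl in self.classes)
        return {cl.value: c.get(cl.value, 0) for cl in ConservationClass}

    def column_to_residue_number(self, member_id: str, column: int) -> int | None:
        """1-based residue number of ``member_id`` at 0-based ``column``; None on gap."""
        if member_id not in self.col_to_resnum:
            raise AlignmentError(f"member {member_id!r} not in profile")
        cols = self.col_to_resnum[member_id]
        if not 0 <= column < len(cols):
            raise AlignmentError(f"column {column} out of range [0, {len(cols)})")
        return cols[column]

    def residue_number_to_column(self, member_id: str, resnum: int) -> int:
        if member_id not in self._resnum_to_col:
            raise AlignmentError(f"member {member_id!r} not in profile")
        try:
            return self._resnum_to_col[member_id][resnum]
        except KeyError:
            raise AlignmentError(
                f"residue number {resnum} out of range for member {member_id!r}"
            ) from None


class DifferenceKind(enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"


@dataclass(frozen=True)
class ExclusiveDifference:
    """A position where one member deviates from an otherwise unanimous family.

    ``family_residue`` is the residue carried by every non-target member
    (None for an insertion, where the family carries a gap);
    ``target_residue`` is what the deviating member carries;
    ``target_resnum`` is its 1-based position in the target's own sequence.
    """

    column: int
    kind: DifferenceKind
    family_residue: str | None
    target_residue: str
    target_resnum: int


def read_alignment(
    path: str | Path,
    fmt: str = "fasta",
    reference_id: str | None = None,
    allow_extended: bool = False,
) -> Alignment:
    """Read an aligned-FASTA (``fmt='fasta'``) or Clustal (``fmt='clustal'``) file.

    Record order is preserved; gap characters ``.`` and ``~`` are normalized
    to ``-``; residues are uppercased. Symbols outside the 21-letter
    vocabulary raise unless ``allow_extended`` admits B/Z/X-style codes.
    """
    if fmt not in ("fasta", "clustal"):
        raise AlignmentError(f"unsupported alignment format {fmt!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as {fmt}: {exc}") from exc
    records = []
    for rec in msa:
        seq = str(rec.seq).upper().replace(".", GAP).replace("~", GAP)
        sr = SequenceRecord(rec.id, seq, rec.description or "")
        sr.validate_vocabulary(allow_extended=allow_extended)
        records.append(sr)
    return Alignment(records, reference_id=reference_id)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write as aligned FASTA (the round-trip partner of ``read_alignment``)."""
    with open(path, "w") as fh:
        for r in alignment.records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i : i + 60] + "\n")


def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    align_first: bool = False,
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
) -> tuple[float, tuple[str, str]]:
    """Percent identity between two sequences, with the alignment used.

    Identity = identical pairs / columns where both members are non-gap, x100
    (insertion-robust denominator). With ``align_first`` a global alignment
    (BLOSUM62, affine gaps: open ``open_gap``, extend ``extend_gap``) is
    computed; otherwise the inputs must already be aligned and equal length.
    """
    if not seq_a or not seq_b:
        raise AlignmentError("sequences must be nonempty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if align_first:
        aligner = _make_aligner(open_gap, extend_gap)
        best = aligner.align(seq_a.replace(GAP, ""), seq_b.replace(GAP, ""))[0]
        a_row, b_row = str(best[0]), str(best[1])
    else:
        if len(seq_a) != len(seq_b):
            raise AlignmentError(
                f"pre-aligned mode requires equal lengths ({len(seq_a)} vs {len(seq_b)})"
            )
        a_row, b_row = seq_a, seq_b
    both = [(x, y) for x, y in zip(a_row, b_row) if x != GAP and y != GAP]
    if not both:
        raise AlignmentError("no mutually non-gap columns")
    matches = sum(1 for x, y in both if x == y)
    return 100.0 * matches / len(both), (a_row, b_row)


def classify_columns(
    alignment: Alignment,
    conservative_groups: Sequence[Iterable[str]] = CLUSTAL_STRONG_GROUPS,
    exclude_ids: Iterable[str] = (),
) -> ConservationProfile:
    """Classify every column as fully conserved / conservative / non-conserved.

    Conservation is assessed over the records not named in ``exclude_ids``
    (e.g. the family without the hypoallergen candidate, when asking how that
    candidate deviates from otherwise-conserved positions), while the
    column <-> residue-number maps cover all members. A gap anywhere in the
    assessed set forbids FULLY_CONSERVED; a column is CONSERVATIVE when all
    its non-gap residues fall inside a single conservative group and it is
    not fully conserved.
    """
    groups = [frozenset(g) for g in conservative_groups]
    excluded = tuple(exclude_ids)
    for m in excluded:
        alignment.get(m)  # raises on unknown id
    assessed = [r for r in alignment.records if r.id not in excluded]
    if not assessed:
        raise AlignmentError("every member excluded from conservation assessment")

    classes: list[ConservationClass] = []
    consensus: list[str] = []
    counts: list[Counter] = []
    for col in range(alignment.length):
        column = [r.residues[col] for r in assessed]
        non_gap = [c for c in column if c != GAP]
        cnt = Counter(column)
        counts.append(cnt)
        if not non_gap:
            # all assessed members gapped (others carry the column): nothing to conserve
            classes.append(ConservationClass.NON_CONSERVED)
            consensus.append(GAP)
            continue
        res_counter = Counter(non_gap)
        cons = min(sorted(res_counter), key=lambda r: (-res_counter[r], r))
        consensus.append(cons)
        types = set(non_gap)
        if len(types) == 1 and GAP not in column:
            classes.append(ConservationClass.FULLY_CONSERVED)
        elif any(types <= g for g in groups):
            classes.append(ConservationClass.CONSERVATIVE)
        else:
            classes.append(ConservationClass.NON_CONSERVED)

    col_to_resnum: dict[str, list[int | None]] = {}
    for r in alignment.records:
        nums: list[int | None] = []
        n = 0
        for ch in r.residues:
            if ch == GAP:
                nums.append(None)
            else:
                n += 1
                nums.append(n)
        col_to_resnum[r.id] = nums
    return ConservationProfile(
        classes=classes,
        consensus=consensus,
        residue_counts=counts,
        member_ids=[r.id for r in alignment.records],
        col_to_resnum=col_to_resnum,
        excluded_ids=excluded,
    )


def find_exclusive_differences(
    alignment: Alignment,
    target_id: str,
    restrict_to_conserved: bool = True,
) -> list[ExclusiveDifference]:
    """Columns where the family is unanimous and only ``target_id`` deviates.

    A SUBSTITUTION column carries one identical residue in every non-target
    member and a different residue in the target; an INSERTION column carries
    a gap in every non-target member and a residue in the target. With
    ``restrict_to_conserved`` False, substitution columns may additionally
    contain gaps among the non-target members (the unanimity then applies to
    their non-gap residues only).
    """
    target = alignment.get(target_id)
    others = [r for r in alignment.records if r.id != target_id]
    if not others:
        raise AlignmentError("alignment has no non-target members")

    resnum = 0
    out: list[ExclusiveDifference] = []
    for col in range(alignment.length):
        t = target.residues[col]
        if t != GAP:
            resnum += 1
        column = [r.residues[col] for r in others]
        types = set(c for c in column if c != GAP)
        has_gap = GAP in column
        if not types and t != GAP:
            out.append(
                ExclusiveDifference(col, DifferenceKind.INSERTION, None, t, resnum)
            )
        elif len(types) == 1 and t != GAP and t not in types:
            if restrict_to_conserved and has_gap:
                continue
            out.append(
                ExclusiveDifference(
                    col, DifferenceKind.SUBSTITUTION, next(iter(types)), t, resnum
                )
            )
    return out


def write_profile_tsv(
    profile: ConservationProfile, alignment: Alignment, path: str | Path
) -> None:
    """TSV export: column, class, consensus, residues, per-member residue numbers."""
    with open(path, "w") as fh:
        members = profile.member_ids
        fh.write("column\tclass\tconsensus\tresidues\t" + "\t".join(members) + "\n")
        for col in range(profile.length):
            residues = "".join(sorted(profile.residue_counts[col].elements()))
            nums = [
                str(profile.col_to_resnum[m][col])
                if profile.col_to_resnum[m][col] is not None
                else "-"
                for m in members
            ]
            fh.write(
                f"{col}\t{profile.classes[col].value}\t{profile.consensus[col]}\t"
                f"{residues}\t" + "\t".join(nums) + "\n"
            )
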