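"""Alloantigen epitope candidates from donor-recipient HLA mismatches.

The vaccine cell lines carry allogeneic HLA molecules; residues where a
donor allele differs from *both* of the recipient's alleles at the same
locus are potential alloantigen determinants. Peptide windows covering such
mismatches, excluding any window the recipient's own alleles already
contain, are candidate T-cell epitopes.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .models import HLAAllele, ValidationError

CLASS_I_LENGTHS = (8, 9, 10, 11)
CLASS_II_LENGTHS = (15,)


def _make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _aligned_residues(donor_seq: str, other_seq: str, aligner: Align.PairwiseAligner) -> Dict[int, str]:
    """Map 1-based donor positions to the recipient residue aligned to them.

    Donor positions aligned to a gap are absent from the map (gap columns
    are excluded from mismatch calling).
    """
    alignment = aligner.align(donor_seq, other_seq)[0]
    mapping: Dict[int, str] = {}
    for (d_start, d_end), (o_start, o_end) in zip(*alignment.aligned):
        for offset in range(d_end - d_start):
            mapping[d_start + offset + 1] = other_seq[o_start + offset]
    return mapping


def find_mismatches(
    donor: HLAAllele,
    recipient_alleles: Sequence[HLAAllele],
    align: bool = False,
    aligner: Align.PairwiseAligner | None = None,
) -> Set[int]:
    """Donor positions (1-based) differing from *both* recipient alleles.

    All alleles must share the donor's locus. Sequences of unequal length are
    compared positionally only when ``align`` is set, in which case a global
    pairwise alignment maps donor positions onto each recipient allele and
    gap columns are excluded.
    """
    for rec in recipient_alleles:
        if rec.locus != donor.locus:
            raise ValidationError(
                f"recipient allele {rec.name} is not at donor locus {donor.locus}"
            )
    if not recipient_alleles:
        raise ValidationError("at least one recipient allele is required")

    unequal = any(len(r.protein_seq) != len(donor.protein_seq) for r in recipient_alleles)
    if unequal and not align:
        raise ValidationError(
            "allele sequences differ in length; positional comparison requires align=True"
        )

    if unequal or align:
        aligner = aligner or _make_aligner()
        maps = [_aligned_residues(donor.protein_seq, r.protein_seq, aligner) for r in recipient_alleles]
        mismatches = set()
        for pos in range(1, len(donor.protein_seq) + 1):
            residues = [m.get(pos) for m in maps]
            if any(r is None for r in residues):
                continue
            if all(r != donor.protein_seq[pos - 1] for r in residues):
                mismatches.add(pos)
        return mismatches

    mismatches = set()
    for pos in range(1, len(donor.protein_seq) + 1):
        d = donor.protein_seq[pos - 1]
        if all(r.protein_seq[pos - 1] != d for r in recipient_alleles):
            mismatches.add(pos)
    return mismatches


def mismatch_windows(
    donor_seq: str,
    mismatch_positions: Set[int],
    lengths: Sequence[int] = CLASS_I_LENGTHS,
    recipient_seqs: Sequence[str] = (),
) -> List[str]:
    """All donor k-mers overlapping a mismatch, minus recipient self-windows.

    Windows identical to a same-length substring of any recipient sequence
    are removed: a peptide the recipient's own HLA proteins contain cannot be
    an alloantigen. Output preserves N-to-C order, deduplicated.
    """
    n = len(donor_seq)
    for pos in mismatch_positions:
        if not 1 <= pos <= n:
            raise ValidationError(f"mismatch position {pos} outside sequence of length {n}")
    self_windows: Set[str] = set()
    for seq in recipient_seqs:
        for k in set(lengths):
            for i in range(len(seq) - k + 1):
                self_windows.add(seq[i : i + k])
    intervals: Set[Tuple[int, int]] = set()
    for k in sorted(lengths):
        for pos in mismatch_positions:
            lo = max(1, pos - k + 1)
            hi = min(pos, n - k + 1)
            for start in range(lo, hi + 1):
                intervals.add((start, start + k - 1))
    out: List[str] = []
    seen: Set[str] = set()
    for start, end in sorted(intervals, key=lambda iv: (iv[0], iv[1])):
        pep = donor_seq[start - 1 : end]
        if pep in seen or pep in self_windows:
            continue
        seen.add(pep)
        out.append(pep)
    return out


def derive_allo_candidates(
    donor_alleles: Sequence[HLAAllele],
    recipient_alleles: Sequence[HLAAllele],
    lengths_by_class: Dict[str, Sequence[int]] | None = None,
    align: bool = False,
) -> Dict[str, List[str]]:
    """Mismatch-covering candidate peptides per donor allele.

    Recipient alleles are grouped by locus; donor alleles whose locus the
    recipient shares are compared against both recipient alleles of that
    locus. Deduplication runs across all donor alleles; each peptide is
    reported under the first donor allele that produced it.
    """
    lengths_by_class = lengths_by_class or {"I": CLASS_I_LENGTHS, "II": CLASS_II_LENGTHS}
    by_locus: Dict[str, List[HLAAllele]] = {}
    for allele in recipient_alleles:
        by_locus.setdefault(allele.locus, []).append(allele)
    out: Dict[str, List[str]] = {}
    seen: Set[str] = set()
    for donor in donor_alleles:
        recipients = by_locus.get(donor.locus)
        if not recipients:
            continue
        mismatches = find_mismatches(donor, recipients, align=align)
        windows = mismatch_windows(
            donor.protein_seq,
            mismatches,
            lengths=lengths_by_class[donor.hla_class],
            recipient_seqs=[r.protein_seq for r in recipients],
        )
        fresh = [w for w in windows if w not in seen]
        seen.update(fresh)
        out[donor.name] = fresh
    return out
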