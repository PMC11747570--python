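"""Mutant peptide extraction from protein-level variants.

Given a germline protein and a coding variant, emit every 8-11-mer window of
the mutated protein that overlaps an altered residue. Missense windows are
paired with the positionally corresponding wild-type window; indel and
frameshift windows have no positional counterpart. Windows identical to any
same-length substring of the germline protein are never emitted: a peptide
the patient's proteome already contains cannot be a neoantigen.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Set

from Bio.Seq import Seq

from .models import AMINO_ACIDS, PeptidePair, ProteinVariant, ValidationError

DEFAULT_LENGTHS = (8, 9, 10, 11)


def _windows_overlapping(
    mutant_seq: str,
    altered: Sequence[int],
    lengths: Sequence[int],
) -> List[tuple[int, int]]:
    """1-based closed intervals [start, end] of k-mers overlapping ``altered``."""
    n = len(mutant_seq)
    out: Set[tuple[int, int]] = set()
    for k in sorted(lengths):
        for pos in altered:
            lo = max(1, pos - k + 1)
            hi = min(pos, n - k + 1)
            for start in range(lo, hi + 1):
                out.add((start, start + k - 1))
    # N-to-C order, shorter windows first at equal start
    return sorted(out, key=lambda iv: (iv[0], iv[1]))


def _substrings(seq: str, lengths: Sequence[int]) -> Set[str]:
    subs: Set[str] = set()
    for k in set(lengths):
        for i in range(len(seq) - k + 1):
            subs.add(seq[i : i + k])
    return subs


def build_mutant_protein(variant: ProteinVariant, protein_seq: str) -> tuple[str, List[int]]:
    """Apply the variant to the germline protein.

    Returns the mutant protein and the 1-based altered positions in mutant
    coordinates: substituted/inserted residues for missense and in-frame
    changes, the junction residues for pure deletions.
    """
    pos = variant.protein_pos
    ref_aa, alt_aa = variant.ref_aa, variant.alt_aa
    if pos > len(protein_seq):
        raise ValidationError(
            f"protein position {pos} beyond sequence of length {len(protein_seq)}"
        )
    if ref_aa and protein_seq[pos - 1 : pos - 1 + len(ref_aa)] != ref_aa:
        raise ValidationError(
            f"reference residues {ref_aa!r} do not match protein at position {pos}"
        )
    mutant = protein_seq[: pos - 1] + alt_aa + protein_seq[pos - 1 + len(ref_aa) :]
    if alt_aa:
        altered = list(range(pos, pos + len(alt_aa)))
    else:
        # pure deletion: the junction residues flanking the deleted stretch
        altered = [p for p in (pos - 1, pos) if 1 <= p <= len(mutant)]
    return mutant, altered


def translate_frameshift(coding_seq: str) -> str:
    """Translate a mutant coding sequence to the first stop codon."""
    return str(Seq(coding_seq).translate(to_stop=True))


def extract_mutant_peptides(
    variant: ProteinVariant,
    protein_seq: str,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    frameshift_tail: Optional[str] = None,
    frameshift_coding_seq: Optional[str] = None,
) -> List[PeptidePair]:
    """Emit every mutant k-mer overlapping an altered residue.

    For frameshifts the novel C-terminal sequence must be supplied, either as
    translated residues (``frameshift_tail``) or as the mutant coding
    sequence from the variant position onward (``frameshift_coding_seq``).
    Windows containing ambiguous residues (X) are dropped with a warning, as
    downstream predictors cannot score them. Duplicate mutant sequences from
    one variant keep the first occurrence in N-to-C order.
    """
    protein_seq = protein_seq.upper()
    if variant.consequence_kind == "frameshift":
        if frameshift_tail is None and frameshift_coding_seq is not None:
            frameshift_tail = translate_frameshift(frameshift_coding_seq)
        if frameshift_tail is None:
            raise ValidationError(
                "frameshift extraction needs the mutant tail or coding sequence"
            )
        if variant.protein_pos > len(protein_seq):
            raise ValidationError(
                f"protein position {variant.protein_pos} beyond sequence "
                f"of length {len(protein_seq)}"
            )
        mutant = protein_seq[: variant.protein_pos - 1] + frameshift_tail.upper()
        altered = list(range(variant.protein_pos, len(mutant) + 1))
        if not altered:
            return []
        paired = False
    else:
        mutant, altered = build_mutant_protein(variant, protein_seq)
        paired = variant.consequence_kind == "missense"

    self_peptides = _substrings(protein_seq, lengths)
    pairs: List[PeptidePair] = []
    seen: Set[str] = set()
    for start, end in _windows_overlapping(mutant, altered, lengths):
        pep = mutant[start - 1 : end]
        if "X" in pep:
            warnings.warn(
                f"window {pep} at {start} contains ambiguous residues; dropped"
            )
            continue
        if set(pep) - AMINO_ACIDS:
            continue
        if pep in seen:
            continue
        if pep in self_peptides:
            # identical to a germline substring: not a mutant peptide
            continue
        seen.add(pep)
        if paired:
            wt = protein_seq[start - 1 : end]
            mut_pos = frozenset(
                i + 1 for i, (a, b) in enumerate(zip(pep, wt)) if a != b
            )
        else:
            wt = None
            mut_pos = frozenset(
                p - start + 1 for p in altered if start <= p <= end
            )
        if not mut_pos:
            continue
        pairs.append(
            PeptidePair(
                mutant=pep,
                wildtype=wt,
                genomic_key=variant.genomic_key,
                transcript=variant.transcript,
                mut_positions=mut_pos,
            )
        )
    return pairs


def trim_to_nonanchor(icore: str) -> str:
    """Strip HLA anchor residues: keep the 4th through penultimate residues.

    Anchor positions contact the HLA groove, so T-cell receptors mostly read
    the central residues; this trims the interaction core accordingly.
    """
    if len(icore) < 5:
        raise ValidationError(f"icore {icore!r} too short to trim (need >= 5 residues)")
    return icore[3:-1]
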