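"""Peptide feature battery for immunogenicity analysis.

Formula-level features are computed here: the differential agretopicity
index (DAI), the patient harmonic-mean best rank (PHBR), HLA promiscuity
counts, expression-derived features, a substitution-matrix string-kernel
self-similarity, and physicochemical properties. Features that require an
externally trained model reach the feature table only as pass-through
columns from a prediction file.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .models import AMINO_ACIDS, PredictionRecord, ValidationError

STRONG_BINDER_RANK = 0.5
WEAK_BINDER_RANK = 2.0


def dai(mut_rank: float, wt_rank: float) -> float:
    """Differential agretopicity index: mutant rank over wild-type rank.

    Values below 1 mean the mutation improved predicted presentation.
    """
    if mut_rank <= 0 or wt_rank <= 0:
        raise ValidationError(f"ranks must be positive, got ({mut_rank}, {wt_rank})")
    return mut_rank / wt_rank


def phbr(best_rank_per_slot: Sequence[float]) -> float:
    """Patient harmonic-mean best rank over the six class I allele slots.

    Homozygous loci contribute their allele twice, so the harmonic mean is
    always over exactly six slots. The harmonic mean is dominated by the
    best-presenting allele, matching how presentation on any single allele
    suffices for recognition.
    """
    if len(best_rank_per_slot) != 6:
        raise ValidationError(
            f"PHBR needs exactly 6 allele slots, got {len(best_rank_per_slot)}"
        )
    if any(r <= 0 for r in best_rank_per_slot):
        raise ValidationError("PHBR ranks must be positive")
    return len(best_rank_per_slot) / sum(1.0 / r for r in best_rank_per_slot)


def promiscuity(records: Sequence[PredictionRecord]) -> Tuple[int, int]:
    """Number of alleles bound strongly (< 0.5) and weakly ([0.5, 2))."""
    n_strong = sum(1 for r in records if r.rank_el < STRONG_BINDER_RANK)
    n_weak = sum(
        1 for r in records if STRONG_BINDER_RANK <= r.rank_el < WEAK_BINDER_RANK
    )
    return n_strong, n_weak


def expression_features(
    tpm: float,
    rna_vaf: Optional[float] = None,
    melanocyte_tpm: Optional[float] = None,
    pseudocount: float = 0.01,
) -> Dict[str, float]:
    """Mutant-transcript expression and tumor/melanocyte fold change.

    ``mut_expression`` is TPM x RNA VAF — expression attributable to the
    mutated transcript copy. ``log2_fc_melanocyte`` compares vaccine (tumor)
    expression to healthy melanocytes with a pseudocount guarding zeros.
    """
    if tpm < 0:
        raise ValidationError(f"TPM must be >= 0, got {tpm}")
    out: Dict[str, float] = {}
    if rna_vaf is not None:
        out["mut_expression"] = tpm * rna_vaf
    if melanocyte_tpm is not None:
        if melanocyte_tpm < 0:
            raise ValidationError(f"melanocyte TPM must be >= 0, got {melanocyte_tpm}")
        out["log2_fc_melanocyte"] = math.log2(
            (tpm + pseudocount) / (melanocyte_tpm + pseudocount)
        )
    return out


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_KERNEL_RESIDUES = sorted(AMINO_ACIDS)
_KERNEL_INDEX = {aa: i for i, aa in enumerate(_KERNEL_RESIDUES)}


def _shifted_matrix() -> np.ndarray:
    m = np.zeros((20, 20))
    for i, a in enumerate(_KERNEL_RESIDUES):
        for j, b in enumerate(_KERNEL_RESIDUES):
            m[i, j] = _BLOSUM62[a][b]
    return m - m.min()  # shift so every entry is non-negative


_SHIFTED_BLOSUM = _shifted_matrix()


def _kernel_raw(a: str, b: str, k_max: int, matrix: np.ndarray) -> float:
    ia = np.array([_KERNEL_INDEX[x] for x in a])
    ib = np.array([_KERNEL_INDEX[x] for x in b])
    pair = matrix[np.ix_(ia, ib)]  # per-position substitution weights
    total = 0.0
    for k in range(1, k_max + 1):
        if k > len(a) or k > len(b):
            break
        # product of weights along each diagonal window pair of length k
        for i in range(len(a) - k + 1):
            for j in range(len(b) - k + 1):
                prod = 1.0
                for offset in range(k):
                    prod *= pair[i + offset, j + offset]
                total += prod
    return total


def kernel_similarity(
    pep_a: str, pep_b: str, k_max: int = 3, matrix: np.ndarray | None = None
) -> float:
    """Normalized alignment-free string-kernel similarity in [0, 1].

    The kernel sums substitution-matrix-weighted products over all k-mer
    pairs for k = 1..k_max (default matrix: BLOSUM62 shifted non-negative);
    the similarity is K(a,b) / sqrt(K(a,a) K(b,b)), so identical peptides
    score 1.
    """
    for pep in (pep_a, pep_b):
        if not pep:
            raise ValidationError("kernel similarity requires non-empty peptides")
        invalid = set(pep) - AMINO_ACIDS
        if invalid:
            raise ValidationError(f"invalid residues {sorted(invalid)} in {pep!r}")
    matrix = _SHIFTED_BLOSUM if matrix is None else matrix
    kab = _kernel_raw(pep_a, pep_b, k_max, matrix)
    kaa = _kernel_raw(pep_a, pep_a, k_max, matrix)
    kbb = _kernel_raw(pep_b, pep_b, k_max, matrix)
    return kab / math.sqrt(kaa * kbb)


def _isoelectric_point(peptide: str, tol: float = 1e-4) -> float:
    """pI by bisection of the Henderson-Hasselbalch net charge over pH 0-14.

    Uses the standard per-residue pKa table; the full pH range matters for
    short very acidic or very basic peptides whose pI falls outside the
    usual protein range.
    """
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    charge = IsoelectricPoint(peptide).charge_at_pH
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def physchem(peptide: str) -> Dict[str, float]:
    """GRAVY, average molecular weight, aromaticity, and isoelectric point."""
    invalid = set(peptide) - AMINO_ACIDS
    if invalid:
        raise ValidationError(f"invalid residues {sorted(invalid)} in {peptide!r}")
    analysis = ProteinAnalysis(peptide)
    return {
        "gravy": analysis.gravy(),
        "molecular_weight": analysis.molecular_weight(),
        "aromaticity": analysis.aromaticity(),
        "isoelectric_point": _isoelectric_point(peptide),
    }


def build_feature_vector(
    mutant: str,
    wildtype: Optional[str],
    mut_rank_el: float,
    wt_rank_el: Optional[float],
    rank_stab: Optional[float],
    class_i_ranks: Sequence[float],
    records_per_allele: Sequence[PredictionRecord],
    tpm: float,
    rna_vaf: Optional[float] = None,
    melanocyte_tpm: Optional[float] = None,
    icore: Optional[str] = None,
    passthrough: Optional[Dict[str, float]] = None,
) -> Dict[str, float]:
    """Assemble the named feature map for one tested peptide."""
    from .peptides import trim_to_nonanchor

    features: Dict[str, float] = {
        "mut_rank_el": mut_rank_el,
        "length": float(len(mutant)),
        "combined_tpm": tpm,
    }
    if rank_stab is not None:
        features["rank_stab"] = rank_stab
    if wildtype is not None and wt_rank_el is not None:
        features["wt_rank_el"] = wt_rank_el
        features["dai"] = dai(mut_rank_el, wt_rank_el)
        features["kernel_self_similarity"] = kernel_similarity(mutant, wildtype)
    if len(class_i_ranks) == 6:
        features["phbr"] = phbr(class_i_ranks)
    n_strong, n_weak = promiscuity(records_per_allele)
    features["n_strong_alleles"] = float(n_strong)
    features["n_weak_alleles"] = float(n_weak)
    features.update(
        expression_features(tpm, rna_vaf=rna_vaf, melanocyte_tpm=melanocyte_tpm)
    )
    if icore is not None and wildtype is not None and len(icore) >= 5:
        trimmed_mut = trim_to_nonanchor(icore)
        # the wild-type counterpart of the icore window within the peptide
        start = mutant.find(icore)
        if start >= 0 and len(wildtype) == len(mutant):
            wt_icore = wildtype[start : start + len(icore)]
            trimmed_wt = trim_to_nonanchor(wt_icore)
            if trimmed_mut and trimmed_wt:
                features["kernel_self_similarity_nonanchor"] = kernel_similarity(
                    trimmed_mut, trimmed_wt
                )
    features.update(physchem(mutant))
    if passthrough:
        features.update(passthrough)
    return features
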