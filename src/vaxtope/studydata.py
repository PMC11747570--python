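"""Published summary tables from the VACCIMEL melanoma vaccine study.

These constants are the study's printed per-patient results — variant
category counts, ELISpot positivity tallies, the dual-patient epitope panel,
and time-course response magnitudes. They serve as inputs for re-deriving the
study's summary statistics; the underlying sequencing data are not public.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: Variant counts per patient by antigen category (V / TV / T).
VARIANT_COUNTS: Dict[str, Dict[str, int]] = {
    "#005": {"V": 9540, "TV": 5, "T": 219},
    "#006": {"V": 9074, "TV": 9, "T": 153},
    "#032": {"V": 7770, "TV": 1882, "T": 1591},
    "#045": {"V": 9623, "TV": 21, "T": 644},
}

#: Candidate epitope counts per patient by category.
CANDIDATE_EPITOPE_COUNTS: Dict[str, Dict[str, int]] = {
    "#005": {"V": 210, "TV": 1, "T": 20},
    "#006": {"V": 173, "TV": 5, "T": 35},
    "#032": {"V": 156, "TV": 766, "T": 130},
    "#045": {"V": 129, "TV": 4, "T": 37},
}

#: ELISpot positives/tested per patient and category; None = not assessed.
POSITIVITY_COUNTS: Dict[str, Dict[str, Tuple[int, int] | None]] = {
    "#005": {"V": None, "TV": None, "T": (7, 21)},
    "#006": {"V": (2, 46), "TV": None, "T": (10, 47)},
    "#032": {"V": (16, 43), "TV": (15, 46), "T": (5, 12)},
    "#045": {"V": (26, 47), "TV": None, "T": None},
}

#: Epitopes tested in both patients #006 and #032 (shared HLA-B alleles):
#: (antigen gene, epitope, restricting HLA, response in #006, response in
#: #032, category). Responses are True (+) / False (-).
DUAL_PATIENT_PANEL: List[Tuple[str, str, str, bool, bool, str]] = [
    ("PLA2G4B", "LPSKDLVI", "HLA-B5101", False, False, "V"),
    ("NPHP4", "KAVSATEPVTF", "HLA-B5701", False, False, "V"),
    ("TBC1D1", "LIKEDAVHW", "HLA-B5701", False, False, "TV"),
    ("HRCT1", "RAQPWPFRW", "HLA-B5701", False, False, "V"),
    ("INSR", "RSYALVSLF", "HLA-B5701", False, False, "V"),
    ("ZDHHC12", "NPFDRGLTRI", "HLA-B5101", True, True, "TV"),
    ("KCTD17", "KTKLLQARGTW", "HLA-B5701", True, True, "V"),
    ("MAGEC1", "FPSSTSSI", "HLA-B5101", False, True, "V"),
    ("MARCH7", "RPKENSMSI", "HLA-B5101", False, True, "V"),
    ("MRPL38", "IGLPPPKVSW", "HLA-B5701", False, True, "V"),
    ("TTC37", "KSIDLYLAL", "HLA-B5701", False, True, "V"),
    ("NUB1", "KTNGGRCRIW", "HLA-B5701", False, True, "V"),
    ("KLHL30", "RSLLALSSPYF", "HLA-B5701", False, True, "V"),
    ("DNMT3B", "TSWPSPPSSY", "HLA-B5701", False, True, "V"),
    ("L3MBTL2", "FPSYNSSV", "HLA-B5101", True, False, "V"),
    ("CREBBP", "LPAQPQPSPV", "HLA-B5101", True, False, "V"),
    ("HSPG2", "VPLSPATNMSV", "HLA-B5101", True, False, "V"),
]

#: Neoantigens tested at multiple time points: (patient, category, antigen,
#: epitope, {timepoint: magnitude in spots per 100,000 effector cells}).
TIME_COURSE: List[Tuple[str, str, str, str, Dict[str, float]]] = [
    ("#006", "T", "ZNF416", "KSKLVRHQRI", {"PRE": 72, "Post1": 52, "Post2": 105, "Post3": 45}),
    ("#006", "T", "B4GALNT3", "PVKNLPQV", {"PRE": 0, "Post1": 0, "Post2": 0, "Post3": 192}),
    ("#006", "T", "IPO8", "NISEDVIFF", {"PRE": 0, "Post1": 0, "Post2": 220, "Post3": 212}),
    ("#006", "T", "PTPRU", "DHYAYSYYL", {"PRE": 0, "Post1": 0, "Post2": 268, "Post3": 220}),
    ("#006", "T", "PRICKLE3", "KRIPLPPHLC", {"PRE": 0, "Post1": 0, "Post2": 325, "Post3": 225}),
    ("#006", "T", "TRIOBP", "RTSSTQQDNPK", {"PRE": 285, "Post1": 285, "Post2": 315, "Post3": 232}),
    ("#006", "T", "IFT80", "DDIYPIDFY", {"PRE": 0, "Post1": 0, "Post2": 0, "Post3": 245}),
    ("#006", "T", "PRICKLE3", "SSEDDGFFLGK", {"PRE": 0, "Post1": 0, "Post2": 0, "Post3": 262}),
    ("#006", "T", "ZNF878", "ALSYLVSFQR", {"PRE": 238, "Post1": 330, "Post2": 300, "Post3": 265}),
    ("#006", "T", "IQCF2", "LVRRTLLHV", {"PRE": 0, "Post1": 238, "Post2": 362, "Post3": 295}),
    ("#032", "TV", "ITGAL", "STALRLTAF", {"PRE": 89, "Post1": 372, "Post2": 0, "Post3": 0}),
    ("#032", "TV", "PCNT", "TSLPQTQGL", {"PRE": 2, "Post1": 81, "Post2": 68, "Post3": 0}),
    ("#032", "TV", "ALDH3B2", "VTLGHGLPELY", {"PRE": 0, "Post1": 0, "Post2": 226, "Post3": 0}),
    ("#032", "TV", "CD177", "ALAPALWWR", {"PRE": 65, "Post1": 190, "Post2": 280, "Post3": 0}),
    ("#032", "T", "LHB", "AWASREPLRPR", {"PRE": 24, "Post1": 0, "Post2": 178, "Post3": 93}),
    ("#032", "T", "PPP1R15A", "QSAHFRGW", {"PRE": 229, "Post1": 0, "Post2": 0, "Post3": 304}),
    ("#032", "TV", "CRYBB3", "SPDHKLHLF", {"PRE": 19, "Post1": 48, "Post2": 0, "Post3": 324}),
    ("#032", "T", "ADM2", "AALGCISLLW", {"PRE": 16, "Post1": 25, "Post2": 0, "Post3": 348}),
    ("#032", "T", "KRT40", "SSQLAQIQR", {"PRE": 21, "Post1": 207, "Post2": 0, "Post3": 377}),
]


def positivity_percentages() -> Dict[str, Dict[str, float]]:
    """Percent positive per (patient, category) recomputed from the tallies."""
    out: Dict[str, Dict[str, float]] = {}
    for patient, by_cat in POSITIVITY_COUNTS.items():
        out[patient] = {}
        for category, tally in by_cat.items():
            if tally is None:
                continue
            positives, tested = tally
            out[patient][category] = 100.0 * positives / tested
    return out
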