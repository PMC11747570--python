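from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from vaxtope.models import ExpressionProfile, PeptidePair, ProteinVariant
from vaxtope.prioritize import PeptideCandidate


def make_variant(**overrides) -> ProteinVariant:
    defaults = dict(
        sample_id="vaccine",
        chrom="chr1",
        pos=100,
        ref="A",
        alt="T",
        gene="GENE1",
        transcript="TX1",
        consequence_kind="missense",
        protein_pos=10,
        ref_aa="L",
        alt_aa="W",
        filter_pass_count=2,
        vaf_by_line={"line1": 0.4, "line2": 0.1},
        rna_coverage=25,
        rna_vaf=0.5,
    )
    defaults.update(overrides)
    return ProteinVariant(**defaults)


def make_candidate(**overrides) -> PeptideCandidate:
    pair = overrides.pop(
        "pair",
        PeptidePair(
            mutant="KTKLLQARG",
            wildtype="KTKLLQARA",
            genomic_key=("chr1", 100, "A", "T"),
            transcript="TX1",
            mut_positions=frozenset({9}),
        ),
    )
    defaults = dict(
        pair=pair,
        allele="HLA-B*57:01",
        locus="B",
        category="V",
        mut_rank_el=0.3,
        wt_rank_el=3.0,
        rank_stab=1.5,
        classII_min_rank=4.0,
        tpm=5.0,
        rna_coverage=12,
        max_vaf=0.15,
    )
    defaults.update(overrides)
    return PeptideCandidate(**defaults)


@pytest.fixture
def expression_two_genes() -> ExpressionProfile:
    return ExpressionProfile.from_per_line(
        {
            ("line1", "GENE1"): 30.0,
            ("line2", "GENE1"): 10.0,
            ("line1", "GENE2"): 60.0,
            ("line2", "GENE2"): 0.0,
        }
    )
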