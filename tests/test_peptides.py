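"""Mutant peptide extraction against sliding-window enumeration."""

from __future__ import annotations

import numpy as np
import pytest

from vaxtope.models import ValidationError
from vaxtope.peptides import extract_mutant_peptides, trim_to_nonanchor

from conftest import make_variant

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def oracle_missense_windows(protein, pos, alt_aa, lengths):
    """Independent enumeration: every substring of the mutated protein that
    covers the substituted residue and differs from all germline substrings."""
    mutant = protein[: pos - 1] + alt_aa + protein[pos:]
    germ_subs = {
        mutant_len: {
            protein[i : i + mutant_len] for i in range(len(protein) - mutant_len + 1)
        }
        for mutant_len in set(lengths)
    }
    out = []
    for k in sorted(lengths):
        for start in range(len(mutant) - k + 1):
            if start + 1 <= pos <= start + k:
                pep = mutant[start : start + k]
                if pep not in germ_subs[k] and pep not in out:
                    out.append(pep)
    return out


class TestMissense:
    def test_interior_missense_yields_38_windows(self):
        protein = "".join(RESIDUES[i % 20] for i in range(40))
        pos = 20
        alt = "W" if protein[pos - 1] != "W" else "Y"
        v = make_variant(protein_pos=pos, ref_aa=protein[pos - 1], alt_aa=alt)
        pairs = extract_mutant_peptides(v, protein)
        assert len(pairs) == 8 + 9 + 10 + 11

    def test_nine_mers_around_an_l_to_w_change(self):
        protein = "MACDEFGHIKLMNPQRSTVW"
        v = make_variant(protein_pos=11, ref_aa="L", alt_aa="W")
        pairs = extract_mutant_peptides(v, protein, lengths=[9])
        assert len(pairs) == 9
        for pair in pairs:
            assert "W" in pair.mutant
            (mp,) = pair.mut_positions
            assert pair.mutant[mp - 1] == "W"
            assert pair.wildtype[mp - 1] == "L"

    def test_near_n_terminus_truncates_windows(self):
        protein = "ML" + "A" * 40
        v = make_variant(protein_pos=2, ref_aa="L", alt_aa="W")
        pairs = extract_mutant_peptides(v, protein, lengths=[8])
        assert len(pairs) == 2

    def test_random_instances_match_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(12, 60))
            protein = "".join(rng.choice(list(RESIDUES), size=n))
            pos = int(rng.integers(1, n + 1))
            alt = str(rng.choice([r for r in RESIDUES if r != protein[pos - 1]]))
            v = make_variant(protein_pos=pos, ref_aa=protein[pos - 1], alt_aa=alt)
            got = [p.mutant for p in extract_mutant_peptides(v, protein)]
            expected = oracle_missense_windows(protein, pos, alt, (8, 9, 10, 11))
            assert sorted(got) == sorted(expected)

    def test_mut_positions_mark_exactly_the_differing_residues(self):
        protein = "MACDEFGHIKLMNPQRSTVW"
        v = make_variant(protein_pos=11, ref_aa="L", alt_aa="W")
        for pair in extract_mutant_peptides(v, protein):
            diff = {
                i + 1
                for i, (a, b) in enumerate(zip(pair.mutant, pair.wildtype))
                if a != b
            }
            assert diff == set(pair.mut_positions)

    def test_no_emitted_peptide_is_a_germline_substring(self):
        # mutating A->C inside a poly-A stretch: most windows still equal
        # germline poly-A-containing substrings and must be suppressed
        protein = "MC" + "A" * 20 + "CM"
        v = make_variant(protein_pos=10, ref_aa="A", alt_aa="C")
        germ_subs = {
            protein[i : i + k]
            for k in (8, 9, 10, 11)
            for i in range(len(protein) - k + 1)
        }
        pairs = extract_mutant_peptides(v, protein)
        assert pairs and all(p.mutant not in germ_subs for p in pairs)


class TestOtherConsequences:
    def test_inframe_deletion_has_no_wildtype_counterpart(self):
        protein = "MACDEFGHIKLMNPQRSTVWACDEFGHIK"
        v = make_variant(
            consequence_kind="inframe_deletion", protein_pos=12, ref_aa="MNP", alt_aa=""
        )
        pairs = extract_mutant_peptides(v, protein, lengths=[9])
        assert pairs
        assert all(p.wildtype is None for p in pairs)

    def test_frameshift_requires_tail_and_covers_novel_residues(self):
        protein = "MACDEFGHIKLMNPQRSTVW"
        v = make_variant(consequence_kind="frameshift", protein_pos=15, ref_aa="", alt_aa="")
        with pytest.raises(ValidationError):
            extract_mutant_peptides(v, protein)
        pairs = extract_mutant_peptides(v, protein, frameshift_tail="WYWYWYWY")
        assert pairs and all(p.wildtype is None for p in pairs)

    def test_frameshift_coding_sequence_is_translated(self):
        protein = "MACDEFGHIKLMNPQRSTVW"
        v = make_variant(consequence_kind="frameshift", protein_pos=15, ref_aa="", alt_aa="")
        # TGG TAC TGG TAC TGG TAC TGG TAC TAA -> WYWYWYWY then stop
        coding = "TGGTACTGGTACTGGTACTGGTACTAA"
        with_tail = extract_mutant_peptides(v, protein, frameshift_tail="WYWYWYWY")
        with_cds = extract_mutant_peptides(v, protein, frameshift_coding_seq=coding)
        assert [p.mutant for p in with_cds] == [p.mutant for p in with_tail]

    def test_position_beyond_protein_errors(self):
        v = make_variant(protein_pos=99)
        with pytest.raises(ValidationError):
            extract_mutant_peptides(v, "MACDEFGHIK")

    def test_ambiguous_residue_windows_dropped(self):
        protein = "MAXDEFGHIKLMNPQRSTVW"
        v = make_variant(protein_pos=11, ref_aa="L", alt_aa="W")
        with pytest.warns(UserWarning, match="ambiguous"):
            pairs = extract_mutant_peptides(v, protein, lengths=[11])
        assert all("X" not in p.mutant for p in pairs)


class TestNonAnchorTrim:
    @pytest.mark.parametrize(
        "icore,expected",
        [("KTKLLQARGTW", "LLQARGT"), ("ABCDE", "D"), ("LPSKDLVI", "KDLV")],
    )
    def test_keeps_fourth_to_penultimate(self, icore, expected):
        assert trim_to_nonanchor(icore) == expected

    def test_short_input_errors(self):
        with pytest.raises(ValidationError):
            trim_to_nonanchor("ABCD")
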