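"""Selection cascade fidelity and the deterministic curation surrogate."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from vaxtope.models import PeptidePair, ValidationError
from vaxtope.prioritize import (
    CascadeThresholds,
    apply_cascade,
    candidates_from_frame,
    candidates_to_frame,
    curate_selection,
)

from conftest import make_candidate


class TestCascade:
    def test_candidate_meeting_all_thresholds_survives(self):
        survivors, trace = apply_cascade([make_candidate()])
        assert len(survivors) == 1
        assert trace[0]["survivor"] and trace[0]["first_fail"] is None
        assert [name for name, _ in survivors[0].filter_trace] == [
            "vaf",
            "expression",
            "rna_coverage",
            "mut_binding",
            "wt_nonbinding",
            "stability",
            "hla_c_exclusion",
            "classII_exclusion",
        ]

    @pytest.mark.parametrize(
        "overrides,failing",
        [
            ({"max_vaf": 0.10}, "vaf"),
            ({"tpm": 0.0}, "expression"),
            ({"rna_coverage": 9}, "rna_coverage"),
            ({"mut_rank_el": 0.5}, "mut_binding"),
            ({"wt_rank_el": 1.999}, "wt_nonbinding"),
            ({"rank_stab": 2.0}, "stability"),
            ({"allele": "HLA-C*07:01", "locus": "C"}, "hla_c_exclusion"),
            ({"classII_min_rank": 0.99}, "classII_exclusion"),
        ],
    )
    def test_each_filter_rejects_at_its_quoted_boundary(self, overrides, failing):
        survivors, trace = apply_cascade([make_candidate(**overrides)])
        assert survivors == []
        assert trace[0]["first_fail"] == failing

    def test_boundary_values_on_the_passing_side(self):
        ok = make_candidate(
            max_vaf=0.101, wt_rank_el=2.0, rank_stab=1.999, classII_min_rank=1.0
        )
        survivors, _ = apply_cascade([ok])
        assert len(survivors) == 1

    def test_wildtype_free_peptides_skip_the_wt_filter(self):
        pair = PeptidePair(
            mutant="KTKLLQARG",
            wildtype=None,
            genomic_key=("chr1", 5, "A", "T"),
            transcript="TX1",
            mut_positions=frozenset({1}),
        )
        survivors, _ = apply_cascade([make_candidate(pair=pair, wt_rank_el=None)])
        assert len(survivors) == 1

    def test_missing_score_raises_naming_the_candidate(self):
        with pytest.raises(ValidationError, match="KTKLLQARG.*Rank_EL"):
            apply_cascade([make_candidate(mut_rank_el=None)])

    def test_tightening_thresholds_never_grows_the_survivor_set(self):
        rng = np.random.default_rng(8)
        candidates = [
            make_candidate(
                mut_rank_el=float(rng.uniform(0, 1)),
                wt_rank_el=float(rng.uniform(0, 5)),
                rank_stab=float(rng.uniform(0, 4)),
                classII_min_rank=float(rng.uniform(0, 3)),
                tpm=float(rng.uniform(0, 10)),
                max_vaf=float(rng.uniform(0, 0.5)),
                rna_coverage=int(rng.integers(0, 30)),
            )
            for _ in range(120)
        ]
        previous = None
        for scale in (2.0, 1.0, 0.5, 0.25):
            thresholds = CascadeThresholds(
                max_mut_rank_el=0.5 * scale,
                max_rank_stab=2.0 * scale,
            )
            survivors, _ = apply_cascade(candidates, thresholds)
            ids = {id(c.pair) for c in survivors}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_survivor_set_is_input_order_invariant(self):
        rng = np.random.default_rng(9)
        candidates = [
            make_candidate(
                mut_rank_el=float(rng.uniform(0, 1)),
                rank_stab=float(rng.uniform(0, 4)),
            )
            for _ in range(50)
        ]
        forward, _ = apply_cascade(candidates)
        backward, _ = apply_cascade(list(reversed(candidates)))
        assert {c.mut_rank_el for c in forward} == {c.mut_rank_el for c in backward}

    def test_candidate_frame_round_trip(self):
        candidates = [make_candidate(), make_candidate(mut_rank_el=0.1, tpm=9.0)]
        frame = candidates_to_frame(candidates)
        rebuilt = candidates_from_frame(frame)
        assert [c.peptide for c in rebuilt] == [c.peptide for c in candidates]
        assert [c.mut_rank_el for c in rebuilt] == [c.mut_rank_el for c in candidates]


def pair_for(peptide, pos):
    return PeptidePair(
        mutant=peptide,
        wildtype=None,
        genomic_key=("chr1", pos, "A", "T"),
        transcript="TX1",
        mut_positions=frozenset({1}),
    )


class TestCuration:
    def test_per_variant_dedup_keeps_best_rank(self):
        a = make_candidate(pair=pair_for("AAAAAAAA", 1), mut_rank_el=0.3)
        b = make_candidate(pair=pair_for("CCCCCCCC", 1), mut_rank_el=0.1)
        selected = curate_selection([a, b], k=1)
        assert [c.peptide for c in selected] == ["CCCCCCCC"]

    def test_k_equal_to_available_returns_everything(self):
        candidates = [
            make_candidate(pair=pair_for("AAAAAAAA", 1), tpm=1.0),
            make_candidate(pair=pair_for("CCCCCCCC", 2), tpm=5.0),
            make_candidate(pair=pair_for("DDDDDDDD", 3), tpm=9.0),
        ]
        assert len(curate_selection(candidates, k=3)) == 3

    def test_k_beyond_available_errors(self):
        with pytest.raises(ValidationError):
            curate_selection([make_candidate()], k=2)

    def test_collinear_points_match_exhaustive_max_min_dispersion(self):
        """Five collinear candidates with known gaps: greedy farthest-point
        selection of 3 recovers the exhaustive max-min-distance subset
        (both endpoints plus the best interior point)."""
        peptides = ["AAAAAAAA", "CCCCCCCC", "DDDDDDDD", "EEEEEEEE", "FFFFFFFF"]
        stabs = [0.1, 0.5, 0.9, 1.3, 1.7]
        tpms = [1.0, 2.0, 3.0, 4.0, 5.0]
        candidates = [
            make_candidate(pair=pair_for(p, i + 1), rank_stab=s, tpm=t)
            for i, (p, s, t) in enumerate(zip(peptides, stabs, tpms))
        ]
        selected = {c.peptide for c in curate_selection(candidates, k=3)}

        # oracle: rank-transform both axes as the selector does, then try
        # every 3-subset
        from scipy.stats import rankdata

        x = (rankdata(stabs) - 1) / 4
        y = (rankdata([np.log1p(t) for t in tpms]) - 1) / 4
        points = np.column_stack([x, y])

        def min_pairwise(subset):
            return min(
                np.linalg.norm(points[i] - points[j])
                for i, j in combinations(subset, 2)
            )

        best = max(combinations(range(5), 3), key=min_pairwise)
        assert selected == {peptides[i] for i in best}
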