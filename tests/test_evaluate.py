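"""AUC/pAUC, rank tests, concordance, and cohort overlap."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from vaxtope import studydata
from vaxtope.evaluate import (
    auc_and_pauc,
    cohort_overlap,
    compare_categories,
    concordance,
    feature_screen,
    mann_whitney,
    pearson_with_df,
    significance_stars,
)
from vaxtope.models import ValidationError


def auc_oracle(labels, scores):
    """Pairwise counting: P(score_pos > score_neg) with ties at half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        auc, pauc = auc_and_pauc([1, 0], [0.9, 0.1])
        assert auc == 1.0 and pauc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        auc, _ = auc_and_pauc([1, 0, 1, 0], [3.0, 3.0, 3.0, 3.0])
        assert auc == pytest.approx(0.5)

    def test_worked_example(self):
        auc, _ = auc_and_pauc([1, 1, 0, 0], [4, 2, 3, 1])
        assert auc == pytest.approx(3 / 4)

    def test_matches_pairwise_oracle_on_small_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = rng.integers(0, 5, size=n).astype(float)  # ties likely
            auc, _ = auc_and_pauc(labels, scores)
            assert auc == pytest.approx(auc_oracle(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)
        a1, p1 = auc_and_pauc(labels, scores)
        a2, p2 = auc_and_pauc(labels, np.exp(3 * scores))
        assert a1 == pytest.approx(a2) and p1 == pytest.approx(p2)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            auc_and_pauc([1, 1], [0.1, 0.2])


class TestMannWhitney:
    def test_separated_triplets_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        _, p = mann_whitney([5.0, 6.0, 7.0], [5.5, 6.5, 6.0])
        assert p > 0.05

    def test_exact_p_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            values = rng.permutation(np.arange(na + nb, dtype=float) * 1.37)
            a, b = values[:na], values[na:]
            _, p = mann_whitney(a, b)
            # oracle: enumerate every assignment of the pooled values
            pooled = np.concatenate([a, b])
            u_obs = sum(1 for x in a for y in b if x > y)
            n_extreme = 0
            n_total = 0
            for idx in combinations(range(na + nb), na):
                grp = pooled[list(idx)]
                rest = np.delete(pooled, list(idx))
                u = sum(1 for x in grp for y in rest if x > y)
                n_total += 1
                if min(u, na * nb - u) <= min(u_obs, na * nb - u_obs):
                    n_extreme += 1
            assert p == pytest.approx(n_extreme / n_total)

    @pytest.mark.parametrize(
        "p,stars",
        [(0.03, "*"), (0.005, "**"), (0.0005, "***"), (0.00005, "****"), (0.2, "ns")],
    )
    def test_star_annotation(self, p, stars):
        assert significance_stars(p) == stars


class TestCompareCategories:
    def test_pairwise_table_with_stars(self):
        table = compare_categories({"V": [1, 2, 3], "T": [10, 11, 12]})
        row = table.iloc[0]
        assert row["p"] == pytest.approx(0.1)
        assert row["stars"] == "ns"

    def test_empty_category_skipped_with_note(self):
        table = compare_categories({"V": [1, 2], "T": [3, 4], "TVG": []})
        notes = table[table["stars"].str.contains("skipped")]
        assert list(notes["category_a"]) == ["TVG"]

    def test_fewer_than_two_nonempty_errors(self):
        with pytest.raises(ValidationError):
            compare_categories({"V": [1.0], "T": []})


class TestConcordance:
    def test_study_panel_has_ten_discordant_calls(self):
        calls = [(a, b) for _, _, _, a, b, _ in studydata.DUAL_PATIENT_PANEL]
        result = concordance(calls)
        assert result.n_discordant == 10
        assert result.n_concordant == 7
        assert result.n_both_positive == 2

    def test_all_equal_calls(self):
        result = concordance([(True, True), (False, False)])
        assert result.n_discordant == 0 and result.fraction_concordant == 1.0

    def test_single_discordant_pair(self):
        result = concordance([(True, False)])
        assert (result.n_concordant, result.n_discordant) == (0, 1)
        assert result.fraction_concordant == 0.0


class TestCohortOverlap:
    def test_hand_computed_toy_cohort(self):
        vaccine = {f"PEP{i}" for i in range(10)}
        cohort = [
            ("a", 1.0, set()),
            ("b", 2.0, {"PEP1"}),
            ("c", 3.0, {"PEP1", "PEP2", "XXX"}),
            ("d", 10.0, {"PEP1", "PEP2", "PEP3", "PEP4", "PEP5"}),
        ]
        result = cohort_overlap(cohort, vaccine)
        assert [result.n_shared_by_patient[p] for p in "abcd"] == [0, 1, 2, 5]
        assert result.n_patients_with_any == 3
        assert result.n_patients_with_multiple == 2
        r_expected, _, _ = pearson_with_df([1.0, 2.0, 3.0, 10.0], [0, 1, 2, 5])
        assert result.pearson_r == pytest.approx(r_expected)
        assert result.df == 2

    def test_empty_vaccine_set_gives_absent_correlation(self):
        cohort = [("a", 1.0, {"PEP1"}), ("b", 2.0, {"PEP2"}), ("c", 3.0, {"PEP3"})]
        result = cohort_overlap(cohort, set())
        assert result.pearson_r is None
        assert all(v == 0 for v in result.n_shared_by_patient.values())

    def test_planted_linear_relation_recovered(self):
        rng = np.random.default_rng(11)
        vaccine = {f"V{i:03d}" for i in range(500)}
        cohort = []
        tmbs = rng.uniform(1, 40, size=26)
        for i, tmb in enumerate(tmbs):
            n_shared = max(0, int(round(0.5 * tmb + rng.normal(0, 2))))
            shared = {f"V{j:03d}" for j in range(n_shared)}
            private = {f"P{i}_{j}" for j in range(5)}
            cohort.append((f"pt{i}", float(tmb), shared | private))
        result = cohort_overlap(cohort, vaccine)
        assert result.pearson_r > 0.6

    def test_null_feature_screen_centres_on_half(self):
        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(20):
            frame = pd.DataFrame(
                {
                    "positive": rng.integers(0, 2, size=100),
                    "magnitude": rng.normal(size=100),
                    **{f"f{i}": rng.normal(size=100) for i in range(5)},
                }
            )
            screen = feature_screen(frame, [f"f{i}" for i in range(5)])
            aucs.extend(screen["auc"])
        assert 0.45 < np.mean(aucs) < 0.55

    def test_feature_correlated_with_its_own_magnitude_scores_unity(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=60)
        frame = pd.DataFrame(
            {
                "positive": rng.integers(0, 2, size=60),
                "magnitude": values,
                "self": values,
            }
        )
        frame.loc[:1, "positive"] = [0, 1]
        screen = feature_screen(frame, ["self"])
        assert screen.iloc[0]["pearson_r"] == pytest.approx(1.0)

    def test_constant_feature_reports_absent_correlation(self):
        rng = np.random.default_rng(14)
        frame = pd.DataFrame(
            {
                "positive": [0, 0, 1, 1] * 5,
                "magnitude": rng.normal(size=20),
                "const": np.ones(20),
            }
        )
        screen = feature_screen(frame, ["const"])
        assert screen.iloc[0]["pearson_r"] is None or np.isnan(
            screen.iloc[0]["pearson_r"]
        )
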