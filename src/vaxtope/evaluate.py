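"""Feature-immunogenicity evaluation, category comparisons, and overlaps.

Classification performance of a feature is summarized by the ROC AUC (the
Mann-Whitney probability, ties counted half) and a partial AUC over the
low-false-positive-rate region [0, 0.1], normalized by the cap so a perfect
classifier scores 1. Response-intensity associations use Pearson
correlation with t-based two-sided p-values at n - 2 degrees of freedom,
and category contrasts use the Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .models import ValidationError


def auc_and_pauc(
    labels: Sequence[int], scores: Sequence[float], fpr_cap: float = 0.1
) -> Tuple[float, float]:
    """ROC AUC and the normalized partial AUC over FPR in [0, fpr_cap].

    The partial area is integrated by the trapezoidal rule with linear
    interpolation of the ROC curve at the cap, then divided by the cap so
    the statistic lives on [0, 1].
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("AUC requires both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    if fpr_cap <= 0 or fpr_cap > 1:
        raise ValidationError(f"fpr_cap must be in (0, 1], got {fpr_cap}")
    tpr_at_cap = float(np.interp(fpr_cap, fpr, tpr))
    mask = fpr <= fpr_cap
    xs = np.append(fpr[mask], fpr_cap)
    ys = np.append(tpr[mask], tpr_at_cap)
    pauc = float(np.trapezoid(ys, xs)) / fpr_cap
    return auc, pauc


def pearson_with_df(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[Optional[float], Optional[float], int]:
    """Pearson r, two-sided t-based p, and degrees of freedom n - 2.

    Returns (None, None, df) when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    df = len(x) - 2
    if np.std(x) == 0 or np.std(y) == 0 or len(x) < 3:
        return None, None, df
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), df


def feature_screen(
    table: pd.DataFrame,
    feature_columns: Sequence[str],
    label_column: str = "positive",
    magnitude_column: str = "magnitude",
    strong_binder_column: Optional[str] = None,
    strong_binder_rank: float = 0.5,
    fpr_cap: float = 0.1,
) -> pd.DataFrame:
    """Rank features by their immunogenicity classification performance.

    When ``strong_binder_column`` is given, the analysis is restricted to
    predicted strong binders (rank strictly below ``strong_binder_rank``),
    since HLA binding is a prerequisite for recognition and would otherwise
    confound the comparison. Output has one row per feature with AUC,
    partial AUC, and Pearson r against the response magnitude, sorted by
    partial AUC (descending).
    """
    if strong_binder_column is not None:
        table = table[table[strong_binder_column] < strong_binder_rank]
    labels = table[label_column].astype(int).to_numpy()
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValidationError("feature screen needs >= 2 observations per class")
    rows = []
    for feature in feature_columns:
        values = table[feature].to_numpy(dtype=float)
        if np.std(values) == 0:
            auc, pauc = 0.5, fpr_cap / 2  # diagonal ROC, normalized by the cap
            r, p, df = None, None, len(values) - 2
        else:
            auc, pauc = auc_and_pauc(labels, values, fpr_cap=fpr_cap)
            r, p, df = pearson_with_df(values, table[magnitude_column].to_numpy(dtype=float))
        rows.append(
            {
                "feature": feature,
                "auc": auc,
                "pauc": pauc,
                "pearson_r": r,
                "pearson_p": p,
                "df": df,
                "n": len(values),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("pauc", ascending=False, kind="mergesort").reset_index(drop=True)


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 8
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free groups.

    Exact enumeration applies when both groups have at most ``exact_max_n``
    observations and no ties are present; otherwise the normal approximation
    with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = len(a) <= exact_max_n and len(b) <= exact_max_n
    method = "exact" if small and not has_ties else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def compare_categories(
    magnitudes_by_category: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise Mann-Whitney contrasts of response magnitude across categories."""
    names = [c for c, values in magnitudes_by_category.items() if len(values) > 0]
    skipped = [c for c, values in magnitudes_by_category.items() if len(values) == 0]
    if len(names) < 2:
        raise ValidationError("need >= 2 non-empty categories to compare")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = mann_whitney(magnitudes_by_category[a], magnitudes_by_category[b])
            rows.append(
                {
                    "category_a": a,
                    "category_b": b,
                    "n_a": len(magnitudes_by_category[a]),
                    "n_b": len(magnitudes_by_category[b]),
                    "U": u,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    for c in skipped:
        rows.append(
            {
                "category_a": c,
                "category_b": None,
                "n_a": 0,
                "n_b": 0,
                "U": np.nan,
                "p": np.nan,
                "stars": "skipped (empty category)",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConcordanceResult:
    n_concordant: int
    n_discordant: int
    fraction_concordant: float
    n_both_positive: int
    n_both_negative: int


def concordance(calls: Sequence[Tuple[bool, bool]]) -> ConcordanceResult:
    """Agreement of per-peptide positivity calls between two patients."""
    if not calls:
        raise ValidationError("concordance requires at least one peptide")
    both_pos = sum(1 for a, b in calls if a and b)
    both_neg = sum(1 for a, b in calls if not a and not b)
    n_conc = both_pos + both_neg
    n_disc = len(calls) - n_conc
    return ConcordanceResult(
        n_concordant=n_conc,
        n_discordant=n_disc,
        fraction_concordant=n_conc / len(calls),
        n_both_positive=both_pos,
        n_both_negative=both_neg,
    )


@dataclass
class CohortOverlapResult:
    n_shared_by_patient: Dict[str, int]
    n_patients_with_any: int
    n_patients_with_multiple: int
    pearson_r: Optional[float]
    pearson_p: Optional[float]
    df: int


def cohort_overlap(
    cohort: Sequence[Tuple[str, float, Set[str]]],
    vaccine_peptides: Set[str],
) -> CohortOverlapResult:
    """Overlap between each cohort patient's neoepitopes and vaccine peptides.

    ``cohort`` holds (patient, TMB, neoepitope set) triples, with the
    neoepitope sets already restricted to presented candidates upstream.
    Sharing is exact string identity. The summary correlates TMB with the
    per-patient shared count (absent when either series is constant).
    """
    shared = {patient: len(peptides & vaccine_peptides) for patient, _, peptides in cohort}
    tmbs = [tmb for _, tmb, _ in cohort]
    counts = [shared[patient] for patient, _, _ in cohort]
    r, p, df = pearson_with_df(tmbs, counts)
    return CohortOverlapResult(
        n_shared_by_patient=shared,
        n_patients_with_any=sum(1 for c in counts if c >= 1),
        n_patients_with_multiple=sum(1 for c in counts if c > 1),
        pearson_r=r,
        pearson_p=p,
        df=df,
    )
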