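"""ELISpot response magnitude and positivity calling.

Magnitude is the background-subtracted mean spot count scaled to 100,000
effector cells. Positivity uses a distribution-free resampling (DFR) test
when at least triplicate wells exist in both arms: the statistic
``mean(stim) - multiplier * mean(ctrl)`` is compared against its resampling
distribution over all reassignments of the pooled wells into the two arms.
With fewer replicates an empirical rule applies instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import ELISpotAssay, ImmunogenicityRecord, ValidationError

SCALE_CELLS = 100_000
#: Exact enumeration is used up to this many wells per arm.
EXACT_LIMIT = 5
MC_RESAMPLES = 10_000


def magnitude(assay: ELISpotAssay) -> float:
    """Signed spots per 100,000 effector cells (not floored)."""
    stim = float(np.mean(assay.stim_counts))
    ctrl = float(np.mean(assay.ctrl_counts))
    return (stim - ctrl) * SCALE_CELLS / assay.cells_per_well


def dfr_test(
    assay: ELISpotAssay,
    multiplier: float = 2.0,
    seed: int = 0,
) -> float:
    """Distribution-free resampling p-value for H0: mean(stim) <= m * mean(ctrl).

    The null distribution re-assigns the pooled wells into arms of the
    observed sizes: exhaustively for up to 5 wells per arm (20 splits for
    3+3), by seeded Monte-Carlo with 10,000 resamples beyond that. The
    p-value is the proportion of resampled statistics at least as large as
    the observed one; the observed split is one of the resamples, so p is
    never zero.
    """
    if multiplier not in (1.0, 2.0, 1, 2):
        raise ValidationError(f"multiplier must be 1 or 2, got {multiplier}")
    n_stim, n_ctrl = len(assay.stim_counts), len(assay.ctrl_counts)
    if n_stim < 3 or n_ctrl < 3:
        raise ValidationError(
            "DFR requires >= 3 replicates per arm; use the empirical rule instead"
        )
    pooled = np.array(assay.stim_counts + assay.ctrl_counts, dtype=float)
    total = n_stim + n_ctrl

    def statistic(stim_idx: np.ndarray) -> float:
        mask = np.zeros(total, dtype=bool)
        mask[stim_idx] = True
        return float(pooled[mask].mean() - multiplier * pooled[~mask].mean())

    observed = statistic(np.arange(n_stim))
    if max(n_stim, n_ctrl) <= EXACT_LIMIT:
        stats = [
            statistic(np.array(idx)) for idx in combinations(range(total), n_stim)
        ]
        n_total = comb(total, n_stim)
    else:
        rng = np.random.default_rng(seed)
        stats = [observed]  # observed split included
        for _ in range(MC_RESAMPLES - 1):
            idx = rng.choice(total, size=n_stim, replace=False)
            stats.append(statistic(idx))
        n_total = MC_RESAMPLES
    hits = sum(1 for s in stats if s >= observed - 1e-12)
    return hits / n_total


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p_values[idx])
        running = max(running, value)
        adjusted[idx] = running
    return adjusted


@dataclass
class PositivityConfig:
    alpha: float = 0.05
    adjust: str = "holm"            # "holm" or "none", within (patient, timepoint)
    multiplier: float = 2.0
    empirical_min_magnitude: float = 20.0   # spots per 100,000 cells
    empirical_stim_ratio: float = 2.0       # mean(stim) >= ratio * mean(ctrl)
    seed: int = 0


def call_positivity(
    assays: Sequence[ELISpotAssay],
    config: PositivityConfig | None = None,
    categories: Optional[Dict[Tuple[str, str], str]] = None,
) -> List[ImmunogenicityRecord]:
    """Call each assay positive or negative.

    DFR applies wherever both arms have at least triplicates, with the
    multiple-testing adjustment applied within each (patient, timepoint)
    batch; otherwise the empirical rule requires both a minimum magnitude
    and a stimulated mean at least twice the control mean. ``categories``
    optionally maps (patient, peptide) to an antigen category.
    """
    config = config or PositivityConfig()
    if config.adjust not in ("holm", "none"):
        raise ValidationError(f"unknown adjustment {config.adjust!r}")
    records: List[ImmunogenicityRecord] = []
    dfr_indices: Dict[Tuple[str, str], List[int]] = {}
    for assay in assays:
        raw = magnitude(assay)
        floored = max(0.0, raw)
        category = categories.get((assay.patient, assay.peptide)) if categories else None
        if len(assay.stim_counts) >= 3 and len(assay.ctrl_counts) >= 3:
            p = dfr_test(assay, multiplier=config.multiplier, seed=config.seed)
            record = ImmunogenicityRecord(
                patient=assay.patient,
                timepoint=assay.timepoint,
                peptide=assay.peptide,
                category=category,
                magnitude=floored,
                raw_magnitude=raw,
                p_value=p,
                positive=False,  # set after batch adjustment
                method="DFR",
            )
            dfr_indices.setdefault((assay.patient, assay.timepoint), []).append(
                len(records)
            )
        else:
            stim = float(np.mean(assay.stim_counts))
            ctrl = float(np.mean(assay.ctrl_counts))
            positive = (
                floored >= config.empirical_min_magnitude
                and stim >= config.empirical_stim_ratio * ctrl
            )
            record = ImmunogenicityRecord(
                patient=assay.patient,
                timepoint=assay.timepoint,
                peptide=assay.peptide,
                category=category,
                magnitude=floored,
                raw_magnitude=raw,
                p_value=None,
                positive=positive,
                method="empirical",
            )
        records.append(record)

    for batch in dfr_indices.values():
        raw_ps = [records[i].p_value for i in batch]
        adjusted = holm_adjust(raw_ps) if config.adjust == "holm" else list(raw_ps)
        for i, p_adj in zip(batch, adjusted):
            records[i].positive = p_adj <= config.alpha
    return records
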