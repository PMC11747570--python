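"""Peptide-HLA scoring interface with a deterministic mock predictor.

The pipeline never embeds the external presentation/stability predictors; it
scores every peptide through this interface. Two concrete backends exist:

* :class:`MockPredictor` — a seeded pseudo-energy model producing percentile
  ranks with the same conventions as the real tools (0-100 scale, lower =
  stronger), so the whole pipeline is exercisable offline;
* :class:`TablePredictor` — a lookup over a precomputed prediction table,
  the adapter for scores produced by any external tool.
"""

from __future__ import annotations

import zlib
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .models import AMINO_ACIDS, PredictionRecord, ValidationError

_RESIDUES = sorted(AMINO_ACIDS)
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(_RESIDUES)}
_MAX_LEN = 15
_CORE_LEN = 9


class MissingScoreError(KeyError):
    """A requested (peptide, allele) pair has no score available."""


class PredictorInterface(ABC):
    """Deterministic peptide-HLA scorer: identical inputs, identical records."""

    @abstractmethod
    def score(self, peptide: str, allele: str) -> PredictionRecord:
        ...

    def score_batch(
        self, pairs: Iterable[Tuple[str, str]]
    ) -> List[PredictionRecord]:
        return [self.score(peptide, allele) for peptide, allele in pairs]


class MockPredictor(PredictorInterface):
    """Seeded position-weight pseudo-energy model with percentile ranks.

    Each allele gets an independent position x residue weight table derived
    from (seed, allele name). A peptide's pseudo-energy is the minimum over
    its 9-mer windows of the summed per-position weights; the reported
    %Rank_EL is the percentile of that energy within a seeded reference
    distribution of random 9-mers for the allele, so ranks are uniform on
    (0, 100] over random peptides. Stability ranks use an independent weight
    table. The icore is the minimal-energy 9-mer window (the whole peptide
    when shorter than 9).
    """

    def __init__(self, seed: int = 0, reference_size: int = 100_000) -> None:
        self.seed = int(seed)
        self.reference_size = int(reference_size)
        self._tables: Dict[Tuple[str, str], np.ndarray] = {}
        self._references: Dict[Tuple[str, str], np.ndarray] = {}

    def _rng_for(self, allele: str, kind: str) -> np.random.Generator:
        key = zlib.crc32(f"{kind}:{allele}".encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    def _weights(self, allele: str, kind: str) -> np.ndarray:
        cache_key = (allele, kind)
        if cache_key not in self._tables:
            rng = self._rng_for(allele, kind)
            self._tables[cache_key] = rng.normal(size=(_CORE_LEN, len(_RESIDUES)))
        return self._tables[cache_key]

    def _reference(self, allele: str, kind: str) -> np.ndarray:
        cache_key = (allele, kind)
        if cache_key not in self._references:
            weights = self._weights(allele, kind)
            rng = self._rng_for(allele, f"ref:{kind}")
            idx = rng.integers(0, len(_RESIDUES), size=(self.reference_size, _CORE_LEN))
            energies = weights[np.arange(_CORE_LEN), idx].sum(axis=1)
            self._references[cache_key] = np.sort(energies)
        return self._references[cache_key]

    def _energy(self, peptide: str, allele: str, kind: str) -> Tuple[float, str]:
        weights = self._weights(allele, kind)
        idx = np.array([_RESIDUE_INDEX[aa] for aa in peptide])
        if len(peptide) < _CORE_LEN:
            # short peptide: average per-position weight over the positions used
            energy = float(weights[np.arange(len(peptide)), idx].sum())
            energy *= _CORE_LEN / len(peptide)
            return energy, peptide
        best_energy, best_core = np.inf, peptide[:_CORE_LEN]
        for start in range(len(peptide) - _CORE_LEN + 1):
            window = idx[start : start + _CORE_LEN]
            energy = float(weights[np.arange(_CORE_LEN), window].sum())
            if energy < best_energy:
                best_energy, best_core = energy, peptide[start : start + _CORE_LEN]
        return best_energy, best_core

    def _rank(self, energy: float, allele: str, kind: str) -> float:
        reference = self._reference(allele, kind)
        below = int(np.searchsorted(reference, energy, side="left"))
        return 100.0 * (below + 1) / (len(reference) + 1)

    def score(self, peptide: str, allele: str) -> PredictionRecord:
        if not 8 <= len(peptide) <= _MAX_LEN:
            raise ValidationError(f"peptide length out of range 8-{_MAX_LEN}: {peptide!r}")
        invalid = set(peptide) - AMINO_ACIDS
        if invalid:
            raise ValidationError(f"invalid residues {sorted(invalid)} in {peptide!r}")
        el_energy, icore = self._energy(peptide, allele, "el")
        stab_energy, _ = self._energy(peptide, allele, "stab")
        return PredictionRecord(
            peptide=peptide,
            allele=allele,
            rank_el=self._rank(el_energy, allele, "el"),
            rank_stab=self._rank(stab_energy, allele, "stab"),
            icore=icore,
        )


class TablePredictor(PredictorInterface):
    """Lookup-backed predictor over precomputed (peptide, allele) records.

    A missing pair raises :class:`MissingScoreError`; scores are never
    defaulted. Conflicting duplicate rows are rejected at load time.
    """

    def __init__(self, records: Iterable[PredictionRecord]) -> None:
        self._records: Dict[Tuple[str, str], PredictionRecord] = {}
        for rec in records:
            key = (rec.peptide, rec.allele)
            existing = self._records.get(key)
            if existing is not None and existing != rec:
                raise ValidationError(
                    f"conflicting duplicate prediction rows for {key}"
                )
            self._records[key] = rec

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TablePredictor":
        from .io_formats import read_prediction_tsv

        return cls(read_prediction_tsv(path))

    def score(self, peptide: str, allele: str) -> PredictionRecord:
        try:
            return self._records[(peptide, allele)]
        except KeyError:
            raise MissingScoreError(
                f"no prediction for peptide {peptide!r} on allele {allele!r}"
            ) from None


def read_prediction_table(path: str | Path) -> TablePredictor:
    """Load an externally produced prediction TSV as a predictor."""
    return TablePredictor.from_tsv(path)


def best_rank_per_slot(
    predictor: PredictorInterface, peptide: str, class_i_slots: Sequence[str]
) -> List[float]:
    """%Rank_EL for a peptide on each of the six class I allele slots.

    Homozygous loci repeat their allele, contributing two identical slots.
    """
    return [predictor.score(peptide, allele).rank_el for allele in class_i_slots]
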