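"""Amino-acid composition enrichment of a protein set against a background.

Used to characterize co-regulated protein sets — in the motivating study,
storage proteins upregulated by metal treatments, whose glutamine-, proline-
and cysteine-rich composition suggests chelation and radical-scavenging
roles. Enrichment follows the "X% higher" convention:

    enrichment_pct = 100 * (observed_frequency / background_frequency - 1)

Residues are pooled over all sequences by default; X and other ambiguous
symbols are excluded from both numerator and denominator. The shipped
background is an approximate average amino-acid composition of plant
proteins (normalized dicot proteome frequencies); pass your own table to
override it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = ["AMINO_ACIDS", "PLANT_AVERAGE_AA_FREQUENCIES", "CompositionReport", "aa_enrichment"]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_raw_plant_freq = {
    "A": 0.063, "R": 0.053, "N": 0.044, "D": 0.054, "C": 0.018,
    "Q": 0.035, "E": 0.067, "G": 0.064, "H": 0.023, "I": 0.053,
    "L": 0.095, "K": 0.064, "M": 0.024, "F": 0.043, "P": 0.047,
    "S": 0.091, "T": 0.051, "W": 0.0125, "Y": 0.029, "V": 0.069,
}
_total = sum(_raw_plant_freq.values())
#: Average amino-acid composition of plant proteins (shipped default
#: background, normalized to sum to 1).
PLANT_AVERAGE_AA_FREQUENCIES: dict[str, float] = {
    aa: v / _total for aa, v in _raw_plant_freq.items()
}


@dataclass
class CompositionReport:
    """Per-amino-acid observed/background frequencies and percent enrichment.

    ``frame`` is indexed by one-letter residue with columns observed,
    background, enrichment_pct; ``total_residues`` counts the residues that
    entered the observed frequencies.
    """

    frame: pd.DataFrame
    total_residues: int

    def enrichment(self, aa: str) -> float:
        return float(self.frame.at[aa, "enrichment_pct"])


def aa_enrichment(sequences: Iterable[str],
                  background: Mapping[str, float] | None = None,
                  per_protein: bool = False) -> CompositionReport:
    """Composition enrichment of a protein set.

    Parameters
    ----------
    sequences
        Amino-acid strings (or a mapping id → sequence; values are used).
    background
        Per-residue frequency table covering all 20 standard amino acids,
        positive, summing to 1 (±1e-6); defaults to the shipped plant
        average.
    per_protein
        Average per-sequence frequency vectors instead of pooling residues
        (pooling is the default).
    """
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    else:
        sequences = list(sequences)
    bg = dict(PLANT_AVERAGE_AA_FREQUENCIES if background is None else background)
    missing = [aa for aa in AMINO_ACIDS if aa not in bg]
    if missing:
        raise ConfigError(f"background is missing amino acid(s) {missing}")
    vals = np.array([bg[aa] for aa in AMINO_ACIDS], float)
    if np.any(vals <= 0):
        raise ConfigError("background frequencies must be positive")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ConfigError(f"background frequencies must sum to 1, got {vals.sum()!r}")

    def freq_vector(seq: str) -> tuple[np.ndarray, int]:
        seq = seq.upper()
        counts = np.array([seq.count(aa) for aa in AMINO_ACIDS], float)
        total = int(counts.sum())  # X/ambiguous residues fall out here
        return counts, total

    if per_protein:
        vectors = []
        n_res = 0
        for seq in sequences:
            counts, total = freq_vector(seq)
            if total:
                vectors.append(counts / total)
                n_res += total
        if not vectors:
            raise ValueError("no standard residues in the given sequences")
        observed = np.mean(vectors, axis=0)
        total_residues = n_res
    else:
        pooled = np.zeros(len(AMINO_ACIDS))
        for seq in sequences:
            counts, _ = freq_vector(seq)
            pooled += counts
        total_residues = int(pooled.sum())
        if total_residues == 0:
            raise ValueError("no standard residues in the given sequences")
        observed = pooled / total_residues

    enrichment = 100.0 * (observed / vals - 1.0)
    frame = pd.DataFrame(
        {"observed": observed, "background": vals, "enrichment_pct": enrichment},
        index=pd.Index(AMINO_ACIDS, name="amino_acid"),
    )
    return CompositionReport(frame=frame, total_residues=total_residues)
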