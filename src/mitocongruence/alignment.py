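"""Aligned nucleotide matrices and their partitioned variant.

Internally partitions are half-open 0-based column intervals; the 1-based
inclusive NEXUS charset convention is confined to the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

# IUPAC nucleotide codes as 4-bit masks over (A, C, G, T)
IUPAC_MASKS: dict[str, int] = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011,
    "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, "?": 0b1111,
}

BASES = "ACGT"


@dataclass
class Alignment:
    """Taxa-by-sites nucleotide matrix.

    ``matrix`` is a 2-D array of single uppercase characters; rows are
    ordered as ``taxa``.
    """

    taxa: list[str]
    matrix: np.ndarray  # dtype '<U1', shape (n_taxa, n_sites)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dup}")
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxon list")
        self.matrix = np.char.upper(self.matrix)
        bad = set(np.unique(self.matrix)) - set(IUPAC_MASKS)
        if bad:
            raise ValueError(f"unknown residue characters: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_sequences(cls, records: Mapping[str, str]) -> "Alignment":
        taxa = list(records)
        lengths = {t: len(records[t]) for t in taxa}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"ragged alignment rows: {lengths}")
        matrix = np.array(
            [list(records[t].upper()) for t in taxa], dtype="<U1"
        )
        return cls(taxa, matrix)

    def sequence(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(self.matrix[i])

    def masks(self) -> np.ndarray:
        """IUPAC bitmask matrix (uint8), same shape as ``matrix``."""
        lut = np.zeros(128, dtype=np.uint8)
        for ch, m in IUPAC_MASKS.items():
            lut[ord(ch)] = m
        codes = self.matrix.view(np.uint32).reshape(self.matrix.shape)
        return lut[codes]

    def columns(self, index: Sequence[int]) -> "Alignment":
        return Alignment(list(self.taxa), self.matrix[:, list(index)])

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in keep]
        return Alignment(list(keep), self.matrix[idx])

    def concat(self, other: "Alignment") -> "Alignment":
        if self.taxa != other.taxa:
            if set(self.taxa) != set(other.taxa):
                raise ValueError("taxon sets differ")
            other = other.subset_taxa(self.taxa)
        return Alignment(
            list(self.taxa), np.hstack([self.matrix, other.matrix])
        )

    def empirical_frequencies(self, floor: float = 1e-4) -> np.ndarray:
        """Base composition over unambiguous residues, floored away
        from zero so likelihoods stay finite."""
        counts = np.array(
            [(self.matrix == b).sum() for b in BASES], dtype=float
        )
        if counts.sum() == 0:
            counts[:] = 1.0
        freqs = counts / counts.sum()
        freqs = np.maximum(freqs, floor)
        return freqs / freqs.sum()


@dataclass
class PartitionedAlignment:
    """Alignment plus an ordered map of gene name -> column interval.

    Intervals are half-open 0-based ``(start, stop)`` and must be
    pairwise disjoint and within the matrix.
    """

    alignment: Alignment
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        n = self.alignment.n_sites
        spans = sorted(self.partitions.values())
        prev_stop = 0
        for start, stop in spans:
            if not (0 <= start < stop <= n):
                raise ValueError(
                    f"partition interval ({start}, {stop}) outside matrix"
                    f" of {n} sites"
                )
            if start < prev_stop:
                raise ValueError("overlapping partitions")
            prev_stop = stop

    @property
    def gene_names(self) -> list[str]:
        return list(self.partitions)

    def gene_width(self, gene: str) -> int:
        start, stop = self.partitions[gene]
        return stop - start

    def extract(self, genes: Sequence[str]) -> Alignment:
        """Column-concatenation of the named genes, in stored order.

        Serves both single-gene matrices and antigene (complement)
        matrices.
        """
        unknown = [g for g in genes if g not in self.partitions]
        if unknown:
            raise KeyError(f"unknown genes: {unknown}")
        wanted = set(genes)
        cols: list[np.ndarray] = []
        for name, (start, stop) in self.partitions.items():
            if name in wanted:
                cols.append(self.alignment.matrix[:, start:stop])
        return Alignment(list(self.alignment.taxa), np.hstack(cols))

    def gene_alignment(self, gene: str) -> Alignment:
        return self.extract([gene])

    def antigene_alignment(self, gene: str) -> Alignment:
        others = [g for g in self.gene_names if g != gene]
        return self.extract(others)

    def subset_taxa(self, keep: Sequence[str]) -> "PartitionedAlignment":
        return PartitionedAlignment(
            self.alignment.subset_taxa(keep), dict(self.partitions)
        )
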