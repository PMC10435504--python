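"""Synthetic genome model: chromosome lengths and ordered feature positions.

The model is deliberately artificial (no real reference is downloaded): a
karyotype of 22 autosome-like chromosomes with linearly decreasing lengths,
genes placed on a jittered regular grid so genomic order is well defined, and
ATAC tiles derived from the same coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeModel", "default_genome"]


@dataclass
class GenomeModel:
    """Chromosome lengths plus per-chromosome ordered gene positions.

    Attributes
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp (insertion order is genomic
        order).
    gene_positions
        Mapping chromosome name -> strictly increasing array of gene midpoint
        positions (0-based).
    """

    chrom_lengths: dict[str, int]
    gene_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.gene_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"gene positions on {chrom} not strictly increasing")
            if pos.size and (pos[0] < 0 or pos[-1] >= self.chrom_lengths[chrom]):
                raise ValueError(f"gene positions on {chrom} out of bounds")
            self.gene_positions[chrom] = pos

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_genes(self) -> int:
        return int(sum(len(p) for p in self.gene_positions.values()))

    def gene_table(self):
        """Flat (gene_id, chrom, pos) table in genomic order."""
        import pandas as pd

        rows = []
        for chrom, pos in self.gene_positions.items():
            for i, p in enumerate(pos):
                rows.append((f"g_{chrom}_{i}", chrom, int(p)))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos"])


def default_genome(
    n_chroms: int = 22,
    max_length: int = 100_000_000,
    min_length: int = 40_000_000,
    genes_per_mb: float = 5.0,
    seed: int = 0,
) -> GenomeModel:
    """Build the default synthetic karyotype.

    Chromosome lengths decrease linearly from ``max_length`` to
    ``min_length``; genes sit on a regular grid with deterministic jitter so
    spacing is irregular but order is fixed for a given seed.
    """
    rng = np.random.default_rng(seed)
    lengths = np.linspace(max_length, min_length, n_chroms).astype(np.int64)
    chrom_lengths = {str(i + 1): int(lengths[i]) for i in range(n_chroms)}
    gene_positions: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_genes = max(1, int(length / 1e6 * genes_per_mb))
        spacing = length / (n_genes + 1)
        grid = spacing * (np.arange(1, n_genes + 1))
        jitter = rng.uniform(-0.3, 0.3, size=n_genes) * spacing
        pos = np.sort((grid + jitter).astype(np.int64))
        # enforce strict increase after rounding
        pos = np.maximum.accumulate(pos + np.arange(n_genes))
        pos = np.clip(pos, 0, length - 1)
        pos = np.unique(pos)
        gene_positions[chrom] = pos
    return GenomeModel(chrom_lengths=chrom_lengths, gene_positions=gene_positions)
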