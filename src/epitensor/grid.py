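"""Genome binning at the three model resolutions.

The model represents the genomic axis at 25 bp, 250 bp and 5 kbp. A
:class:`GenomicGrid` holds chromosome names and lengths and derives the
per-chromosome bin counts at each resolution. All coordinates are 0-based
half-open; 25-bp bin ``i`` covers ``[25*i, 25*i + 25)`` and terminal partial
bins are kept (ceil counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BIN_SIZE = 25
MID_RATIO = 10     # 250 bp / 25 bp
COARSE_RATIO = 200  # 5 kbp / 25 bp


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


@dataclass(frozen=True)
class GenomicGrid:
    """Chromosome sizes and the 25-bp binning they induce."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = BIN_SIZE

    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.chrom_names)})

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomicGrid":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[self._chrom_idx(chrom)]

    def _chrom_idx(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins_25(self, chrom: str) -> int:
        return _ceil_div(self.length(chrom), self.bin_size)

    def n_bins_250(self, chrom: str) -> int:
        return _ceil_div(self.n_bins_25(chrom), MID_RATIO)

    def n_bins_5k(self, chrom: str) -> int:
        return _ceil_div(self.n_bins_25(chrom), COARSE_RATIO)

    def multiscale_indices(self, chrom: str, bin25) -> tuple:
        """Map a 25-bp bin index to its (fine, mid, coarse) factor indices.

        ``bin25`` may be a scalar or an integer array; indices are
        per-chromosome.
        """
        n = self.n_bins_25(chrom)
        b = np.asarray(bin25)
        if np.any(b < 0) or np.any(b >= n):
            raise IndexError(f"bin index out of range [0, {n}) on {chrom}")
        i250 = b // MID_RATIO
        i5k = b // COARSE_RATIO
        if np.isscalar(bin25) or b.ndim == 0:
            return int(b), int(i250), int(i5k)
        return b, i250, i5k

    def bin_of(self, chrom: str, pos_bp: int) -> int:
        """25-bp bin containing basepair ``pos_bp``."""
        if not 0 <= pos_bp < self.length(chrom):
            raise IndexError(f"position {pos_bp} outside {chrom}")
        return pos_bp // self.bin_size

    def total_bins_25(self) -> int:
        return sum(self.n_bins_25(c) for c in self.chrom_names)
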