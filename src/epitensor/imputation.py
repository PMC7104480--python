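"""Genome-wide imputation of missing (cell, assay) tracks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import EpiTensorModel
from .signal_io import SignalVector, inverse_arcsinh, write_signal


@dataclass
class ImputedTrack:
    """Predicted arcsinh signal per 25-bp bin for one (cell, assay, chrom)."""

    cell: str
    assay: str
    chrom: str
    values: np.ndarray


def impute_track(model: EpiTensorModel, cell: str, assay: str, chrom: str,
                 batch_size: int = 100_000, clip_negative: bool = False) -> ImputedTrack:
    """Impute one chromosome track; a pure, deterministic function of the model.

    Predictions are on the arcsinh scale and are not clipped to >= 0 by
    default (``clip_negative=True`` clamps at zero).
    """
    if cell not in model.cell_index:
        raise KeyError(f"unknown cell {cell!r}")
    if assay not in model.assay_index:
        raise KeyError(f"unknown assay {assay!r}")
    if chrom not in model.grid:
        raise KeyError(f"untrained or unknown chromosome: {chrom}")
    n = model.grid.n_bins_25(chrom)
    out = np.empty(n, dtype=np.float64)
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        out[lo:hi] = model.predict(cell, assay, chrom, np.arange(lo, hi))
    if clip_negative:
        np.maximum(out, 0.0, out=out)
    return ImputedTrack(cell, assay, chrom, out)


def export_imputed(track: ImputedTrack, path, grid,
                   inverse_transform: bool = False, precision: int = 4) -> None:
    """Write an imputed track as bedGraph.

    ``inverse_transform=True`` applies sinh to restore the -log10 p scale.
    """
    values = track.values
    if inverse_transform:
        values = inverse_arcsinh(values)
    write_signal(SignalVector(track.chrom, values), path, grid,
                 precision=precision)
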