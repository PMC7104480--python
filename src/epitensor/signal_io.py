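"""Reading, binning, transforming and writing genomic signal tracks.

Signal tracks are -log10 p enrichment values binned at 25 bp and stored on the
arcsinh scale (``asinh(x) = ln(x + sqrt(1+x^2))``), the variance-stabilising
transform used for both training and evaluation. Peak calls come from MACS2
narrowPeak files; evaluation regions (promoters, gene bodies, enhancers) are
BED intervals. All file formats are plain text, tab-separated, 0-based
half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .grid import GenomicGrid


# ---------------------------------------------------------------------------
# transforms

def arcsinh_transform(x):
    """Apply ``asinh`` to raw -log10 p values.

    Strictly increasing; ``asinh(2) = 1.4436``, which rounds to the 1.44 peak
    threshold corresponding to p = 0.01.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("arcsinh_transform requires finite input")
    out = np.arcsinh(x)
    return float(out) if out.ndim == 0 else out


def inverse_arcsinh(y):
    """Invert :func:`arcsinh_transform` (``sinh``)."""
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("inverse_arcsinh requires finite input")
    out = np.sinh(y)
    return float(out) if out.ndim == 0 else out


PEAK_THRESHOLD = float(np.round(np.arcsinh(2.0), 2))  # 1.44, arcsinh of -log10(0.01)


# ---------------------------------------------------------------------------
# domain types

@dataclass
class SignalVector:
    """One arcsinh-scale value per 25-bp bin of one chromosome."""

    chrom: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("SignalVector values must be 1-D")

    def validate(self, grid: GenomicGrid) -> "SignalVector":
        n = grid.n_bins_25(self.chrom)
        if len(self.values) != n:
            raise ValueError(
                f"{self.chrom}: expected {n} bins, got {len(self.values)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.chrom}: non-finite signal values")
        return self


@dataclass
class PeakCalls:
    """Boolean peak indicator per 25-bp bin for one chromosome."""

    chrom: str
    indicator: np.ndarray

    def __post_init__(self):
        self.indicator = np.asarray(self.indicator, dtype=bool)


@dataclass
class RegionSet:
    """A list of (chrom, start, end, strand, label) intervals."""

    regions: list
    kind: str = "generic"

    def __post_init__(self):
        for r in self.regions:
            chrom, start, end, strand, _label = r
            if not start < end:
                raise ValueError(f"region {chrom}:{start}-{end} has start >= end")
            if strand not in ("+", "-", "."):
                raise ValueError(f"bad strand {strand!r}")

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def bins(self, grid: GenomicGrid, chrom: str) -> np.ndarray:
        """Sorted unique 25-bp bin indices covered by regions on ``chrom``."""
        bins = []
        n = grid.n_bins_25(chrom)
        for c, start, end, _strand, _label in self.regions:
            if c != chrom:
                continue
            b0 = start // grid.bin_size
            b1 = -(-end // grid.bin_size)  # ceil: any overlap marks the bin
            bins.append(np.arange(max(b0, 0), min(b1, n)))
        if not bins:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(bins))


# ---------------------------------------------------------------------------
# binning

def bin_track(intervals, grid: GenomicGrid, chrom: str,
              aggregator: str = "mean") -> SignalVector:
    """Bin (start, end, value) records into 25-bp bins.

    Each bin takes the coverage-weighted mean of overlapping interval values
    (or the max with ``aggregator="max"``); uncovered basepairs count as 0
    toward the mean, and wholly uncovered bins are 0. Terminal partial bins
    average over their actual width.
    """
    if aggregator not in ("mean", "max"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    length = grid.length(chrom)
    n = grid.n_bins_25(chrom)
    values = np.zeros(n, dtype=np.float64)
    bs = grid.bin_size
    if aggregator == "mean":
        weight = np.zeros(n, dtype=np.float64)
        n_iv = np.zeros(n, dtype=np.int64)
        only_val = np.zeros(n, dtype=np.float64)
    for start, end, val in intervals:
        if start < 0 or end > length:
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} (length {length})")
        if end <= start:
            continue
        b0, b1 = start // bs, (end - 1) // bs
        for b in range(b0, b1 + 1):
            lo, hi = max(start, b * bs), min(end, (b + 1) * bs)
            w = hi - lo
            if aggregator == "mean":
                values[b] += w * val
                weight[b] += w
                n_iv[b] += 1
                only_val[b] = val
            else:
                values[b] = max(values[b], val)
    if aggregator == "mean":
        # bin width: 25 bp except possibly the last bin
        widths = np.full(n, bs, dtype=np.float64)
        widths[-1] = length - (n - 1) * bs
        covered = weight > 0
        values[covered] /= widths[covered]
        # a bin fully covered by a single interval takes its value exactly
        # (the weighted mean would only re-derive it with rounding error)
        exact = (n_iv == 1) & (weight == widths)
        values[exact] = only_val[exact]
    return SignalVector(chrom, values)


# ---------------------------------------------------------------------------
# readers

def read_chrom_sizes(path) -> GenomicGrid:
    """Read a two-column ``name<TAB>length`` chromosome-sizes file."""
    sizes = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected name<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return GenomicGrid.from_dict(sizes)


def read_bedgraph(path, grid: GenomicGrid, chrom: str,
                  transform: bool = False) -> SignalVector:
    """Read a 4-column bedGraph and bin it to 25 bp.

    With ``transform=True`` the values are arcsinh-transformed after binning
    (for raw -log10 p input).
    """
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{i}: expected 4 bedGraph columns")
            if parts[0] != chrom:
                continue
            intervals.append((int(parts[1]), int(parts[2]), float(parts[3])))
    vec = bin_track(intervals, grid, chrom)
    if transform:
        vec = SignalVector(chrom, arcsinh_transform(vec.values))
    return vec


def read_bigwig(path, grid: GenomicGrid, chrom: str,
                transform: bool = False) -> SignalVector:
    """Read a bigWig track, when pyBigWig is available."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("bigWig support requires pyBigWig") from exc
    n = grid.n_bins_25(chrom)
    with pyBigWig.open(str(path)) as bw:
        vals = bw.stats(chrom, 0, grid.length(chrom), nBins=n, type="mean")
    values = np.array([v if v is not None else 0.0 for v in vals])
    if transform:
        values = arcsinh_transform(values)
    return SignalVector(chrom, values)


def read_narrowpeak(path, grid: GenomicGrid, chrom: str) -> PeakCalls:
    """Read MACS2 narrowPeak (BED6+4); a bin is true iff it overlaps a peak."""
    n = grid.n_bins_25(chrom)
    indicator = np.zeros(n, dtype=bool)
    length = grid.length(chrom)
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{i}: narrowPeak needs 10 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{i}: malformed coordinates") from None
            if parts[0] != chrom:
                continue
            if start < 0 or end > length or start >= end:
                raise ValueError(f"{path}:{i}: bad interval [{start}, {end})")
            b0 = start // grid.bin_size
            b1 = min(-(-end // grid.bin_size), n)
            indicator[b0:b1] = True
    return PeakCalls(chrom, indicator)


def read_bed_regions(path, kind: str = "generic") -> RegionSet:
    """Read BED (3+ columns) into a :class:`RegionSet`."""
    regions = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else f"region{i}"
            strand = parts[5] if len(parts) > 5 else "."
            regions.append((parts[0], int(parts[1]), int(parts[2]), strand, name))
    return RegionSet(regions, kind=kind)


def promoter_regions(tss_records, span_bp: int, grid: GenomicGrid) -> RegionSet:
    """Build promoter intervals spanning ``span_bp`` upstream of each TSS.

    For a + strand gene the promoter is ``[tss - span, tss)``; for - strand,
    ``[tss, tss + span)``. Intervals are clipped to chromosome bounds.
    """
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    regions = []
    for rec in tss_records:
        chrom, tss, strand = rec[0], rec[1], rec[2]
        label = rec[3] if len(rec) > 3 else f"tss{tss}"
        length = grid.length(chrom)
        if not 0 <= tss <= length:
            raise ValueError(f"TSS {tss} outside {chrom}")
        if strand == "+":
            start, end = max(tss - span_bp, 0), tss
        elif strand == "-":
            start, end = tss, min(tss + span_bp, length)
        else:
            raise ValueError(f"promoter needs stranded TSS, got {strand!r}")
        if start < end:
            regions.append((chrom, start, end, strand, label))
    return RegionSet(regions, kind="promoter")


# ---------------------------------------------------------------------------
# writers

def write_signal(vector: SignalVector, path, grid: GenomicGrid,
                 precision: int = 4, mode: str = "w") -> None:
    """Write a SignalVector as bedGraph, run-length merging equal bins.

    Values are rounded to ``precision`` decimals; with the default 4 this
    round-trips through :func:`bin_track` for values produced at that
    precision. ``precision=None`` writes full ``repr`` floats (bit-exact
    round trip).
    """
    length = grid.length(vector.chrom)
    bs = grid.bin_size
    vals = vector.values
    dirname = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(dirname):
        raise FileNotFoundError(f"directory does not exist: {dirname}")
    with open(path, mode, encoding="utf-8", newline="\n") as fh:
        run_start = 0
        for b in range(1, len(vals) + 1):
            if b < len(vals) and vals[b] == vals[run_start]:
                continue
            start_bp = run_start * bs
            end_bp = min(b * bs, length)
            v = vals[run_start]
            text = repr(float(v)) if precision is None else f"{v:.{precision}f}"
            fh.write(f"{vector.chrom}\t{start_bp}\t{end_bp}\t{text}\n")
            run_start = b


def write_narrowpeak(calls: PeakCalls, path, grid: GenomicGrid,
                     mode: str = "w") -> None:
    """Write contiguous true runs of a PeakCalls indicator as narrowPeak."""
    bs = grid.bin_size
    length = grid.length(calls.chrom)
    ind = calls.indicator
    with open(path, mode, encoding="utf-8", newline="\n") as fh:
        b = 0
        k = 0
        while b < len(ind):
            if not ind[b]:
                b += 1
                continue
            e = b
            while e < len(ind) and ind[e]:
                e += 1
            start_bp, end_bp = b * bs, min(e * bs, length)
            fh.write(f"{calls.chrom}\t{start_bp}\t{end_bp}\tpeak{k}\t0\t.\t0\t-1\t-1\t-1\n")
            k += 1
            b = e


def write_bed_regions(regions: RegionSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom, start, end, strand, label in regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t{strand}\n")
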