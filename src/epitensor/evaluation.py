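"""Imputation quality metrics.

Six MSE variants over arcsinh-scale tracks:

- ``mse_global`` — all positions;
- ``mse_1obs`` / ``mse_1imp`` — the top 1% of positions ranked by observed
  or by imputed signal (where imputation errors hurt peak calling most);
- ``mse_prom`` / ``mse_gene`` / ``mse_enh`` — positions inside promoters,
  gene bodies, FANTOM5 enhancers.

Plus the peak-count-stratified evaluation: per assay, MACS2 peak calls are
summed across cell types per 25-bp bin, never-peak bins are discarded, and
MSE / precision / recall are computed separately at each peak count after
thresholding signal at 1.44 (arcsinh of -log10 p = 2, i.e. p = 0.01).
Pairwise mark relationships are Pearson correlations of per-region mean
signal between two assays. Average precision uses the step-interpolation
formula with one threshold per distinct score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GenomicGrid
from .signal_io import PEAK_THRESHOLD, RegionSet

MSE_METRICS = ("mse_global", "mse_1obs", "mse_1imp",
               "mse_prom", "mse_gene", "mse_enh")


@dataclass
class EvaluationReport:
    metrics: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.metrics[key]


def _check_pair(observed, imputed):
    observed = np.asarray(observed, dtype=np.float64)
    imputed = np.asarray(imputed, dtype=np.float64)
    if observed.shape != imputed.shape:
        raise ValueError(
            f"length mismatch: {observed.shape} vs {imputed.shape}")
    return observed, imputed


def mse_global(observed, imputed) -> float:
    """Mean squared error over all positions."""
    observed, imputed = _check_pair(observed, imputed)
    return float(np.mean((observed - imputed) ** 2))


def top1_indices(values, n_top: int) -> np.ndarray:
    """Indices of the ``n_top`` largest values, ties broken by lower index."""
    values = np.asarray(values)
    # stable sort on (-value, index): mergesort keeps index order within ties
    order = np.argsort(-values, kind="stable")
    return np.sort(order[:n_top])


def mse_top1(observed, imputed, rank_by: str = "observed") -> float:
    """MSE over the top 1% of positions ranked by observed or imputed signal."""
    observed, imputed = _check_pair(observed, imputed)
    n = len(observed)
    if n < 100:
        raise ValueError(f"need >= 100 positions for a top-1% set, got {n}")
    if rank_by not in ("observed", "imputed"):
        raise ValueError(f"rank_by must be 'observed' or 'imputed'")
    ranker = observed if rank_by == "observed" else imputed
    idx = top1_indices(ranker, n // 100)
    return float(np.mean((observed[idx] - imputed[idx]) ** 2))


def mse_regions(observed, imputed, regions: RegionSet, grid: GenomicGrid,
                chrom: str) -> float:
    """MSE over the union of bins covered by regions (deduplicated)."""
    observed, imputed = _check_pair(observed, imputed)
    if len(regions) == 0:
        raise ValueError("empty region set")
    bins = regions.bins(grid, chrom)
    if len(bins) == 0:
        raise ValueError(f"no region overlaps {chrom}")
    return float(np.mean((observed[bins] - imputed[bins]) ** 2))


def evaluate_track(observed, imputed, grid, chrom, promoters=None, genes=None,
                   enhancers=None, **metadata) -> EvaluationReport:
    """Compute the full MSE suite for one track pair."""
    report = EvaluationReport(metadata=dict(metadata, chrom=chrom))
    report.metrics["mse_global"] = mse_global(observed, imputed)
    report.metrics["mse_1obs"] = mse_top1(observed, imputed, "observed")
    report.metrics["mse_1imp"] = mse_top1(observed, imputed, "imputed")
    for name, regions in (("mse_prom", promoters), ("mse_gene", genes),
                          ("mse_enh", enhancers)):
        if regions is not None:
            report.metrics[name] = mse_regions(observed, imputed, regions,
                                               grid, chrom)
    return report


# ---------------------------------------------------------------------------
# peak-count stratification

@dataclass
class PeakStratification:
    """Per-bin count of cell types with a MACS2 peak, for one assay."""

    counts: np.ndarray
    n_cells: int

    @property
    def included(self) -> np.ndarray:
        """Bins that were a peak in at least one cell type."""
        return self.counts > 0


def stratify_by_peak_count(peak_calls_per_cell) -> PeakStratification:
    """Sum boolean peak indicators across cell types per 25-bp bin.

    Bins with count 0 (never a peak) are flagged excluded from the
    stratified evaluation.
    """
    calls = [np.asarray(p.indicator if hasattr(p, "indicator") else p,
                        dtype=bool) for p in peak_calls_per_cell]
    if not calls:
        raise ValueError("need peak calls for at least one cell type")
    lengths = {len(c) for c in calls}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent grids: lengths {sorted(lengths)}")
    return PeakStratification(np.sum(calls, axis=0).astype(np.int64),
                              len(calls))


def stratified_prf(signals_per_cell, peak_calls_per_cell,
                   stratification: PeakStratification | None = None,
                   threshold: float = PEAK_THRESHOLD) -> dict:
    """Per-peak-count MSE/precision/recall of thresholded signal vs calls.

    For each count value c in 1..n_cells, restricts to bins where exactly c
    cell types have a peak and, pooling all cell types, compares
    ``signal >= threshold`` (inclusive) against the MACS2 calls. ``signals``
    may be observed or imputed tracks. Precision is omitted (key absent) in
    strata with no predicted peaks; MSE here is the mean squared difference
    between the signal and the binarized calls scaled to the threshold
    convention, so it is only reported when observed signal is also supplied
    via ``stratified_mse``.

    Returns ``{count: {"precision": ..., "recall": ..., "n_bins": ...}}``.
    """
    signals = [np.asarray(s.values if hasattr(s, "values") else s,
                          dtype=np.float64) for s in signals_per_cell]
    calls = [np.asarray(p.indicator if hasattr(p, "indicator") else p,
                        dtype=bool) for p in peak_calls_per_cell]
    if len(signals) != len(calls):
        raise ValueError("signals and peak calls must align per cell type")
    if stratification is None:
        stratification = stratify_by_peak_count(calls)
    counts = stratification.counts
    sig = np.stack(signals)       # cells x bins
    call = np.stack(calls)
    pred = sig >= threshold
    out = {}
    for c in range(1, stratification.n_cells + 1):
        bins = counts == c
        if not bins.any():
            continue
        p, t = pred[:, bins], call[:, bins]
        tp = int(np.sum(p & t))
        fp = int(np.sum(p & ~t))
        fn = int(np.sum(~p & t))
        entry = {"n_bins": int(bins.sum()),
                 "recall": tp / (tp + fn) if tp + fn else None}
        if tp + fp > 0:
            entry["precision"] = tp / (tp + fp)
        out[c] = entry
    return out


def stratified_mse(observed_per_cell, imputed_per_cell,
                   stratification: PeakStratification) -> dict:
    """MSE between observed and imputed signal per peak-count stratum."""
    obs = np.stack([np.asarray(v, dtype=np.float64) for v in observed_per_cell])
    imp = np.stack([np.asarray(v, dtype=np.float64) for v in imputed_per_cell])
    if obs.shape != imp.shape:
        raise ValueError("observed/imputed shape mismatch")
    out = {}
    for c in range(1, stratification.n_cells + 1):
        bins = stratification.counts == c
        if not bins.any():
            continue
        out[c] = float(np.mean((obs[:, bins] - imp[:, bins]) ** 2))
    return out


def average_activity_baseline(trackset, assay: str, chrom: str,
                              exclude_cells=()) -> np.ndarray:
    """Per-bin mean over a trackset's tracks of one assay.

    The standard position-wise reference predictor for imputation: it knows
    where signal usually is but nothing about the target cell type.
    """
    vals = [trackset.values(c, a, chrom) for c, a in trackset.tracks()
            if a == assay and c not in set(exclude_cells)]
    if not vals:
        raise ValueError(f"no tracks for assay {assay!r}")
    return np.mean(vals, axis=0)


# ---------------------------------------------------------------------------
# pairwise mark relationships

def pairwise_relationship(track_a, track_b, regions: RegionSet,
                          grid: GenomicGrid, chrom: str,
                          method: str = "pearson") -> float:
    """Correlation of per-region mean signal between two assays.

    Positive values mean the two marks co-occur across the regions (e.g.
    H3K36me3 with RNA-seq over gene bodies); negative values mean mutual
    exclusion (e.g. H3K4me3 with H3K27me3 over promoters).
    """
    track_a = np.asarray(track_a, dtype=np.float64)
    track_b = np.asarray(track_b, dtype=np.float64)
    means_a, means_b = [], []
    for c, start, end, _strand, _label in regions:
        if c != chrom:
            continue
        sub = RegionSet([(c, start, end, _strand, _label)])
        bins = sub.bins(grid, chrom)
        if len(bins) == 0:
            continue
        means_a.append(track_a[bins].mean())
        means_b.append(track_b[bins].mean())
    if len(means_a) < 3:
        raise ValueError(f"need >= 3 regions on {chrom}, got {len(means_a)}")
    a, b = np.array(means_a), np.array(means_b)
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        from scipy.stats import spearmanr
        return float(spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# average precision

def average_precision(labels, scores) -> float:
    """AP = sum_n (R_n - R_{n-1}) * P_n over descending score thresholds.

    One threshold per distinct score; tied scores enter as a single
    threshold. Invariant under strictly increasing transforms of scores.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined with no positives")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    npred = np.arange(1, len(y) + 1)
    # keep only the last index of each tied-score block
    block_end = np.ones(len(s), dtype=bool)
    block_end[:-1] = s[:-1] != s[1:]
    tp, npred = tp[block_end], npred[block_end]
    precision = tp / npred
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))
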