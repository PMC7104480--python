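"""Synthetic epigenome compendia with known latent structure.

The generator emulates the statistical structure the factorization model
assumes: a low-rank-plus-nonlinearity tensor over (cell, assay, position).
Signal is built on the -log10 p scale from Gaussian peak bumps; each peak is
either *constitutive* (active in every cell type) or *facultative* (active
in a random subset), each assay responds to each peak with a fixed weight,
truncated Gaussian noise is added, and the arcsinh transform is applied.
A fraction of (cell, assay) tracks is masked as missing so imputation can be
scored against held-out truth. Per-track peak calls mark bins where the
noiseless signal reaches -log10 p = 2.

Everything is reproducible from a mandatory seed, and every emitted file
parses back through :mod:`epitensor.signal_io`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .grid import GenomicGrid
from .signal_io import (PeakCalls, RegionSet, SignalVector, arcsinh_transform,
                        write_narrowpeak, write_signal)
from .training import TrackSet


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a desk-scale compendium.

    Defaults: 6 cell types x 5 assays over one 1.25-Mbp chromosome (50,000
    25-bp bins), ~8 peaks per thousand bins, 70% of peaks facultative with a
    50% chance of silencing per cell, raw-scale noise sd 0.25, and 80% of
    tracks observed. The conditions are calibrated so that cell-type-specific
    (facultative) peak structure, rather than measurement noise, dominates
    the error of position-wise baselines — the regime the stratified
    evaluation and the structure-recovery check probe.
    """

    n_cells: int = 6
    n_assays: int = 5
    chrom_lengths: tuple = (("chrS", 1_250_000),)
    peak_density: float = 0.008          # expected peaks per 25-bp bin
    facultative_fraction: float = 0.7
    silencing_probability: float = 0.5   # per cell, facultative peaks
    assay_response_probability: float = 0.9
    amplitude_range: tuple = (4.0, 12.0)
    peak_width_bins: tuple = (10, 40)
    noise_sd: float = 0.25
    observed_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("facultative_fraction", "silencing_probability",
                     "observed_fraction", "assay_response_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1 or self.n_assays < 1:
            raise ValueError("need at least one cell and one assay")

    def grid(self) -> GenomicGrid:
        return GenomicGrid.from_dict(dict(self.chrom_lengths))


@dataclass
class Compendium:
    """A generated compendium plus its generative ground truth."""

    spec: SyntheticSpec
    grid: GenomicGrid
    tracks: TrackSet                  # all tracks, including held-out truth
    observed: list                    # (cell, assay) keys visible to training
    peak_calls: dict                  # (cell, assay) -> {chrom: PeakCalls}
    truth: dict = field(default_factory=dict)

    @property
    def cells(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.spec.n_cells)]

    @property
    def assays(self) -> list[str]:
        return [f"A{i:02d}" for i in range(self.spec.n_assays)]

    def hidden(self) -> list:
        all_keys = [(c, a) for c in self.cells for a in self.assays]
        return [k for k in all_keys if k not in set(self.observed)]

    def observed_tracks(self) -> TrackSet:
        return self.tracks.subset(self.observed)


def make_compendium(spec: SyntheticSpec) -> Compendium:
    """Draw a full compendium from the generative model (seeded)."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    cells = [f"C{i:02d}" for i in range(spec.n_cells)]
    assays = [f"A{i:02d}" for i in range(spec.n_assays)]

    tracks = TrackSet(grid)
    peak_calls: dict = {}
    truth: dict = {"chroms": {}}

    for chrom in grid.chrom_names:
        n = grid.n_bins_25(chrom)
        n_peaks = max(int(round(spec.peak_density * n)), 1)
        centers = rng.uniform(0, n, size=n_peaks)
        widths = rng.uniform(*spec.peak_width_bins, size=n_peaks)
        amps = rng.uniform(*spec.amplitude_range, size=n_peaks)
        constitutive = rng.random(n_peaks) >= spec.facultative_fraction
        # cell activity: constitutive peaks in every cell; facultative in a
        # random subset (each cell silenced independently)
        active = rng.random((spec.n_cells, n_peaks)) >= spec.silencing_probability
        active[:, constitutive] = True
        # assay response weights, shared across cells
        responds = rng.random((spec.n_assays, n_peaks)) < spec.assay_response_probability
        weights = rng.uniform(0.3, 1.0, size=(spec.n_assays, n_peaks)) * responds

        bins = np.arange(n)
        bumps = np.empty((n_peaks, n), dtype=np.float64)
        for p in range(n_peaks):
            sigma = widths[p] / 4.0
            bumps[p] = np.exp(-0.5 * ((bins - centers[p]) / sigma) ** 2)
        peak_matrix = amps[:, None] * bumps  # peaks x bins

        truth["chroms"][chrom] = {
            "centers": centers, "widths": widths, "amplitudes": amps,
            "constitutive": constitutive, "active": active, "weights": weights,
        }

        for ci, cell in enumerate(cells):
            cell_signal = (active[ci][:, None] * peak_matrix)  # peaks x bins
            for ai, assay in enumerate(assays):
                clean = weights[ai] @ cell_signal  # -log10 p scale
                noisy = np.maximum(
                    clean + rng.normal(0.0, spec.noise_sd, size=n), 0.0)
                tracks.add(cell, assay, chrom, arcsinh_transform(noisy))
                peak_calls.setdefault((cell, assay), {})[chrom] = PeakCalls(
                    chrom, clean >= 2.0)

    all_keys = [(c, a) for c in cells for a in assays]
    n_obs = int(round(spec.observed_fraction * len(all_keys)))
    if n_obs == 0:
        raise ValueError("observed_fraction leaves no observed tracks")
    order = rng.permutation(len(all_keys))
    observed = sorted(all_keys[i] for i in order[:n_obs])
    return Compendium(spec, grid, tracks, observed, peak_calls, truth)


# ---------------------------------------------------------------------------
# task labels

def make_task_labels(compendium: Compendium, task: str = "expression",
                     p_hi: float = 0.9, p_lo: float = 0.05,
                     n_background: int | None = None,
                     gene_half_width_bp: int = 500,
                     seed: int | None = None):
    """Binary labels correlated with the compendium's latent structure.

    For ``task="expression"``: one locus per peak plus background loci at
    random non-peak positions; a locus is labelled positive with probability
    ``p_hi`` when it sits on a constitutive peak and ``p_lo`` otherwise.
    Returns ``(RegionSet, labels, metadata)``; metadata records the exact
    generative rule.
    """
    if task != "expression":
        raise ValueError(f"unknown task {task!r}")
    spec = compendium.spec
    rng = np.random.default_rng(spec.seed + 1000 if seed is None else seed)
    grid = compendium.grid
    regions, is_constitutive = [], []
    for chrom, info in compendium.truth["chroms"].items():
        length = grid.length(chrom)
        for center, constit in zip(info["centers"], info["constitutive"]):
            mid = int(center) * grid.bin_size
            start = max(mid - gene_half_width_bp, 0)
            end = min(mid + gene_half_width_bp, length)
            regions.append((chrom, start, end, "+", f"gene_{chrom}_{len(regions)}"))
            is_constitutive.append(bool(constit))
        n_bg = n_background if n_background is not None else len(info["centers"])
        for _ in range(n_bg):
            mid = int(rng.integers(0, length))
            start = max(mid - gene_half_width_bp, 0)
            end = min(mid + gene_half_width_bp, length)
            regions.append((chrom, start, end, "+", f"bg_{chrom}_{len(regions)}"))
            is_constitutive.append(False)
    is_constitutive = np.array(is_constitutive)
    p = np.where(is_constitutive, p_hi, p_lo)
    labels = rng.random(len(p)) < p
    metadata = {"task": task, "rule": "Bernoulli(p_hi) at constitutive-peak "
                "loci, Bernoulli(p_lo) elsewhere", "p_hi": p_hi, "p_lo": p_lo,
                "n_loci": len(labels)}
    return RegionSet(regions, kind="gene_body"), labels, metadata


# ---------------------------------------------------------------------------
# export

def write_compendium(compendium: Compendium, outdir) -> None:
    """Emit manifest.tsv, per-track bedGraph + narrowPeak, chrom.sizes."""
    os.makedirs(outdir, exist_ok=True)
    grid = compendium.grid
    with open(os.path.join(outdir, "chrom.sizes"), "w", encoding="utf-8",
              newline="\n") as fh:
        for name, length in zip(grid.chrom_names, grid.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
    with open(os.path.join(outdir, "manifest.tsv"), "w", encoding="utf-8",
              newline="\n") as fh:
        for cell, assay in compendium.observed:
            track_path = os.path.join(outdir, f"{cell}.{assay}.bedgraph")
            fh.write(f"{cell}\t{assay}\t{track_path}\n")
            for k, chrom in enumerate(grid.chrom_names):
                mode = "w" if k == 0 else "a"
                write_signal(SignalVector(
                    chrom, compendium.tracks.values(cell, assay, chrom)),
                    track_path, grid, mode=mode)
                write_narrowpeak(
                    compendium.peak_calls[(cell, assay)][chrom],
                    os.path.join(outdir, f"{cell}.{assay}.narrowPeak"), grid,
                    mode=mode)


def write_truth(compendium: Compendium, path) -> None:
    """Store the generative ground truth in an HDF5 container."""
    import h5py
    import json

    with h5py.File(path, "w") as f:
        f.attrs["spec"] = json.dumps(asdict(compendium.spec))
        f.attrs["observed"] = json.dumps(compendium.observed)
        for chrom, info in compendium.truth["chroms"].items():
            g = f.create_group(f"truth/{chrom}")
            for key, arr in info.items():
                g.create_dataset(key, data=np.asarray(arr))
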