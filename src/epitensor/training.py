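"""Model fitting: sampling scheme, ADAM optimizer, two-stage protocol.

The loss is the global mean squared error on the arcsinh scale, fit with
ADAM (lr 0.01, beta1 0.9, beta2 0.999, epsilon 1e-8, learning-rate decay
``lr_t = lr / (1 + decay * t)`` with decay 1e-8). An *epoch* is one pass
through the genomic axis: every 25-bp bin of the training subset is seen
exactly once, paired with a (cell, assay) drawn uniformly from the observed
tracks, in a freshly shuffled order.

Training runs in two stages so the genome factors never need to be resident
genome-wide at once: stage 1 jointly optimizes everything on a small pilot
subset of positions (800 epochs); stage 2 freezes cell, assay and network
weights and fits the genome factors per chromosome (200 epochs each). The
freeze is byte-exact. No early stopping is used in either stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict

import numpy as np

from .grid import GenomicGrid
from .model import EpiTensorModel, ModelConfig
from . import signal_io


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 1e-8
    epochs_stage1: int = 800
    epochs_stage2: int = 200
    batch_size: int = 40000
    dropout: float = 0.0  # hidden-layer inverted dropout during training
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epsilon <= 0:
            raise ValueError("rates must be positive")
        if self.epochs_stage1 < 1 or self.epochs_stage2 < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def desk_stage1(cls, seed: int = 0) -> "TrainingConfig":
        """Stage-1 settings for CPU-scale synthetic runs.

        Keeps the reference optimizer settings and 800 epochs but uses
        hidden-layer dropout 0.2 (regularizing the shared network learned
        from the small pilot) and batch size 5,000.
        """
        return cls(batch_size=5_000, dropout=0.2, seed=seed)

    @classmethod
    def desk_stage2(cls, seed: int = 0) -> "TrainingConfig":
        """Stage-2 settings for CPU-scale synthetic runs.

        1000 epochs: at desk scale the held-in loss is still decreasing at
        200 epochs, and there is no early stopping in either stage.
        """
        return cls(batch_size=5_000, epochs_stage2=1000, seed=seed)


# desk-scale pilot subset: 1% of a 50k-bin chromosome holds too few peaks to
# teach the shared network anything, so desk runs use 10%
DESK_PILOT_FRACTION = 0.10


# ---------------------------------------------------------------------------
# track container

class TrackSet:
    """Sparse (cell, assay) -> per-chromosome arcsinh signal vectors."""

    def __init__(self, grid: GenomicGrid):
        self.grid = grid
        self.data: dict = {}

    def add(self, cell: str, assay: str, chrom: str, values) -> None:
        values = np.asarray(values, dtype=np.float32)
        n = self.grid.n_bins_25(chrom)
        if len(values) != n:
            raise ValueError(f"{chrom}: expected {n} bins, got {len(values)}")
        self.data.setdefault((cell, assay), {})[chrom] = values

    def tracks(self) -> list[tuple[str, str]]:
        return sorted(self.data.keys())

    @property
    def cells(self) -> list[str]:
        return sorted({c for c, _ in self.data})

    @property
    def assays(self) -> list[str]:
        return sorted({a for _, a in self.data})

    def values(self, cell: str, assay: str, chrom: str) -> np.ndarray:
        return self.data[(cell, assay)][chrom]

    def subset(self, tracks) -> "TrackSet":
        out = TrackSet(self.grid)
        for key in tracks:
            out.data[key] = self.data[key]
        return out

    @classmethod
    def from_manifest(cls, manifest_path, grid: GenomicGrid,
                      transform: bool = False) -> "TrackSet":
        """Load tracks from a TSV manifest with columns cell, assay, path."""
        ts = cls(grid)
        with open(manifest_path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{manifest_path}:{i}: need cell<TAB>assay<TAB>path")
                cell, assay, path = parts[:3]
                for chrom in grid.chrom_names:
                    vec = signal_io.read_bedgraph(path, grid, chrom, transform=transform)
                    ts.add(cell, assay, chrom, vec.values)
        return ts


# ---------------------------------------------------------------------------
# regions and folds

def make_training_regions(pairs, grid: GenomicGrid) -> list[tuple[str, int, int]]:
    """Validate (chrom, start_bin, end_bin) pilot regions (half-open bins)."""
    seen: dict[str, list] = {}
    out = []
    for chrom, start, end in pairs:
        n = grid.n_bins_25(chrom)
        if not (0 <= start < end <= n):
            raise ValueError(f"region ({chrom}, {start}, {end}) outside grid")
        for s, e in seen.get(chrom, []):
            if start < e and s < end:
                raise ValueError(f"overlapping regions on {chrom}")
        seen.setdefault(chrom, []).append((start, end))
        out.append((chrom, int(start), int(end)))
    return out


def sample_pilot_regions(grid: GenomicGrid, fraction: float = 0.01,
                         seed: int = 0, n_segments: int = 4):
    """Pick contiguous bin segments covering ~``fraction`` of the genome.

    Stands in for the designated pilot subset (~1% of positions) when no BED
    is supplied; stage-1 results are not sensitive to the particular subset.
    """
    rng = np.random.default_rng(seed)
    total = grid.total_bins_25()
    target = max(int(round(total * fraction)), n_segments)
    seg_len = max(target // n_segments, 1)
    regions = []
    for _ in range(n_segments):
        chrom = grid.chrom_names[rng.integers(len(grid.chrom_names))]
        n = grid.n_bins_25(chrom)
        length = min(seg_len, n)
        start = int(rng.integers(0, n - length + 1))
        regions.append((chrom, start, start + length))
    # merge overlaps rather than reject them
    merged: list = []
    for chrom, s, e in sorted(regions):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return make_training_regions(merged, grid)


def regions_from_bed(regionset, grid: GenomicGrid):
    """Convert a BED RegionSet to bin-space training regions (merged)."""
    by_chrom: dict[str, list] = {}
    for chrom, start, end, _strand, _label in regionset:
        n = grid.n_bins_25(chrom)
        b0 = start // grid.bin_size
        b1 = min(-(-end // grid.bin_size), n)
        by_chrom.setdefault(chrom, []).append((b0, b1))
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return make_training_regions(merged, grid)


def make_track_folds(tracks, k: int = 5, seed: int = 0) -> list[list]:
    """Seeded random partition of tracks into k folds (sizes differ by <=1)."""
    tracks = list(tracks)
    if k > len(tracks):
        raise ValueError(f"k={k} exceeds number of tracks ({len(tracks)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tracks))
    folds: list[list] = [[] for _ in range(k)]
    for i, j in enumerate(order):
        folds[i % k].append(tracks[j])
    return folds


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """ADAM with per-step learning-rate decay ``lr_t = lr / (1 + decay*t)``."""

    def __init__(self, config: TrainingConfig):
        self.lr = config.learning_rate
        self.b1, self.b2 = config.beta1, config.beta2
        self.eps = config.epsilon
        self.decay = config.decay
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict, trainable) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * (self.t - 1))
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for key in trainable:
            g = grads.get(key)
            if g is None:
                continue
            if key not in self.m:
                self.m[key] = np.zeros_like(params[key])
                self.v[key] = np.zeros_like(params[key])
            m, v = self.m[key], self.v[key]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            params[key] -= (lr_t * (m / bc1)
                            / (np.sqrt(v / bc2) + self.eps)).astype(params[key].dtype)


# ---------------------------------------------------------------------------
# initialization

def initialize(model: EpiTensorModel, seed: int = 0) -> EpiTensorModel:
    """Embeddings ~ U(-0.5, 0.5); dense layers Glorot-uniform; biases zero."""
    rng = np.random.default_rng(seed)
    for key, arr in model.params.items():
        if isinstance(key, tuple) or key in ("cell", "assay"):
            model.params[key] = rng.uniform(-0.5, 0.5, arr.shape).astype(np.float32)
    L = model.config.n_hidden_layers
    for i in range(1, L + 1):
        W = model.params[f"W{i}"]
        limit = np.sqrt(6.0 / (W.shape[0] + W.shape[1]))
        model.params[f"W{i}"] = rng.uniform(-limit, limit, W.shape).astype(np.float32)
        model.params[f"b{i}"][:] = 0.0
    wout = model.params["Wout"]
    limit = np.sqrt(6.0 / (wout.shape[0] + 1))
    model.params["Wout"] = rng.uniform(-limit, limit, wout.shape).astype(np.float32)
    model.params["bout"][:] = 0.0
    return model


def _init_rows(shape, rng):
    return rng.uniform(-0.5, 0.5, shape).astype(np.float32)


# ---------------------------------------------------------------------------
# epoch sampling

def sample_epoch(regions, observed_tracks, rng):
    """One epoch of tensor indices over a bin subset.

    ``regions`` is a list of (chrom, start_bin, end_bin); every bin in the
    subset appears exactly once, each paired with one observed (cell, assay)
    track drawn uniformly at random. Returns ``(chrom_ids, bins, track_ids)``
    index arrays plus the chromosome name list, in a seeded shuffled order.
    """
    if len(observed_tracks) == 0:
        raise ValueError("no observed tracks to sample from")
    chrom_names = sorted({c for c, _, _ in regions})
    chrom_lookup = {c: i for i, c in enumerate(chrom_names)}
    chrom_ids, bins = [], []
    for chrom, start, end in regions:
        chrom_ids.append(np.full(end - start, chrom_lookup[chrom], dtype=np.int32))
        bins.append(np.arange(start, end, dtype=np.int64))
    chrom_ids = np.concatenate(chrom_ids)
    bins = np.concatenate(bins)
    order = rng.permutation(len(bins))
    track_ids = rng.integers(0, len(observed_tracks), size=len(bins))
    return chrom_ids[order], bins[order], track_ids, chrom_names


# ---------------------------------------------------------------------------
# one SGD step

def train_step(model: EpiTensorModel, batch, targets, adam: Adam,
               trainable, dropout: float = 0.0, rng=None) -> float:
    """One ADAM update on the batch-mean squared error.

    ``batch`` is ``(chrom, cell_ids, assay_ids, bins)`` for one chromosome;
    parameters outside ``trainable`` are left bit-identical. Returns the
    batch loss; aborts on non-finite loss.
    """
    chrom, cell_ids, assay_ids, bins = batch
    targets = np.asarray(targets, dtype=np.float32)
    cache: list = []
    X = model.assemble_input(cell_ids, assay_ids, chrom, bins)
    masks = None
    if dropout > 0.0:
        if rng is None:
            raise ValueError("dropout requires an rng")
        h = model.config.n_hidden_units
        masks = [(rng.random((len(bins), h)) >= dropout).astype(np.float32)
                 / (1.0 - dropout)
                 for _ in range(model.config.n_hidden_layers)]
    y = model.forward(X, cache=cache, dropout_masks=masks)
    resid = y - targets
    loss = float(np.mean(resid ** 2))
    if not np.isfinite(loss):
        raise RuntimeError(
            f"non-finite loss on {chrom} batch of {len(bins)}; aborting")
    dy = (2.0 / len(bins)) * resid
    want_dnn = any(isinstance(k, str) and k not in ("cell", "assay")
                   for k in trainable)
    dX, grads = model.backward(cache, dy, want_param_grads=want_dnn,
                               dropout_masks=masks)

    slices = model.config.component_slices()
    i25, i250, i5k = model.grid.multiscale_indices(chrom, bins)
    scatter = (("cell", "cell", cell_ids), ("assay", "assay", assay_ids),
               (("g25", chrom), "g25", i25), (("g250", chrom), "g250", i250),
               (("g5k", chrom), "g5k", i5k))
    for key, comp, idx in scatter:
        if key in trainable:
            g = np.zeros_like(model.params[key])
            np.add.at(g, idx, dX[:, slices[comp]])
            grads[key] = g
    adam.step(model.params, grads, trainable)
    return loss


def _run_epochs(model, trackset, regions, trainable, config, n_epochs,
                seed, reinit_keys=(), log=None):
    """Shared epoch loop for the two stages."""
    track_list = trackset.tracks()
    cell_ids = np.array([model.cell_index[c] for c, _ in track_list])
    assay_ids = np.array([model.assay_index[a] for _, a in track_list])
    chroms = sorted({c for c, _, _ in regions})
    values = {}
    for chrom in chroms:
        values[chrom] = np.stack(
            [trackset.values(c, a, chrom) for c, a in track_list])
    rng = np.random.default_rng(seed)
    adam = Adam(config)
    history = []
    for _epoch in range(n_epochs):
        e_chrom, e_bins, e_tracks, chrom_names = sample_epoch(
            regions, track_list, rng)
        losses, counts = [], []
        for lo in range(0, len(e_bins), config.batch_size):
            hi = min(lo + config.batch_size, len(e_bins))
            bc, bb, bt = e_chrom[lo:hi], e_bins[lo:hi], e_tracks[lo:hi]
            for ci, chrom in enumerate(chrom_names):
                sel = bc == ci
                if not sel.any():
                    continue
                bins_s, tracks_s = bb[sel], bt[sel]
                targets = values[chrom][tracks_s, bins_s]
                loss = train_step(
                    model, (chrom, cell_ids[tracks_s], assay_ids[tracks_s],
                            bins_s), targets, adam, trainable,
                    dropout=config.dropout, rng=rng)
                losses.append(loss)
                counts.append(len(bins_s))
        epoch_loss = float(np.average(losses, weights=counts))
        history.append(epoch_loss)
        if log is not None:
            log(_epoch, epoch_loss)
    return history


def fit_stage1(trackset: TrackSet, regions, model: EpiTensorModel,
               config: TrainingConfig, log=None) -> list[float]:
    """Jointly fit cell, assay, pilot-region genome factors and the DNN.

    Runs for ``epochs_stage1`` epochs over the pilot subset; returns the
    per-epoch loss history. Genome-factor rows outside the pilot regions keep
    their initialization (they receive zero gradient and zero ADAM moment).
    """
    if not regions:
        raise ValueError("stage 1 needs non-empty training regions")
    regions = make_training_regions(regions, model.grid)
    trainable = {"cell", "assay", *model.dnn_keys()}
    for chrom in sorted({c for c, _, _ in regions}):
        trainable.update(model.genome_keys(chrom))
    return _run_epochs(model, trackset, regions, trainable, config,
                       config.epochs_stage1, config.seed, log=log)


def fit_stage2(trackset: TrackSet, chrom: str, model: EpiTensorModel,
               config: TrainingConfig, reinitialize: bool = False,
               log=None) -> list[float]:
    """Fit the genome factors of one chromosome with everything else frozen.

    Cell, assay and DNN parameters are bit-identical before and after. With
    ``reinitialize=True`` the chromosome's genome factors are re-drawn
    U(-0.5, 0.5) first (fresh start for chromosomes not covered in stage 1).
    """
    if chrom not in model.grid:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if reinitialize:
        rng = np.random.default_rng(config.seed + 1)
        for key in model.genome_keys(chrom):
            model.params[key] = _init_rows(model.params[key].shape, rng)
    regions = [(chrom, 0, model.grid.n_bins_25(chrom))]
    trainable = set(model.genome_keys(chrom))
    return _run_epochs(model, trackset, regions, trainable, config,
                       config.epochs_stage2, config.seed + 2, log=log)


def fit_two_stage(trackset: TrackSet, pilot_regions, model: EpiTensorModel,
                  config: TrainingConfig, stage2_config: TrainingConfig | None = None,
                  chroms=None, log=None) -> dict:
    """Full protocol: stage 1 on the pilot subset, stage 2 per chromosome.

    ``stage2_config`` overrides the stage-2 settings (e.g. to disable
    dropout there); by default both stages share ``config``.
    """
    history = {"stage1": fit_stage1(trackset, pilot_regions, model, config,
                                    log=log)}
    pilot_chroms = {c for c, _, _ in pilot_regions}
    for chrom in (chroms or model.grid.chrom_names):
        history[chrom] = fit_stage2(
            trackset, chrom, model, stage2_config or config,
            reinitialize=chrom not in pilot_chroms, log=log)
    return history


def fit_new_entity(model: EpiTensorModel, kind: str, name: str,
                   trackset: TrackSet, config: TrainingConfig,
                   epochs: int | None = None) -> EpiTensorModel:
    """Extend a pretrained model with one new cell type or assay.

    All existing parameters are frozen (byte-exact); only the single new
    factor row is learned, from as little as one track. Works because the
    shared network and the other axis factors already define the signal
    space. Returns a new model; the input model is untouched.
    """
    if kind not in ("cell", "assay"):
        raise ValueError("kind must be 'cell' or 'assay'")
    registry = model.cells if kind == "cell" else model.assays
    if name in registry:
        raise ValueError(f"{kind} {name!r} already registered")
    new_tracks = [t for t in trackset.tracks()
                  if (t[0] if kind == "cell" else t[1]) == name]
    if not new_tracks:
        raise ValueError(f"no tracks for new {kind} {name!r}")
    for c, a in new_tracks:
        other = a if kind == "cell" else c
        other_reg = model.assays if kind == "cell" else model.cells
        if other not in other_reg:
            raise KeyError(f"track ({c}, {a}): {other!r} not in model")

    cells = model.cells + [name] if kind == "cell" else model.cells
    assays = model.assays + [name] if kind == "assay" else model.assays
    extended = EpiTensorModel(model.config, model.grid, cells, assays)
    extended.params = {k: v.copy() for k, v in model.params.items()}
    rng = np.random.default_rng(config.seed + 3)
    old = model.params[kind]
    width = old.shape[1]
    extended.params[kind] = np.concatenate(
        [old, _init_rows((1, width), rng)], axis=0)

    regions = [(c, 0, model.grid.n_bins_25(c)) for c in model.grid.chrom_names]
    sub = trackset.subset(new_tracks)
    n_epochs = epochs if epochs is not None else config.epochs_stage2
    _run_epochs(extended, sub, regions, {kind}, config, n_epochs,
                config.seed + 4)
    return extended


def write_loss_log(history, path) -> None:
    """Per-epoch loss log as TSV (stage, epoch, loss)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["stage", "epoch", "loss"])
        for stage, losses in history.items():
            for i, loss in enumerate(losses):
                w.writerow([stage, i, f"{loss:.6g}"])
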