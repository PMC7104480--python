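"""Deep tensor factorization model.

The observed data form a 3-D tensor over (cell type, assay, genomic
position). Instead of a scalar product, the model combines per-axis latent
factors with a feed-forward network: each prediction concatenates the cell
embedding, the assay embedding, and three genomic embeddings at 25-bp,
250-bp and 5-kbp resolution, and passes the result through two ReLU hidden
layers to a linear scalar output on the arcsinh signal scale.

Defaults follow the reference topology: 32 cell factors, 256 assay factors,
25/40/45 genomic factors at the three scales, and two 2048-unit hidden
layers, for a 398-wide network input. Genomic factor indices are
per-chromosome.

The forward and backward passes are implemented directly in numpy; gradients
are exact (ReLU subgradient 0 at the kink) and are shared by the trainer and
by integrated-gradients attribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import h5py
import numpy as np

from .grid import GenomicGrid, MID_RATIO, COARSE_RATIO

FORMAT_VERSION = 1

COMPONENTS = ("cell", "assay", "g25", "g250", "g5k")


@dataclass(frozen=True)
class ModelConfig:
    """Factor widths and network topology."""

    n_cell_factors: int = 32
    n_assay_factors: int = 256
    n_g25: int = 25
    n_g250: int = 40
    n_g5k: int = 45
    n_hidden_layers: int = 2
    n_hidden_units: int = 2048

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def input_width(self) -> int:
        return (self.n_cell_factors + self.n_assay_factors
                + self.n_g25 + self.n_g250 + self.n_g5k)

    @property
    def genomic_width(self) -> int:
        """Per-position latent width (g25 + g250 + g5k); 110 at defaults."""
        return self.n_g25 + self.n_g250 + self.n_g5k

    def component_slices(self) -> dict[str, slice]:
        """Fixed concatenation order: cell | assay | g25 | g250 | g5k."""
        widths = (self.n_cell_factors, self.n_assay_factors,
                  self.n_g25, self.n_g250, self.n_g5k)
        out, off = {}, 0
        for name, w in zip(COMPONENTS, widths):
            out[name] = slice(off, off + w)
            off += w
        return out

    @classmethod
    def desk(cls) -> "ModelConfig":
        """Small topology for CPU-scale runs on synthetic compendia."""
        return cls(n_cell_factors=16, n_assay_factors=16, n_g25=16, n_g250=8,
                   n_g5k=8, n_hidden_layers=2, n_hidden_units=128)


def dnn_parameter_count(config: ModelConfig) -> int:
    d, h, L = config.input_width, config.n_hidden_units, config.n_hidden_layers
    n = d * h + h
    n += (L - 1) * (h * h + h)
    n += h + 1  # linear output
    return n


def parameter_count(config: ModelConfig, grid: GenomicGrid, n_cells: int,
                    n_assays: int, include_dnn: bool = False) -> int:
    """Total learnable parameters for a model on ``grid``.

    The genomic part sums, per chromosome, the three embedding matrices:
    ``n25 * n_g25 + n250 * n_g250 + n5k * n_g5k``. At the human-genome scale
    of ~115 million 25-bp bins this is ~3.4e9 parameters — the saving of the
    multi-scale genome representation over single-resolution factorization.
    """
    total = 0
    for chrom in grid.chrom_names:
        total += grid.n_bins_25(chrom) * config.n_g25
        total += grid.n_bins_250(chrom) * config.n_g250
        total += grid.n_bins_5k(chrom) * config.n_g5k
    total += n_cells * config.n_cell_factors + n_assays * config.n_assay_factors
    if include_dnn:
        total += dnn_parameter_count(config)
    return total


class EpiTensorModel:
    """Five embedding matrices plus DNN weights, with the prediction function.

    Parameters are stored in a flat dict keyed by:

    - ``"cell"``, ``"assay"``: embedding matrices (entities x factors);
    - ``("g25", chrom)``, ``("g250", chrom)``, ``("g5k", chrom)``:
      per-chromosome genomic embeddings;
    - ``"W1"``/``"b1"`` ... and ``"Wout"``/``"bout"``: dense weights.

    All arrays are float32.
    """

    def __init__(self, config: ModelConfig, grid: GenomicGrid,
                 cells: list[str], assays: list[str]):
        if len(set(cells)) != len(cells) or len(set(assays)) != len(assays):
            raise ValueError("duplicate cell or assay names")
        self.config = config
        self.grid = grid
        self.cells = list(cells)
        self.assays = list(assays)
        self.cell_index = {c: i for i, c in enumerate(self.cells)}
        self.assay_index = {a: i for i, a in enumerate(self.assays)}
        self.params: dict = {}
        self._alloc()

    def _alloc(self):
        cfg = self.config
        z = lambda *shape: np.zeros(shape, dtype=np.float32)
        self.params["cell"] = z(len(self.cells), cfg.n_cell_factors)
        self.params["assay"] = z(len(self.assays), cfg.n_assay_factors)
        for chrom in self.grid.chrom_names:
            self.params[("g25", chrom)] = z(self.grid.n_bins_25(chrom), cfg.n_g25)
            self.params[("g250", chrom)] = z(self.grid.n_bins_250(chrom), cfg.n_g250)
            self.params[("g5k", chrom)] = z(self.grid.n_bins_5k(chrom), cfg.n_g5k)
        h, d = cfg.n_hidden_units, cfg.input_width
        widths = [d] + [h] * cfg.n_hidden_layers
        for i in range(1, cfg.n_hidden_layers + 1):
            self.params[f"W{i}"] = z(widths[i - 1], widths[i])
            self.params[f"b{i}"] = z(widths[i])
        self.params["Wout"] = z(h)
        self.params["bout"] = z(1)

    # -- index plumbing ----------------------------------------------------

    def genome_keys(self, chrom: str) -> list:
        if chrom not in self.grid:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return [("g25", chrom), ("g250", chrom), ("g5k", chrom)]

    def dnn_keys(self) -> list:
        keys = []
        for i in range(1, self.config.n_hidden_layers + 1):
            keys += [f"W{i}", f"b{i}"]
        return keys + ["Wout", "bout"]

    # -- input assembly ----------------------------------------------------

    def assemble_input(self, cell_id, assay_id, chrom: str, bin25) -> np.ndarray:
        """Concatenate factor slices for one or many tensor indices.

        Order is cell | assay | g25 | g250 | g5k (persisted with the model;
        attribution aggregation relies on it). Scalar indices give a 1-D
        vector; array indices give a (B, input_width) batch.
        """
        i25, i250, i5k = self.grid.multiscale_indices(chrom, bin25)
        cell_id = np.asarray(cell_id)
        assay_id = np.asarray(assay_id)
        if np.any(cell_id >= len(self.cells)) or np.any(assay_id >= len(self.assays)):
            raise IndexError("cell or assay id out of range")
        b = np.asarray(i25)
        if b.ndim > 0:  # scalar entity ids broadcast across a bin batch
            cell_id, assay_id = (np.broadcast_to(cell_id, b.shape),
                                 np.broadcast_to(assay_id, b.shape))
        parts = (self.params["cell"][cell_id],
                 self.params["assay"][assay_id],
                 self.params[("g25", chrom)][i25],
                 self.params[("g250", chrom)][i250],
                 self.params[("g5k", chrom)][i5k])
        return np.concatenate(parts, axis=-1)

    # -- network -----------------------------------------------------------

    def forward(self, X: np.ndarray, cache: list | None = None,
                dropout_masks: list | None = None) -> np.ndarray:
        """Feed-forward pass: ReLU hidden layers, linear scalar output.

        ``dropout_masks`` (training only) are per-hidden-layer inverted
        dropout multipliers applied after the ReLU.
        """
        X = np.asarray(X, dtype=np.float32)
        squeeze = X.ndim == 1
        h = X.reshape(1, -1) if squeeze else X
        if h.shape[1] != self.config.input_width:
            raise ValueError(
                f"input width {h.shape[1]} != {self.config.input_width}")
        if cache is not None:
            cache.append(h)
        for i in range(1, self.config.n_hidden_layers + 1):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = np.maximum(z, 0.0)
            if dropout_masks is not None:
                h = h * dropout_masks[i - 1]
            if cache is not None:
                cache.append(h)
        y = h @ self.params["Wout"] + self.params["bout"][0]
        return float(y[0]) if squeeze else y

    def backward(self, cache: list, dy: np.ndarray,
                 want_param_grads: bool = True,
                 dropout_masks: list | None = None):
        """Backpropagate ``dy`` (dL/dy per sample) through the network.

        Returns ``(dX, grads)`` where ``dX`` is the gradient with respect to
        the concatenated input batch and ``grads`` maps DNN parameter names to
        gradients (empty when ``want_param_grads`` is false). ReLU uses
        subgradient 0 at exactly-zero pre-activations.
        """
        L = self.config.n_hidden_layers
        grads: dict = {}
        h_last = cache[L]
        dy = np.asarray(dy, dtype=np.float32)
        if want_param_grads:
            grads["Wout"] = h_last.T @ dy
            grads["bout"] = np.array([dy.sum()], dtype=np.float32)
        dh = np.outer(dy, self.params["Wout"])
        for i in range(L, 0, -1):
            dz = dh * (cache[i] > 0)
            if dropout_masks is not None:
                dz = dz * dropout_masks[i - 1]
            if want_param_grads:
                grads[f"W{i}"] = cache[i - 1].T @ dz
                grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return dh, grads

    def predict(self, cell, assay, chrom: str, bin25) -> np.ndarray:
        """Imputed arcsinh signal at the given tensor indices.

        ``cell``/``assay`` may be names or integer ids; ``bin25`` a scalar or
        array of 25-bp bin indices.
        """
        cell_id = self.cell_index[cell] if isinstance(cell, str) else cell
        assay_id = self.assay_index[assay] if isinstance(assay, str) else assay
        return self.forward(self.assemble_input(cell_id, assay_id, chrom, bin25))

    def parameter_count(self, include_dnn: bool = True) -> int:
        return parameter_count(self.config, self.grid, len(self.cells),
                               len(self.assays), include_dnn=include_dnn)

    def copy(self) -> "EpiTensorModel":
        other = EpiTensorModel(self.config, self.grid, self.cells, self.assays)
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Write the model to a single HDF5 container."""
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = FORMAT_VERSION
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["chrom_names"] = json.dumps(list(self.grid.chrom_names))
            f.attrs["chrom_lengths"] = json.dumps(list(self.grid.chrom_lengths))
            f.attrs["cells"] = json.dumps(self.cells)
            f.attrs["assays"] = json.dumps(self.assays)
            f.create_dataset("factors/cell", data=self.params["cell"])
            f.create_dataset("factors/assay", data=self.params["assay"])
            for chrom in self.grid.chrom_names:
                for res in ("g25", "g250", "g5k"):
                    f.create_dataset(f"factors/{chrom}/{res}",
                                     data=self.params[(res, chrom)])
            for key in self.dnn_keys():
                f.create_dataset(f"dnn/{key}", data=self.params[key])

    @classmethod
    def load(cls, path) -> "EpiTensorModel":
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise ValueError(
                    f"model format version {version} unsupported "
                    f"(expected {FORMAT_VERSION})")
            config = ModelConfig(**json.loads(f.attrs["config"]))
            grid = GenomicGrid(tuple(json.loads(f.attrs["chrom_names"])),
                               tuple(json.loads(f.attrs["chrom_lengths"])))
            model = cls(config, grid, json.loads(f.attrs["cells"]),
                        json.loads(f.attrs["assays"]))
            model.params["cell"] = f["factors/cell"][:]
            model.params["assay"] = f["factors/assay"][:]
            for chrom in grid.chrom_names:
                for res in ("g25", "g250", "g5k"):
                    model.params[(res, chrom)] = f[f"factors/{chrom}/{res}"][:]
            for key in model.dnn_keys():
                model.params[key] = f[f"dnn/{key}"][:]
        return model
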