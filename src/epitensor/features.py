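"""Latent genomic factors as features for downstream prediction tasks.

A trained model carries, for every 25-bp position, a concatenated
(g25 | g250 | g5k) latent vector — 110 features at the default widths,
versus 1014 experiments in the full raw compendium. These builders turn the
factors into per-locus feature matrices:

- :func:`window_factor_mean` — mean factor vector over a +-``half_width``
  window (the +-250 bp convention around a TSS or enhancer midpoint);
- :func:`promoter_multiwindow_features` — eight adjacent windows spanning
  +-2 kbp of a TSS, 565 features (vs 8112 for the raw-track equivalent);
- :func:`aggregate_factors` — coarse aggregation (default 40 kbp, the
  replication-timing / FIRE resolution).

The cross-validation harnesses score feature sets by average precision:
:func:`cv_classify` is the 20-fold gradient-boosted-trees protocol;
:func:`cv_pei` is the repeated 5-fold logistic-regression protocol used for
promoter-enhancer interactions. Learners are injected through a minimal
fit/score contract so any conforming implementation can back them.
"""

from __future__ import annotations

import warnings

import numpy as np

from .evaluation import average_precision
from .grid import COARSE_RATIO, MID_RATIO
from .model import EpiTensorModel
from .signal_io import RegionSet

ROADMAP_N_TRACKS = 1014  # observed experiments in the full human compendium


def genomic_factor_matrix(model: EpiTensorModel, chrom: str,
                          bins: np.ndarray) -> np.ndarray:
    """Per-bin concatenated (g25 | g250 | g5k) factors; width 110 at defaults."""
    bins, i250, i5k = model.grid.multiscale_indices(chrom, np.asarray(bins))
    return np.concatenate([
        model.params[("g25", chrom)][bins],
        model.params[("g250", chrom)][i250],
        model.params[("g5k", chrom)][i5k]], axis=-1).astype(np.float64)


def window_factor_mean(model: EpiTensorModel, chrom: str, center_bp: int,
                       half_width_bp: int = 250) -> np.ndarray:
    """Mean concatenated genomic factor vector over ``center +- half_width``.

    With the default half width the window covers exactly 20 of the 25-bp
    bins. Windows reaching past a chromosome end are clipped with a warning.
    """
    bs = model.grid.bin_size
    n = model.grid.n_bins_25(chrom)
    b0 = (center_bp - half_width_bp) // bs
    b1 = -(-(center_bp + half_width_bp) // bs)
    if b0 < 0 or b1 > n:
        warnings.warn(f"window around {chrom}:{center_bp} clipped to chromosome")
        b0, b1 = max(b0, 0), min(b1, n)
    if b1 <= b0:
        raise ValueError(f"empty window around {chrom}:{center_bp}")
    return genomic_factor_matrix(model, chrom, np.arange(b0, b1)).mean(axis=0)


def promoter_multiwindow_features(model: EpiTensorModel, chrom: str,
                                  tss_bp: int, strand: str = "+") -> np.ndarray:
    """Multi-window promoter representation: 565 features at default widths.

    Eight adjacent 500-bp windows span ``tss +- 2 kbp``; each contributes the
    mean of its g25 rows (25) and the mean of its g250 rows (40), and the
    single g5k row of the block containing the TSS (45) is appended once:
    8 x 65 + 45 = 565. The raw-track equivalent would carry
    ``8 x 1014 = 8112`` columns. Windows are ordered upstream to downstream
    along the gene's strand.
    """
    cfg = model.config
    bs = model.grid.bin_size
    n = model.grid.n_bins_25(chrom)
    span = 2000
    if tss_bp - span < 0 or tss_bp + span > model.grid.length(chrom):
        raise ValueError(f"+-2 kbp around {chrom}:{tss_bp} out of bounds")
    window_bp = span // 2  # 8 windows across 4 kbp
    starts = [tss_bp - span + i * window_bp for i in range(8)]
    if strand == "-":
        starts = starts[::-1]
    g25 = model.params[("g25", chrom)]
    g250 = model.params[("g250", chrom)]
    parts = []
    for s in starts:
        b0, b1 = s // bs, (s + window_bp) // bs
        parts.append(g25[b0:b1].mean(axis=0))
        parts.append(g250[b0 // MID_RATIO:-(-b1 // MID_RATIO)].mean(axis=0))
    tss_bin = min(tss_bp // bs, n - 1)
    parts.append(model.params[("g5k", chrom)][tss_bin // COARSE_RATIO])
    out = np.concatenate(parts).astype(np.float64)
    assert len(out) == 8 * (cfg.n_g25 + cfg.n_g250) + cfg.n_g5k
    return out


def raw_track_feature_width(n_tracks: int = ROADMAP_N_TRACKS,
                            n_windows: int = 8) -> int:
    """Column count of the equivalent raw-track multi-window representation."""
    return n_windows * n_tracks


def aggregate_factors(model: EpiTensorModel, chrom: str,
                      resolution_bp: int = 40_000) -> np.ndarray:
    """Mean concatenated factors per coarse locus (default 40 kbp = 1600 bins).

    The terminal partial locus averages over its actual bins.
    """
    if resolution_bp % model.grid.bin_size:
        raise ValueError("resolution must be a multiple of the bin size")
    per = resolution_bp // model.grid.bin_size
    n = model.grid.n_bins_25(chrom)
    rows = []
    for lo in range(0, n, per):
        rows.append(genomic_factor_matrix(
            model, chrom, np.arange(lo, min(lo + per, n))).mean(axis=0))
    return np.stack(rows)


def region_feature_matrix(model: EpiTensorModel, regions: RegionSet,
                          half_width_bp: int = 250) -> np.ndarray:
    """Window-mean features at each region midpoint (rows align with regions)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for chrom, start, end, _strand, _label in regions:
            rows.append(window_factor_mean(model, chrom, (start + end) // 2,
                                           half_width_bp))
    return np.stack(rows)


# ---------------------------------------------------------------------------
# labels

def expression_labels(rna_values, gene_bodies: RegionSet, grid, chrom,
                      threshold: float = 0.5) -> np.ndarray:
    """Gene is active iff its mean gene-body coverage exceeds ``threshold``.

    Strict inequality: a mean of exactly 0.5 is inactive.
    """
    rna_values = np.asarray(rna_values, dtype=np.float64)
    labels = []
    for c, start, end, _strand, label in gene_bodies:
        if c != chrom:
            continue
        if end <= start:
            raise ValueError(f"zero-length gene {label}")
        bins = RegionSet([(c, start, end, _strand, label)]).bins(grid, chrom)
        labels.append(rna_values[bins].mean() > threshold)
    return np.array(labels, dtype=bool)


# ---------------------------------------------------------------------------
# learners

class GradientBoostedLearner:
    """XGBoost classifier with the reference hyperparameters.

    Up to 5000 estimators of depth 6, early-stopped when validation
    performance has not improved for 20 rounds; other settings default.
    """

    def __init__(self, n_estimators: int = 5000, max_depth: int = 6,
                 early_stopping_rounds: int = 20, seed: int = 0):
        self.kwargs = dict(n_estimators=n_estimators, max_depth=max_depth,
                           early_stopping_rounds=early_stopping_rounds,
                           random_state=seed)

    def fit(self, X, y, X_val, y_val):
        from xgboost import XGBClassifier
        self._clf = XGBClassifier(eval_metric="logloss", verbosity=0,
                                  **self.kwargs)
        self._clf.fit(X, y, eval_set=[(X_val, y_val)], verbose=False)
        return self

    def predict_scores(self, X):
        return self._clf.predict_proba(X)[:, 1]


class LogisticLearner:
    """L2 logistic regression; C chosen on an internal 3-fold CV.

    The grid is scikit-learn's default: 10 strengths log-spaced between
    1e-4 and 1e4.
    """

    C_GRID = np.logspace(-4, 4, 10)

    def __init__(self, seed: int = 0, max_iter: int = 2000):
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X, y, X_val=None, y_val=None):
        from sklearn.linear_model import LogisticRegressionCV, LogisticRegression
        if len(np.unique(y)) < 2:
            raise ValueError("single-class training fold")
        try:
            self._clf = LogisticRegressionCV(
                Cs=self.C_GRID, cv=3, max_iter=self.max_iter,
                random_state=self.seed).fit(X, y)
        except ValueError:
            # a class too small for 3-fold stratification: fall back to C=1
            self._clf = LogisticRegression(max_iter=self.max_iter).fit(X, y)
        return self

    def predict_scores(self, X):
        return self._clf.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# cross-validation harnesses

def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Uniform random fold assignment (sizes differ by at most one)."""
    rng = np.random.default_rng(seed)
    fold = np.arange(n) % k
    return fold[rng.permutation(n)]


def cv_classify(features, labels, learner_factory=None, k: int = 20,
                seed: int = 0) -> dict:
    """20-fold CV: per evaluation, 18 folds train, 1 validates early
    stopping, 1 tests; returns per-fold AP and their mean (MAP).

    Test folds without a positive instance are skipped with a warning and
    recorded under ``"skipped"``.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if learner_factory is None:
        learner_factory = lambda: GradientBoostedLearner(seed=seed)
    fold = make_folds(len(y), k, seed)
    aps, skipped = {}, []
    for i in range(k):
        test, val = fold == i, fold == (i + 1) % k
        train = ~(test | val)
        if not y[test].any():
            warnings.warn(f"fold {i} has no positives; skipped")
            skipped.append(i)
            continue
        learner = learner_factory().fit(X[train], y[train], X[val], y[val])
        aps[i] = average_precision(y[test], learner.predict_scores(X[test]))
    if not aps:
        raise ValueError("every test fold lacked positives")
    return {"ap_per_fold": aps, "map": float(np.mean(list(aps.values()))),
            "skipped": skipped}


def cv_pei(features, labels, seed: int = 0, n_repeats: int = 20, k: int = 5,
           learner_factory=None) -> dict:
    """Repeated shuffled k-fold logistic-regression harness.

    5-fold CV repeated 20 times with a fresh shuffle each repeat (used when
    positives are too scarce for 20 folds); AP averaged over all
    evaluations.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if int(y.sum()) < 2:
        raise ValueError("too few positive instances")
    if learner_factory is None:
        learner_factory = lambda: LogisticLearner(seed=seed)
    aps = []
    for rep in range(n_repeats):
        fold = make_folds(len(y), k, seed + rep)
        for i in range(k):
            test = fold == i
            train = ~test
            if not y[test].any() or len(np.unique(y[train])) < 2:
                continue
            learner = learner_factory().fit(X[train], y[train])
            aps.append(average_precision(y[test],
                                         learner.predict_scores(X[test])))
    return {"mean_ap": float(np.mean(aps)), "n_evaluations": len(aps)}
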