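# Methods

## The model

Epigenomic compendia form a sparse 3-D tensor indexed by cell type, assay,
and genomic position: each observed experiment is a genome-wide track of
-log10 p enrichment values binned at 25 bp, and most (cell, assay) pairs
have never been measured. `epitensor` imputes the missing tracks by deep
tensor factorization: each axis is represented by learned latent factors,
and a feed-forward network — rather than a scalar product — combines them
into a prediction.

Five embedding matrices carry the factors. At the reference widths, every
cell type has 32 factors, every assay 256, and every genomic position three
sets of factors at three scales: 25 per 25-bp bin, 40 per 250-bp bin and 45
per 5-kbp bin. The three scales encode the prior that epigenomic phenomena
operate at the scale of transcription-factor binding sites, nucleosomes,
and broad domains, and they shrink the genomic parameter count by roughly
3.4x relative to a single fine-scale embedding (≈3.4 billion instead of
≈11.5 billion genome parameters at human-genome size, as
`model.parameter_count` computes). For a prediction at (cell c, assay a,
bin g) the five factor vectors are concatenated in the fixed order
cell | assay | g25 | g250 | g5k (398 inputs at reference widths) and passed
through two ReLU hidden layers of 2048 units to a linear scalar output on
the arcsinh signal scale. The concatenation order is persisted with the
model; attribution aggregation depends on it.

All signal is transformed with arcsinh(x) = ln(x + sqrt(1+x^2)) before
training and evaluation; this variance-stabilizing transform keeps the shape
of the signal while damping outliers, and maps the -log10 p = 2 peak
threshold (p = 0.01) to 1.44.

## Training

The loss is the global MSE on the arcsinh scale, minimized with ADAM
(learning rate 0.01, beta1 0.9, beta2 0.999, epsilon 1e-8) and a per-step
learning-rate decay of 1e-8 with `lr_t = lr / (1 + decay * t)`, exposed in
`TrainingConfig`. Embeddings initialize U(-0.5, 0.5); dense
layers are Glorot-uniform; biases zero.

An **epoch** is one pass along the genomic axis: every 25-bp bin of the
training subset is visited exactly once, in a fresh seeded shuffle, paired
with one (cell, assay) drawn uniformly from the observed tracks. Only
observed tensor entries ever contribute to the loss.

Training is two-staged so genome factors never need to be resident
genome-wide: stage 1 jointly fits everything for 800 epochs on a small
pilot subset of positions; stage 2 freezes cell, assay and network weights
(byte-exactly — frozen parameters are simply never updated, and ADAM holds
no state for them) and fits the genome factors chromosome by chromosome for
a fixed number of epochs. No early stopping is used; validation loss may be
logged but never acts. Optimizer state is reset between stages. Genome
factor rows outside the pilot keep their initialization through stage 1
(zero gradient, zero moment) and are either reused or freshly re-drawn at
stage 2 (`reinitialize=True` for chromosomes absent from the pilot).

A pretrained model extends to a new cell type or assay by freezing every
existing parameter and fitting only the one new factor row
(`fit_new_entity`), which works from as little as a single observed track
because the shared network and the other axes already define the signal
space.

### Desk-scale settings

The reference topology is impractical for a CPU-only numpy run at
genome scale, so synthetic-compendium work uses a documented smaller
configuration (`ModelConfig.desk()`: 16/16 cell/assay factors, 16/8/8
genomic factors, two 128-unit hidden layers) and the training protocol of
`TrainingConfig.desk_stage1/desk_stage2`: batch size 5,000; stage 1 with
hidden-layer dropout 0.2 (inverted dropout — the standard regularizer for
this architecture, and clearly beneficial here); stage 2 for 1,000 epochs
without dropout. Two empirical observations drove these choices: the
pilot subset must contain enough peaks to teach the shared network the
factor-decoding function, so desk runs use 10% of the (50,000-bin)
chromosome rather than the 1% that is appropriate at genome scale; and at
desk scale held-in loss is still falling at 200 stage-2 epochs, so the
fixed epoch count is larger. Stage-1 dropout is what closes most of the
generalization gap to held-out (cell, assay) pairs — without it the genome
factors fit the observed tracks well but transfer poorly to unmeasured
combinations.

## Synthetic compendia

`synthetic.make_compendium` draws data with exactly the structure the model
assumes: Gaussian peak bumps (width 10–40 bins) on the -log10 p scale with
amplitudes U(4, 12); 30% of peaks constitutive (present in all cells), 70%
facultative with each cell silenced independently with probability 0.5;
per-assay response weights (each assay responds to a peak with probability
0.9, weight U(0.3, 1)); truncated Gaussian noise (sd 0.25) added on the raw
scale; arcsinh applied; 20% of tracks hidden as imputation targets. Defaults
are 6 cells x 5 assays x one 1.25-Mbp chromosome. The conditions are
calibrated so that cell-type-specific peak structure, not noise, dominates
the error of position-wise baselines; with high noise or very sparse peaks
the average-activity baseline sits at the noise floor and no imputation
method could halve it. Per-track peak calls mark bins whose noiseless
signal reaches -log10 p = 2, mimicking MACS2 output.

What the generator does **not** emulate: irregular real peak shapes,
assay-class-specific signal distributions (broad vs punctate marks),
replicate structure, mappability artifacts, and chromosome-scale domain
organization. Passing the structure-recovery check therefore demonstrates
that the implementation can recover planted low-rank-plus-nonlinearity
structure from a partially observed tensor — not that it would reproduce
real-compendium accuracy.

The held-out benchmark compares against the **average-activity baseline**:
for each held-out (cell, assay), the per-bin mean over the observed tracks
of that assay. This baseline knows where signal usually is but nothing
about the target cell type; beating half of its MSE requires recovering
cell-specific (facultative) activity. Across seeds the two-stage desk
protocol attains pooled ratios of roughly 0.40–0.47.

## Evaluation metrics

Six MSE variants per track pair: global; the top 1% of positions ranked by
observed (`mse_1obs`) or imputed (`mse_1imp`) signal, with the top-1% count
`floor(N/100)` and ties at the cutoff broken by ascending position index;
and region-restricted MSE over promoters (2 kbp upstream of the TSS,
strand-aware), gene bodies and enhancers, with bins shared by overlapping
regions deduplicated. Peak-count stratification sums per-cell MACS2 calls
per bin, discards never-peak bins, and reports MSE, precision and recall
per count after thresholding signal at 1.44 (inclusive); strata with no
predicted peaks omit precision rather than reporting 0 or NaN. Pairwise
mark relationships are Pearson correlations of per-region mean signal
(Spearman optional). Average precision uses the step formula
`sum_n (R_n - R_{n-1}) P_n` with one threshold per distinct score.

## Latent features

Per-position genomic representation: the concatenated (g25 | g250 | g5k)
vector, 110 features at reference widths. Window features average this
vector over the covered 25-bp bins (mid/coarse rows repeat across their
bins before averaging). The 8-window promoter builder spans ±2 kbp of the
TSS with eight adjacent 500-bp windows, each contributing its mean g25 and
mean g250 rows (65 features), plus the single g5k row of the block holding
the TSS: 8x65 + 45 = 565 — versus 8 x 1014 = 8112 columns for the raw-track
equivalent. (Note the window arithmetic: eight 250-bp windows would span
only ±1 kbp; 500-bp windows reconcile the ±2 kbp span with the 565-feature
count.) Coarse aggregation averages per-bin vectors over 40-kbp loci for
replication-timing / FIRE-style tasks.

Cross-validation harnesses take any learner meeting a small
`fit(X, y, X_val, y_val)` / `predict_scores(X)` contract.
`cv_classify` is 20-fold: 18 folds train, one validates early stopping, one
tests; the default learner is XGBoost (≤5000 estimators, depth 6, early
stopping after 20 stagnant rounds). `cv_pei` is 5-fold repeated 20 times
with re-shuffling, L2 logistic regression with the regularization strength
chosen from 10 log-spaced points in [1e-4, 1e4] on an internal 3-fold CV —
used when positives are too scarce for 20 folds. Fold assignment is
instance-level uniform at random (no stratification); test folds without a
positive are skipped and recorded.

## Attribution

Integrated gradients with the right-Riemann approximation: attribution_i =
(x_i - x'_i) * (1/m) * sum_k df/dx_i at x' + (k/m)(x - x'). The reference
x' is the all-zero input by default ("mean factor row" available); m
defaults to 128 and the completeness residual |sum a_i - (f(x) - f(x'))| is
reported with every result (for linear regions the formula is exact at any
m; on random small networks the residual is below 1e-3 by m = 512).
Gradients at exactly-zero ReLU pre-activations use subgradient 0.
Attributions partition into the five components by the concatenation
slices; per-bin component tracks over a region export as bedGraph, and the
stratified summary averages component attributions by (number of cell types
with a peak) x (peak present in this cell type or not), binarizing signal
at -log10 p = 2 when calls are derived from signal.

## Numerical choices and limitations

Factors and network weights are float32 (storage and compute); equality in
tests uses 1e-5 relative tolerance except for the freeze contracts, which
are byte-exact. Batched prediction may differ from row-at-a-time prediction
in the final float32 bit (BLAS summation order). bedGraph export writes 4
decimal places by default (`precision=None` gives bit-exact round trips).
Imputed values are not clipped to >= 0 unless requested. Binning uses the
coverage-weighted mean (max optional) with uncovered basepairs counted as
zero; partial terminal bins average over their actual width. Coordinates
are 0-based half-open throughout; bin i covers [25i, 25i+25).

The trainer is plain numpy on one CPU: adequate for desk-scale compendia
(minutes), not for a 1014-track genome-wide run. The PREDICTD ensemble
parameter total (92.2e9) used in the parameter-ratio arithmetic is a
documented constant, not a computation, since the comparison method's
factor widths are not part of this package.
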