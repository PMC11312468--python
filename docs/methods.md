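# Methods

## Model

The aggregator is a Deep Sets function f(X) = ρ(Σ_m φ(x_m)) over the M×D
matrix of a well's cell features. φ is a single affine map D→N followed by a
leaky ReLU (negative slope 0.01); the cell dimension is collapsed by
summation; ρ is two affine maps N→H and H→L, each followed by a leaky ReLU.
Default widths are N=2048, H=512, L=2048; the desk-scale benchmarks in the
tests and the acceptance script use N=128, H=64, L=128, which is ample for
D=20 synthetic features. The projection ρ is *not* discarded after training:
the evaluated profile is v = ρ(z), because the projection is tied to the
similarity structure the loss optimizes (the pooled z remains accessible for
ablation).

Sum pooling (not mean) is used deliberately: it preserves set-size
information, and the resulting size sensitivity is countered by training-time
set-size augmentation rather than by normalization. Weights are initialized
fan-in-scaled uniform, U(−1/√fan_in, 1/√fan_in), biases zero, from a seeded
generator.

The network, its backpropagation, and the AdamW optimizer are implemented
directly on numpy arrays. The layers are three small dense affine maps, so
the closed-form gradients are a page of code, and a dedicated tensor
framework would add nothing but weight. Two numerical choices matter:

* The first-layer affine map is computed with `einsum` rather than a BLAS
  gemm. BLAS switches kernels with the matrix shape, so the same cell row can
  produce results differing in the last bit depending on how many cells
  accompany it; einsum's per-row reduction is shape-stable.
* Pooling sums rows by balanced recursive halving (split at ⌊M/2⌋). This
  makes the pooled sum self-similar under concatenation: z(X ⊎ X) splits into
  two bit-identical halves, so it equals 2·z(X) *exactly* in floating point
  (doubling is exact in binary). General additivity z(X ⊎ Y) = z(X) + z(Y)
  holds to round-off, exactly when |X| = |Y|.

## Loss

The supervised contrastive loss is computed on L2-normalized embeddings with
temperature τ (default 0.1). Two denominator conventions are implemented and
must be chosen explicitly:

* `supcon_standard` (default): the denominator runs over all samples except
  the anchor — the definition in the original SupCon work.
* `paper_literal`: the denominator runs over different-label samples only.
  This variant can be negative (the positive term is not part of the
  denominator); its one-hot two-class value is 4(ln 2 − 1) ≈ −1.2274 versus
  4·ln(1 + 2/e) ≈ +2.2058 for the standard form.

Gradients are analytic: with S = UUᵀ/τ, dL/dU = (G + Gᵀ)U/τ where G holds the
softmax weights and positive-pair terms, then back through the normalization
u = v/‖v‖. The implementation is checked against a naive O(B²) double loop to
1e-14 and against central finite differences.

## Training

AdamW (β = 0.9/0.999, ε = 1e-8) with decoupled weight decay applied to weight
matrices only; defaults lr 5e-4, weight decay 1e-2, 100 epochs. Views are
augmented cell sets: the size is round(Normal(count_mean, count_sd)) clipped
at min_count (default 10); a coin flip (p = 0.5) decides between sampling
with replacement from one randomly chosen well or from the pooled cells of
two distinct wells of the same compound (single-well compounds always use
one well). Batches hold `compounds_per_batch` compounds × `views_per_compound`
views (8×2 by default; at least two views per compound, otherwise anchors
have no positives). `rounds_per_epoch` (default 4) controls how many such
sets are drawn per compound per epoch — more rounds mean more optimizer
steps per epoch, which is what lets the desk-scale benchmarks converge
within 40 epochs.

Validation replicate-retrieval mAP is computed from full wells (no
augmentation, no subsampling — augmentation is a training-time device only)
at every `val_every` epochs, and the returned model is the snapshot with the
highest validation mAP; without a validation table the final epoch is
returned with a warning. One global seed feeds named sub-streams
(augmentation, batch order) via `SeedSequence.spawn`, so runs are exactly
reproducible. Train/validation compound disjointness is the caller's
responsibility; the moment benchmarks deliberately validate on the training
compounds because the question they answer is *learnability* of a moment,
not generalization to unseen compounds.

## Preprocessing

Both profiling routes share: plate-level standardization of every feature to
zero mean and unit (population) variance over all cells of the plate,
computed *before* control removal so controls inform plate statistics;
removal of any cell row containing a missing value; removal of
negative-control wells (compound sentinel, default "DMSO"). The learned
aggregator consumes this table directly. The average-profile baseline
additionally takes per-well feature means, RobustMAD-normalizes per plate
(subtract the feature median over wells, divide by the median absolute
deviation + 1e-18 — no 1.4826 consistency constant; the literal
mean-absolute-deviation reading is available via `mad_statistic="mean"`),
and applies feature selection: variance threshold 1e-5, then greedy
correlation pruning at |r| > 0.9, scanning features in canonical order and
dropping the later member of each offending pair for determinism.

Numerical caveat: with an odd number of wells per plate the post-RobustMAD
feature medians are exactly zero (the median is a data point); with an even
count the midpoint median can leave a ~1-ulp residue. Zero-variance features
standardize to zeros rather than erroring — constant features are
uninformative, not fatal.

## Retrieval evaluation

Queries are individual wells. Candidates are ranked by descending cosine
similarity, ties broken by canonical well-key order (and logged). Replicate
retrieval marks other wells of the query's compound as positives; compounds
with a single well are excluded and logged. Mechanism-of-action retrieval
uses the sister-compound protocol: the query's own-compound wells are removed
from the candidate list entirely (not scored as negatives — the
own-compound-as-negatives alternative is behind a flag), positives are wells
of other compounds sharing the mechanism, and mechanisms represented by a
single compound are excluded with their compounds. APs aggregate upward:
query → compound (mean over its wells) → mechanism (mean over member
compounds) → mAP. Chance level is estimated by `random_ranking_null`, which
permutes profile-to-well assignment and reports the empirical mean and
standard deviation of the null mAP distribution.

## Interpretability

Sensitivity analysis backpropagates the contrastive loss of a loss-bearing
batch to the inputs and scores cell m as Σ_d |∂L/∂x_{m,d}|. The inference
batch is assembled like a training batch but from full wells without cell
sampling, since the loss needs label context. Critical-point analysis scores
cell m as the L1 norm of its first-layer activations, post-nonlinearity by
default (pre-activation behind a flag): under sum pooling, cells with large
first-layer activations dominate the pooled representation. Both scores are
min-max normalized per well, added, and the sum min-max normalized again;
constant score vectors (e.g. single-cell wells) map to zeros rather than
erroring. Cells with combined score > 0.8 are flagged most relevant, < 0.2
least relevant (strict inequalities). Feature attribution reports the
Pearson correlation of every input feature with the combined score, sorted
by |r|; zero-variance features are reported as undefined (NaN), not 0.

## Synthetic data

The generator emulates the structure of Cell Painting screens: `n_plates`
plates, `n_compounds` compounds with `replicates_per_compound` wells placed
either across plates (LINCS-style; replicates must be found across plates)
or within one plate (JUMP-pilot-style), DMSO control wells drawn from a
shared standard-normal null, Gaussian cells-per-well counts, per-plate
affine batch effects (offset sd `batch_effect_sd`, log-scale sd half that),
and Bernoulli missing values at `nan_rate`. Compounds are grouped into
mechanisms in blocks of `moa_groups`.

Three effect modes control where compound identity lives:

* **mean** — compound means drawn N(0, effect²·I) around a shared
  mechanism-level base mean (half the effect), identity covariance, zero
  skew. Default effect 1.0 gives well-separated populations.
* **covariance** — all compounds have zero mean and share a fixed eigenvalue
  spectrum (linear, spread set by the effect, normalized to unit mean);
  each compound gets its own Haar-random rotation of that spectrum, keeping
  marginal variances comparable while changing correlation structure.
  Generation verifies that population correlation structures are pairwise
  separated (the full effect at D=2; a third of the effect above, since
  rotation spreads differences over ~D²/2 entries) and retries the draw up
  to 50 times before raising. Default effect 0.6. Means match at the
  population level by default, which keeps replicate well means independent;
  `centering="exact"` additionally subtracts each compound's pooled sample
  mean. Exact centering is not the default because constraining R replicate
  well means to sum to zero anticorrelates them (corr −1/(R−1)), pushing the
  average-profile baseline systematically *below* chance instead of to it.
* **skewness** — standardized gamma marginals (zero mean, unit variance
  exactly in population), shape varied per compound so population skews
  2/√shape are spaced by the effect (default 0.5), tied by a shared Gaussian
  copula (uniform 0.2 correlation). Verification compares sample variances
  (ratio within (0.9, 1.1)) and skewness gaps (at least half the effect)
  when at least 5000 cells per compound are available — sample skewness of
  heavy-tailed marginals is biased low at smaller n, where only the rank
  agreement with the configured skews is checked.

`moment_benchmark` wraps the generator with batch effects, controls, and
missing values switched off, so compounds differ *only* in the named moment:
in covariance and skewness modes the per-well averages of different
compounds are statistically indistinguishable and the average-profile
baseline performs at chance — the designed contrast for the headline
property. The benchmark conditions used throughout the tests and the
acceptance script are 8 compounds × 4 replicate wells over 2 plates, 300
cells/well, D=20 features, reduced model widths (128/64/128), ≤40 training
epochs — sizes at which the full method runs in seconds per benchmark on one
CPU while leaving a wide margin between the trained model (mAP ≳ 0.5 on
skewness, ≈1.0 on covariance) and the permutation null (≈0.19).

What passing these benchmarks does *not* show: the generator draws
i.i.d. cells from parametric families, so it says nothing about spatial
context, plate-position gradients, segmentation errors, or the heavy
feature-correlation structure of real CellProfiler output; conclusions about
real screens require training on real screens.

## Known limitations

* The numpy implementation is single-threaded per layer and sized for
  desk-scale data; paper-scale widths (2048/512/2048) on millions of cells
  would want a GPU framework.
* Checkpoint files are `.npz` archives with a versioned JSON header; they
  store weights only, not optimizer state, so training cannot resume
  mid-run.
* The even-well-count RobustMAD median residue (~1 ulp) noted above.
* Hyperparameter search is out of scope; the defaults are fixed, documented
  choices.
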