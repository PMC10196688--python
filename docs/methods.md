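# Methods

`microgen` imputes whole missing samples in longitudinal microbiome
studies with a phylogeny-aware, bidirectional-recurrent adversarial
network, and ships the comparison baselines, a synthetic cohort
simulator with controllable missingness mechanisms, and an evaluation
suite. This note records the model, the numerical choices made where the
design was genuinely open, and the limits of what the synthetic
experiments can show.

## Data model and preprocessing

A cohort is a tensor of relative abundances (RA) over S subjects, k
study timepoints and n taxa, with a binary observation mask e: a sample
is either fully observed (its RA vector sums to 1) or entirely missing
(stored as a zero vector, e = 0). Timepoints are real study times (we
use months), not indices, so gap-dependent machinery sees true elapsed
time.

Zeros are replaced by a single pseudo-count c = (smallest nonzero RA in
the whole cohort) / 2. The minimum is global rather than per sample so
that the zero-restoration threshold used in post-processing is one well
defined number. Each observed sample is renormalized to sum to 1 after
adding c; centering makes this cosmetic for the subsequent centered
log-ratio (clr) transform, but it keeps every stored composition valid.
The clr transform is clr_j = ln x_j − (1/n) Σ_m ln x_m (natural log, the
compositional-data convention); every observed sample's clr values sum
to zero, and missing samples remain zero vectors.

Per subject, forward time gaps follow the recurrence δf_1 = 0, δf_i =
t_i − t_{i−1} if the previous sample is observed, accumulating across
runs of missing samples otherwise; δb is the mirror image from the end
of the series.

## Phylum clustering and OTU ordering

Taxa are partitioned by phylum. Within each cluster the Spearman
correlation matrix is computed on clr values pooled over all observed
samples (subjects × timepoints); pooling maximizes the sample count for
rank estimation. Each taxon is scored by the geometric mean of the
absolute correlations with every cluster member — the self-correlation
term is included, which rescales all scores by a common root and cannot
change their order — and clusters are sorted by that score, descending,
with deterministic lexicographic tie-breaks on taxon ids. The ordering
places co-varying OTUs next to each other so that a small 1-D
convolution along the taxon axis sees locally coherent signal. Taxa
constant across all observed samples have undefined rank correlations;
their entries are set to 0 with a warning.

## Generator

Per cluster of width ≥ 3, features are extracted by two 1-D
convolutions along the ordered-OTU axis (kernel 3, 16 then 8 filters,
same padding, stride 1), each followed by a LeakyReLU (slope 0.2) and a
max-pool of size 2 with ceil semantics; clusters narrower than the
kernel contribute their clr values unchanged. Dropout (rate 0.7) is
applied once per cluster module, on its output features, during
training only: applying it after each of the two layers would leave an
effective keep rate of 0.09, which we judged unintended. With pool size
2, a width-8 cluster yields 8 · ⌈⌈8/2⌉/2⌉ = 16 features.

The concatenated features, together with the sample's mask bit and the
direction's time gap, feed a one-layer tanh RNN (hidden size 32, a
configurable default) run forward and, independently, backward. Each
direction's output at timestep i is produced from the hidden state of
the **previous** step in that direction through a linear layer — the
one-step-ahead alignment used by recurrent imputation models (GRU-D,
BRITS). Producing the output from the same step's hidden state would
let the network copy its own input at observed timesteps and learn no
temporal structure.

The two direction outputs are blended with temporal decay factors
λ = exp(−ReLU(W δ + b)), one scalar (W, b) pair per direction,
broadcast across taxa: x̃ = λf ⊙ x̃f + λb ⊙ x̃b, with no constraint that
λf + λb = 1. The final output passes observed values through exactly:
x̄ = x ⊙ e + x̃ ⊙ (1 − e).

Numerical choices (the design was open on all of these):

- Network inputs are standardized per taxon (mean/sd over observed
  samples); missing samples remain exact zero vectors, preserving the
  x_i = 0 convention. Outputs are de-standardized by the same affine
  map, so an all-zero network output predicts the cohort mean profile.
  Without this, tanh/LSTM units saturate at initialization on clr
  values of magnitude ~7.
- Recurrent weights are initialized orthogonally (memory preservation
  over long gaps); input/output weights use Glorot uniform.
- The decay biases start at ln 2, i.e. λf = λb = 1/2 at zero gap, so
  the initial blend is the mean profile rather than twice it.
- λ is floored at 1e−30 where the exponential would underflow in
  single precision.
- All network arithmetic is float32; the final passthrough is
  recomposed in float64 so imputed output equals the input bit-for-bit
  at observed entries. Training is bit-reproducible given a seed.

## Discriminator and losses

The discriminator is a 10-unit LSTM over the k timesteps with two
heads: the final hidden state → dense → sigmoid gives the probability
that the input is real; each timestep's hidden state → dense → softmax
predicts its timepoint (k classes, target = the timestep's own index).
The real branch sees x̄ ⊙ e, the fake branch x̄ ⊙ (1 − e), both
standardized like the generator inputs. The timepoint loss is computed
on the real branch, where the true time structure is defined.

Generator loss: lossG + lossR + lossC with
lossG = −log D(x̄ ⊙ (1 − e)) (mean over subjects),
lossR = Σ_i ‖(x_i − x̃_i) e_i‖₁ / ‖e‖₁ (L1 on observed entries, pooled
over the batch), and lossC = (1/k) Σ_i ‖x̃f_i − x̃b_i‖₁ (mean over
subjects). Discriminator loss: binary cross-entropy plus the timepoint
cross-entropy. Logarithms are clamped away from 0/1 by 1e−7.

The clamped form is deliberate. The two discriminator branches have
complementary support, so the discriminator can separate them from the
zero pattern alone and eventually saturates; with a clamped loss the
adversarial term then goes inert and the generator continues to learn
from lossR + lossC. A saturation-free (softplus) form was tried and
feeds a permanent, value-free gradient into the generator that degrades
reconstruction — see Limitations.

Training: full batch (cohorts are small), separate Adam optimizers for
generator and discriminator at learning rate 1e−3, five discriminator
steps per generator step, early stopping when the total generator loss
has not reached a new minimum for `patience_epochs` (default 1000)
consecutive epochs, best weights restored, with a hard `max_epochs` cap
(default 20000). The "rnn" variant drops the discriminator and the CNN
(training on lossR + lossC, with lossG pinned at ln 2); the "bigan"
variant drops only the CNN.

## Baselines

Seven comparison imputers operate on the clr tensor with the same
observed-value-passthrough contract. Mean/median pool within subject
across time (cohort-mean fallback when a subject has no observations).
Linear/cubic fit least-squares polynomials over the observed (t, value)
pairs per subject and taxon, reducing the order when there are too few
points, with nearest-observed-value extrapolation at the edges (true
polynomial extrapolation produces wild clr values that would dominate
the MAE). Moving-window averages the observed values in a centered
3-timepoint window, expanding until it finds one. LOCF carries the last
observation forward and back-fills leading gaps with the first. MICE is
deterministic chained-equation regression per taxon (subjects as rows,
timepoints as columns), mean-initialized, 10 sweeps, single imputation,
ordinary least squares as the per-column estimator — a deliberate
simplification of full MICE that keeps results reproducible and makes
the single-predictor case equal to the closed-form regression.

## Synthetic cohorts

`generate_base_cohort` emulates the structure an infant-gut cohort
provides: per subject, a sparse Dirichlet baseline composition
(fraction `sparsity` = 0.3 of taxa structurally zero, constant over the
series), log-scale AR(1) dynamics (coefficient 0.9) with per-taxon
innovations (sd 1.0 natural-log units per visit) plus a per-phylum
drift process (sd 0.6) shared by the taxa of a phylum, which induces
the within-phylum correlation the feature extractor relies on.
Compositions are renormalized at each timepoint; timepoints are months
4, 7, …. The innovation scale was calibrated so that adjacent-visit
within-subject dissimilarity lands in the range reported for real
infant cohorts (Bray–Curtis ~0.3–0.6) rather than the near-static
regime a smaller value produces.

`perturb_subjects` implements the template-expansion recipe: each new
subject copies a random template subject; every nonzero taxon receives
additive Gaussian noise (sd 1e−6, mean drawn once per run uniformly
from [1e−6, 2e−6]); the net perturbation is re-distributed equally
across the nonzero taxa so zeros are preserved and each sample still
sums to one exactly; negatives are clipped to a 1e−12 floor and the
sample renormalized.

`ampute` removes whole samples. MCAR draws an exact-size uniform subset
of samples, repaired so no subject loses its last observed sample.
MAR/MNAR follow the weighted-sum-score mechanism: subjects are split
uniformly among missingness patterns (default: odd vs even timepoints);
each subject's score is a weighted sum of standardized per-sample
summary variables, with the to-be-amputed variables zero-weighted under
MAR and the to-be-observed variables zero-weighted under MNAR; a
logistic curve whose offset is tuned by bisection converts scores to
amputation probabilities at the requested overall rate. The summary
variable is the per-sample mean log abundance — the location term the
clr transform subtracts; the clr values themselves average to exactly
zero within each sample and carry no location information. The original
dataset is never modified; amputation returns a copy.

## Evaluation

The headline metric is clr-MAE: the mean absolute difference between
true and imputed clr values over all (missing sample, taxon) entries.
Post-processing maps clr output to RA by exponentiation and
normalization, zeroes entries below the recorded pseudo-count, and adds
the removed mass in equal parts to the remaining nonzero taxa. Alpha
diversity is the Shannon index (natural log); beta diversity is
Bray–Curtis. The diversity comparison reports the paired t-test and
Pearson correlation of Shannon values over missing samples, the Pearson
correlation of the matched upper triangles of the true and imputed
Bray–Curtis matrices, and a 2-D non-metric MDS embedding of the pooled
distance matrix (coordinates and stress only; plotting is left to the
user). Zero preservation is the symmetric difference and recall of the
zero-RA sets over missing-sample entries.

`benchmark` runs the 10-fold protocol: subjects are split into folds;
per fold, the test subjects' samples at the evaluation timepoints
(default: all interior timepoints, since a subject with no observations
is undefined for within-subject methods) are masked on top of any
existing missingness, every method imputes the masked cohort, and
clr-MAE against the ground truth is recorded. The scaled-down
configuration used by the acceptance checks is 30 subjects × 8
timepoints × 60 taxa × 4 phyla with 20% MCAR, and adversarial training
on a 300-epoch budget (within a 3000-epoch cap) with patience 100 —
sizes chosen to keep a full 5-seed, 10-fold comparison tractable on one
CPU.

## Limitations

- The adversarial objective supervises missing positions only through
  the discriminator, and the discriminator's two branches are separable
  from their support pattern alone, so its signal carries little value
  information. Consequently, at missing positions far from any observed
  sample the trained generator regresses toward the cohort-mean
  profile.
- On synthetic cohorts whose subjects carry strong idiosyncratic
  structure (subject-specific zero patterns dominate the clr scale),
  within-subject baselines (LOCF, mean, interpolation) therefore beat
  the adversarial model at this scale; the benchmark reports this
  honestly rather than asserting the opposite. Cohorts in which
  subjects share most of their structure (the template-perturbation
  design) narrow the gap but do not reverse it under the scaled-down
  training budget.
- Whole samples are missing or present; within-sample (entry-level)
  missingness is out of scope. Subjects are assumed to share one
  timepoint grid; irregular per-subject schedules degrade all methods.
- The simulator draws subjects independently given phylum drift and
  does not model sequencing noise, compositional count sampling, or
  taxon-taxon ecological interactions; passing tests on it show
  correctness of the machinery, not performance on real cohorts.
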